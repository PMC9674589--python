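"""Selection likelihood from local genealogies.

The derived-allele frequency trajectory ``x(t)`` is a latent Markov chain on
a discretized frequency grid, evolving backwards in time under a
Wright-Fisher diffusion with additive selection ``s`` inside an analysis
window (default the last 500 generations) and neutrally outside it.  The
genealogy at the focal SNP is the observation: lineages carrying the derived
allele coalesce at rate ``k(k-1)/2 / (2N x)`` per generation and ancestral
lineages at ``k(k-1)/2 / (2N (1-x))``.  A forward filter over the grid
integrates the trajectory out; the likelihood additionally conditions on the
trajectory being absorbed at frequency 0 (the mutation origin) within the
branch on which the mutation sits.

``SelectionModel`` bundles a sample of local trees with a demography and a
selection-coefficient grid; ``fit`` maximizes the tree-averaged likelihood
over the grid and reports the log-likelihood ratio against neutrality
(natural-log units throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, norm

from .demography import Demography
from .trees import LocalTree

__all__ = [
    "wf_transition",
    "TrajectoryModel",
    "tree_loglik",
    "SelectionModel",
    "SelectionFit",
    "SelectionResult",
    "fit_selection",
    "replicate_median",
    "allele_age",
    "default_s_grid",
]


def wf_transition(x: float, s: float, N: float, dt: float = 1.0):
    """Forward-time mean and variance of the Wright-Fisher frequency change.

    ``mean = clip(x + s x (1-x) dt, 0, 1)``; ``variance = x(1-x) dt / (2N)``
    with diploid ``N``.  The boundaries are absorbing (zero variance).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must be in [0, 1]")
    if N < 2 or dt < 0:
        raise ValueError("need N >= 2 and dt >= 0")
    mean = min(max(x + s * x * (1.0 - x) * dt, 0.0), 1.0)
    var = x * (1.0 - x) * dt / (2.0 * N)
    return mean, var


def default_s_grid(n_per_side: int = 6, s_min: float = 1e-4, s_max: float = 0.2):
    """Symmetric log-spaced selection grid over ±[s_min, s_max] plus 0."""
    pos = np.logspace(np.log10(s_min), np.log10(s_max), n_per_side)
    return np.concatenate([-pos[::-1], [0.0], pos])


@dataclass
class TrajectoryModel:
    """Latent frequency-trajectory model for one selection coefficient.

    ``window = (t_start, t_end)`` in generations ago bounds the period in
    which selection acts; outside it the trajectory is neutral.  The grid
    has ``n_bins`` logit-spaced interior bins on ``(grid_lo, 1-grid_lo)``
    plus an absorbing origin state at frequency 0.  ``fixed_freq`` clamps
    the trajectory to a constant (used for closed-form checks);
    ``anchor='binomial'`` weights the initial state by the binomial
    likelihood of the observed derived count.
    """

    demography: Demography
    s: float = 0.0
    window: tuple[float, float] = (0.0, 500.0)
    n_bins: int = 50
    grid_lo: float = 5e-4
    freq_grid: np.ndarray | None = None
    fixed_freq: float | None = None
    anchor: str = "binomial"

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("window must satisfy t_start <= t_end")
        if self.freq_grid is not None:
            g = np.asarray(self.freq_grid, dtype=float)
            if np.any(np.diff(g) <= 0) or g[0] <= 0 or g[-1] >= 1:
                raise ValueError("freq_grid must be strictly increasing in (0,1)")
            self.freq_grid = g

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin edges, bin centers) of the interior frequency grid."""
        if self.freq_grid is not None:
            c = self.freq_grid
            inner = 0.5 * (c[1:] + c[:-1])
            edges = np.concatenate([[max(c[0] / 2, 1e-8)], inner, [(1 + c[-1]) / 2]])
            return edges, c
        lo = self.grid_lo
        z = np.linspace(np.log(lo / (1 - lo)), np.log((1 - lo) / lo), self.n_bins + 1)
        edges = 1.0 / (1.0 + np.exp(-z))
        centers = 0.5 * (edges[1:] + edges[:-1])
        return edges, centers


# ---------------------------------------------------------------------------
# transition matrices (augmented with the absorbing origin state)
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict = {}
_STACK_CACHE: dict = {}


def _aug_matrix(s: float, N: float, dt: int, edges: np.ndarray, centers: np.ndarray):
    """Backward-time transition matrix over interior bins + origin state.

    The backward drift is ``-s x (1-x) - x/(2N)`` per generation: the
    selection term reversed in time plus the h-transform conditioning drift
    of a segregating allele traced back to its origin (applied at every s so
    likelihood ratios stay fair).  The variance is ``x(1-x)/(2N)`` per
    generation.  For a ``dt``-generation segment the moments are integrated
    along the deterministic mean path and discretized as one Gaussian over
    the bin edges; the source mass is treated as uniform within its bin
    (3-point quadrature), which keeps diffusion faithful even where a single
    generation's spread is much smaller than a bin.  Mass crossing the
    lowest edge is absorbed at the origin state.
    """
    key = (round(float(s), 12), round(float(N), 6), int(dt), edges.tobytes())
    hit = _MATRIX_CACHE.get(key)
    if hit is not None:
        return hit
    n = len(centers)
    width = np.diff(edges)
    # three quadrature points per source bin (uniform-within-bin source)
    offs = np.array([1.0 / 6.0, 0.5, 5.0 / 6.0])
    x0 = (edges[:-1][:, None] + offs[None, :] * width[:, None]).ravel()
    # integrate mean and variance along the deterministic backward path
    nsub = int(min(max(dt, 1), 64))
    h = dt / nsub
    x = x0.copy()
    var = np.zeros_like(x)
    for _ in range(nsub):
        var += x * (1.0 - x) / (2.0 * N) * h
        x = np.clip(x + (-s * x * (1.0 - x) - x / (2.0 * N)) * h, 0.0, 1.0)
    sd = np.sqrt(np.maximum(var, 1e-20))
    cdf = norm.cdf((edges[None, :] - x[:, None]) / sd[:, None])
    T3 = np.diff(cdf, axis=1)
    a3 = cdf[:, 0]  # below the lowest edge: mutation origin
    T3[:, -1] += 1.0 - cdf[:, -1]  # clip spill at the top
    T = T3.reshape(n, 3, n).mean(axis=1)
    a = a3.reshape(n, 3).mean(axis=1)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = T
    aug[:n, n] = a
    aug[n, n] = 1.0
    _MATRIX_CACHE[key] = aug
    return aug


_DT_STEPS = (256, 192, 128, 96, 64, 48, 32, 24, 16, 12, 8, 6, 4, 3, 2, 1)


def _split_dt(length: int) -> list[int]:
    """Greedy decomposition of a segment into few cached step sizes."""
    out, rest = [], int(length)
    while rest > 0:
        for d in _DT_STEPS:
            if d <= rest:
                out.append(d)
                rest -= d
                break
    return out


# ---------------------------------------------------------------------------
# the forward filter
# ---------------------------------------------------------------------------


def _coal_hazard(k: int, two_n_x: np.ndarray) -> np.ndarray:
    """Per-generation coalescence hazard for k lineages among 2N·x copies.

    The filter uses the continuous-hazard convention: survival over dt
    generations is ``exp(-hazard*dt)`` and a coalescence event contributes
    the hazard as a density, matching the exponential waiting times of the
    structured-coalescent genealogy sampler.
    """
    if k < 2:
        return np.zeros_like(two_n_x)
    return k * (k - 1) / 2.0 / np.maximum(two_n_x, 1e-12)


def _tree_loglik_multi(
    tree: LocalTree, model: TrajectoryModel, s_values: np.ndarray
) -> np.ndarray:
    """Log-likelihood of one tree for every s in ``s_values`` (batched)."""
    n, d = tree.n_leaves, tree.n_derived
    if d == 0 or d == n:
        raise ValueError("monomorphic at focal SNP: derived class empty or full")
    sched = tree.class_schedule()
    if model.fixed_freq is not None:
        return _fixed_freq_loglik(tree, model, s_values, sched)

    edges, centers = model.grid()
    nb = len(centers)
    s_values = np.asarray(s_values, dtype=float)
    n_s = len(s_values)
    dem = model.demography
    win_start, win_end = model.window

    # integerized event times (generation resolution)
    t_child = int(round(sched.t_child))
    has_parent = np.isfinite(sched.t_parent)
    t_parent = int(round(sched.t_parent)) if has_parent else None
    if has_parent and t_parent <= t_child:
        t_parent = t_child + 1
    t_end = t_parent if has_parent else t_child
    ev_d = [max(1, int(round(t))) for t in sched.derived_times]
    ev_a = [max(1, int(round(t))) for t in sched.ancestral_times if t <= t_end]

    # breakpoints: events, window bounds, epoch changes, branch interval ends
    bps = set(ev_d) | set(ev_a) | {t_end}
    for t0 in (win_start, win_end, t_child):
        if 0 < t0 < t_end:
            bps.add(int(round(t0)))
    for st in dem.starts:
        if 0 < st < t_end:
            bps.add(int(st))
    bps = sorted(bps)

    # initial state: sample-frequency anchor
    if model.anchor == "binomial":
        w0 = binom.pmf(d, n, centers)
    else:
        w0 = np.ones(nb)
    state = np.zeros((n_s, nb + 1))
    state[:, :nb] = w0[None, :]
    loglik = np.zeros(n_s)
    tot = state.sum(axis=1)
    state /= tot[:, None]
    loglik += np.log(tot)

    from collections import Counter

    ev_d_count, ev_a_count = Counter(ev_d), Counter(ev_a)
    kd, ka = d, n - d
    t = 0
    dead = np.zeros(n_s, dtype=bool)
    for b in bps:
        if b > t_end:
            break
        # constant (kd, ka, N, selection-active) between breakpoints: epoch
        # starts and window bounds are breakpoints themselves
        for dt in _split_dt(b - t):
            seg_n = dem.size_at(t + 0.5)
            in_window = t + dt <= win_end and t >= win_start
            absorb_ok = t >= t_child
            two_n = 2.0 * seg_n
            h_d = _coal_hazard(kd, two_n * centers)
            h_a = _coal_hazard(ka, two_n * (1.0 - centers))
            is_event_step = t + dt == b
            n_ev_d = ev_d_count.get(b, 0) if is_event_step else 0
            n_ev_a = ev_a_count.get(b, 0) if is_event_step else 0
            # exponential survival over the dt generations
            emit = np.exp(-(h_d + h_a) * dt)
            h_a0 = _coal_hazard(ka, np.array([two_n]))[0]  # ancestral rate at x=0
            emit_origin = np.exp(-h_a0 * dt) if kd <= 1 else 0.0
            if in_window:
                skey = (s_values.tobytes(), round(seg_n, 6), dt, edges.tobytes())
                mats = _STACK_CACHE.get(skey)
                if mats is None:
                    mats = np.stack(
                        [_aug_matrix(sv, seg_n, dt, edges, centers) for sv in s_values]
                    )
                    _STACK_CACHE[skey] = mats
                state = np.einsum("si,sij->sj", state, mats)
            else:
                mat = _aug_matrix(0.0, seg_n, dt, edges, centers)
                state = state @ mat
            if not absorb_ok:
                state[:, nb] = 0.0
            state[:, :nb] *= emit[None, :]
            state[:, nb] *= emit_origin
            # coalescence-event emissions (hazard as density)
            for cls, cnt in (("d", n_ev_d), ("a", n_ev_a)):
                for _ in range(cnt):
                    if cls == "d":
                        hk = _coal_hazard(kd, two_n * centers)
                        state[:, :nb] *= hk[None, :]
                        state[:, nb] = 0.0  # derived event impossible post-origin
                        kd -= 1
                    else:
                        hk = _coal_hazard(ka, two_n * (1.0 - centers))
                        state[:, :nb] *= hk[None, :]
                        state[:, nb] *= _coal_hazard(ka, np.array([two_n]))[0]
                        ka -= 1
            tot = state.sum(axis=1)
            alive = tot > 0
            dead |= ~alive
            tot[~alive] = 1.0
            state /= tot[:, None]
            state[dead] = 0.0
            loglik += np.where(dead, -np.inf, np.log(tot))
            t += dt
    if has_parent:
        final = state[:, nb]
    else:
        final = state.sum(axis=1)
    with np.errstate(divide="ignore"):
        out = loglik + np.log(final)
    return out


def _fixed_freq_loglik(tree, model, s_values, sched):
    """Trajectory clamped to a constant frequency: exponential survival plus
    hazard densities for each class-internal coalescence, up to the last
    event (no origin conditioning in clamped mode)."""
    x = float(model.fixed_freq)
    n, d = tree.n_leaves, tree.n_derived
    dem = model.demography
    events = [(max(1, int(round(t))), "d") for t in sched.derived_times] + [
        (max(1, int(round(t))), "a") for t in sched.ancestral_times
    ]
    events.sort()
    ll = binom.logpmf(d, n, x) if model.anchor == "binomial" else 0.0
    kd, ka = d, n - d
    t = 0
    for te, cls in events:
        for g in range(t, te):
            two_n = 2.0 * dem.size_at(g + 0.5)
            h_d = _coal_hazard(kd, np.array([two_n * x]))[0]
            h_a = _coal_hazard(ka, np.array([two_n * (1 - x)]))[0]
            ll -= h_d + h_a
        two_n = 2.0 * dem.size_at(te - 0.5)
        if cls == "d":
            ll += np.log(_coal_hazard(kd, np.array([two_n * x]))[0])
            kd -= 1
        else:
            ll += np.log(_coal_hazard(ka, np.array([two_n * (1 - x)]))[0])
            ka -= 1
        t = te
    return np.full(len(np.atleast_1d(s_values)), ll)


def tree_loglik(tree: LocalTree, model: TrajectoryModel) -> float:
    """Log-likelihood of a local tree under a trajectory model with ``model.s``."""
    return float(_tree_loglik_multi(tree, model, np.array([model.s]))[0])


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class SelectionModel:
    """Per-SNP selection model over a sample of local trees.

    Parameters
    ----------
    trees
        One or more :class:`LocalTree` replicates for the focal SNP (e.g.
        independent draws of the genealogy).  All must share the same leaf
        count and derived count.
    demography
        Piecewise-constant diploid population size.
    s_grid
        Candidate selection coefficients; must contain 0 so that the
        likelihood ratio against neutrality is well defined.
    """

    def __init__(
        self,
        trees: list[LocalTree] | LocalTree,
        demography: Demography,
        s_grid: np.ndarray | None = None,
        window: tuple[float, float] = (0.0, 500.0),
        n_bins: int = 50,
        grid_lo: float = 5e-4,
        anchor: str = "binomial",
        snp_id: str | None = None,
    ) -> None:
        self.trees = [trees] if isinstance(trees, LocalTree) else list(trees)
        if not self.trees:
            raise ValueError("need at least one local tree")
        nd = {(t.n_leaves, t.n_derived) for t in self.trees}
        if len(nd) != 1:
            raise ValueError("all tree replicates must share (n_leaves, n_derived)")
        self.demography = demography
        self.s_grid = (
            default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
        )
        if not np.any(self.s_grid == 0.0):
            raise ValueError("s_grid must contain 0 (the neutral model)")
        self.window = window
        self.n_bins = n_bins
        self.grid_lo = grid_lo
        self.anchor = anchor
        self.snp_id = snp_id

    def _template(self, s: float = 0.0) -> TrajectoryModel:
        return TrajectoryModel(
            demography=self.demography,
            s=s,
            window=self.window,
            n_bins=self.n_bins,
            grid_lo=self.grid_lo,
            anchor=self.anchor,
        )

    def loglik_profile(self) -> np.ndarray:
        """Tree-averaged log-likelihood at every grid point.

        Averaging is in likelihood space across the tree sample (the sample
        stands in for draws of the branch-length posterior).
        """
        per_tree = np.stack(
            [_tree_loglik_multi(t, self._template(), self.s_grid) for t in self.trees]
        )  # (n_trees, n_s)
        return logsumexp(per_tree, axis=0) - np.log(len(self.trees))

    def fit(self) -> "SelectionFit":
        profile = self.loglik_profile()
        i_null = int(np.flatnonzero(self.s_grid == 0.0)[0])
        if not np.any(np.isfinite(profile)):
            # degenerate tree/grid combination: fall back to the null
            i_hat, logLR = i_null, 0.0
        else:
            i_hat = int(np.nanargmax(np.where(np.isfinite(profile), profile, -np.inf)))
            logLR = float(profile[i_hat] - profile[i_null])
            if not np.isfinite(logLR):
                logLR = 0.0
        ages = [allele_age(t) for t in self.trees]
        return SelectionFit(
            model=self,
            s_hat=float(self.s_grid[i_hat]),
            logLR=max(logLR, 0.0),
            loglik_profile=profile,
            allele_age_generations=float(np.median(ages)),
            derived_freq=self.trees[0].n_derived / self.trees[0].n_leaves,
        )


@dataclass
class SelectionFit:
    """Results of one :meth:`SelectionModel.fit` run."""

    model: SelectionModel
    s_hat: float
    logLR: float
    loglik_profile: np.ndarray
    allele_age_generations: float
    derived_freq: float

    @property
    def s_grid(self) -> np.ndarray:
        return self.model.s_grid

    def support_interval(self, drop: float = 1.92) -> tuple[float, float]:
        """Grid-based likelihood support interval (default ~95%: ΔlogL 1.92)."""
        ok = self.loglik_profile >= self.loglik_profile.max() - drop
        return float(self.s_grid[ok].min()), float(self.s_grid[ok].max())

    def summary(self) -> str:
        lo, hi = self.support_interval()
        dem = self.model.demography
        lines = [
            "Selection likelihood fit",
            "=" * 44,
            f"SNP id:              {self.model.snp_id or '-'}",
            f"trees in sample:     {len(self.model.trees)}",
            f"derived frequency:   {self.derived_freq:.4f}",
            f"s_hat:               {self.s_hat:+.5g}",
            f"support interval:    [{lo:+.4g}, {hi:+.4g}]",
            f"logLR vs neutrality: {self.logLR:.4f}",
            f"allele age:          {self.allele_age_generations:.1f} generations"
            f" ({dem.generations_to_years(self.allele_age_generations):.0f} y)",
            f"window (gen ago):    {self.model.window}",
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):  # pragma: no cover - convenience plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.s_grid, self.loglik_profile, marker="o")
        ax.axvline(self.s_hat, ls="--", color="C1")
        ax.set_xlabel("selection coefficient s")
        ax.set_ylabel("log-likelihood")
        return ax


def fit_selection(
    trees,
    demography: Demography,
    s_grid: np.ndarray | None = None,
    **kwargs,
) -> SelectionFit:
    """Functional wrapper: grid MLE of s and logLR for a sample of trees."""
    return SelectionModel(trees, demography, s_grid=s_grid, **kwargs).fit()


# ---------------------------------------------------------------------------
# replicate-median rule and allele age
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Aggregated per-SNP selection call (median over stochastic runs)."""

    snp_id: str | None
    s_hat: float
    logLR_replicates: list[float]
    logLR_median: float
    s_median: float
    allele_age_generations: float
    derived_freq: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.logLR_replicates and not np.isclose(
            self.logLR_median, float(np.median(self.logLR_replicates))
        ):
            raise ValueError("logLR_median must be the median of the replicates")


def replicate_median(run, snp_id: str | None = None, max_diff: float = 2.0):
    """Run a stochastic selection fit 2-3 times and report medians.

    ``run(i)`` must return an object with ``logLR``, ``s_hat``,
    ``allele_age_generations`` and ``derived_freq`` (e.g. a
    :class:`SelectionFit` on a fresh tree sample).  A third run is added only
    when the first two logLR values differ by more than ``max_diff`` units.
    """
    fits = [run(0), run(1)]
    if abs(fits[0].logLR - fits[1].logLR) > max_diff:
        fits.append(run(2))
    loglrs = [float(f.logLR) for f in fits]
    ss = [float(f.s_hat) for f in fits]
    return SelectionResult(
        snp_id=snp_id,
        s_hat=float(np.median(ss)),
        logLR_replicates=loglrs,
        logLR_median=float(np.median(loglrs)),
        s_median=float(np.median(ss)),
        allele_age_generations=float(np.median([f.allele_age_generations for f in fits])),
        derived_freq=float(fits[0].derived_freq),
        meta={"n_runs": len(fits)},
    )


def allele_age(
    tree: LocalTree, root_branch_offset: float = 0.0
) -> float:
    """Approximate allele age: midpoint of the mutation branch, in generations.

    When the mutation branch hangs above the root (no parent time) the lower
    end plus ``root_branch_offset`` is returned; callers can detect the case
    through ``tree.t_parent`` being infinite.
    """
    t_child, t_parent = tree.t_child, tree.t_parent
    if not np.isfinite(t_parent):
        return t_child + root_branch_offset
    return 0.5 * (t_child + t_parent)
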
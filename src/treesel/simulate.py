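"""Synthetic-data generators with known selection ground truth.

This module provides the study's simulated inputs end to end:

* forward Wright-Fisher allele-frequency trajectories with additive
  selection (:func:`simulate_trajectory`);
* backward neutral trajectories for segregating alleles, used to build
  demography-matched null distributions (:func:`backward_neutral_trajectories`);
* structured-coalescent genealogies conditioned on a trajectory
  (:func:`sample_genealogy`), giving ground-truth local trees without any
  tree inference;
* a desk-scale forward Wright-Fisher haplotype simulator with recombination
  and infinite-sites mutation (:func:`simulate_haplotypes`), which tracks the
  true genealogy at a selected site;
* a fast neutral coalescent haplotype source backed by msprime
  (:func:`coalescent_haplotypes`) for large neutral fixtures;
* scenario fixtures for the hitchhiker classifier (:func:`make_locus_fixture`).

Frequencies are stored present-backwards: index ``t`` of a trajectory is the
frequency ``t`` generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .demography import Demography, SimParams
from .haplotypes import HaplotypeMatrix
from .trees import LocalTree

__all__ = [
    "Trajectory",
    "SimulationError",
    "simulate_trajectory",
    "conditioned_sweep_trajectory",
    "backward_neutral_trajectories",
    "sample_genealogy",
    "simulate_haplotypes",
    "coalescent_haplotypes",
    "make_locus_fixture",
]


class SimulationError(RuntimeError):
    """A stochastic generator failed to produce the requested configuration."""


@dataclass
class Trajectory:
    """Derived-allele frequency through time.

    ``freqs[t]`` is the frequency ``t`` generations before present
    (``freqs[0]`` is today).  Frequency 0 is absorbing looking backwards: the
    first index at which the trajectory hits 0 is the allele's origin.
    """

    freqs: np.ndarray
    s_true: float
    demography: Demography
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def present_freq(self) -> float:
        return float(self.freqs[0])

    @property
    def freqs_forward(self) -> np.ndarray:
        """The same trajectory in forward time (index 0 = oldest)."""
        return self.freqs[::-1]

    @property
    def origin_generation(self) -> float | None:
        """First generation ago at which the frequency is 0, if any."""
        zeros = np.flatnonzero(self.freqs == 0.0)
        return int(zeros[0]) if zeros.size else None


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectory(
    s: float,
    demography: Demography,
    init_freq: float,
    n_generations: int,
    seed: int | None = None,
    deterministic: bool = False,
) -> Trajectory:
    """Forward binomial Wright-Fisher trajectory with additive selection.

    The expected per-generation change is ``s * x * (1 - x)`` (genic
    selection, linearized); sampling is binomial over the ``2N`` copies of
    the epoch in force at each generation.  ``init_freq`` applies
    ``n_generations`` generations before present.  With ``deterministic``
    the infinite-population mean path is returned.
    """
    if not 0.0 <= init_freq <= 1.0:
        raise ValueError("init_freq must be in [0, 1]")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    x = float(init_freq)
    forward = np.empty(n_generations + 1)
    forward[0] = x
    for g in range(1, n_generations + 1):
        t_ago = n_generations - g
        if x in (0.0, 1.0):
            forward[g] = x
            continue
        p = min(max(x + s * x * (1.0 - x), 0.0), 1.0)
        if deterministic:
            x = p
        else:
            two_n = int(round(2.0 * demography.size_at(t_ago)))
            x = rng.binomial(two_n, p) / two_n
        forward[g] = x
    return Trajectory(
        freqs=forward[::-1].copy(),
        s_true=s,
        demography=demography,
        meta={"seed": seed, "deterministic": deterministic},
    )


def backward_neutral_trajectories(
    present_freqs: np.ndarray,
    demography: Demography,
    seed: int | None = None,
    max_generations: int = 200_000,
) -> list[Trajectory]:
    """Neutral trajectories run backwards from the present to the origin.

    Going back in time, a segregating neutral allele under the stationary
    1/x influx density evolves as a Wright-Fisher walk with drift
    ``-x / (2N)`` per generation (the h-transform of neutral drift towards
    absorption at 0).  Each trajectory ends with its first 0, the mutation
    origin.  Walkers not absorbed within ``max_generations`` are force
    absorbed and flagged in ``meta['forced_origin']``.

    The batch is simulated in two vectorized passes with the same random
    stream: the first records absorption times, the second fills exact-length
    frequency arrays.
    """
    present_freqs = np.asarray(present_freqs, dtype=float)
    if np.any((present_freqs <= 0) | (present_freqs >= 1)):
        raise ValueError("present frequencies must be strictly inside (0, 1)")
    n = present_freqs.size

    def _run(buf: np.ndarray | None, offsets: np.ndarray | None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        x = present_freqs.copy()
        active = np.arange(n)
        lengths = np.full(n, max_generations + 1, dtype=np.int64)
        if buf is not None:
            buf[offsets] = present_freqs
        t = 0
        while active.size and t < max_generations:
            t += 1
            two_n = int(round(2.0 * demography.size_at(t)))
            p = x[active] * (1.0 - 1.0 / two_n)
            k = rng.binomial(two_n, p)
            xa = k / two_n
            x[active] = xa
            if buf is not None:
                buf[offsets[active] + t] = xa
            absorbed = xa == 0.0
            if absorbed.any():
                lengths[active[absorbed]] = t + 1
                active = active[~absorbed]
        return lengths

    lengths = _run(None, None)
    forced = lengths > max_generations
    lengths = np.minimum(lengths, max_generations + 1)
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
    buf = np.zeros(int(lengths.sum()))
    _run(buf, offsets)
    out = []
    for i in range(n):
        freqs = buf[offsets[i] : offsets[i] + lengths[i]].copy()
        freqs[-1] = 0.0  # force-absorb stragglers at the cap
        out.append(
            Trajectory(
                freqs=freqs,
                s_true=0.0,
                demography=demography,
                meta={"seed": seed, "walker": i, "forced_origin": bool(forced[i])},
            )
        )
    return out


def conditioned_sweep_trajectory(
    s: float,
    demography: Demography,
    target_freq: float = 0.6,
    seed: int | None = None,
    max_generations: int = 5000,
    max_retries: int = 500,
) -> Trajectory:
    """Selected-allele trajectory conditioned on reaching ``target_freq``.

    Forward binomial Wright-Fisher from a single copy with additive
    selection ``s``; runs are restarted until one segregates up to the
    target frequency, which becomes the present day (an ongoing sweep).
    The backward-stored trajectory ends at the mutation origin.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        two_n = int(round(2.0 * demography.size_at(0)))
        x = 1.0 / two_n
        path = [x]
        for _ in range(max_generations):
            p = min(max(x + s * x * (1.0 - x), 0.0), 1.0)
            x = rng.binomial(two_n, p) / two_n
            path.append(x)
            if x == 0.0 or x >= target_freq:
                break
        if x >= target_freq:
            return Trajectory(
                freqs=np.array(path[::-1] + [0.0]),
                s_true=s,
                demography=demography,
                meta={"seed": seed, "attempt": attempt, "target_freq": target_freq},
            )
    raise SimulationError(
        f"no trajectory reached frequency {target_freq} in {max_retries} attempts "
        f"(s={s})"
    )


# ---------------------------------------------------------------------------
# structured coalescent conditioned on a trajectory
# ---------------------------------------------------------------------------


def _inverse_hazard(cum: np.ndarray, start: float, target: float) -> float:
    """Smallest time with cumulative hazard >= target, linearly interpolated.

    ``cum[i]`` is the hazard accumulated over generations [0, i); returns inf
    if the target is not reached within the array.
    """
    i0 = int(np.floor(start))
    frac = start - i0
    if i0 >= len(cum) - 1:
        return np.inf
    base = cum[i0] + frac * (cum[i0 + 1] - cum[i0]) if i0 + 1 < len(cum) else cum[i0]
    goal = base + target
    if goal > cum[-1]:
        return np.inf
    j = int(np.searchsorted(cum, goal, side="left"))
    j = max(j, i0 + 1)
    lo, hi = cum[j - 1], cum[j]
    f = 0.0 if hi <= lo else (goal - lo) / (hi - lo)
    return float(max(j - 1 + f, start + 1e-9))


def _epochwise_exponential(
    demography: Demography, k: int, t0: float, rng: np.random.Generator
) -> float:
    """Next single-class coalescence time after ``t0`` under piecewise-constant N."""
    pairs = k * (k - 1) / 2.0
    target = rng.exponential()
    t = t0
    while True:
        N = demography.size_at(t)
        t_next = demography.next_change_after(t)
        rate = pairs / (2.0 * N)
        span = t_next - t
        if rate * span >= target:
            return t + target / rate
        target -= rate * span
        t = t_next


def sample_genealogy(
    trajectory: Trajectory,
    n_samples: int,
    n_derived: int,
    seed: int | None = None,
) -> LocalTree:
    """Sample a local tree conditional on a derived-allele trajectory.

    Lineages are split into a derived class (coalescing at rate
    ``k(k-1)/2 / (2N x(t))`` per generation) and an ancestral class (rate
    ``k(k-1)/2 / (2N (1-x(t)))``).  At the mutation origin (first backward
    time with ``x = 0``) the single remaining derived lineage joins the
    ancestral class and the standard coalescent continues to the root.
    Derived lineages still uncoalesced at the origin are force-joined just
    below it (flagged in ``tree.meta``).

    When ``n_derived == n_samples`` the sampler degenerates to a single-class
    coalescent along the trajectory (no origin required).
    """
    if not 1 <= n_derived <= n_samples:
        raise ValueError("need 1 <= n_derived <= n_samples")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    x = trajectory.freqs
    dem = trajectory.demography
    origin = trajectory.origin_generation
    single_class = n_derived == n_samples
    if origin is None and not single_class:
        raise SimulationError(
            "trajectory never reaches the mutation origin (frequency 0): "
            f"min frequency {x.min():.4g} over {len(x)} generations; extend the "
            "trajectory or check the demography"
        )
    horizon = origin if origin is not None else len(x) - 1
    t_gens = np.arange(horizon)
    two_n = 2.0 * dem.sizes(t_gens)
    xx = np.clip(x[:horizon], 1.0 / two_n, 1.0)
    lam_d = 1.0 / (two_n * xx)
    lam_a = 1.0 / (two_n * np.clip(1.0 - xx, 1.0 / two_n, 1.0))
    cum_d = np.concatenate([[0.0], np.cumsum(lam_d)])
    cum_a = np.concatenate([[0.0], np.cumsum(lam_a)])

    labels = tuple(f"hap{i}" for i in range(n_samples))
    parent = list(np.full(n_samples, -1, dtype=np.int64))
    times = [0.0] * n_samples
    derived = list(range(n_derived))
    ancestral = list(range(n_derived, n_samples))
    next_node = n_samples
    forced = False
    t = 0.0

    def merge(pool: list[int], when: float) -> int:
        nonlocal next_node
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        node = next_node
        next_node += 1
        parent.append(-1)
        times.append(when)
        parent[a] = node
        parent[b] = node
        pool[:] = [v for v in pool if v not in (a, b)] + [node]
        return node

    # two-class phase along the trajectory
    while len(derived) > 1 or len(ancestral) > 1:
        kd, ka = len(derived), len(ancestral)
        td = (
            _inverse_hazard(cum_d, t, rng.exponential() / (kd * (kd - 1) / 2.0))
            if kd > 1
            else np.inf
        )
        ta = (
            _inverse_hazard(cum_a, t, rng.exponential() / (ka * (ka - 1) / 2.0))
            if ka > 1
            else np.inf
        )
        if not np.isfinite(min(td, ta)):
            break
        if td <= ta:
            t = td
            merge(derived, t)
        else:
            t = ta
            merge(ancestral, t)

    if single_class:
        # extend beyond the trajectory with its last frequency if needed
        while len(derived) > 1:
            k = len(derived)
            t = _epochwise_exponential(dem, k, max(t, float(horizon)), rng)
            merge(derived, t)
        tree = LocalTree(
            np.array(parent), np.array(times), labels, derived[0],
            meta={"seed": seed, "forced_origin_merges": False},
        )
        return tree

    # force-resolve derived lineages that survive to the origin
    eps = 1e-6
    while len(derived) > 1:
        forced = True
        t = origin - eps * (len(derived) - 1)
        merge(derived, t)
    mutation_node = derived[0]

    # single merged class from the origin to the root
    pool = ancestral + [mutation_node]
    t = max(t, float(origin))
    while len(pool) > 1:
        t = _epochwise_exponential(dem, len(pool), t, rng)
        merge(pool, t)

    return LocalTree(
        np.array(parent),
        np.array(times),
        labels,
        mutation_node,
        meta={"seed": seed, "forced_origin_merges": forced, "origin": float(origin)},
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher haplotype simulation
# ---------------------------------------------------------------------------

_MAX_FORWARD_N = 500  # diploids; forward simulation is desk scale by design


def _make_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    length: float,
    recomb_rate: float,
    site: float | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Recombine two parental haplotypes; return gamete and the index (0/1)
    of the parental haplotype that contributes position ``site``."""
    n_break = rng.poisson(recomb_rate * length)
    first = int(rng.integers(2))
    if n_break == 0:
        gam = hap_a if first == 0 else hap_b
        return gam.copy(), first
    breaks = np.sort(rng.random(n_break) * length)
    edges = np.concatenate([[0.0], breaks, [length]])
    pieces = []
    src_at_site = first
    for seg in range(len(edges) - 1):
        hap = hap_a if (first + seg) % 2 == 0 else hap_b
        lo, hi = edges[seg], edges[seg + 1]
        pieces.append(hap[np.searchsorted(hap, lo) : np.searchsorted(hap, hi)])
        if site is not None and lo <= site < hi:
            src_at_site = (first + seg) % 2
    return np.concatenate(pieces), src_at_site


def _drop_fixed(pop: list[np.ndarray]) -> list[np.ndarray]:
    allpos, counts = np.unique(np.concatenate(pop), return_counts=True)
    fixed = allpos[counts == len(pop)]
    if fixed.size == 0:
        return pop
    return [hap[~np.isin(hap, fixed)] for hap in pop]


def _int_positions(float_pos: np.ndarray) -> np.ndarray:
    ipos = np.floor(float_pos).astype(np.int64) + 1
    for i in range(1, len(ipos)):
        if ipos[i] <= ipos[i - 1]:
            ipos[i] = ipos[i - 1] + 1
    return ipos


def simulate_haplotypes(
    params: SimParams,
    demography: Demography,
    selected_site: tuple[float, float, int] | None = None,
    seed: int | None = None,
    burn_in: int | None = None,
    max_retries: int = 20,
    final_freq_range: tuple[float, float] = (0.0, 1.0),
    mask=None,
):
    """Forward discrete-generation Wright-Fisher haplotype simulation.

    Recombination is uniform at ``params.recombination_rate`` per bp per
    generation; mutation is infinite-sites at ``params.mutation_rate`` per bp
    per generation.  ``selected_site`` is ``(position, s, onset_generation)``:
    a single derived mutation injected ``onset_generation`` generations
    before present into one haplotype, with additive fitness ``1 + s`` per
    copy thereafter.  If the selected allele is lost (or its final frequency
    falls outside ``final_freq_range``) the sweep phase is retried from the
    pre-onset population state up to ``max_retries`` times.

    Returns ``(haps, truth)`` where ``truth`` is ``None`` for neutral runs
    and otherwise a dict with the selected site's ``Trajectory``, its column
    index in the matrix, and the true :class:`LocalTree` of the sampled
    haplotypes at the selected position.

    ``mask`` is a callability-mask hook: a callable mapping a float position
    array to a boolean keep-array.  The default keeps every site.
    """
    N0 = demography.size_at(0)
    if any(n > _MAX_FORWARD_N for n in demography.Ns):
        raise ValueError(
            f"forward simulation is limited to N <= {_MAX_FORWARD_N} diploids; "
            "use coalescent_haplotypes for larger neutral samples"
        )
    rng = np.random.default_rng(seed)
    L = float(params.sequence_length)
    mu, rho = params.mutation_rate, params.recombination_rate
    onset = selected_site[2] if selected_site is not None else 0
    if burn_in is None:
        burn_in = int(8 * 2 * N0)
    total_gens = burn_in + onset

    # ---- neutral burn-in (time-ago total_gens .. onset) ----
    two_n = int(round(2 * demography.size_at(total_gens)))
    pop: list[np.ndarray] = [np.empty(0) for _ in range(two_n)]
    for g in range(total_gens - onset):
        t_child = total_gens - (g + 1)
        pop = _wf_generation(pop, demography, t_child, L, mu, rho, None, None, rng)[0]
        if g % 50 == 49:
            pop = _drop_fixed(pop)
    pop = _drop_fixed(pop)

    if selected_site is None:
        return _collect_sample(pop, params, L, rng, mask, None, None, None), None

    # ---- sweep phase with retries from the pre-onset state ----
    pos_sel, s_sel, _ = selected_site
    for attempt in range(max_retries):
        sub = np.random.default_rng(rng.integers(2**31))
        cur = [h.copy() for h in pop]
        sel = np.zeros(len(cur), dtype=np.int8)
        sel[int(sub.integers(len(cur)))] = 1
        anc_rows = [np.arange(len(cur))]  # pedigree at the selected site
        traj_fwd = [sel.mean()]
        lost = False
        for g in range(onset):
            t_child = onset - (g + 1)
            cur, sel, src = _wf_generation(
                cur, demography, t_child, L, mu, rho, pos_sel, (sel, s_sel), sub
            )
            anc_rows.append(src)
            traj_fwd.append(sel.mean())
            if sel.sum() == 0:
                lost = True
                break
        if lost:
            continue
        final = sel.mean()
        if not final_freq_range[0] <= final <= final_freq_range[1]:
            continue
        cur = _drop_fixed(cur)
        freqs_back = np.array(traj_fwd[::-1] + [0.0])  # origin just before onset
        traj = Trajectory(
            freqs=freqs_back, s_true=s_sel, demography=demography,
            meta={"seed": seed, "attempt": attempt, "onset": onset},
        )
        haps, truth = _collect_sample(cur, params, L, rng, mask, pos_sel, sel, anc_rows)
        truth["trajectory"] = traj
        return haps, truth
    raise SimulationError(
        f"selected allele lost or out of range in all {max_retries} attempts "
        f"(s={s_sel}, onset={onset})"
    )


def _wf_generation(pop, demography, t_child, L, mu, rho, pos_sel, selection, rng):
    """One Wright-Fisher generation; returns (offspring, sel_alleles, src_rows)."""
    n_par = len(pop)
    two_n_next = int(round(2 * demography.size_at(max(t_child, 0))))
    if selection is not None:
        sel, s = selection
        w = 1.0 + s * (sel[0::2] + sel[1::2])
        prob = w / w.sum()
    else:
        sel, prob = None, None
    parents = rng.choice(n_par // 2, size=two_n_next, p=prob)
    offspring: list[np.ndarray] = []
    new_sel = np.zeros(two_n_next, dtype=np.int8)
    src_rows = np.zeros(two_n_next, dtype=np.int64)
    for i, par in enumerate(parents):
        a, b = 2 * par, 2 * par + 1
        gam, src = _make_gamete(pop[a], pop[b], L, rho, pos_sel, rng)
        n_mut = rng.poisson(mu * L)
        if n_mut:
            gam = np.sort(np.concatenate([gam, rng.random(n_mut) * L]))
        offspring.append(gam)
        hap_idx = a if src == 0 else b
        src_rows[i] = hap_idx
        if sel is not None:
            new_sel[i] = sel[hap_idx]
    return offspring, new_sel, src_rows


def _collect_sample(pop, params, L, rng, mask, pos_sel, sel, anc_rows):
    n = min(params.n_samples, len(pop))
    take = np.sort(rng.choice(len(pop), size=n, replace=False))
    sample = [pop[i] for i in take]
    if any(len(h) for h in sample):
        allpos = np.unique(np.concatenate(sample))
    else:
        allpos = np.empty(0)
    mat = np.zeros((n, len(allpos)), dtype=np.int8)
    for r, hap in enumerate(sample):
        mat[r, np.searchsorted(allpos, hap)] = 1
    counts = mat.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    if mask is not None and allpos.size:
        seg &= np.asarray(mask(allpos), dtype=bool)
    allpos, mat = allpos[seg], mat[:, seg]
    float_pos = allpos
    truth = None
    if pos_sel is not None:
        col = sel[take].astype(np.int8)
        insert_at = int(np.searchsorted(float_pos, pos_sel))
        float_pos = np.insert(float_pos, insert_at, pos_sel)
        mat = np.insert(mat, insert_at, col, axis=1)
        tree = _tree_from_pedigree(anc_rows, take, col)
        truth = {"selected_index": insert_at, "selected_column": col, "tree": tree}
    ipos = _int_positions(float_pos) if len(float_pos) else np.empty(0, dtype=np.int64)
    haps = HaplotypeMatrix(matrix=mat, positions=ipos, meta={"sampled_rows": take})
    if truth is not None:
        truth["selected_position"] = (
            int(ipos[truth["selected_index"]]) if len(ipos) else None
        )
    return (haps, truth) if pos_sel is not None else haps


def _tree_from_pedigree(anc_rows, take, derived_col):
    """Genealogy of the sampled haplotypes at the tracked site.

    ``anc_rows[g][i]`` is the parental haplotype (generation g-1 indexing)
    of haplotype ``i`` in generation ``g``; generation ``len(anc_rows)-1`` is
    the present.  Lineages that fail to coalesce within the recorded window
    are star-joined above it (``meta['forced_root']``).
    """
    n = len(take)
    lineage = np.asarray(take, dtype=np.int64).copy()
    node_of = list(range(n))
    parent = [-1] * n
    times = [0.0] * n
    nxt = n
    forced = False
    for back, rows in enumerate(reversed(anc_rows[1:]), start=1):
        lineage = rows[lineage]
        # merge lineages that landed on the same parental haplotype
        uniq, inv = np.unique(lineage, return_inverse=True)
        if len(uniq) < len(lineage):
            new_nodes = []
            new_lineage = []
            for u in range(len(uniq)):
                members = [node_of[i] for i in range(len(lineage)) if inv[i] == u]
                node = members[0]
                for j, m in enumerate(members[1:], start=1):
                    parent.append(-1)
                    times.append(back + 0.25 * j / max(len(members), 1))
                    parent[node] = nxt
                    parent[m] = nxt
                    node = nxt
                    nxt += 1
                new_nodes.append(node)
                new_lineage.append(uniq[u])
            node_of = new_nodes
            lineage = np.array(new_lineage)
        if len(lineage) == 1:
            break
    depth = len(anc_rows)
    while len(node_of) > 1:  # star-join leftovers above the recorded window
        forced = True
        parent.append(-1)
        times.append(depth + 1.0 + 0.25 * (nxt - n))
        parent[node_of[0]] = nxt
        parent[node_of[1]] = nxt
        node_of = [nxt] + node_of[2:]
        nxt += 1
    labels = tuple(f"hap{i}" for i in range(n))
    carriers = [i for i in range(n) if derived_col[i] == 1]
    if not carriers or len(carriers) == n:
        return None  # monomorphic at the tracked site in this sample
    parent_arr = np.array(parent)
    mrca = carriers[0]
    for c in carriers[1:]:
        mrca = _walk_mrca(parent_arr, mrca, c)
    tree = LocalTree(parent_arr, np.array(times), labels, mrca,
                     meta={"forced_root": forced})
    if tree.derived_leaves != {labels[i] for i in carriers}:
        return None  # recombination pathology; caller may resample
    return tree


def _walk_mrca(parent, a, b):
    seen = set()
    while a >= 0:
        seen.add(int(a))
        a = parent[a]
    while int(b) not in seen:
        b = parent[b]
    return int(b)


# ---------------------------------------------------------------------------
# msprime-backed neutral haplotypes
# ---------------------------------------------------------------------------


def coalescent_haplotypes(
    params: SimParams, demography: Demography, seed: int | None = None
) -> HaplotypeMatrix:
    """Neutral phased haplotypes from the coalescent (msprime backend).

    Used for large neutral fixtures (e.g. haplotype-statistic scans) where
    the desk-scale forward simulator would be too small.  Derived alleles are
    coded 1; multiallelic sites are dropped.
    """
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=demography.Ns[0])
    for start, N in demography.epochs[1:]:
        dem.add_population_parameters_change(time=start, initial_size=N)
    n_ind = (params.n_samples + 1) // 2
    ts = msprime.sim_ancestry(
        samples=n_ind,
        demography=dem,
        sequence_length=params.sequence_length,
        recombination_rate=params.recombination_rate,
        random_seed=None if seed is None else (seed % (2**31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=None if seed is None else (seed % (2**31 - 2)) + 2,
    )
    keep_cols, keep_pos = [], []
    G = ts.genotype_matrix()
    for j, site in enumerate(ts.sites()):
        states = {m.derived_state for m in site.mutations} | {site.ancestral_state}
        if len(states) != 2 or np.any(G[j] > 1):
            continue
        keep_cols.append(j)
        keep_pos.append(int(site.position) + 1)
    mat = G[keep_cols].T.astype(np.int8)[: params.n_samples]
    pos = np.asarray(keep_pos, dtype=np.int64)
    uniq = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.empty(0, bool)
    return HaplotypeMatrix(
        matrix=mat[:, uniq], positions=pos[uniq], meta={"seed": seed, "engine": "msprime"}
    )


# ---------------------------------------------------------------------------
# classifier scenario fixtures
# ---------------------------------------------------------------------------

SUBSCENARIO_CODES = {
    ("A", "risk"): 1,
    ("A", "protective"): 2,
    ("B", "risk"): 3,
    ("B", "protective"): 4,
    ("A", "missing"): 5,
    ("B", "missing"): 6,
}


def _column_pair(base: np.ndarray, flip_frac: float, rng) -> np.ndarray:
    flips = rng.random(base.size) < flip_frac
    return (base ^ flips).astype(np.int8)


def _emp_r2(a: np.ndarray, b: np.ndarray) -> float:
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    d = (a & b).mean() - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def make_locus_fixture(
    scenario: str,
    seed: int | None = None,
    subscenario: str = "risk",
    n_hap: int = 200,
    threshold: float = 1.59,
    max_retries: int = 50,
):
    """Construct a risk-locus fixture realizing a known evolutionary scenario.

    Scenarios follow the selection-target taxonomy: (A) the top candidate
    causal SNP (highest PICS) is the sweep-driving mutation; (B) it is a
    hitchhiker, in weak LD (r² < 0.6) with the true target; (C) it is in
    strong LD (r² >= 0.6) with a stronger target, so neither can be ruled
    out; (D) the top candidate is untestable (fails the derived-count
    filter).  ``subscenario`` controls whether the risk or the protective
    allele of the top candidate rides with the selected allele, or whether
    allele information is missing.

    Returns ``(haps, candidates, truth)``: a haplotype matrix, a candidate
    table (PICS, risk alleles, per-SNP selection statistics with planted
    noise), and the ground-truth labels.
    """
    import pandas as pd

    if scenario not in {"A", "B", "C", "D"}:
        raise ValueError("scenario must be one of A, B, C, D")
    if subscenario not in {"risk", "protective", "missing"}:
        raise ValueError("subscenario must be risk, protective or missing")
    rng = np.random.default_rng(seed)

    target = (rng.random(n_hap) < 0.55).astype(np.int8)
    while not 0.25 < target.mean() < 0.8:
        target = (rng.random(n_hap) < 0.55).astype(np.int8)

    # top-PICS column in the configured LD with the target
    if scenario == "A":
        pics_col, want = None, None
    elif scenario == "B":
        pics_col, want = 0.24, (0.05, 0.50)
    elif scenario == "C":
        pics_col, want = 0.07, (0.65, 0.98)
    else:  # D: rare, untestable
        pics_col, want = None, None
    top = None
    if scenario in {"B", "C"}:
        for _ in range(max_retries):
            cand = _column_pair(target, pics_col, rng)
            r2 = _emp_r2(cand, target)
            if want[0] <= r2 <= want[1] and 0 < cand.mean() < 1:
                top = cand
                break
        if top is None:
            raise SimulationError(
                f"could not realize r² in {want} at n_hap={n_hap}"
            )
    elif scenario == "D":
        top = np.zeros(n_hap, dtype=np.int8)
        top[rng.choice(n_hap, size=3, replace=False)] = 1

    # supporting high-LD columns (consistency of the signal) and fillers
    supporters = [_column_pair(target, 0.04, rng) for _ in range(2)]
    fillers = [
        (rng.random(n_hap) < rng.uniform(0.2, 0.8)).astype(np.int8) for _ in range(4)
    ]
    expanded = [_column_pair(target, 0.10, rng) for _ in range(2)]

    cols, rows = [], []
    t_loglr = 4.0 + rng.normal(0, 0.25)
    s_t = 0.04 + 0.02 * rng.random()

    def add(col, snp_id, pics, risk_allele, source, loglr, s_med, testable=True,
            reason="", branch=None, role=""):
        cols.append(col)
        rows.append(
            dict(snp_id=snp_id, pics=pics, risk_allele=risk_allele, source=source,
                 logLR_median=loglr, s_median=s_med, testable=testable,
                 reason=reason, branch_id=branch, role=role,
                 disease="synthetic_disease")
        )

    risk_of_top = {"risk": "derived", "protective": "ancestral", "missing": None}[
        subscenario
    ]
    top_pics = 0.55 + 0.2 * rng.random()
    if scenario == "A":
        add(target, "rs_target", top_pics, risk_of_top, "reported",
            t_loglr, s_t, branch="b_target", role="target+top_pics")
    else:
        add(target, "rs_target", 0.12 + 0.1 * rng.random(), None, "reported",
            t_loglr, s_t, branch="b_target", role="target")
        if scenario == "D":
            add(top, "rs_top", top_pics, risk_of_top, "reported",
                np.nan, np.nan, testable=False, reason="minor derived count < 4",
                branch=None, role="top_pics")
        else:
            top_lr = t_loglr - 1.0 if scenario == "C" else 1.8 + 0.3 * rng.random()
            add(top, "rs_top", top_pics, risk_of_top, "reported",
                top_lr, 0.02 * rng.random(), branch="b_top", role="top_pics")
    for i, col in enumerate(supporters):
        add(col, f"rs_sup{i}", 0.05 + 0.15 * rng.random(), None, "reported",
            t_loglr - 1.0 - 0.5 * rng.random(), s_t * (0.7 + 0.2 * rng.random()),
            branch=f"b_sup{i}", role="supporter")
    for i, col in enumerate(fillers):
        add(col, f"rs_fill{i}", 0.02 + 0.1 * rng.random(), None, "reported",
            max(0.05, threshold + 0.4 - 0.9 * i + 0.2 * rng.normal()),
            0.01 * rng.normal(), branch=f"b_fill{i}", role="filler")
    for i, col in enumerate(expanded):
        add(col, f"rs_exp{i}", np.nan, None, "ld_expanded",
            t_loglr - 1.6 - 0.3 * rng.random(), s_t * 0.8,
            branch=f"b_exp{i}", role="expanded")

    order = rng.permutation(len(cols))
    positions = np.sort(rng.choice(np.arange(1000, 50000), len(cols), replace=False))
    matrix = np.stack([cols[i] for i in order], axis=1)
    table = pd.DataFrame([rows[i] for i in order])
    table["position"] = positions
    haps = HaplotypeMatrix(
        matrix=matrix, positions=positions, snp_ids=list(table["snp_id"]),
        meta={"seed": seed, "scenario": scenario},
    )
    truth = {
        "scenario": scenario,
        "subscenario": SUBSCENARIO_CODES.get((scenario, subscenario))
        if scenario in {"A", "B"}
        else None,
        "target_snp": "rs_target",
        "top_pics_snp": "rs_target" if scenario == "A" else "rs_top",
        "selected_allele": "derived",
    }
    return haps, table, truth
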
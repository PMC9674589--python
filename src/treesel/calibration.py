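"""Demography-matched neutral calibration of the selection test.

A genome scan's logLR values are inflated by genetic drift under the target
population's demography.  The calibration pipeline therefore simulates many
independent neutral SNPs under the same demography, computes their logLR
distribution, and uses its empirical 95% percentile as the neutrality
rejection threshold (at the cost of ~5% false rejections on neutral data).

SNP ascertainment mirrors a sequencing pipeline: a minor-derived-count floor
for the simulated null and a MAF floor for the empirical scan, followed by
deterministic thinning (every k-th SNP) to decorrelate the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import Demography
from .haplotypes import HaplotypeMatrix
from .likelihood import SelectionModel, default_s_grid, replicate_median
from .simulate import backward_neutral_trajectories, sample_genealogy

__all__ = [
    "NullDistribution",
    "ascertain_snps",
    "thin_snps",
    "calibrate_threshold",
    "false_rejection_rate",
    "simulate_null_distribution",
]


@dataclass
class NullDistribution:
    """Empirical neutral logLR distribution with provenance."""

    logLR_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.logLR_values = np.asarray(self.logLR_values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.logLR_values)

    def percentiles(self, levels=(95, 99, 99.9)) -> dict:
        return {lv: calibrate_threshold(self, lv, min_values=1) for lv in levels}


def ascertain_snps(
    haps: HaplotypeMatrix,
    min_derived_count: int | None = 4,
    min_maf: float | None = 0.05,
) -> np.ndarray:
    """Indices of SNPs surviving the ascertainment filters.

    Removes sites whose minor derived allele count is below
    ``min_derived_count`` and sites with MAF not strictly above ``min_maf``.
    Either rule can be disabled with ``None`` (the simulated-null pipeline
    uses the count rule, the empirical scan the MAF rule).
    """
    keep = np.ones(haps.n_sites, dtype=bool)
    if min_derived_count is not None:
        keep &= haps.minor_derived_counts() >= min_derived_count
    if min_maf is not None:
        keep &= haps.maf() > min_maf
    return np.flatnonzero(keep)


def thin_snps(snp_list, step: int = 76):
    """Deterministic thinning: keep every ``step``-th element (1-based).

    Positions ``step, 2*step, ...`` are retained, so ``floor(n/step)``
    survive.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if isinstance(snp_list, np.ndarray):
        return snp_list[step - 1 :: step]
    return list(snp_list)[step - 1 :: step]


def calibrate_threshold(
    null: NullDistribution | np.ndarray, level: float = 95, min_values: int = 100
) -> float:
    """Nearest-rank empirical percentile of the null logLR distribution.

    Returns the order statistic of rank ``ceil(level/100 * n)``.  Requires at
    least ``min_values`` null values.
    """
    values = null.logLR_values if isinstance(null, NullDistribution) else np.asarray(null)
    n = len(values)
    if n < min_values:
        raise ValueError(
            f"need at least {min_values} null logLR values to calibrate, got {n}"
        )
    if not 0 < level <= 100:
        raise ValueError("level must be in (0, 100]")
    rank = max(int(math.ceil(level / 100.0 * n)), 1)
    return float(np.sort(values)[rank - 1])


def false_rejection_rate(
    threshold: float, independent_null: NullDistribution | np.ndarray
) -> float:
    """Percentage of an independent neutral batch at or above the threshold."""
    values = (
        independent_null.logLR_values
        if isinstance(independent_null, NullDistribution)
        else np.asarray(independent_null)
    )
    return float(100.0 * np.mean(values >= threshold))


# ---------------------------------------------------------------------------
# the simulated null pipeline
# ---------------------------------------------------------------------------


def _draw_present_freqs(
    n_snps: int,
    n_samples: int,
    min_derived_count: int,
    rng: np.random.Generator,
    lo: float = 0.01,
    hi: float = 0.99,
):
    """Present-day frequencies of ascertained neutral SNPs.

    Population frequencies follow the stationary neutral site-frequency
    density (∝ 1/x); sample derived counts are binomial draws, and sites are
    kept only if the minor derived count passes the ascertainment floor.
    Returns (frequencies, derived counts).
    """
    freqs, counts = [], []
    while len(freqs) < n_snps:
        m = 4 * (n_snps - len(freqs)) + 16
        u = rng.random(m)
        x = lo * (hi / lo) ** u  # inverse CDF of 1/x on [lo, hi]
        d = rng.binomial(n_samples, x)
        ok = np.minimum(d, n_samples - d) >= min_derived_count
        freqs.extend(x[ok])
        counts.extend(d[ok])
    return np.array(freqs[:n_snps]), np.array(counts[:n_snps], dtype=int)


def simulate_null_distribution(
    demography: Demography,
    n_snps: int = 2000,
    n_samples: int = 30,
    seed: int | None = None,
    s_grid: np.ndarray | None = None,
    window=(0.0, 500.0),
    min_derived_count: int = 4,
    n_bins: int = 50,
    use_replicate_rule: bool = True,
    progress: bool = False,
) -> NullDistribution:
    """Neutral logLR distribution matched to a demography.

    Each SNP is an independent neutral locus: a present-day frequency drawn
    from the ascertained neutral site-frequency density, a backward neutral
    trajectory to its origin, and fresh structured-coalescent genealogies on
    which the selection likelihood is maximized.  With
    ``use_replicate_rule`` each SNP follows the 2-or-3-run median rule on
    independent genealogy draws; otherwise a single run per SNP is used.
    """
    rng = np.random.default_rng(seed)
    if s_grid is None:
        s_grid = default_s_grid()
    freqs, counts = _draw_present_freqs(n_snps, n_samples, min_derived_count, rng)
    trajectories = backward_neutral_trajectories(
        freqs, demography, seed=int(rng.integers(2**31))
    )
    values = np.empty(n_snps)
    for i, (traj, d) in enumerate(zip(trajectories, counts)):
        def one_run(_rep, _traj=traj, _d=d):
            tree = sample_genealogy(
                _traj, n_samples, int(_d), seed=int(rng.integers(2**31))
            )
            return SelectionModel(
                tree, demography, s_grid=s_grid, window=window, n_bins=n_bins
            ).fit()

        if use_replicate_rule:
            values[i] = replicate_median(one_run).logLR_median
        else:
            values[i] = one_run(0).logLR
        if progress and (i + 1) % 200 == 0:  # pragma: no cover
            print(f"  null SNP {i + 1}/{n_snps}")
    return NullDistribution(
        logLR_values=values,
        provenance={
            "demography": list(map(list, demography.epochs)),
            "seed": seed,
            "n_snps": n_snps,
            "n_samples": n_samples,
            "min_derived_count": min_derived_count,
            "replicate_rule": use_replicate_rule,
        },
    )
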
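"""Integrated haplotype score (iHS) for haplotype-based sweep detection.

EHH(x) is the probability that two randomly drawn carrier haplotypes of a
core allele are identical over the interval from the core SNP to position x;
it starts at 1 and decays with distance.  iHH is the area under the EHH
curve over genetic distance (both directions from the core, truncated where
EHH drops below a cutoff), computed separately for carriers of the ancestral
and the derived core allele.  The unstandardized score is
``ln(iHH_ancestral / iHH_derived)``; scores are then standardized to mean 0
and unit variance within derived-allele-frequency bins, and outliers are
called from the top tail of |iHS|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix

__all__ = [
    "IHSResult",
    "ehh",
    "ihs",
    "ihs_scan",
    "standardize_ihs",
    "call_ihs_outliers",
]


@dataclass
class IHSResult:
    snp_id: str
    daf: float
    ihh_ancestral: float
    ihh_derived: float
    ihs_unstd: float
    truncated: bool
    ihs_std: float | None = None
    daf_bin: int | None = None


def _ehh_one_side(sub: np.ndarray, stop_below: float | None = None) -> np.ndarray:
    """EHH along columns of ``sub`` (carriers x sites ordered outward).

    With ``stop_below`` the walk terminates one site after the curve first
    drops below that value (the remainder is not needed for integration).
    """
    n = sub.shape[0]
    pairs_total = n * (n - 1) / 2.0
    out = [1.0]
    groups = np.zeros(n, dtype=np.int64)
    for j in range(sub.shape[1]):
        # refine the partition by the allele at the next site
        groups = groups * 2 + sub[:, j]
        uniq, groups = np.unique(groups, return_inverse=True)  # re-compact labels
        counts = np.bincount(groups)
        val = (counts * (counts - 1) / 2.0).sum() / pairs_total
        out.append(val)
        if stop_below is not None and val < stop_below:
            break
    return np.asarray(out)


def ehh(
    haps: HaplotypeMatrix,
    core_snp: int | str,
    core_allele: int,
    direction: str,
    stop_below: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve from a core SNP in one direction.

    Returns ``(site_indices, ehh_values)`` where the first entry is the core
    itself with EHH = 1.  Requires at least two carrier haplotypes.  With
    ``stop_below`` the curve is truncated one site after first falling below
    that value.
    """
    core = core_snp if isinstance(core_snp, (int, np.integer)) else haps.index_of(core_snp)
    if direction not in {"left", "right"}:
        raise ValueError("direction must be 'left' or 'right'")
    carriers = haps.matrix[:, core] == core_allele
    if carriers.sum() < 2:
        raise ValueError("core allele has fewer than two carriers")
    if direction == "right":
        cols = np.arange(core + 1, haps.n_sites)
    else:
        cols = np.arange(core - 1, -1, -1)
    sub = haps.matrix[np.ix_(carriers, cols)]
    values = _ehh_one_side(sub, stop_below)
    return np.concatenate([[core], cols])[: len(values)], values


def _ihh_allele(
    haps, core, allele, cutoff, cm, truncation_policy
) -> tuple[float, bool]:
    """Trapezoid-integrated EHH area (cM) for one core allele, both sides."""
    area, truncated = 0.0, False
    for direction in ("left", "right"):
        idx, vals = ehh(haps, core, allele, direction, stop_below=cutoff)
        dist = np.abs(cm[idx] - cm[core])
        below = np.flatnonzero(vals < cutoff)
        stop = below[0] + 1 if below.size else len(vals)
        if not below.size:
            truncated = True  # hit the region edge before the EHH cutoff
        area += float(np.trapezoid(vals[:stop], dist[:stop]))
    if truncated and truncation_policy == "drop":
        return np.nan, True
    return area, truncated


def ihs(
    haps: HaplotypeMatrix,
    core_snp: int | str,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    cm_per_mb: float = 1.0,
    truncation_policy: str = "keep",
) -> IHSResult:
    """Unstandardized iHS at one core SNP.

    EHH is integrated over genetic distance (a constant-rate map is assumed
    when the matrix carries none) until it drops below ``ehh_cutoff``; when
    the curve reaches the region edge first the result is flagged truncated
    and, under ``truncation_policy='drop'``, set to NaN.
    """
    core = core_snp if isinstance(core_snp, (int, np.integer)) else haps.index_of(core_snp)
    daf = float(haps.daf()[core])
    if min(daf, 1 - daf) <= maf_min:
        raise ValueError(f"core SNP MAF {min(daf, 1 - daf):.3f} <= {maf_min}")
    cm = haps.cm_positions(cm_per_mb)
    ihh_a, trunc_a = _ihh_allele(haps, core, 0, ehh_cutoff, cm, truncation_policy)
    ihh_d, trunc_d = _ihh_allele(haps, core, 1, ehh_cutoff, cm, truncation_policy)
    if not np.isfinite(ihh_a) or not np.isfinite(ihh_d) or ihh_a <= 0 or ihh_d <= 0:
        unstd = np.nan
    else:
        unstd = float(np.log(ihh_a / ihh_d))
    return IHSResult(
        snp_id=haps.snp_ids[core],
        daf=daf,
        ihh_ancestral=ihh_a,
        ihh_derived=ihh_d,
        ihs_unstd=unstd,
        truncated=trunc_a or trunc_d,
    )


def ihs_scan(
    haps: HaplotypeMatrix,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    cm_per_mb: float = 1.0,
    truncation_policy: str = "keep",
) -> pd.DataFrame:
    """iHS over every SNP passing the MAF filter; returns a tidy table."""
    rows = []
    mafs = haps.maf()
    for j in range(haps.n_sites):
        if mafs[j] <= maf_min:
            continue
        try:
            r = ihs(haps, j, maf_min, ehh_cutoff, cm_per_mb, truncation_policy)
        except ValueError:
            continue
        rows.append(vars(r))
    return pd.DataFrame(rows)


def standardize_ihs(
    results: pd.DataFrame, n_bins: int = 50, min_per_bin: int = 10
) -> pd.DataFrame:
    """Standardize iHS within derived-allele-frequency bins.

    Equal-width DAF bins; bins with fewer than ``min_per_bin`` usable scores
    are merged with their right neighbour (leftover tail merges left).
    Adds ``ihs_std`` and ``daf_bin`` columns.
    """
    out = results.copy()
    usable = out["ihs_unstd"].notna()
    edges = np.linspace(0, 1, n_bins + 1)
    raw_bin = np.clip(np.digitize(out["daf"], edges) - 1, 0, n_bins - 1)
    # merge sparse bins rightwards
    mapping = {}
    carry: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero((raw_bin == b) & usable.to_numpy())
        carry.append(b)
        if len(np.flatnonzero(np.isin(raw_bin, carry) & usable.to_numpy())) >= min_per_bin:
            for cb in carry:
                mapping[cb] = b
            carry = []
    if carry:  # leftover sparse tail joins the last complete bin
        last = max(mapping.values()) if mapping else n_bins - 1
        for cb in carry:
            mapping[cb] = last
    bins = np.array([mapping[b] for b in raw_bin])
    out["daf_bin"] = bins
    out["ihs_std"] = np.nan
    for b in np.unique(bins):
        sel = (bins == b) & usable.to_numpy()
        vals = out.loc[sel, "ihs_unstd"]
        sd = vals.std(ddof=1)
        if len(vals) >= 2 and sd > 0:
            out.loc[sel, "ihs_std"] = (vals - vals.mean()) / sd
    return out


def call_ihs_outliers(results: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Flag the top fraction of SNPs by |standardized iHS|.

    The realized |iHS| cutoff is dataset specific and reported in the
    ``abs_cutoff`` attribute of the returned frame; boundary ties are all
    included (the flagged count may exceed the nominal fraction).
    """
    if "ihs_std" not in results.columns:
        raise ValueError("standardize_ihs must be applied first")
    usable = results["ihs_std"].notna()
    scores = results.loc[usable, "ihs_std"].abs()
    k = max(int(np.floor(top_fraction * len(scores))), 1)
    cutoff = float(np.sort(scores.to_numpy())[::-1][k - 1])
    out = results.copy()
    out["ihs_outlier"] = False
    out.loc[usable, "ihs_outlier"] = scores >= cutoff
    out.attrs["abs_cutoff"] = cutoff
    return out
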
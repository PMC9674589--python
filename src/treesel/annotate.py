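"""Post-scan annotation: sample QC, eQTL FDR matching, enrichment testing.

Sample QC mirrors a panmixia-oriented sequencing pipeline: principal
component outliers, singleton-count tails and excessive pairwise IBD
sharing are removed before tree-based analyses.  eQTL summary tables are
filtered at a per-tissue false discovery rate and joined with candidate
SNPs; enrichment in a cell-type class is assessed with Fisher's exact test.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleQCTable",
    "sample_qc",
    "fdr_qvalues",
    "match_eqtls",
    "fisher_enrichment",
]


@dataclass
class SampleQCTable:
    """Per-sample QC statistics plus the pairwise total-IBD matrix (cM)."""

    frame: pd.DataFrame  # columns: PC1, PC2, singleton_count; index: sample ids
    ibd: np.ndarray

    def __post_init__(self) -> None:
        required = {"PC1", "PC2", "singleton_count"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"QC table lacks columns: {sorted(missing)}")
        self.ibd = np.asarray(self.ibd, dtype=float)
        n = len(self.frame)
        if self.ibd.shape != (n, n):
            raise ValueError("IBD matrix must be n_samples x n_samples")
        if np.any(self.ibd < 0) or not np.allclose(self.ibd, self.ibd.T):
            raise ValueError("IBD matrix must be symmetric and non-negative")


def _nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (rank ceil(q/100*n) of the sorted values)."""
    v = np.sort(np.asarray(values, dtype=float))
    rank = max(int(math.ceil(q / 100.0 * len(v))), 1)
    return float(v[rank - 1])


def sample_qc(
    table: SampleQCTable,
    pc_lo: float = 2.5,
    pc_hi: float = 97.5,
    singleton_trim: float = 2.5,
    ibd_cm: float = 166.2,
    ibd_partners: int = 1,
):
    """Apply the three sample-removal rules in order; return kept samples.

    (a) samples outside the nearest-rank [pc_lo, pc_hi] percentile range of
    PC1 or PC2; (b) the top and bottom ``singleton_trim``% by singleton
    count; (c) samples sharing at least ``ibd_cm`` total IBD with more than
    ``ibd_partners`` other samples.  Each rule is evaluated on the samples
    surviving the previous ones.  With the nearest-rank convention a sample
    equal to the percentile bound is kept, so degenerate constant columns
    remove nothing.  Returns ``(kept_ids, removals)`` where ``removals``
    maps sample id -> reason.
    """
    df = table.frame
    ids = list(df.index)
    removals: dict = {}
    alive = np.ones(len(ids), dtype=bool)

    # (a) PCA outliers
    for pc in ("PC1", "PC2"):
        vals = df[pc].to_numpy()[alive]
        lo, hi = _nearest_rank(vals, pc_lo), _nearest_rank(vals, pc_hi)
        for i in np.flatnonzero(alive):
            v = df[pc].iloc[i]
            if v < lo or v > hi:
                removals.setdefault(ids[i], f"{pc} outside [{pc_lo}, {pc_hi}] percentile")
    for i, sid in enumerate(ids):
        if sid in removals:
            alive[i] = False

    # (b) singleton-count tails
    vals = df["singleton_count"].to_numpy()[alive]
    lo = _nearest_rank(vals, singleton_trim)
    hi = _nearest_rank(vals, 100.0 - singleton_trim)
    for i in np.flatnonzero(alive):
        v = df["singleton_count"].iloc[i]
        if v < lo or v > hi:
            removals[ids[i]] = f"singleton count outside {singleton_trim}% tails"
            alive[i] = False

    # (c) excessive IBD sharing with more than ibd_partners samples
    sub = np.flatnonzero(alive)
    ibd = table.ibd[np.ix_(sub, sub)]
    n_partners = (ibd >= ibd_cm).sum(axis=1) - (np.diag(ibd) >= ibd_cm).astype(int)
    for local_i, i in enumerate(sub):
        if n_partners[local_i] > ibd_partners:
            removals[ids[i]] = (
                f"total IBD >= {ibd_cm} cM with {n_partners[local_i]} samples"
            )
            alive[i] = False

    kept = [ids[i] for i in np.flatnonzero(alive)]
    return kept, removals


def fdr_qvalues(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (optionally Storey-π₀ adjusted).

    ``method='storey'`` multiplies the BH q-values by the π₀ estimate
    ``min(1, mean(p > 0.5) / 0.5)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError("method must be 'bh' or 'storey'")
    return q


def match_eqtls(
    candidates: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    fdr: float = 0.10,
    pics_min: float | None = None,
    logLR_min: float | None = None,
    method: str = "bh",
):
    """Match candidate SNPs against per-tissue eQTL summary statistics.

    FDR is controlled within each tissue; significant records (q <=
    ``fdr``) are joined with the candidate table on ``snp_id``.  Optional
    ``pics_min`` / ``logLR_min`` restrict the candidates (e.g. to likely
    causal SNPs, or to selection targets).  Returns ``(matches, crosstab)``
    where the cross-tab counts disease x tissue pairs with an explicit
    ``no_eQTL`` column for candidates without any significant match.
    Tissues with zero tests are skipped.
    """
    need_c = {"snp_id", "disease"}
    if not need_c <= set(candidates.columns):
        raise ValueError("candidates need columns snp_id, disease")
    need_e = {"snp_id", "gene", "tissue", "p_value"}
    if not need_e <= set(eqtl_table.columns):
        raise ValueError("eQTL table needs columns snp_id, gene, tissue, p_value")

    cand = candidates.copy()
    if pics_min is not None and "pics" in cand.columns:
        cand = cand[cand["pics"] > pics_min]
    if logLR_min is not None and "logLR_median" in cand.columns:
        cand = cand[cand["logLR_median"] >= logLR_min]

    pieces = []
    for tissue, grp in eqtl_table.groupby("tissue"):
        if len(grp) == 0:
            continue
        g = grp.copy()
        g["q_value"] = fdr_qvalues(g["p_value"].to_numpy(), method=method)
        pieces.append(g[g["q_value"] <= fdr])
    significant = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else eqtl_table.iloc[0:0].assign(q_value=[])
    )
    matches = cand.merge(significant, on="snp_id", how="inner")

    diseases = sorted(cand["disease"].unique())
    tissues = sorted(eqtl_table["tissue"].unique())
    crosstab = pd.DataFrame(0, index=diseases, columns=tissues + ["no_eQTL"])
    for (dis, tis), grp in matches.groupby(["disease", "tissue"]):
        crosstab.loc[dis, tis] = len(grp)
    matched_snps = set(matches["snp_id"])
    for dis, grp in cand.groupby("disease"):
        crosstab.loc[dis, "no_eQTL"] = int((~grp["snp_id"].isin(matched_snps)).sum())
    return matches, crosstab


FisherResult = namedtuple("FisherResult", ["odds_ratio", "p_value", "haldane"])


def fisher_enrichment(table2x2) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value is the exact hypergeometric two-sided probability; the odds
    ratio uses the Haldane 0.5 correction when any cell is zero (flagged).
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0:
        raise ValueError("table has an all-zero margin")
    _, p = fisher_exact(t.astype(int), alternative="two-sided")
    haldane = bool(np.any(t == 0))
    tc = t + 0.5 if haldane else t
    odds = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    return FisherResult(float(odds), float(p), haldane)
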
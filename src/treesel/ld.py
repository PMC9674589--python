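"""Linkage-disequilibrium computations on phased haplotypes.

Composite r² on 0/1 haplotype columns, candidate-set expansion at r² >= 0.8,
LD-block partition (connected components at r² >= 0.6, which guarantees that
any two SNPs in different blocks have r² < 0.6), and most-common-haplotype
summaries for annotation panels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .haplotypes import HaplotypeMatrix

__all__ = [
    "CandidateSNP",
    "LDBlock",
    "r_squared",
    "r_squared_matrix",
    "expand_candidates",
    "ld_blocks",
    "top_haplotypes",
]


@dataclass
class CandidateSNP:
    """A candidate causal SNP at a risk locus.

    ``pics`` is the fine-mapping probability of being causal, present only
    for SNPs from the reported candidate list; LD-expanded SNPs carry no
    PICS score.
    """

    snp_id: str
    position: int
    diseases: tuple[str, ...] = ()
    risk_allele: str | None = None  # 'ancestral' | 'derived' | None
    pics: float | None = None
    source: str = "reported"  # 'reported' | 'ld_expanded'

    def __post_init__(self) -> None:
        if self.source not in {"reported", "ld_expanded"}:
            raise ValueError("source must be 'reported' or 'ld_expanded'")
        has_pics = self.pics is not None and not (
            isinstance(self.pics, float) and np.isnan(self.pics)
        )
        if has_pics != (self.source == "reported"):
            raise ValueError("pics must be present iff source == 'reported'")
        if self.risk_allele not in {None, "ancestral", "derived"}:
            raise ValueError("risk_allele must be 'ancestral', 'derived' or None")


@dataclass
class LDBlock:
    """A maximal set of SNPs not separable at the block r² cutoff."""

    block_id: int
    snp_ids: list[str]
    positions: np.ndarray
    index_snps: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions.min()), int(self.positions.max())


def r_squared(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Composite r² between two phased 0/1 haplotype columns.

    ``(p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))``; monomorphic columns
    give NaN (undefined, not zero).
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (va * vb))


def r_squared_matrix(haps: HaplotypeMatrix, indices=None) -> np.ndarray:
    """Pairwise r² among the given site indices (all sites by default)."""
    m = haps.matrix if indices is None else haps.matrix[:, np.asarray(indices)]
    x = m.astype(float)
    p = x.mean(axis=0)
    v = p * (1 - p)
    cov = x.T @ x / x.shape[0] - np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / np.outer(v, v)
    r2[:, v == 0] = np.nan
    r2[v == 0, :] = np.nan
    return r2


def expand_candidates(
    reported: list[CandidateSNP],
    haps: HaplotypeMatrix,
    r2_min: float = 0.8,
    logger=None,
) -> list[CandidateSNP]:
    """Add every matrix SNP in high LD (r² >= ``r2_min``) with a reported SNP.

    Returns the union of the reported set and the expansion, with added SNPs
    tagged ``ld_expanded``.  Reported SNPs absent from the matrix are
    skipped with a warning.  The operation is idempotent: expanding an
    already-expanded set adds nothing new.
    """
    present, skipped = [], []
    for c in reported:
        try:
            haps.index_of(c.snp_id)
            present.append(c)
        except KeyError:
            skipped.append(c.snp_id)
    if skipped and logger is not None:
        logger.warning("reported SNPs absent from matrix, skipped: %s", skipped)
    out = list(reported)
    have = {c.snp_id for c in reported}
    rep_idx = [haps.index_of(c.snp_id) for c in present]
    if not rep_idx:
        return out
    x = haps.matrix.astype(float)
    p = x.mean(axis=0)
    v = p * (1 - p)
    xr = x[:, rep_idx]
    cov = x.T @ xr / x.shape[0] - np.outer(p, p[rep_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / np.outer(v, v[rep_idx])
    linked = np.nanmax(np.where(np.isnan(r2), -1.0, r2), axis=1) >= r2_min
    for j in np.flatnonzero(linked):
        sid = haps.snp_ids[j]
        if sid in have:
            continue
        have.add(sid)
        out.append(
            CandidateSNP(
                snp_id=sid,
                position=int(haps.positions[j]),
                source="ld_expanded",
                pics=None,
            )
        )
    return out


def ld_blocks(
    snp_ids: list[str], haps: HaplotypeMatrix, r2_cut: float = 0.6
) -> list[LDBlock]:
    """Partition SNPs into LD blocks.

    Blocks are the connected components of the graph with an edge wherever
    r² >= ``r2_cut``; by construction any two SNPs in different blocks have
    r² < ``r2_cut``.  Within-block pairs may fall below the cutoff (only the
    cross-block property is guaranteed).  Blocks are ordered by leftmost
    position.
    """
    idx = [haps.index_of(s) for s in snp_ids]
    r2 = r_squared_matrix(haps, idx)
    adj = np.where(np.isnan(r2), 0.0, r2) >= r2_cut
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    blocks = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        pos = haps.positions[np.asarray(idx)[members]]
        blocks.append(
            LDBlock(
                block_id=-1,
                snp_ids=[snp_ids[m] for m in members],
                positions=np.asarray(pos),
            )
        )
    blocks.sort(key=lambda b: b.span[0])
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def top_haplotypes(
    block: LDBlock, haps: HaplotypeMatrix, k: int = 2
) -> list[tuple[str, float]]:
    """The ``k`` most frequent haplotypes over a block's SNPs.

    Haplotypes are strings over {0=ancestral, 1=derived} in position order;
    ties in frequency are broken lexicographically.
    """
    if not block.snp_ids:
        raise ValueError("block has no member SNPs")
    idx = sorted(haps.index_of(s) for s in block.snp_ids)
    sub = haps.matrix[:, idx]
    strings = ["".join(map(str, row)) for row in sub]
    counts = Counter(strings)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(strings)
    return [(h, c / n) for h, c in ranked[:k]]


def blocks_to_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    """BED-like table of blocks (1-based inclusive spans, member list)."""
    rows = [
        dict(
            block_id=b.block_id,
            start=b.span[0],
            end=b.span[1],
            n_snps=len(b.snp_ids),
            members=",".join(b.snp_ids),
        )
        for b in blocks
    ]
    return pd.DataFrame(rows)
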
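"""Phased 0/1 haplotype matrices (ancestral/derived coding)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeMatrix"]


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: rows are haplotypes, columns are polarized SNPs.

    ``matrix`` holds 0 (ancestral) / 1 (derived); ``positions`` are 1-based
    bp, strictly increasing.  ``genetic_map`` optionally gives cumulative cM
    at each site; when absent a constant cM/Mb rate is assumed by consumers.
    """

    matrix: np.ndarray
    positions: np.ndarray
    snp_ids: list[str] | None = None
    genetic_map: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")
        if np.any((self.matrix != 0) & (self.matrix != 1)):
            raise ValueError("matrix entries must be 0 (ancestral) or 1 (derived)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.positions < 1):
            raise ValueError("positions are 1-based and must be >= 1")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{p}" for p in self.positions]
        if len(self.snp_ids) != self.matrix.shape[1]:
            raise ValueError("snp_ids length must match number of sites")
        if self.genetic_map is not None:
            self.genetic_map = np.asarray(self.genetic_map, dtype=float)
            if len(self.genetic_map) != self.matrix.shape[1]:
                raise ValueError("genetic_map length must match number of sites")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(np.int64)

    def daf(self) -> np.ndarray:
        """Derived allele frequency per site."""
        return self.derived_counts() / self.n_haplotypes

    def maf(self) -> np.ndarray:
        f = self.daf()
        return np.minimum(f, 1.0 - f)

    def minor_derived_counts(self) -> np.ndarray:
        """Folded derived allele count, min(#derived, #ancestral)."""
        c = self.derived_counts()
        return np.minimum(c, self.n_haplotypes - c)

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError as exc:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from exc

    def column(self, snp: int | str) -> np.ndarray:
        idx = snp if isinstance(snp, (int, np.integer)) else self.index_of(snp)
        return self.matrix[:, idx]

    def subset_sites(self, indices) -> "HaplotypeMatrix":
        indices = np.asarray(indices, dtype=np.int64)
        return HaplotypeMatrix(
            matrix=self.matrix[:, indices],
            positions=self.positions[indices],
            snp_ids=[self.snp_ids[i] for i in indices],
            genetic_map=None if self.genetic_map is None else self.genetic_map[indices],
            meta=dict(self.meta),
        )

    def cm_positions(self, cm_per_mb: float = 1.0) -> np.ndarray:
        """Cumulative genetic positions, falling back to a constant map."""
        if self.genetic_map is not None:
            return self.genetic_map
        return self.positions * cm_per_mb / 1e6
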
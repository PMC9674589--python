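"""File formats: phased VCF, newick tree samples with a SNP sidecar,
demography tables, per-SNP results, and the run configuration.

Coordinates are 1-based inclusive throughout (VCF dialect); haplotypes are
polarized to ancestral/derived at ingest using the INFO/AA annotation, and
sites that cannot be polarized are dropped (counted in ``meta``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .demography import Demography
from .haplotypes import HaplotypeMatrix
from .likelihood import SelectionResult
from .trees import LocalTree

logger = logging.getLogger("treesel")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_trees",
    "write_trees",
    "read_demography",
    "write_demography",
    "results_to_frame",
    "write_results",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(haps: HaplotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write phased haplotypes as an uncompressed VCF.

    Consecutive haplotype pairs become diploid samples with phased GT; the
    ancestral allele is written to INFO/AA (REF is always ancestral here).
    """
    if haps.n_haplotypes % 2 != 0:
        raise ValueError("need an even number of haplotypes to form diploid samples")
    n_ind = haps.n_haplotypes // 2
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(f"ind{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(haps.n_sites):
            col = haps.matrix[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(n_ind))
            fh.write(
                f"{chrom}\t{haps.positions[j]}\t{haps.snp_ids[j]}\tA\tG\t.\t.\t"
                f"AA=A\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> HaplotypeMatrix:
    """Read a phased VCF into a polarized 0/1 haplotype matrix.

    Sites are polarized by INFO/AA: when AA equals ALT the column is
    flipped.  Multiallelic sites and sites with missing or unrecognizable AA
    are dropped (counts recorded in ``meta``); any unphased genotype is an
    error naming the first offending record.
    """
    vcf = VCF(str(path))
    cols, positions, ids = [], [], []
    dropped_aa = dropped_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped_multi += 1
            continue
        aa = var.INFO.get("AA")
        if aa is None:
            dropped_aa += 1
            continue
        aa = str(aa).upper()
        if aa == var.REF.upper():
            flip = False
        elif aa == var.ALT[0].upper():
            flip = True
        else:
            dropped_aa += 1
            continue
        hap = []
        for g in var.genotypes:  # [allele_a, allele_b, phased]
            alleles, phased = g[:-1], g[-1]
            if len(alleles) > 1 and not phased:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} ({var.ID})"
                )
            hap.extend(int(a) for a in alleles)
        col = np.asarray(hap, dtype=np.int8)
        if flip:
            col = 1 - col
        cols.append(col)
        positions.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"snp{var.POS}")
    if dropped_aa or dropped_multi:
        logger.info(
            "read_vcf: dropped %d unpolarizable and %d multiallelic sites",
            dropped_aa,
            dropped_multi,
        )
    matrix = np.stack(cols, axis=1) if cols else np.zeros((0, 0), dtype=np.int8)
    return HaplotypeMatrix(
        matrix=matrix,
        positions=np.asarray(positions, dtype=np.int64),
        snp_ids=ids,
        meta={"dropped_unpolarizable": dropped_aa, "dropped_multiallelic": dropped_multi},
    )


# ---------------------------------------------------------------------------
# trees + sidecar
# ---------------------------------------------------------------------------


def write_trees(
    trees: dict[str, list[LocalTree]], out_dir: str | Path, sidecar: str = "trees.tsv"
) -> Path:
    """Write per-SNP tree samples as newick files plus a sidecar TSV.

    One file per SNP (one newick per line, branch lengths in generations);
    the sidecar maps ``snp_id`` to the tree file and the derived-carrier
    leaf set.  Returns the sidecar path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for snp_id, sample in trees.items():
        fname = f"{snp_id}.nwk"
        with open(out_dir / fname, "w") as fh:
            for t in sample:
                fh.write(t.to_newick() + "\n")
        carriers = ",".join(sorted(sample[0].derived_leaves))
        rows.append(dict(snp_id=snp_id, tree_file=fname, derived_leaves=carriers))
    side = out_dir / sidecar
    pd.DataFrame(rows).to_csv(side, sep="\t", index=False)
    return side


def read_trees(
    sidecar: str | Path, ultrametric_tol: float = 1.0
) -> dict[str, list[LocalTree]]:
    """Read tree samples back from a sidecar TSV written by :func:`write_trees`.

    Validates that the derived carriers form a clade on every tree (the
    mutation must map to a single branch) and that tips are coeval within
    ``ultrametric_tol`` generations.
    """
    sidecar = Path(sidecar)
    table = pd.read_csv(sidecar, sep="\t")
    out: dict[str, list[LocalTree]] = {}
    for _, row in table.iterrows():
        carriers = set(str(row["derived_leaves"]).split(","))
        sample = []
        with open(sidecar.parent / row["tree_file"]) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    sample.append(
                        LocalTree.from_newick(line, carriers, ultrametric_tol)
                    )
        out[str(row["snp_id"])] = sample
    return out


# ---------------------------------------------------------------------------
# demography / results tables
# ---------------------------------------------------------------------------


def write_demography(dem: Demography, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#generation_time_years={dem.generation_time_years}\n")
        fh.write("start_generation\tN\n")
        for start, N in dem.epochs:
            fh.write(f"{start}\t{N}\n")


def read_demography(path: str | Path) -> Demography:
    gen_time = 28.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#generation_time_years="):
            gen_time = float(first.split("=", 1)[1])
    table = pd.read_csv(path, sep="\t", comment="#")
    epochs = tuple(
        (int(r["start_generation"]), float(r["N"])) for _, r in table.iterrows()
    )
    return Demography(epochs=epochs, generation_time_years=gen_time)


def results_to_frame(results: list[SelectionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            dict(
                snp_id=r.snp_id,
                derived_freq=r.derived_freq,
                s_hat=r.s_hat,
                logLR_runs=";".join(f"{v:.6g}" for v in r.logLR_replicates),
                logLR_median=r.logLR_median,
                s_median=r.s_median,
                allele_age_generations=r.allele_age_generations,
            )
        )
    return pd.DataFrame(rows)


def write_results(results: list[SelectionResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All fixed thresholds and sizes of a pipeline run.

    Defaults follow the study conventions: neutrality rejection at the 95%
    percentile of the simulated null, LD expansion at r² >= 0.8, LD blocks
    at r² < 0.6, MAF > 0.05, minor derived count >= 4, eQTL FDR 10%, top-5%
    iHS outliers, selection window 0-500 generations ago.
    """

    seed: int = 1
    out_dir: str = "treesel_out"
    demography_path: str | None = None
    threshold_level: float = 95.0
    r2_expand: float = 0.8
    r2_block: float = 0.6
    min_maf: float = 0.05
    min_derived_count: int = 4
    fdr: float = 0.10
    ihs_top_fraction: float = 0.05
    window: tuple[float, float] = (0.0, 500.0)
    n_null_snps: int = 400
    null_n_samples: int = 30
    n_loci_per_scenario: int = 5
    ihs_n_haplotypes: int = 60
    ihs_sequence_length: float = 4e5

    def __post_init__(self) -> None:
        if not (0 < self.threshold_level <= 100):
            raise ValueError("threshold_level must be in (0, 100]")
        for name in ("r2_expand", "r2_block", "min_maf", "fdr", "ihs_top_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.window[0] > self.window[1]:
            raise ValueError("window start must not exceed its end")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where results land does not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
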
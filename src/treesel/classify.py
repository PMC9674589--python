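"""Classification of risk loci into selection-target vs hitchhiker scenarios.

Within a risk locus that shows a consistent selection signal, the SNP(s)
with the highest logLR are the likely sweep-driving mutations ("targets"),
while the SNP(s) with the highest PICS fine-mapping score are the likely
causal disease variants.  Comparing the two sets yields four scenarios:

* **A** — the top causal candidate is (one of) the selection target(s);
* **B** — the top causal candidate is a hitchhiker: weak LD (r² below the
  block cutoff) with every target;
* **C** — complex: strong LD (r² >= cutoff) between the top candidate and a
  stronger target, so neither explanation can be ruled out;
* **D** — the top causal candidate is untestable (no selection estimate).

Haplotype phase further splits A and B into sub-scenarios by whether the
risk or the protective allele of the top candidate rides with the selected
allele; loci with missing risk-allele annotation fall into dedicated
"allele-info-missing" classes (never guessed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix
from .ld import r_squared_matrix

__all__ = [
    "LocusEvidence",
    "ScenarioCall",
    "consistency_filter",
    "finemap_target",
    "selected_allele",
    "classify_locus",
    "summarize_calls",
    "evidence_from_table",
    "SUBSCENARIO_LABELS",
]

SUBSCENARIO_LABELS = {
    1: "risk allele is the selection target",
    2: "protective allele is the selection target",
    3: "risk allele hitchhiking",
    4: "protective allele hitchhiking",
    5: "target scenario, allele info missing",
    6: "hitchhiking scenario, allele info missing",
}


@dataclass
class LocusEvidence:
    """Per-risk-locus evidence table for classification.

    ``candidates`` must carry columns ``snp_id, logLR_median, s_median,
    pics, risk_allele, testable`` (optionally ``reason``, ``branch_id``).
    ``r2`` is the pairwise r² matrix among the candidates, in table order.
    ``haps`` (optional) provides phased haplotypes for phase sub-scenarios.
    """

    locus_id: str
    candidates: pd.DataFrame
    r2: np.ndarray | None = None
    haps: HaplotypeMatrix | None = None
    block_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"snp_id", "logLR_median", "s_median", "pics", "risk_allele", "testable"}
        missing = required - set(self.candidates.columns)
        if missing:
            raise ValueError(f"candidate table lacks columns: {sorted(missing)}")
        if len(self.candidates) == 0:
            raise ValueError("locus must have at least one candidate SNP")
        if self.r2 is not None:
            self.r2 = np.asarray(self.r2, dtype=float)
            k = len(self.candidates)
            if self.r2.shape != (k, k):
                raise ValueError("r2 matrix must be square over the candidates")

    def tested(self) -> pd.DataFrame:
        return self.candidates[self.candidates["testable"].astype(bool)]


def evidence_from_table(
    locus_id: str, table: pd.DataFrame, haps: HaplotypeMatrix | None = None
) -> LocusEvidence:
    """Assemble :class:`LocusEvidence` from a candidate table and haplotypes."""
    r2 = None
    if haps is not None:
        idx = [haps.index_of(s) for s in table["snp_id"]]
        r2 = r_squared_matrix(haps, idx)
    return LocusEvidence(locus_id=locus_id, candidates=table.reset_index(drop=True),
                         r2=r2, haps=haps)


def _distinct_branches(df: pd.DataFrame) -> int:
    """Count SNPs on distinct tree branches.

    Uses ``branch_id`` when available; otherwise SNPs with identical
    (logLR, s) values are assumed to share a branch (perfectly linked SNPs
    are assigned the same value).
    """
    if "branch_id" in df.columns and df["branch_id"].notna().any():
        return df["branch_id"].nunique()
    pairs = {(round(l, 9), round(s, 9)) for l, s in zip(df["logLR_median"], df["s_median"])}
    return len(pairs)


def consistency_filter(
    evidence: LocusEvidence, threshold: float, min_support: int = 2
):
    """Require a consistent, not single-SNP, selection signal at the locus.

    Passes iff the median logLR of the tested SNPs is at or above the
    threshold AND at least ``min_support`` SNPs on distinct tree branches
    exceed it.  An isolated spike (one high chunk amid low neighbours)
    fails.  Returns ``(passed, supporting_snp_ids, reason)``.
    """
    tested = evidence.tested()
    if len(tested) == 0:
        return False, [], "no testable SNPs at locus"
    med = float(tested["logLR_median"].median())
    above = tested[tested["logLR_median"] >= threshold]
    n_branches = _distinct_branches(above) if len(above) else 0
    if med < threshold:
        return False, [], f"median logLR {med:.3g} below threshold {threshold:.3g}"
    if n_branches < min_support:
        return (
            False,
            list(above["snp_id"]),
            f"only {n_branches} distinct branch(es) above threshold "
            f"(need {min_support}): isolated spike",
        )
    return True, list(above["snp_id"]), ""


def finemap_target(
    evidence: LocusEvidence, threshold: float, tie_tol: float = 0.5
) -> list[str]:
    """SNP set with logLR within ``tie_tol`` of the locus maximum.

    Fine-mapping resolution is bounded by LD: perfectly linked SNPs share a
    branch and hence a logLR value, and are returned together.
    """
    tested = evidence.tested()
    if len(tested) == 0:
        return []
    top = float(tested["logLR_median"].max())
    if top < threshold:
        return []
    hit = tested[tested["logLR_median"] >= top - tie_tol]
    return list(hit["snp_id"])


def selected_allele(s_median: float) -> str:
    """Which allele selection favours, from the sign of s (derived-allele
    convention: positive s means a rising derived-allele trajectory)."""
    if s_median > 0:
        return "derived"
    if s_median < 0:
        return "ancestral"
    raise ValueError("s == 0: selected allele undefined")


@dataclass
class ScenarioCall:
    """Per-locus classification outcome."""

    locus_id: str
    scenario: str  # 'A' | 'B' | 'C' | 'D'
    subscenario: int | None
    target_snps: list[str]
    top_pics_snps: list[str]
    selected_alleles: dict
    rationale: str = ""
    passed_consistency: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in {"A", "B", "C", "D"}:
            raise ValueError("scenario must be A, B, C or D")
        if self.subscenario is not None and self.subscenario not in SUBSCENARIO_LABELS:
            raise ValueError("unknown subscenario code")


def _phase_linked_allele(
    haps: HaplotypeMatrix, target_snp: str, target_allele: str, pics_snp: str
) -> str:
    """Allele of ``pics_snp`` on the majority haplotype carrying the selected
    allele of ``target_snp`` ('ancestral' or 'derived')."""
    t = haps.column(target_snp)
    p = haps.column(pics_snp)
    carrier = t == (1 if target_allele == "derived" else 0)
    if carrier.sum() == 0:
        return "derived" if p.mean() >= 0.5 else "ancestral"
    return "derived" if p[carrier].mean() >= 0.5 else "ancestral"


def _subscenario(scenario, evidence, targets, top_pics):
    """Phase sub-class for scenarios A and B (None for C and D)."""
    if scenario not in {"A", "B"}:
        return None, ""
    cands = evidence.candidates.set_index("snp_id")
    pics_snp = top_pics[0]
    risk = cands.loc[pics_snp, "risk_allele"]
    missing_code = 5 if scenario == "A" else 6
    if risk not in ("ancestral", "derived"):
        return missing_code, "risk-allele annotation missing"
    # selected allele of the (first classifiable) target, preferring the
    # top-PICS SNP itself when it is a target
    ordered = [t for t in targets if t == pics_snp] + [
        t for t in targets if t != pics_snp
    ]
    tgt = None
    for t in ordered:
        s = cands.loc[t, "s_median"]
        if pd.notna(s) and s != 0:
            tgt = (t, selected_allele(float(s)))
            break
    if tgt is None:
        return missing_code, "selected allele undefined (s == 0)"
    target_snp, sel_allele = tgt
    if scenario == "A" and pics_snp in targets:
        linked = sel_allele if pics_snp == target_snp else None
    else:
        linked = None
    if linked is None:
        if evidence.haps is None:
            return missing_code, "no haplotypes to resolve phase"
        linked = _phase_linked_allele(evidence.haps, target_snp, sel_allele, pics_snp)
    if scenario == "A":
        code = 1 if linked == risk else 2
    else:
        code = 3 if linked == risk else 4
    return code, SUBSCENARIO_LABELS[code]


def classify_locus(
    evidence: LocusEvidence,
    threshold: float,
    targets: list[str] | None = None,
    strong_ld: float = 0.6,
    tie_tol: float = 0.5,
    pics_tie_tol: float = 0.05,
    min_support: int = 2,
) -> ScenarioCall:
    """Assign the locus to scenario A/B/C/D with a phase sub-scenario.

    ``targets`` defaults to :func:`finemap_target`.  The top-PICS set is the
    reported candidates within ``pics_tie_tol`` of the maximum PICS.  The
    boundary between B (hitchhiking) and C (cannot rule out either) is the
    strong-LD cutoff ``strong_ld``, the same r² that defines LD blocks.
    """
    cands = evidence.candidates
    passed, _support, reason = consistency_filter(evidence, threshold, min_support)
    if targets is None:
        targets = finemap_target(evidence, threshold, tie_tol) if passed else []
    with_pics = cands[cands["pics"].notna()]
    if len(with_pics) == 0:
        raise ValueError("locus has no PICS-scored candidates")
    top_val = float(with_pics["pics"].max())
    top_pics = list(
        with_pics[with_pics["pics"] >= top_val - pics_tie_tol]["snp_id"]
    )
    sel_alleles = {}
    for t in targets:
        s = cands.set_index("snp_id").loc[t, "s_median"]
        sel_alleles[t] = (
            selected_allele(float(s)) if pd.notna(s) and s != 0 else "undefined"
        )

    top_rows = cands[cands["snp_id"].isin(top_pics)]
    if not top_rows["testable"].astype(bool).any():
        scenario, why = "D", "top-PICS SNP(s) untestable: no selection estimate"
    elif set(top_pics) & set(targets):
        scenario, why = "A", "top-PICS SNP is among the selection targets"
    else:
        strong = False
        if evidence.r2 is not None and targets:
            ids = list(cands["snp_id"])
            ti = [ids.index(t) for t in targets]
            pi = [ids.index(p) for p in top_pics]
            sub = evidence.r2[np.ix_(ti, pi)]
            strong = bool(np.nanmax(sub) >= strong_ld) if sub.size else False
        if strong:
            scenario, why = (
                "C",
                f"strong LD (r² >= {strong_ld}) between a target and the "
                "top-PICS SNP: cannot rule out either",
            )
        else:
            scenario, why = "B", "top-PICS SNP in weak LD with all targets: hitchhiker"
    sub_code, sub_why = _subscenario(scenario, evidence, targets, top_pics)
    rationale = why if not sub_why else f"{why}; {sub_why}"
    if not passed:
        rationale = f"consistency filter failed ({reason}); {rationale}"
    return ScenarioCall(
        locus_id=evidence.locus_id,
        scenario=scenario,
        subscenario=sub_code,
        target_snps=list(targets),
        top_pics_snps=top_pics,
        selected_alleles=sel_alleles,
        rationale=rationale,
        passed_consistency=passed,
    )


def summarize_calls(calls: list[ScenarioCall], n_tested_loci: int) -> pd.DataFrame:
    """Scenario counts and integer percentages over the tested loci.

    Percentages are ``round(100 * count / denominator)`` with the
    denominator made explicit in the table.
    """
    if n_tested_loci <= 0:
        raise ValueError("denominator n_tested_loci must be positive")
    counts = {s: 0 for s in ["A", "B", "C", "D"]}
    subcounts: dict[int, int] = {}
    for c in calls:
        counts[c.scenario] += 1
        if c.subscenario is not None:
            subcounts[c.subscenario] = subcounts.get(c.subscenario, 0) + 1
    rows = []
    for s in ["A", "B", "C", "D"]:
        rows.append(
            dict(
                scenario=s,
                count=counts[s],
                denominator=n_tested_loci,
                percent=int(np.floor(100.0 * counts[s] / n_tested_loci + 0.5)),
            )
        )
    for code in sorted(subcounts):
        rows.append(
            dict(
                scenario=f"sub{code}",
                count=subcounts[code],
                denominator=n_tested_loci,
                percent=int(np.floor(100.0 * subcounts[code] / n_tested_loci + 0.5)),
            )
        )
    return pd.DataFrame(rows)
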
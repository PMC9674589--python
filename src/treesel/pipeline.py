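"""End-to-end orchestration on synthetic data.

``run_pipeline`` chains the stages of the study workflow — simulate and
calibrate a demography-matched neutral null, generate risk-locus fixtures,
classify them into selection-target/hitchhiker scenarios, run the iHS
comparison scan, and match a synthetic eQTL table — writing TSV outputs
with a config hash and per-stage logging of filter counts.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import fisher_enrichment, match_eqtls
from .calibration import calibrate_threshold, simulate_null_distribution
from .classify import classify_locus, evidence_from_table, summarize_calls
from .demography import Demography, SimParams
from .ihs import call_ihs_outliers, ihs_scan, standardize_ihs
from .io import RunConfig, read_demography
from .simulate import coalescent_haplotypes, make_locus_fixture

logger = logging.getLogger("treesel")

__all__ = ["run_pipeline", "default_demography"]


def default_demography() -> Demography:
    """Desk-scale stand-in for a European-like size history: large present
    size, an intermediate bottleneck, and a moderate ancestral size."""
    return Demography(epochs=((0, 20000), (300, 5000), (3000, 10000)))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the result tables and writes them to
    ``config.out_dir``.  Outputs carry the config hash in a provenance file
    and as a ``# config_hash`` header line."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    dem = (
        read_demography(config.demography_path)
        if config.demography_path
        else default_demography()
    )

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, sep="\t", index=False)

    # stage 1: neutral null + threshold
    logger.info("stage=calibrate seed=%d n_snps=%d", stage_seed[0], config.n_null_snps)
    null = simulate_null_distribution(
        dem,
        n_snps=config.n_null_snps,
        n_samples=config.null_n_samples,
        seed=stage_seed[0],
        window=config.window,
        min_derived_count=config.min_derived_count,
        use_replicate_rule=False,
    )
    threshold = calibrate_threshold(null, config.threshold_level)
    _write(pd.DataFrame({"logLR": null.logLR_values}), "null_logLR.tsv")

    # stage 2: scenario fixtures -> classification
    logger.info("stage=classify seed=%d", stage_seed[1])
    rng = np.random.default_rng(stage_seed[1])
    calls, call_rows = [], []
    for scenario in "ABCD":
        for i in range(config.n_loci_per_scenario):
            haps, table, truth = make_locus_fixture(
                scenario, seed=int(rng.integers(2**31)), threshold=threshold
            )
            ev = evidence_from_table(f"{scenario}{i}", table, haps)
            call = classify_locus(ev, threshold=threshold, strong_ld=config.r2_block)
            calls.append(call)
            call_rows.append(
                dict(
                    locus=call.locus_id,
                    truth=truth["scenario"],
                    scenario=call.scenario,
                    subscenario=call.subscenario,
                    targets=",".join(call.target_snps),
                    top_pics=",".join(call.top_pics_snps),
                    rationale=call.rationale,
                )
            )
    calls_df = pd.DataFrame(call_rows)
    summary = summarize_calls(calls, n_tested_loci=len(calls))
    _write(calls_df, "scenario_calls.tsv")
    _write(summary, "scenario_summary.tsv")

    # stage 3: iHS comparison scan on a neutral panel
    logger.info("stage=ihs seed=%d", stage_seed[2])
    panel = coalescent_haplotypes(
        SimParams(
            n_samples=config.ihs_n_haplotypes,
            sequence_length=config.ihs_sequence_length,
            recombination_rate=1.25e-8,
        ),
        dem,
        seed=stage_seed[2],
    )
    ihs_table = ihs_scan(panel, maf_min=config.min_maf)
    if len(ihs_table):
        ihs_table = call_ihs_outliers(
            standardize_ihs(ihs_table, n_bins=10), config.ihs_top_fraction
        )
    _write(ihs_table, "ihs.tsv")

    # stage 4: synthetic eQTL matching + enrichment
    logger.info("stage=annotate seed=%d", stage_seed[3])
    rng = np.random.default_rng(stage_seed[3])
    cand = pd.DataFrame(
        dict(
            snp_id=[f"rs{i}" for i in range(40)],
            disease=rng.choice(["IBD", "MS", "psoriasis"], 40),
            pics=rng.random(40),
            logLR_median=rng.exponential(1.0, 40),
        )
    )
    tissues = ["T_cell", "monocyte", "liver"]
    eqtl = pd.DataFrame(
        dict(
            snp_id=rng.choice(cand["snp_id"], 300),
            gene=[f"GENE{i%30}" for i in range(300)],
            tissue=rng.choice(tissues, 300),
            p_value=np.concatenate(
                [rng.uniform(0, 1e-4, 40), rng.uniform(0, 1, 260)]
            ),
        )
    )
    matches, crosstab = match_eqtls(cand, eqtl, fdr=config.fdr)
    immune = {"T_cell", "monocyte"}
    in_imm = matches["tissue"].isin(immune)
    strong = matches["logLR_median"] >= threshold
    table2x2 = [
        [int((in_imm & strong).sum()), int((in_imm & ~strong).sum())],
        [int((~in_imm & strong).sum()), int((~in_imm & ~strong).sum())],
    ]
    try:
        fisher = fisher_enrichment(table2x2)
        fisher_out = {"odds_ratio": fisher.odds_ratio, "p_value": fisher.p_value}
    except ValueError:
        fisher_out = {"odds_ratio": None, "p_value": None}
    _write(matches, "eqtl_matches.tsv")
    _write(crosstab.reset_index(names="disease"), "eqtl_crosstab.tsv")

    provenance = {
        "config_hash": chash,
        "seed": config.seed,
        "threshold": threshold,
        "threshold_level": config.threshold_level,
        "null_provenance": null.provenance,
        "fisher_immune_enrichment": fisher_out,
        "counts": {
            "null_snps": null.n,
            "loci_classified": len(calls),
            "ihs_snps": int(len(ihs_table)),
            "eqtl_matches": int(len(matches)),
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return {
        "threshold": threshold,
        "null": null,
        "calls": calls_df,
        "summary": summary,
        "ihs": ihs_table,
        "eqtl_matches": matches,
        "eqtl_crosstab": crosstab,
        "provenance": provenance,
    }
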
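# treesel

Genealogy-based detection and fine-mapping of natural selection at disease
risk loci.

## The problem

Risk loci for inflammatory and autoimmune diseases often sit on unusually
long, common haplotypes — a classic footprint of positive selection.  But a
haplotype-level signal cannot say *which* SNP drove the sweep: the candidate
causal variant may be the selection target itself, or a neutral **hitchhiker**
dragged up in frequency by linkage with a nearby selected mutation.  Telling
these scenarios apart matters: variants with a real adaptive history are
prime candidates for functional follow-up.

`treesel` implements the full analysis as a tested, reusable pipeline for
population geneticists:

1. **Per-SNP selection test from local trees.**  For each SNP the genealogy
   of the sampled haplotypes (its local tree) is scored under a hidden
   Markov model of the derived-allele frequency trajectory x(t): backwards
   in time x(t) follows a Wright–Fisher diffusion with per-generation drift
   −s·x(1−x) and variance x(1−x)/2N; lineages carrying the derived allele
   coalesce at rate k(k−1)/2 / (2N·x), ancestral lineages at
   k(k−1)/2 / (2N·(1−x)).  The likelihood L(s) is maximized over a grid of
   selection coefficients, and evidence for selection is the log-likelihood
   ratio logLR = ln L(ŝ) − ln L(0) (natural log).  Selection acts inside an
   analysis window (default the last 500 generations).  Because the test is
   stochastic (trees are sampled), each SNP is run 2–3 times and assigned
   the median logLR and ŝ.
2. **Simulation-calibrated neutrality threshold.**  Genetic drift under the
   target population's demography inflates logLR; the null is therefore
   simulated under the matched piecewise-constant Ne history and the 95%
   empirical percentile of the neutral logLR distribution becomes the
   rejection threshold (at the cost of ~5% false rejections).
3. **Scenario classification.**  Within each risk locus, the SNP set with
   the top logLR (the putative selection targets) is compared with the SNP
   set with the top PICS fine-mapping score (the putative causal variants):
   scenario **A** (causal = target), **B** (causal is a hitchhiker, weak LD
   with every target), **C** (strong LD, r² ≥ 0.6 — cannot rule out either),
   **D** (top causal SNP untestable).  Haplotype phase further resolves
   whether the risk or the protective allele rides with the selected allele.
4. **Supporting machinery.**  LD tools (r², candidate expansion at r² ≥ 0.8,
   LD blocks at r² < 0.6), an iHS scan for method comparison, sample-QC /
   FDR / enrichment helpers, and a synthetic-data module that generates all
   inputs — trajectories, structured-coalescent genealogies conditioned on
   them, forward Wright–Fisher haplotypes, and scenario fixtures — with
   known ground truth.

## Worked example

Fit the selection model to genealogies of an ongoing sweep (s = 0.05,
diploid N = 1000) and compare against a simulation-calibrated threshold:

```python
import treesel as ts

dem = ts.Demography.constant(1000)          # 2N = 2000 haploid copies
traj = ts.conditioned_sweep_trajectory(0.05, dem, target_freq=0.6, seed=42)
d = int(round(traj.present_freq * 30))
trees = [ts.sample_genealogy(traj, 30, d, seed=s) for s in (1, 2, 3)]
fit = ts.SelectionModel(trees, dem, snp_id="sweep_demo").fit()
print(fit.summary())

null = ts.simulate_null_distribution(dem, n_snps=400, n_samples=30, seed=7,
                                     use_replicate_rule=False)
thr = ts.calibrate_threshold(null, level=95)
print("95% neutral threshold:", round(thr, 3))
```

prints

```
Selection likelihood fit
============================================
SNP id:              sweep_demo
trees in sample:     3
derived frequency:   0.6333
s_hat:               +0.043734
support interval:    [+0.04373, +0.04373]
logLR vs neutrality: 8.4087
allele age:          220.9 generations (6184 y)
window (gen ago):    (0.0, 500.0)
95% neutral threshold: 1.784
```

The true coefficient (0.05) is recovered as ŝ ≈ 0.044, the sweep's logLR
(8.4) is far above the neutral 95% threshold (~1.8), and the inferred allele
age (~220 generations) brackets the simulated origin (169 generations ago).

A thin CLI mirrors the library (`treesel simulate | calibrate | scan |
blocks | classify | ihs | annotate | report | pipeline`); `treesel pipeline`
runs all stages end to end on synthetic data and writes TSV outputs with a
config hash.

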
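# Methods

This note documents the models implemented in `treesel`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## Selection likelihood from a local tree

### Model

For a focal SNP with derived-allele count d among n sampled haplotypes, the
observation is the SNP's local genealogy: topology, node times (generations
before present, tips at 0), and the branch carrying the derived mutation.
The latent variable is the population derived-allele frequency trajectory
x(t), t in generations before present.

Backwards in time, x(t) is modelled as a Markov chain with per-generation
moments

* drift: −s·x(1−x) − x/(2N(t))
* variance: x(1−x)/(2N(t))

The first drift term is the time reversal of additive (genic) selection
with coefficient s on the derived allele; the second is the h-transform
conditioning drift of a currently segregating allele traced back to its
origin (the time-reversed neutral Wright–Fisher walk of an allele destined
to be absorbed at 0 under the stationary 1/x influx density).  The
conditioning term is applied identically at every s so that likelihood
ratios compare only the selection component.  N(t) is a piecewise-constant
diploid effective size (`Demography`); 2N(t) haploid copies enter all
rates.

**Selection convention.** s is additive per derived-allele copy in the
linearized sense: the forward per-generation mean change is s·x(1−x)
(`wf_transition`).  Genotype fitnesses 1 : 1+s : 1+2s give the same
expression to first order in s.  Positive s means a rising derived-allele
trajectory; ŝ > 0 therefore calls the derived allele selected and ŝ < 0 the
ancestral allele.

**Emissions.** Between events, k lineages of the derived class survive one
generation with probability exp(−h_d), h_d = k(k−1)/2 / (2N·x); the
ancestral class analogously with 1−x.  A class-internal coalescence at time
t contributes its hazard as a density.  This continuous-hazard convention
matches the structured-coalescent generator exactly and reduces to the
familiar exponential waiting-time density when x is constant (the
two-lineage closed form ln(1/(2N·x)) − T/(2N·x) is reproduced to machine
precision by the clamped-trajectory mode).

**Origin conditioning.** The mutation branch spans [t_child, t_parent]
(derived-class MRCA up to its parent node).  The filter requires the latent
trajectory to be absorbed at frequency 0 inside that interval: mass
reaching the origin state earlier is impossible given extant derived
lineages and is discarded; mass never absorbed by t_parent contributes
nothing.  After absorption, ancestral-class emissions continue at x = 0
rates; cross-class events above t_parent are dropped — they are (to a very
good approximation) identical under all s and cancel from the likelihood
ratio.  When the mutation sits on the root branch (no t_parent) the filter
integrates to t_child without origin conditioning and flags the case.

**Selection window.** s acts only within a window of generations before
present (default (0, 500], following the idea of testing recent selection
on standing variation); outside the window the trajectory evolves neutrally
(conditioning drift only).  The window is a model parameter; a (0, 0)
window makes all s equivalent and returns logLR = 0.

**Initial condition.** At t = 0 the interior grid states are weighted by
the binomial likelihood Binom(d; n, x) of the observed derived count
(`anchor="binomial"`); the implicit prior is uniform mass per logit bin,
i.e. density ∝ 1/(x(1−x)), close to the neutral site-frequency spectrum.

### Discretization

The frequency grid has `n_bins` (default 50) logit-spaced interior bins on
(grid_lo, 1−grid_lo) with grid_lo = 5·10⁻⁴, plus one absorbing origin
state fed by mass crossing the lowest bin edge.

Transitions are built **per inter-event segment**, not by powering a
one-generation kernel: for a segment of dt generations the deterministic
mean path is integrated (Euler, ≤64 substeps) and the accumulated variance
∫ x(1−x)/2N dt along it defines a single Gaussian step, discretized over
the bin edges with the source mass treated as uniform within its bin
(3-point quadrature).  This matters: iterating a 1-generation kernel on a
coarse grid loses nearly all mid-frequency diffusion (the one-step spread
is much smaller than a bin, so mass re-centres every step), which distorts
the absorption-time law by an order of magnitude and — because extra
downward drift then masquerades as positive selection — biases ŝ upward on
neutral data.  Segments are decomposed greedily into cached step sizes
{1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256}; matrices are
cached per (s, N, dt, grid).  Event times are rounded to whole generations.

The filter is run batched over the whole s grid (default: symmetric
log-spaced, ±[10⁻⁴, 0.2], 6 points per side, plus 0 — 13 values), with
per-step renormalization; log-normalizers accumulate the log-likelihood.

### Estimation and replication

`SelectionModel.fit()` averages the per-tree likelihood over the supplied
tree sample in likelihood space (log-sum-exp), maximizes over the s grid,
and reports ŝ, logLR = log L(ŝ) − log L(0) ≥ 0 (natural log), a
profile-likelihood support interval (ΔlogL ≤ 1.92 by default), and the
allele age.  Because a single run consumes a stochastic tree sample, the
per-SNP pipeline (`replicate_median`) runs the fit twice on fresh tree
draws, adds a third run when the two logLR values differ by more than 2
units, and assigns the median logLR and median ŝ.  Drawing independent
genealogies per replicate stands in for re-sampling branch lengths of one
inferred tree (the package consumes true or externally inferred trees and
does not re-implement branch-length MCMC).

**Allele age** is the midpoint of the mutation branch,
(t_child + t_parent)/2 generations, converted to years with the
demography's generation time (default 28 years).  On a root branch the
lower end plus a configurable offset is returned and flagged.

## Null calibration

Drift under the target demography inflates logLR, so the rejection
threshold is the nearest-rank 95% percentile (rank ⌈0.95·n⌉) of a simulated
neutral logLR distribution, with percentile level, floor on n (default
100), and provenance recorded.  Desk-scale defaults: ≥2000 independent
neutral SNPs, 30 haplotypes per tree.  Each null SNP is built as

1. a present-day frequency drawn from the ascertained neutral SFS
   (density ∝ 1/x on [0.01, 0.99], binomial sampling to the sample count,
   minor derived count ≥ 4 — the simulated-data ascertainment rule; the
   empirical-scan path uses MAF > 0.05 instead, both rules independently
   switchable in `ascertain_snps`);
2. a backward neutral trajectory (binomial Wright–Fisher with the −x/2N
   conditioning drift) run to its origin;
3. fresh structured-coalescent genealogies conditioned on that trajectory,
   scored by the likelihood above.

Deterministic thinning (`thin_snps`, keep every 76th by default, 1-based)
decorrelates genome-scale SNP sets before calibration; the pipeline order
is fixed: filter first, then thin.  `false_rejection_rate` evaluates a
calibrated threshold on an independently seeded batch; by the
order-statistic argument the expected rate is ~5% regardless of the exact
shape of the null, which is the property the acceptance checks exercise
(the published full-scale threshold value itself depends on biobank-scale
data and is not reproduced here).

## Synthetic-data generators

* `simulate_trajectory` — forward binomial Wright–Fisher with additive
  selection; deterministic (infinite-N) mode available; boundaries
  absorbing.  `conditioned_sweep_trajectory` restarts from one copy until
  the allele reaches a target frequency (an ongoing sweep "today").
* `backward_neutral_trajectories` — the h-transformed neutral walk above,
  vectorized in two passes with a shared random stream.
* `sample_genealogy` — structured coalescent conditioned on a trajectory:
  derived/ancestral classes coalesce at k(k−1)/2 / (2N·x) and
  k(k−1)/2 / (2N·(1−x)) per generation (continuous-hazard inversion on the
  per-generation cumulative hazard); at the origin the last derived lineage
  joins the ancestral class and a standard piecewise-exponential coalescent
  finishes the tree.  Derived lineages uncoalesced at the origin are
  force-joined just below it and flagged.
* `simulate_haplotypes` — desk-scale forward Wright–Fisher (N ≤ 500
  diploids by design) with uniform recombination and infinite-sites
  mutation on a continuous sequence; tracks the pedigree at a selected site
  so the *true* local tree and trajectory of the planted sweep are
  returned; lost sweeps are retried from the pre-onset population state.
  The returned tree is fully resolved only within the recorded sweep
  window: neutral lineages that fail to coalesce within it are star-joined
  above (flagged `forced_root`).  A no-op callability-mask hook is exposed
  for site filtering.
* `coalescent_haplotypes` — neutral phased haplotype panels via msprime,
  used where forward simulation would be too small (e.g. iHS panels);
  msprime is never used inside the likelihood.
* `make_locus_fixture` — constructs risk-locus fixtures realizing each
  classification scenario by planting a selected SNP, a top-PICS SNP in a
  controlled LD/phase configuration (empirically verified r² bands with
  retries), supporting high-LD SNPs, fillers, and per-SNP selection
  statistics with noise.  Fixture r² bands deliberately avoid the 0.6
  decision boundary, so classifier-recovery rates quantify the decision
  logic, not boundary noise.

What the generators do **not** emulate: chromosome-scale sequence,
empirical recombination maps (constant rate only), callability masks,
tree-inference error (trees are true by construction), overlapping/linked
null loci (null SNPs are independent), and biobank sample sizes.  Passing
tests therefore validate the algorithms under the stated model, not the
published biobank estimates.

## Scenario classification

Per locus, candidates carry (logLR median, s median, PICS, risk allele,
testable flag) and pairwise r².

* **Consistency filter**: median logLR of tested SNPs ≥ threshold AND at
  least `min_support` (default 2) SNPs on distinct tree branches above it
  (SNPs with identical statistics are treated as one branch when no branch
  id is given) — an isolated single-chunk spike fails.
* **Fine-mapping**: all SNPs within `tie_tol` (default 0.5 logLR units) of
  the locus maximum form the target set; perfectly linked SNPs share a
  value and are returned together.
* **Letters**: D if every top-PICS SNP (PICS within 0.05 of the maximum) is
  untestable; A if the top-PICS set intersects the target set; otherwise C
  when some target has r² ≥ 0.6 with a top-PICS SNP (the same cutoff that
  defines LD blocks — strong LD makes target and causal indistinguishable),
  else B (hitchhiking).
* **Sub-scenarios** (A and B only): the allele of the top-PICS SNP carried
  by the majority of haplotypes bearing the selected allele of the target
  determines whether the risk (codes 1/3) or the protective allele (2/4) is
  selected/hitchhiking; missing risk-allele annotation is never guessed and
  maps to dedicated codes (5/6).  Phase is read from haplotype
  co-occurrence, not signed D′ — simpler and directly testable.

Counts and integer percentages (round-half-up, explicit denominators) come
from `summarize_calls`.

## LD tools

r² is the composite (p_AB − p_A·p_B)² / (p_A(1−p_A)p_B(1−p_B)) on phased
0/1 columns; monomorphic columns yield NaN (undefined, never 0).  Candidate
expansion adds every matrix SNP with r² ≥ 0.8 to a reported SNP
(idempotent; expanded SNPs carry no PICS).  LD blocks are connected
components of the r² ≥ 0.6 graph — single linkage realizes exactly the
guarantee that any two SNPs in *different* blocks have r² < 0.6, while
within-block pairs may be weaker.  Blocks are ordered by leftmost position;
`top_haplotypes` reports the k most frequent haplotype strings with
lexicographic tie-breaks.

## iHS

EHH(x) is the probability that two random carriers of the core allele are
identical between the core and x; it is integrated (trapezoid) over
genetic distance in both directions until EHH < 0.05 (Selscan-compatible
default; curves reaching the region edge first are flagged truncated, with
a keep-or-drop policy).  A constant cM/Mb map (default 1) is assumed when
no genetic map is supplied.  iHS_unstd = ln(iHH_ancestral/iHH_derived) is
standardized to mean 0, SD 1 within derived-allele-frequency bins (default
50 equal-width bins; sparse bins merge rightwards, minimum 10 scores per
bin); outliers are the top 5% by |standardized score|, with boundary ties
all included and the realized |iHS| cutoff reported.

## Annotation helpers

Sample QC applies, in order: PC1/PC2 outside the nearest-rank [2.5, 97.5]
percentile range; top/bottom 2.5% singleton counts; total pairwise IBD ≥
166.2 cM with **more than one** other sample.  Each rule is evaluated on
the survivors of the previous ones; with the nearest-rank convention,
values equal to a percentile bound are kept, so degenerate constant columns
remove nothing.  FDR control is Benjamini–Hochberg step-up (deterministic
default) with an optional Storey π₀ variant (λ = 0.5); eQTL significance is
controlled within each tissue before joining on SNP id, and candidates with
no significant match are reported in an explicit "no eQTL" column.
Enrichment uses the exact two-sided Fisher test, with a Haldane 0.5
correction (flagged) for odds ratios involving zero cells.

## Reproducibility

Every stochastic operation takes an explicit seed and records it in
metadata; the pipeline derives stage seeds from one master seed via
`SeedSequence` and stamps all outputs with a configuration hash (the output
directory is excluded from the hash).  Re-running with the same
configuration is byte-identical.

## Known limitations

* **Neutral ŝ median bias.**  On neutral simulations the ŝ distribution
  has a small positive median, of order +0.001 to +0.003 — an order of
  magnitude below the weakest selection the recovery checks target
  (s = 0.05 is recovered near 0.044).  The residue traces to discretization
  mismatch between the generator and the grid chain over very short
  inter-event segments (the filter is exactly sign-balanced on data
  simulated from its own discretized law).  "Centred at zero" is therefore
  verified as |median ŝ| ≤ 0.005 rather than by a sign test, which at
  hundreds of replicates would detect this scientifically irrelevant
  offset.  The empirical-percentile calibration absorbs the offset by
  construction.
* Post-origin cross-class emissions are dropped from the likelihood; this
  is common to all s and cancels from logLR to first order.
* Event times are rounded to whole generations inside the filter
  (sub-generation timing from the continuous-hazard generator is ignored).
* Grid-induced error: with the default 50-bin logit grid the absorption-
  time law of the latent chain tracks the binomial walk to within a few
  percent; finer grids trade accuracy against the cached-matrix budget.
* The forward haplotype simulator is desk scale (N ≤ 500 diploids) and its
  selected-site trees are unresolved above the recorded sweep window.
* logLR values are in natural-log units; thresholds calibrated in one base
  are not comparable to thresholds computed in another.
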
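# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `flaxgs` pipeline. It is the place where
design decisions that were genuinely open are recorded.

## The synthetic breeding system

No real genotype or phenotype data ships with the package; every analysis
runs on populations from `flaxgs.simpop`, built to have the statistical
structure the downstream methods assume.

**Founder panel.** Founders are fully inbred accessions of a selfing crop.
Haplotypes come from a sequential Markov copying process: the first `n_seed`
(default 16) haplotypes are independent Bernoulli draws with per-locus alt
frequency from `target_maf_dist` (default Uniform(0.1, 0.5)); each later
haplotype copies segments from previously generated ones, switching template
at `copying_rate` per Morgan (default 0.1) and mutating per locus with
probability `mutation_rate` (default 0.001). Each founder is one haplotype
doubled. Consequences of these defaults:

- nearby loci share template segments, so LD is strong and decays with map
  distance — the regime the confidence-interval block definition needs;
- the effective number of independent chromosome segments is small relative
  to a 200–300-line training set, which is what makes within-population
  genomic prediction approach its heritability ceiling, as observed in
  selfing crops with narrow effective population size;
- realized mean π sits slightly below the configured target
  E[2p(1−p)] ≈ 0.39 (seed-pool sampling and copying drift each remove a few
  percent of heterozygosity), in the 0.28–0.40 range typical of diverse
  flax collections.

The defaults were calibrated once against these three behaviors and then
frozen. π is monotone in the configured diversity target, which the suite
checks.

**Crosses.** `make_biparental` derives all lines from a single F1 of two
founders. Meiosis uses the Haldane model — crossover count Poisson in the
chromosome map length, positions uniform, no interference — the simplest
defensible choice when no interference data exist. RIL_F6 lines are produced
by five explicit generations of selfing with both haplotypes tracked, so
residual heterozygosity ((1/2)⁵ ≈ 3.1% at F1-heterozygous loci) and
breakpoint density emerge mechanically rather than analytically. DH lines
double one F1 gamete. Progeny alleles are always copies of parental alleles.

**Trait and trials.** The trait is strictly additive: effects at `n_qtl`
random loci drawn standard normal, true breeding value = dosage · effects,
centered. Non-genetic variance is set so the plot-level narrow-sense h²
matches the request exactly (a `gxe_fraction` of it can be labelled G×E;
default 0 keeps the entry-mean heritability closed form simple). Trials
follow the multi-subset RCBD design: lines split across experiments, a fixed
check set in every experiment, per-plot value = μ + g + year + location +
G×E + block + residual, every component drawn from its configured SD from a
single seeded generator. With 8 experiments × 37 lines + 5 checks the design
has 42 entries per experiment, the configuration used throughout.

**GBS noise** is call-level only: each call independently missing with
`missing_rate`, and retained calls flipped to a random other dosage with
`error_rate`. Read-level simulation is out of scope.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: ascertainment bias of SNP discovery, spatial field
trend (no MAD-style adjustment is implemented), dominance/epistasis,
selection during population development, genotype-calling error correlated
with depth, and population structure beyond the single copying pedigree.

## Marker representations

**D′ confidence intervals.** Haplotype frequencies for a locus pair are
estimated by EM from the 3×3 unphased genotype table (double heterozygotes
are the only ambiguous class; under full inbreeding they are rare and the
estimate is effectively haploid counting). The 95% CI on |D′| follows the
Haploview convention: the multinomial likelihood of the observed table is
evaluated on a grid of |D′| values (allele frequencies held at their
estimates, D̂'s sign retained), normalized to sum to one, and the 5th/95th
percentiles of the cumulative weights are the bounds. Grid resolution is 101
points (configurable); the default thresholds are the algorithm's published
ones — CI-low ≥ 0.70 with CI-high ≥ 0.98 for strong LD, CI-high < 0.90 for
strong recombination, inconclusive otherwise.

**Blocks.** A candidate interval qualifies when its endpoint pair is in
strong LD and ≥ 95% of informative pairs inside it (pairs not inconclusive,
both MAFs ≥ 0.05) are in strong LD. Overlaps are resolved greedily by
descending locus span, ties to the leftmost — mirroring the reference
implementation's behavior. The block finder is verified against an
exhaustive enumeration oracle on all inputs with ≤ 12 loci. Span is capped
at 50 loci by default to bound the O(L·span) pair computation.

**HAP encoding.** The numeric encoding of multi-allelic block loci is this
package's own choice (the source tooling never specifies one): each
haplotype allele with frequency ≥ 0.05 becomes a column holding the carried
count (0/2 for inbred lines), rarer alleles pool into one column, and lines
heterozygous inside the block contribute frequency-weighted average dosages.
Columns of a block always sum to 2 per line, so the features stay
linear-algebra-compatible and closure is testable.

**PC markers** are principal components of the centered (unscaled) training
dosage matrix; N is the smallest count reaching 95% cumulative explained
variance, capped at min(n−1, p) with a warning. PCA is fitted on training
samples only and test samples are projected with training means and
loadings — fitting on combined data would leak test structure into the
features, which the leakage canary test would catch.

## Population statistics

π per SNP uses the unbiased pair-count form [C(m,2) − C(a,2) − C(m−a,2)] /
C(m,2) on non-missing alleles (complete case per locus), averaged over loci
with ≥ 2 alleles. F<sub>ST</sub> is the two-population Weir–Cockerham
estimator: per-locus components a (among populations), b (among individuals
within), c (within individuals) from sample sizes, allele frequencies and
observed heterozygote frequencies, combined as Σa / Σ(a+b+c) across loci.
Negative per-locus components are retained, per the original estimator;
loci monomorphic overall or with fewer than two genotyped individuals in a
population are excluded.

## Phenotype analysis

Stage 1 fits value = line + block by least squares within each experiment
(blocks fixed: experiments are small and a pure LS solve keeps stage 1
deterministic) and reports line lsmeans, which equal raw means in balanced
designs. Connectivity is checked on the line-block incidence graph and
disconnected designs are rejected naming the orphan lines. Stage 2 models
stage-1 means as μ + experiment (fixed) + line (random) + residual.
Variance components are REML estimates; the likelihood is profiled over the
ratio σ²ₑ/σ²_g on the eigenbasis of ZZ′ and maximized by bounded scalar
search (tolerance 1e-8). Plain EM-REML was tried first and stalls
sublinearly when σ²_g approaches zero, so the profiled search is used
throughout; the boundary maps to the edge of the search range and is
reported as σ²_g = 0. BLUPs are returned on the trait scale (grand mean +
shrunken deviation) and verified against a direct V⁻¹ GLS solve. Stage-1
standard errors are carried but stage 2 is unweighted by default. Dual
seed-source estimates are merged by inverse-variance weights when SEs are
available, equal weights otherwise, with the cross-source Pearson r
reported; a constant source is flagged and the merge falls back to the
other source.

## Prediction engines

RR-BLUP and GBLUP share one REML core: with K the marker kernel (ZZ′ or the
VanRaden G + 1e-6 diagonal jitter), the profiled restricted likelihood over
log λ ∈ [−12, 12] is minimized by bounded search (xatol 1e-8). Marker
effects back out as u = Z′(K + λI)⁻¹(y − μ̂); GBLUP predictions for new
samples go through the identical centered-marker path, which equals the
cross-kinship formulation exactly and keeps APP prediction trivial. Feature
identity between fit and predict is enforced by name, never by position.

The elastic net delegates to scikit-learn's coordinate descent with the
penalty chosen by inner 5-fold CV over a log-spaced grid; the pure-ridge
limit (mixing parameter 0) is solved in closed form since coordinate
descent does not support it. Coefficients are reported on the original
feature scale.

The Bayesian ridge is a single-site Gibbs sampler with conjugate
normal/scaled-inverse-χ² updates (default 2000 iterations, 500 burn-in,
prior df 4, prior scales set so the prior modes split var(y) 50/50 between
marker and residual variance). With variances fixed it converges to the
matching ridge solution within Monte-Carlo error, which the suite checks.
Chains are seeded and reproducible.

The stacking ensemble regresses the phenotype on out-of-fold base
predictions by non-negative least squares with an intercept, then combines
full-data base fits with those weights. Duplicating a base leaves
predictions unchanged; a pure-noise base receives (near-)zero weight. The
default base set is RR-BLUP + elastic net + Bayesian ridge; ML/DL models
are deliberately not implemented — the pluggable `GSModel` interface
(`register_model`) is the extension point, reflecting the conclusion that
well-regularized linear models are the reliable default for this problem.

## Evaluation

PA is Pearson r on raw values (standardization is display-only; r is
scale-invariant). CV uses seeded fold assignments, k = 5 folds × 10
partitions = 50 replicates by default; any sample-dependent feature
construction must run inside the training fold, which the `featurizer` hook
makes structural, and a canary test injects a test-fold-phenotype feature
and asserts PA does not rise. APP is a single-replicate evaluation of a
model fitted on one full population and applied to an independent,
harmonized one. The marker-density study samples SNP subsets without
replacement per (bin, replicate) from RNG streams derived from the master
seed, refits everything per subset (variance components included), and
reports mean ± SD per bin; the plateau is operationalized as the smallest
bin reaching 99% of the best bin mean.

## Decisions and economics

Advancement thresholds are the benchmark check's observed value in observed
space and its predicted value in predicted space (two reference lines, one
per axis); comparisons are strict, so a tie with the check does not
advance — ties are implausible on continuous data but the rule must be
deterministic. Reduction = 100·(n_total − n_advanced)/n_total and retention
= 100·|advanced ∩ superior|/|superior| round to the nearest integer, half
away from zero; retention is flagged undefined when no line beats the check
on observed values.

Money is handled as exact rationals of cents. The per-sample GBS cost
a·x + b (defaults a = 1.3594 CAD per million PE150 reads, b = 17.121 CAD)
is truncated — not rounded — to cents, which is required for the per-sample
and program totals to be internally consistent at the published defaults.
The per-line phenotyping default ($195) counts two $75 plots plus FAME and
disease screening at two replications each ($10 and $12.50 per rep); all
components are configurable. Advanced-line counts use nearest-integer
rounding; savings are relative to the conventional program and a zero
conventional cost is rejected as undefined.

## Problem sizes

The shipped study runs at desk scale by choice: a 301-line founder panel
with ~2,000 polymorphic SNPs on 5 chromosomes of 1.5 Morgans, 91 RILs and
76 DH lines, 8 experiments × 42 entries × 2 replications, 50 CV replicates
for the eigen-solved models and 10 for the samplers, and 10 subsampling
replicates per marker bin. The heavy samplers (Bayesian ridge, ensemble)
run on 400-SNP random subsets in the drivers, past the observed PA plateau.

## Known limitations

- One random effect in stage 2: year/location/G×E strata are collapsed into
  the generic "experiment" term; no spatial or AR1 residual models.
- Imputation is marginal (mean or mode), not LD-phasing-based; adequate for
  ridge-type predictors, not for haplotype reconstruction of missing-heavy
  data.
- Harmonization drops allele mismatches rather than attempting strand or
  ref/alt flips.
- The block finder's exhaustive-oracle guarantee is established on small
  inputs; large-input behavior relies on the same code path plus the span
  cap.
- FST is pairwise (two populations per call); multi-population estimators
  are out of scope.
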
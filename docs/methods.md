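# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make output
reproducible.

## Data model and conventions

Ct (cycle-threshold) values are treated as given: no amplification-curve
processing. A Ct value is log-scale by nature (one cycle ≈ one
doubling of template), so all noise models and averages operate
directly on Ct. Undetected reactions are stored as missing and never
imputed — imputing the max cycle number would silently deflate a
gene's apparent variability — and the stability algorithms require
complete cases (`complete_case` drops any sample missing a value among
the genes under analysis, and refuses to proceed below 3 samples or 2
genes, where the statistics are undefined).

Everywhere a standard deviation appears it is the sample SD with the
n−1 denominator. This matches conventional qPCR reporting; BestKeeper's
original mean-absolute-deviation dispersion is available as an explicit
option (`sd_variant="mean_abs_dev"`) rather than a silent default.
Technical replicates in long-layout input are collapsed by arithmetic
mean of Ct (Ct is already log-scale, so this is a geometric mean of
quantities); how replicates were handled ahead of analysis is rarely
stated in publications, so the choice is documented here rather than
inferred.

## Stability algorithms

**Comparative ΔCt.** For genes j,k, V_jk = SD over samples of
(Ct_j − Ct_k); the statistic is mean_{k≠j} V_jk. Per-sample global
shifts (loading differences) cancel exactly in the differences.

**geNorm.** Ct values are transformed to relative quantities
q_sj = A_j^(min_s Ct_sj − Ct_sj), with A_j the gene's amplification
factor (default 2.0 for every gene, under which log₂ q differences are
exactly negated Ct differences and the first-round M value coincides
with the comparative-ΔCt statistic — a cross-check the test suite
enforces to 1e−10). M_j is the mean SD of log₂(q_j/q_k) over partners;
the gene with the highest M is removed and M recomputed until two genes
remain. Each gene's reported statistic is its M at elimination; the
final pair shares the final M and rank 1, with remaining dense ranks
following reverse elimination order (equal statistics share a rank).
geNorm's V_{n/n+1} pairwise variations of successive normalisation
factors are reported in `aux` for information only; the 0.15 cutoff is
deliberately not implemented as a decision rule. Ties for elimination
break to the lexicographically last gene id, making runs reproducible.

**NormFinder.** Sample-centred values d_sj = Ct_sj − mean_genes(Ct_s·)
remove the shared loading effect. With n genes, the model
Ct = α_j + u_s + ε_sj (Var ε = σ²_j) implies
Var(d_j) = σ²_j(n−2)/n + Σσ²/n², and summing over genes closes the
system: σ̂²_j = n/(n−2)·[v_j − Σv/(n(n−1))], where v_j is the observed
centred variance. Negative estimates — possible at small n — truncate
to zero before the square root. The ungrouped statistic √σ̂²_j is the
default because the aggregated workflow this package mirrors does not
consume group labels; the grouped (Andersen-style) mode combines the
per-group decomposition with the systematic between-group deviation:
mean_g(|γ̂_jg| + √(σ̂²_jg/m_g)). The decomposition needs ≥ 3 genes, and
grouped mode ≥ 2 groups of ≥ 3 samples.

**BestKeeper.** The index is the per-sample geometric mean of all
candidate Ct values; each gene reports geometric/arithmetic mean,
min/max, dispersion, CV% (= 100·dispersion/mean) and Pearson r (with
two-sided p) against the index. The ranking statistic is the
dispersion; genes at ≥ 1 cycle are flagged unstable following the
conventional SD < 1 stability rule. Note that unlike the other three
methods BestKeeper's statistic is *not* invariant to per-sample loading
shifts — this is a known property of the method, not a defect, and the
invariance suite tests it only for the other three.

**Comprehensive ranking.** The geometric mean of the four dense method
ranks, computed at full precision and rounded to two decimals only for
reporting. Dense tie-shared integer ranks are used exactly as
tabulated, which is the convention under which published
geometric-mean cells reproduce from their printed sub-ranks. The paper
trail never exhibits a comprehensive tie, so a deterministic tie-break
was chosen: smaller comparative-ΔCt statistic first, then gene id.

## Standard curves

Duplicate dilution points enter the OLS regression of Ct on
log₁₀(dilution) as separate observations (preserving degrees of
freedom for R²) rather than being pre-averaged. The efficiency
relation is fixed to the universal convention
E% = (10^(−1/slope) − 1)·100. A fitted non-negative slope returns a
flagged curve with NaN efficiency instead of raising, since screening
runs should not abort on one failed assay. Published slope/efficiency
tables are not always internally consistent under this relation
(rounded slopes, transcription slips), which is why the package derives
efficiency from the fitted slope and never trusts printed pairs.

## Synthetic data generator

The generative model is
Ct(s, g) = baseline_g + u_s + Σ(matching shifts) + ε_sg with
u_s ~ N(0, sample_effect_sd²) shared across genes and
ε_sg ~ N(0, noise_sd_g²). Gaussian noise on the Ct scale is the
standard qPCR error model. The shared loading effect u_s is what makes
stable genes co-vary; without it every method sees only independent
noise and has nothing to separate. Its default SD of 0.5 cycles is this
package's choice of a realistic RNA-input spread, not an estimate from
data — published tables report only marginal per-gene SDs, which do not
identify the variance decomposition.

The default design: five genes at baseline Ct 12.36 (18S), 27.42
(GAPDH), 26.12 (ACTB), 27.86 (TOP1), 37.19 (RPS29) cycles with
per-gene noise SDs 1.139/1.170/1.858/1.366/1.641, six treatment groups
× two locations × n = 10, and a +1.78-cycle RPS29 shift in
gravity-dependent tissue (38.97 − 37.19). Optional censoring at 45
cycles is off by default; RPS29 runs near cycle 39 and censoring is a
realism knob, not needed for any test.

What the generator does **not** emulate: correlated regulation between
candidate genes (beyond the shared loading effect), amplification-curve
artefacts, inhibitors, heteroskedastic noise at high Ct, or
batch/plate effects. Passing tests therefore demonstrate algorithmic
correctness and recoverability under the stated model, not performance
on any particular real dataset — in particular the synthetic cohort
rankings need not reproduce published rankings, which depend on the
unpublished raw data's correlation structure.

**Recovery benchmark.** The parameter-recovery experiment
(`unstable_benchmark_design`) keeps the default structure but
homogenises candidate technical noise at 0.5 cycles and injects one
extra gene carrying a +3-cycle shift in half the treatment groups.
The homogenisation matters: the injected gene's marginal Ct variance is
0.5² + 3²/4 = 2.5 cycles², and under the heterogeneous Table-style
noise SDs a candidate with SD 1.86 (variance 3.45) would legitimately
be *more* variable than the injected gene, so marginal-variance methods
(ΔCt, geNorm, BestKeeper) could not and should not rank the injected
gene last. With homogeneous noise all four methods rank it last in
essentially every replicate (200/200 at the default settings). The
grouped NormFinder mode is additionally tested against the
heterogeneous design, where its between-group term isolates the shift.

## Relative expression

ΔΔCt centering uses the arithmetic mean ΔCt of the control group
(standard Livak formulation); consequently the geometric mean of
control-group fold changes is exactly 1. With multiple reference genes
the mean of their Ct values is used, i.e. geometric-mean normalisation
on the quantity scale. Group summaries are mean ± SEM of per-sample
fold changes, matching how such results are conventionally plotted.
The omnibus test is a one-way ANOVA; per-group contrasts against the
control use Welch t-tests with Holm adjustment and 0.05/0.01/0.001
star tiers — publications rarely state their post-hoc procedure, and
this is documented as this package's choice. Statistics run on fold
changes by default to match the reporting scale, but `scale="log"`
(ΔΔCt) is provided and is statistically preferable: under Gaussian Ct
noise the F null is exact on the log scale, which is also the scale
the type-I calibration test uses. Fold changes are lognormal, so their
arithmetic mean is biased above 2^(designed shift); recovery checks
compare against the per-dataset SEM, the uncertainty a single study
would report. An efficiency-corrected fold change (per-gene
amplification factors, Pfaffl-style) is available as an option; the
classical 2^(−ΔΔCt) is the default.

`location_compare` runs, per treatment group, a two-sided Welch t-test
of a gene's Ct between the two tissue locations with quartile/min/max
summaries for box-plot-style reporting; arms below n = 2 are skipped
with a warning.

## Problem sizes and determinism

Simulation-backed checks use 50–200 seeded replicates of the 120 × 5
default design (or smaller two-gene designs for expression
calibration) and a 1000-replicate null for the ANOVA type-I rate —
sizes at which Monte-Carlo error is small relative to the tested
effects while the full suite stays fast. Every stochastic component
accepts an explicit seed (numpy `default_rng`); a fixed seed yields
bit-identical matrices and byte-identical pipeline CSVs, which the
pipeline manifest (config hash + seed + version) makes auditable.

## Known limitations

* The exact algorithmic dialects of the web-based aggregation tools
  are unpublished; this package implements the published algorithms,
  and some published statistic/rank cells are mutually inconsistent
  and are deliberately not chased.
* geNorm assumes candidates are not co-regulated; the comprehensive
  geomean weights all four methods equally (no Borda/Kemeny
  alternatives, no method weighting).
* No bootstrap confidence intervals on stability values.
* BestKeeper's Pearson p-values are unadjusted and descriptive.
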
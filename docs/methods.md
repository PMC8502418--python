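# Methods

## The measurement model

A droplet digital PCR well partitions a DNA sample into `n` droplets
(default 25,000). If methylated template is present at a mean of λ copies
per droplet, the number of copies in a droplet is Poisson(λ), so a droplet
amplifies with probability `p = 1 − exp(−λ)` and the positive-droplet count
is Binomial(n, p). Quantification inverts this: `λ̂ = −ln(1 − p̂)`. The
interval on λ̂ is the exact Clopper-Pearson binomial interval on p mapped
through the same (monotone) transform, so its coverage is inherited from
the exact construction; it is conservative, typically slightly above
nominal. A well with every droplet positive carries no concentration
information and raises a saturation error rather than returning infinity.

Copies per microliter are `λ̂ / v × 1000 × d` for droplet volume `v` (nL)
and pre-partition dilution factor `d`. The default droplet volume, 0.59 nL,
is a typical crystal-dPCR partition volume and a stand-in: no instrument
metadata underlies it, and it cancels out of every droplet-count analysis
in the package.

## Blank false positives and the limit of blank

Template-free (unmethylated-DNA) wells occasionally produce positive
droplets — incomplete bisulfite conversion, chemistry artifacts, optical
noise. The limit of blank is the largest count plausibly produced by blanks
at confidence 1 − α. The default estimator is the empirical (1 − α)
quantile of replicate blank counts: the smallest integer c such that at
least a 1 − α fraction of blanks is ≤ c. With the standard design of 12
blank wells at α = 0.05, ⌈0.95 × 12⌉ = 12, so the empirical LOB is the
maximum observed blank count. A model-based alternative fits the blank mean
and returns the (1 − α) Poisson quantile; both record their method. Blank
wells with different droplet totals are treated as exchangeable counts,
on the assumption that the blank false-positive rate does not scale with
input DNA amount.

The simulator draws blank false positives as Poisson with channel-specific
means, 0.2 (NPY channel) and 2.4 (WIF1 channel). These were chosen by
closed-form analysis of the max-of-12-Poisson distribution so that the
empirical 95% LOB over 12 blanks is modally 1 and 5 droplets respectively
(P = 0.72 and 0.35, with the next most likely WIF1 outcome at 0.25); they
are generator parameters, not measured instrument rates.

## Fluorescence, spill-over and gating

Each channel's droplet amplitudes form two homoscedastic Gaussian clusters:
a negative baseline (mean 2000, SD 250, arbitrary units) and a positive
cluster `cluster_separation` SDs above it (default 8). Optical crosstalk is
a forward spill-over matrix S with unit diagonal; observed amplitudes are
`S @ true` per droplet. Compensation multiplies by `S⁻¹` — exact linear
unmixing, hence linear and non-idempotent. A helper estimates S from
single-positive control wells by regressing the bleed channel on the source
channel over positive droplets (baselines removed); it returns the identity
when no controls are supplied.

Automatic gating finds, per channel, the exact two-group split of the
sorted amplitudes minimizing total within-group variance (1-D two-means,
O(n) after sorting, deterministic), and cuts at the midpoint of the two
group means. Droplets exactly at a threshold count negative (strict `>`),
the conservative choice for specificity. Counts are invariant to droplet
order and to strictly monotone rescaling applied to data and threshold
alike.

Degenerate inputs: a constant-amplitude channel has no cluster structure
and raises an error. A channel whose best split separates the group means
by less than 3.5 pooled within-group SDs is treated as a single cluster and
called all-negative; the cutoff sits above the ≈2.65 ratio that the best
split of a single Gaussian attains, so unimodal wells are not half-split,
at the cost of under-calling wells whose true separation is below ≈4 SD —
at such separations automated 1-D gating is unreliable anyway and manual
thresholds should be used. With two clusters 10 SD apart the midpoint lies
5 SD from each mean, so the per-droplet misclassification probability is
Φ(−5) ≈ 2.9 × 10⁻⁷ and a 10,000-droplet well round-trips exactly with
probability ≈ 99.4%; at 2 SD the misclassification rate is Φ(−1) ≈ 0.159
per droplet, which the test suite checks against the gated counts within
binomial error.

## Positivity calling

A marker is positive when its count reaches the marker's threshold
(inclusive ≥). The default panel sets each threshold equal to the marker's
LOB — ≥ 1 droplet for NPY, ≥ 5 for WIF1 — reproducing the assay as
published. This is deliberately tension-laden: a count equal to the LOB is,
by the LOB's own definition, still plausible from a blank, so blank-level
noise occasionally calls positive (with a 0.2-per-well NPY false-positive
rate, a template-free sample is NPY-positive with probability ≈ 0.18). The
package keeps the published behavior as the default and exposes the
conservative variant (`threshold = lob + 1`) through configuration;
thresholds below the LOB require an explicit override flag. The sample
call combines markers by OR (the headline "methylated in either gene"
classifier) or AND; a sample missing one marker's well is called over the
markers present and flagged, never silently assumed negative.

## Diagnostic performance

Sensitivity and specificity carry exact Clopper-Pearson intervals
(Beta-distribution quantiles; lower bound 0 at k = 0, upper bound 1 at
k = n). Display rounding follows clinical-report convention — metric to one
decimal in percent, CI bounds to whole percent — with full precision on the
returned objects. A metric with an empty denominator is reported absent,
not zero. AUC is computed from mid-ranks (the Mann-Whitney probability,
ties half-weighted), making it invariant to monotone score transforms; its
interval is a percentile bootstrap (default 2000 resamples) stratified by
class so every replicate retains both cases and controls — at these cohort
sizes (≈10–22 per class) an assumption-free interval seemed preferable to
a normal approximation. Dilution linearity is ordinary least squares of
counts on concentration with R²; a constant-concentration design is
rejected as degenerate.

## Comparison statistics

The cohort battery wraps scipy.stats. Exactness policy: the signed-rank
test enumerates all 2ⁿ sign patterns for n ≤ 12 (implemented here with
midranks, so tied absolute differences are handled; tie-free cases agree
with scipy's exact method to machine precision), and Mann-Whitney uses
exact enumeration when n₁·n₂ ≤ 100 without cross-group ties; both fall
back to tie-corrected normal approximations, and each result records
which null was used. Two-sided exact p-values are twice the smaller tail,
capped at 1. Kruskal-Wallis and Spearman use their standard tie-corrected
approximations. Spearman results are reported as rho (square it for an
R²-style summary; published reports sometimes conflate the two).

`required_sample_size` inverts the noncentral-t power function of the
two-sample t test (statsmodels) for the smallest per-group n at given
α and power, with Cohen's d scaled by the root-mean-square of the two SDs;
the two-group ANOVA design uses the equivalent F-test power with
f = d/2. When n = 2 already reaches the target power it returns 2 without
iterating.

## The synthetic cohort

Cohort generation mirrors the validation-study structure: 11 tumor/adjacent
tissue pairs, 22 CRC plasmas, 10 control plasmas. Tissue mean positive
counts (6021 NPY / 6776 WIF1 tumor; 115 / 81 adjacent) follow the reported
class means; plasma means (35 NPY / 60 WIF1) are invented at a plausible
ctDNA scale, since no per-sample plasma counts are published. Within a
sample, both markers scale with one latent tumor-DNA load, log-normal
across samples with unit mean and log-SD 1.0 (strictly positive,
heavy-tailed, and reproducing the orders-of-magnitude spread between
tissue and plasma), which induces the positive cross-marker correlation
seen in real tumor panels. Control plasmas draw from blank false-positive
rates only. DNA concentration co-varies with the load so that
concentration-vs-count correlations are reproducible. Stages and histology
cycle through fixed assignments (plasmas predominantly stage IV).

Determinism: one integer seed; every well/sample gets a substream via
`SeedSequence(seed, spawn_key=(index,))`, so identical configurations are
bit-identical and extending a design never perturbs existing wells.

What the generator does **not** emulate: "rain" (intermediate-amplitude)
droplets, amplitude drift, doublets, multi-cluster channels, bisulfite
chemistry, or inter-run batch effects. Passing tests therefore demonstrate
the correctness of the analysis pipeline under the stated stochastic model,
not instrument-level performance on real exports. In particular, simulated
tissue AUCs are essentially 1.0 because the configured class means are far
apart relative to the load dispersion; real cohorts show more overlap.

## Problem sizes in the test suite

The suite's simulation scales are chosen to make sampling error negligible
relative to each assertion's tolerance: 1000 replicate 12-well blank
experiments for the modal LOB, 500 wells per λ for interval coverage
(tolerance ±3 percentage points around 95%), 500 null replicates per rank
test for type-I calibration (3 binomial SE around α, with a small allowance
below for the conservatism of discrete exact nulls), 10,000-droplet wells
for gating round-trips, and 50–100 seeds for cohort-level Monte-Carlo
checks. All are seeded and deterministic.
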
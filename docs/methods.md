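# Methods

This note documents the models implemented in `segvar`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical choices that affect results.

## The synthetic segregant panel

**Meiosis.** Segregants are independent haploid meiotic products of a cross
between two fully homozygous parents coded 0 and 1. Crossovers follow a
Poisson model with no interference: per chromosome the crossover count is
Poisson(length_cM/100) with uniform positions, which makes parental origin
along the ordered markers a two-state Markov chain whose switch probability
between adjacent markers is the Haldane map function r = (1−e^(−2d/100))/2.
The sampler draws the Markov chain directly — at the markers the two
formulations are distribution-identical, and the chain vectorises over
segregants. Defaults: 16 chromosomes of 100 cM, 1,000 evenly spaced markers,
500 segregants — large enough for estimator-recovery tests, small enough that
a full pipeline replicate takes about a second. Missing genotypes can be
planted at a configurable rate (default 0) and are mean-imputed by consumers.

**Traits.** Each of 60 traits gets an importance weight w on an even grid in
[0,1] (shuffled against trait index). A trait's value is

    own additive part + pairwise-epistatic part (30% of traits)
    + w·κ·(shared growth genetic signal) + replicate noise.

In the default `adaptive_divergence` mode both the number of additive loci
(1→10) and the target additive variance (0.05→0.40 before coupling,
κ = 0.5) increase with w — the generating assumption that alleles with
additive effects on fitness-coupled traits were preferentially fixed between
the parents. `decoupled` mode zeroes the growth coupling and serves as the
negative control. Epistasis is a sum of pairwise products of centred codes
(variance 0.15 where present); higher-order epistasis is not modelled.
Environmental noise tops phenotypic variance up to ≈1 per single measurement
(floor 0.3), mimicking a panel whose traits have been made comparable by
quantile normalisation (V_P within a narrow range while h² spans orders of
magnitude). Effect sizes are normal — a modelling choice, since the true
architecture of real morphological traits is unknown.

Every architecture records its realized components: V_A is the variance of
the least-squares additive fit of the noiseless genetic values on all causal
dosages, V_G the variance of the genetic values, V_NonA = V_G − V_A, V_E the
noise variance; V_P = V_A + V_NonA + V_E holds to machine precision, and
heritabilities are recorded both per single measurement and per
replicate-mean (the scale the analysis estimates).

Technical controls: two segregants are re-measured 26 and 28 times on a
positive raw scale, emulating per-experiment control replications used for
the CV filters. Cell counts per measurement are lognormal around 250
(≈99.9% above 100), so the <80-cells filter bites only in planted scenarios.

**Growth curves.** Each (segregant, replicate) occupies one well of an 8×12
plate, filled in row-major order. OD600 follows a logistic
OD(t) = od₀ + K/(1+e^(−m(t−t₀))) sampled hourly over 24 h, with
m = 4·rate·bias/K so the true maximum slope equals the segregant's growth
rate times the smooth positional bias factor (default: cosine bowl, ±7.5%).
t₀ = 10.5 h sits mid-interval of the hourly grid, so the maximum hourly
difference equals K·tanh(v/K) exactly — the discretisation is known in
closed form and tested against it.

**What passing tests do not show.** The generator draws balanced allele
frequencies, independent normal effects, homoscedastic noise and a single
shared growth signal. Real panels have segregation distortion, batch
structure, correlated trait families beyond one latent factor, and
non-Gaussian trait distributions; recovery on synthetic panels demonstrates
estimator correctness under the stated model, not robustness to those
features.

## Preprocessing

Quantile normalisation maps every trait column onto the across-trait mean of
the sorted value vectors, separately per replicate batch and before any
replicate averaging. Ties receive the mean reference value of their tied
ranks; partially missing columns are interpolated onto the common quantile
grid; all-missing columns are excluded from the reference. The operation is
idempotent on complete data.

The CV consistency filter uses the *raw* control replicates: CV = SD/mean per
trait per control; a trait is excluded if CV > 0.4 in either control
(`high_cv`), then if the distance index |CV₁−CV₂|/(CV₁+CV₂) > 0.2
(`inconsistent`); zero-mean traits are excluded as `undefined_cv`. Applying
the CV threshold to each control separately (rather than to the mean CV) is
the stricter of the two readings and is configurable.

The cell-count filter removes a segregant only when *all* of its replicates
were measured from fewer than 80 cells (strict inequality); otherwise only
the failing replicates are masked.

Growth rate: raw Vmax is the maximum slope over a sliding window of hourly
readings (default window 1 interval; no smoothing is assumed). Positional
bias is removed per plate by a robust locally weighted regression of Vmax on
(row, column) — tricube weights over the nearest 70% of wells, local
*quadratic* fit, two bisquare robustness iterations. The raw fitted surface
is divided out, so corrected values are relative growth rates and any
constant bias cancels exactly; dividing by a plate-mean-normalised surface
would leave a global factor in place. The per-segregant fitness estimate is
the mean of corrected replicate values. Gross non-monotone wells (an OD drop
beyond 0.05) are flagged, never silently dropped. The 2-D robust loess is
implemented in the package because no installed library provides one
(available lowess implementations are one-dimensional).

## Heritability

**Broad-sense.** One-way random-effects model y_ij = μ + g_i + e_ij on
normalized replicate values, restricted to segregants with ≥2 replicates,
fit by REML via a closed-form per-group profile likelihood and a bounded 1-D
search over the variance ratio; H² = σ²_G/(σ²_G+σ²_E) with components
clamped at zero. The fit matches `lme4::lmer` to numerical precision (tested
through Rscript). This is single-measurement heritability.

**Kinship.** K = ZZᵀ/Σ_j p_j(1−p_j) with Z the column-centred {0,1} codes
and monomorphic markers dropped — the haploid analogue of the VanRaden
normalisation used by rrBLUP-style software, giving mean diagonal ≈ 1. The
normalisation matters: h² = σ²_A/(σ²_A+σ²_EV) is *not* invariant to a global
rescaling of K, and only a mean-diagonal-1 kinship puts σ²_A on the
phenotypic-variance scale so that ĥ² estimates V_A/V_P.

**Narrow-sense.** Single-variance-component mixed model y = μ + u + e,
u ~ (0, Kσ²_A), fit by REML on the eigenbasis of K with a bounded 1-D search
over δ = σ²_EV/σ²_A (one eigendecomposition shared across traits);
h² = 1/(1+δ). Segregant means enter regardless of replicate count. The
eigen-path optimum matches a dense-likelihood optimisation to 1e−4 in h².
REML rather than ML in both models, matching the conventional behaviour of
lme4 and rrBLUP.

**Jackknife.** Delete-one over segregants (the exchangeable unit):
SE = sqrt((n−1)/n·Σ(θ₋ᵢ−θ̄)²). Leave-one-out failures are reported and
skipped. For the sample mean this reproduces the classical SE identity; for
H² it tracks the empirical sampling SD within 50%.

## QTL mapping

Scan statistic LOD = −n·ln(1−r²)/(2·ln10), r the Pearson correlation between
allele code and (residual) trait value on pairwise-complete observations;
monomorphic markers are flagged with LOD 0. Forward search runs four rounds
at thresholds 2.68/2.92/3.72/4.9; within a round the single best marker is
added and residuals rescanned until nothing clears the round's threshold.
Two guards the escalating-threshold description leaves open are fixed here:
markers within 10 cM of a marker selected in the same round are not
candidates again that round (residualisation handles linked signal across
rounds), and a marker collinear with the selected set is skipped with a
warning. After all rounds the joint OLS model gives per-QTL effects (sign =
sign of the parent-B coefficient) and joint R², the squared multiple
correlation. Thresholds can be recalibrated by permutation: per round, the
smallest LOD t at which (mean permuted count of marker scans ≥ t)/(observed
count ≥ t) ≤ 5%, permuting segregant labels of the residual phenotype so
genotype structure is preserved.

## Importance and exemplars

RTGR = |Pearson r| between segregant trait means and growth rates; 1−CV uses
the mean control CV of consistent traits. Channel (C → cell wall,
D → nucleus) comes from the trait name's initial letter and stage from the
suffix token; four stage tokens A/A1B/B/C are recognised, with B kept as a
configurable token since naming conventions differ on the budded
one-nucleus-at-the-neck class, and anything else mapped to `unassigned`.
Exemplar traits come from affinity propagation on s(i,k) = −‖x_i−x_k‖² over
trait profiles (scikit-learn's implementation behind this module's surface):
damping 0.9, max 1,000 iterations, convergence window 100, preference =
median similarity, fixed tie-breaking jitter seed — the jitter can shift the
exemplar count by ±1–2, which is why tests assert partitions on separable
data rather than exact counts elsewhere. Non-convergence returns a flagged
single-cluster fallback instead of raising. Correlation p-values are
descriptive; no multiple-testing correction across trait categories.

## Evolutionary simulations

**Wright–Fisher.** Binomial resampling of N (haploid) or 2N (diploid)
gametes after a deterministic selection update (haploid fitnesses 1, 1+s;
diploid 1, 1+hs, 1+s). Diffusion companions: fixation probability
(1−e^(−2Nₑsp₀))/(1−e^(−2Nₑs)) and the conditional fixation time obtained by
solving the boundary-value problem a(x)w′ + b(x)w″/2 = −u(x) for
w = u·T* by finite differences — an oracle that avoids transcribing sojourn-
time integrals. Note the simulator reports its own conditional fixation
times alongside the oracle; at N = 100,000 and s = 0.01 (diploid) the
diffusion conditional time from a single copy is ≈1,800 generations,
parameterisation-sensitive, so no external figure is asserted.

**Variance decomposition.** V_A = variance of the least-squares additive fit
on allele dosages (ridge-penalised and flagged when loci ≥ individuals);
V_G = variance of noiseless genetic values when available, else of
genotype-class means; V_NonA = V_G − V_A clamped at 0. All ddof = 0 so
noiseless conservation is exact.

**Depletion (the death process).** A segregant-like haploid panel with an
additive trait; each generation the top 20% by phenotype (or a
fitness-proportional sample, exp(s·z)) mate at random, offspring are meiotic
products with the panel's Haldane recombination fractions, N constant. Only
the causal loci are tracked — neutral markers carry no information for the
recorded statistics. The default start calibrates noise so h₀² = 0.6; under
truncation selection mean h² falls below 0.3 well within 25 generations at
N = 1,000. The specific selection scheme (truncation, constant N, random
mating) is this package's model of the depletion process; fitness-
proportional selection is the alternative mode.

**Birth cycle.** Two demes of N haploids are seeded with disjoint sets of
rare (p₀ = 0.01) beneficial variants: additive loci with effect a and locus
pairs whose {0,1}-product carries the same magnitude — so an epistatic
allele has no marginal fitness effect while its partner is rare, the
cleanest operationalisation of a "nonadditive allele". Fitness-proportional
selection (w = e^(s·genetic value)) with free recombination runs to a
generation cap; the demes are then pooled 50/50 and crossed for one
generation. Reported: per-class fixation fractions (additive ≫ epistatic
under selection; equal under drift), and V_A/V_NonA/h² before divergence,
per fixed deme (≈0) and in the hybrid (large — fixed divergent loci
segregate at 50%). Defaults N = 1,000, a = 0.5, s = 1.0, noise SD 0.5,
150-generation cap: strong selection so the cycle completes at desk scale.

## Numerical choices and degenerate inputs

Variance ratios are optimised on a log scale in [e^(−14), e^(14)] (one-way
model: [e^(−18), e^(18)]) with explicit boundary checks, so H² and h² hit 0
and 1 exactly in degenerate cases. Zero-variance traits produce flagged
all-zero scans; all-missing trait columns are excluded from the quantile
reference; a monomorphic marker set is an error for kinship; estimators
refuse all-single-replicate panels (H²) and non-finite inputs (h²). Pipeline
stage seeds are spawned from the global seed via `SeedSequence`, making
whole runs byte-identical for a fixed config.

## Problem sizes

Default analyses use 500 segregants × 1,000 markers × 60 traits × 2
replicates; estimator-recovery experiments use n = 1,000 (H²) and n = 734
(h²); Monte-Carlo checks use 20,000 Wright–Fisher runs and 50-replicate
evolutionary ensembles. These sizes give tight recovery (sampling SEs well
inside the asserted tolerances) while keeping a full test run to a couple of
minutes on one CPU.
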
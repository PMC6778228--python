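# Methods

## The generative model

Simulated cells emit spikes as a **gamma-renewal process with per-trial
gain**. Within a trial the instantaneous rate is

    r(t) = G · μ_base · g_drug^[drug on] · g_attn(t),

where `g_attn(t)` equals 1 before cue onset and the condition's attention
gain afterwards (a step change at the cue; the within-trial time course of
attentional modulation is not otherwise constrained, and a step is the
simplest form that makes all three analysis windows informative). The
trial gain G is drawn once per trial from Gamma(shape 1/σ²_G, scale σ²_G),
i.e. mean 1 and variance σ²_G, so spike counts in any window follow the
gamma-gain Poisson (negative binomial) law Var[N] = λ + σ²_G λ² that the
gain-variance analysis fits. Spike times are generated by time rescaling:
unit-rate gamma-renewal event times (shape κ) are mapped through the
inverse cumulative intensity, which preserves the renewal structure in
operational time. Regularity (κ) and excitability variance (σ²_G) are
therefore independently controllable — the two properties the clustering
features and the negative-binomial fits need ground truth for.

Two consequences worth knowing: counts are exactly negative binomial only
for κ = 1 (for κ ≠ 1 the renewal structure adds or removes short-timescale
dispersion), and trains are started fresh at stimulus onset rather than in
equilibrium, so the first interval is drawn like any other. Neither
affects the window statistics at the rates and window lengths used here.

## Task structure

Each trial: stimulus onset at t = 0; cue onset uniform in [300, 1400] ms;
first dimming at cue + uniform [1500, 2000] ms. Conditions are the full
factorial of attention {RF, away1, away2} × motion direction {d1, d2} ×
drug {off, on} — six stimulus conditions per drug state. The three
analysis windows are [+100, +400) ms from stimulus onset, [+100, +400) ms
from cue onset, and [−500, 0) ms from first dimming. All windows are
half-open in milliseconds; a spike exactly at a window's end belongs to
the next window, never to two.

## Archetype parameters

`CellArchetype` holds the per-class generative parameters: P2T mean/SD
(µs), base rate (Hz), attention gain (multiplicative, applied post-cue for
attend-RF), drug gain, a factor by which drug application scales
(attention gain − 1), gain variance σ²_G with separate multiplicative
scalings for attend-RF and drug-on conditions, and the renewal shape κ.

`study_population()` provides seven classes (four broad, three narrow,
the third narrow class a high-rate regular-spiking group whose widths
straddle the 250 µs boundary) with drug parameter sets per agent:
acetylcholine raises rates (drug gain 1.35), the antagonists lower them
(0.70 muscarinic, 0.75 nicotinic) and raise gain variance (×1.8 / ×1.6);
all three scale the attention gain down; attention scales σ²_G by 0.6.
These values encode the qualitative effect directions of cholinergic
modulation in frontal cortex at plausible magnitudes; they are defaults of
the simulation, not estimates of any particular dataset.

`separable_population()` is a deliberately well-separated seven-class set
for planted-recovery studies. Its parameter patterns (width, rate,
regularity, attention gain, gain variance) are mutually decorrelated
across classes so that each candidate feature carries independent cluster
information, base rates stay ≥ 8 Hz so window counts are not few-integer
discrete, and within-class width SD is 20 µs — several interpolated
samples, keeping the measured P2T distribution effectively continuous.

## Estimation and numerical choices

**P2T** is measured trough-to-subsequent-peak on a ×10 cubic-spline
interpolated waveform (the interpolation gives sub-sample stability;
waveforms without a trough-then-peak shape are rejected). The narrow/broad
boundary is P2T ≤ 250 µs, inclusive.

**ISI statistics** are computed within trials only — never across trial
boundaries. CV uses the pooled ISIs; CV2 and Lv pool the adjacent-pair
terms across trials. Fewer than three ISIs yields NaNs. For clustering,
ISIs come from all no-drug trials: the features are meant to describe a
cell's intrinsic physiology, not the manipulation. The firing-rate feature
is the mean predimming rate over no-drug trials and the Fano-factor
feature uses the attend-RF no-drug predimming counts (the epoch choice is
a configuration, not a constraint).

**Negative-binomial fits** use the (λ, σ²_G) parameterisation with
σ²_G = 1/r. The MLE of λ is the sample mean in this parameterisation, so
the fit is a one-dimensional profile likelihood in log σ²_G (bounded
scalar minimisation around the method-of-moments start
max(0, (v − m)/m²)), with the Poisson boundary σ²_G = 0 compared
explicitly; under-dispersed samples return the boundary with
`converged=True`. Fits require ≥ 5 trials and at least one spike.

**AUROC** is the exact pair-counting estimator with ties counted half,
identical to the Mann–Whitney U statistic divided by n₁n₂. The attend-away
sample pools both away locations and both directions by default
(configurable); a folded variant max(AUROC, 1 − AUROC) is reported
alongside, never instead.

**The factorial screen** is a fixed-effects ANOVA with all interactions
and Type-II sums of squares (unbalanced designs permitted; single-level
factors are dropped with a warning). A cell is attention-modulated if the
attention main effect or any interaction containing attention has
p < 0.05, and drug-modulated analogously. Population contrasts reuse the
same fixed-effects machinery; no random-effects structure is modelled.

**Modulation indices** use MI = (a − b)/(a + b). The headline per-cell
drug MI computes an MI of condition-mean rates per stimulus condition and
then averages across conditions (mean-of-MIs; the MI-of-means order is
also implemented). The attention gain-variance MI is oriented away − RF so
that attentional stabilisation is positive.

**Clustering.** Features are z-scored per column. Screening ranks
features by PCA-loading importance but selects greedily by marginal gain
in span-explained variance, so a feature nearly collinear with the current
selection (e.g. one of the CV2/Lv pair) adds nothing and is passed over;
selection stops at ≥ 90% explained. Mixtures are diagonal-covariance
Gaussians, best of 100 independently seeded restarts per k ∈ [2, 12];
restarts whose hard assignment leaves a component with fewer than two
members are discarded. Free parameters p = 2kd + (k − 1). Component
variances are floored at 0.01 squared z-units (`REG_COVAR`): the features
are estimates whose sampling error is of order 0.1 z, and an
unconstrained maximum-likelihood mixture will otherwise profit from
components narrower than that noise — spurious splits that information
criteria with weak penalties (AIC in particular) then accept. With the
floor, model-order selection reflects cluster structure rather than
estimation noise. When AIC and BIC disagree on k, the solution whose
clusters mix narrow and broad widths less (summed per-cluster minority
fraction) is used; ties keep the AIC choice. Cells with any missing
feature are excluded and listed.

**Dip test.** Hartigan's dip statistic is implemented from the classical
greatest-convex-minorant / least-concave-majorant algorithm. Calibration
is by Monte Carlo against the uniform null (the asymptotically
least-favourable unimodal distribution) at the observed sample size,
10,000 draws by default, with an add-one correction so p > 0. Samples
under 10 values are flagged untestable. Per-cluster p values are
Benjamini–Hochberg adjusted.

**Behavior.** d′ = z(hit) − z(false alarm); rates of exactly 0 or 1 are
clipped by 1/(2N) (with a warning) before the quantile transform.
Reaction times are divided by their session mean (the per-session mean of
the output is exactly 1), and the drug × locus ANOVA collapses the three
cued locations to RF vs away, with post-hoc two-sided t tests of drug
within each locus.

## Reproducibility

Every stochastic call takes a seed; population simulation spawns
independent child seeds per cell from a `SeedSequence`, and the pipeline
derives each stage's seed deterministically from the master seed via
SHA-256, so a rerun with the same configuration reproduces outputs
bit-for-bit (the manifest records a configuration hash).

## What the generator does and does not emulate

It reproduces the task's factorial condition structure and event schedule,
class-specific waveform width, rate, regularity, attentional gain, drug
gain and gain variance, and behavioral outcome/reaction-time structure
with plantable drug × attention effects. It does not model latency
dynamics or PSTH shape beyond the cue step, bursting or refractoriness
beyond what a gamma renewal implies, noise correlations between cells
(cells are independent), eye movements, or any biophysics. Passing tests
therefore certify the estimators and the pipeline logic under the model's
assumptions — they are evidence about the code, not about any particular
recorded dataset.

## Verification problem sizes

The test suite and the acceptance script size their simulations for tight
statistical checks: gain-variance recovery uses 200 cells × 200 trials per
(σ²_G, λ) cell of the grid with a 15%-of-truth median criterion (0.02
absolute at the boundary); Lv analytics use 20 trains × ~500 ISIs per κ
with 3-SE tolerances; the AUROC null uses 500 cells; planted cluster
recovery uses 7 archetypes × 30 cells at 30 trials per condition; the
screen's type-I calibration uses 1,000 all-null cells against a 3σ
binomial band around 5%; drug-effect directions use 42 cells per agent at
30 trials per condition.

## Known limitations

Gain-variance estimates at realistic trial counts (tens per condition)
are noisy and boundary-biased individually; only averages over conditions
and cells are interpretable, which is how the pipeline reports them. The
fixed-effects approximation ignores between-cell random variation that a
mixed model would absorb. The dip test's uniform-null calibration is
conservative for short-tailed alternatives. CV pools ISIs across epochs
with different rates and therefore exceeds 1 for strongly modulated cells
even at κ = 1; CV2 and Lv are the rate-robust statistics.
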
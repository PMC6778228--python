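# fefattn

Analysis pipeline for **attentional and cholinergic modulation of frontal
eye field (FEF) spike trains**, with a synthetic-data generator that
emulates the underlying covert-attention task so every stage runs with
known ground truth.

The package is aimed at systems neuroscientists analysing trial-based
extracellular recordings collected while a subject performs a
three-stimulus covert attention task (one stimulus in the neuron's
receptive field, two outside it) under local iontophoretic application of
cholinergic agents — acetylcholine, the muscarinic antagonist scopolamine,
or the nicotinic antagonist mecamylamine.

## What it computes

**Spike metrics.** Waveform trough-to-peak time (P2T, measured on a ×10
cubic-interpolated waveform; cells with P2T ≤ 250 µs are *narrow spiking*,
else *broad*), epoch firing rates in the three canonical task windows
(100–400 ms after stimulus onset, 100–400 ms after cue onset, −500–0 ms
before the first dimming), and ISI variability statistics

- CV = sd(ISI)/mean(ISI),
- CV2 = ⟨2|ISIᵢ₊₁ − ISIᵢ| / (ISIᵢ₊₁ + ISIᵢ)⟩,
- Lv = 3/(n−1) · Σᵢ ((ISIᵢ − ISIᵢ₊₁)/(ISIᵢ + ISIᵢ₊₁))²,

plus the Fano factor of trial spike counts.

**Attention statistics.** A per-cell factorial ANOVA screen
(attention × direction × drug, Type-II sums of squares) classifies cells
as attention- or drug-modulated (main effect or interaction, α = 0.05).
Attentional modulation is quantified by the ideal-observer AUROC — the
probability that a single trial's rate drawn from the attend-RF condition
exceeds one drawn from attend-away — and by Cohen's D, each computed
separately for drug-off and drug-on trials.

**Gain variance.** Single-trial spike counts are fitted with a negative
binomial parameterised as a gamma-gain Poisson: counts are Poisson with a
per-trial multiplicative gain G ~ Gamma(mean 1, variance σ²_G), so
Var[N] = λ + σ²_G λ². The fitted σ²_G ("gain variance") measures
trial-to-trial excitability fluctuations beyond Poisson noise. Estimates
are formed per condition (2 attend-RF, 4 attend-away) and averaged within
each side, separately per drug state.

**Modulation indices.** Normalised indices MI = (a − b)/(a + b) for drug
effects on rates (no drug − drug: a drug that raises firing gives negative
values), drug effects on gain variance, and attention effects on gain
variance (away − RF: attentional stabilisation gives positive values).

**Cell-type clustering.** Candidate features {P2T, CV, CV2, Lv, FR, FF,
AUROC} are z-scored, screened to a subset whose span explains ≥ 90% of
total variance (redundant features are eliminated), and clustered with
diagonal-covariance Gaussian mixtures over k = 2..12 (best of many seeded
restarts). AIC = 2p − 2ℓ and BIC = p·ln n − 2ℓ select k; when they
disagree, the solution mixing narrow/broad widths less within clusters
wins. Within-cluster waveform-width bimodality is tested with a
bootstrap-calibrated Hartigan dip test, FDR-adjusted across clusters.

**Behavior.** Hit and correct-rejection rates, signal-detection
sensitivity d′ = z(hit) − z(false alarm), session-normalised reaction
times, and a drug × attention-locus ANOVA on them with post-hoc t tests.

## Worked example

```python
from fefattn import CellArchetype, TaskDesign, simulate_cell, screen_cell
from fefattn.attention import attention_result

arch = CellArchetype(
    name="example", p2t_mean_us=415.0, p2t_sd_us=0.0, base_rate_hz=18.0,
    attention_gain=1.5, drug_gain=1.35, attention_gain_drug_scale=0.4,
    gain_var=0.15, isi_shape=1.0,
)
cell = simulate_cell(arch, TaskDesign(n_trials_per_condition=40), seed=3)

screen = screen_cell(cell)
print(screen.attention_modulated, screen.drug_modulated)
res = attention_result(cell)
print(f"AUROC no drug {res['auroc_nodrug']:.3f}, drug {res['auroc_drug']:.3f}")
```

prints

```
True True
AUROC no drug 0.704, drug 0.573
```

The simulated cell fires 50% harder with attention in its receptive field
and 35% harder under drug, but the drug scales its attention gain down —
so the screen flags both factors, and the drug-on AUROC moves toward
chance (0.5): the ideal observer decodes the locus of attention less well
when the drug is applied. The `examples/` directory contains one short
script per capability (population simulation, attentional modulation, gain
variance, clustering, behavior); each prints the numbers it computes and
what they mean. A thin CLI wraps the pipeline:
`fefattn run-all --seed 1 --out run1` simulates a population and executes
every stage, writing per-cell CSV tables and JSON reports.

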
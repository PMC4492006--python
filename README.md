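# avkit — neuronal avalanche analysis for calcium-imaging rate estimates

Ongoing cortical activity is irregular at the single-neuron level yet
organises, at the population level, into *neuronal avalanches*:
spatiotemporal clusters of activity whose sizes follow a power law
P(s) ∝ s^α with α ≈ −1.5 up to a system-size cut-off, the signature of
neural dynamics near the critical point of a branching process. `avkit`
is a library for detecting and quantifying this organisation in
two-photon calcium-imaging recordings of identified neurons (and in
simulated ground-truth data), aimed at researchers analysing population
activity from GECI-expressing cortical neurons.

## What it computes

**From fluorescence to firing rates.** Ratiometric traces are
baseline-normalised, ΔR/R = (R − R₀)/R₀ with R₀ the per-ROI median,
low-pass filtered (symmetric Gaussian, 3Δt), and deconvolved with a
sparse non-negative solver against an exponential-decay forward model
(τ = 1.5 s, 5% ΔR/R per action potential). The output λ ≥ 0 is the
instantaneous firing-rate estimate, calibrated so one AP contributes
integrated λ ≈ 1. The decay constant is selectable by minimising
reconstruction error over τ ∈ [Δt, 15Δt]; ROIs below ~1 AP/min
(λ_avg/Δt < 0.016 s⁻¹) are dropped.

**Avalanche detection.** A bin is active when any ROI has λ > λ_thr;
maximal runs of active bins, flanked by quiescent bins, are clusters
with size s_λ = Σλ over suprathreshold entries, event count s_k,
and lifetime T = n_bins·Δt. λ_thr is chosen to maximise the cluster
rate; sizes are normalised by the predicted limit Λ = N·λ_avg^pop.
Population-rate thresholding (cascades as runs of λ^pop = Σ_ROI λ above
θ) is available as the alternative cascade definition, and a
rate-preserving shuffle provides the correlation-destroying control.

**Inference.** Doubly truncated power laws P_α(s) = c·s^α on
[s_min, s_max] (c = (α+1)/(s_max^{α+1} − s_min^{α+1})) are fitted by
minimising the Kolmogorov–Smirnov distance D_KS = max_s |C_data − C_α|;
maximum-likelihood fits of the power law and the truncated exponential
P_γ(s) = c·e^{−γs} feed the log-likelihood ratio
LLR = l(α|x) − l(γ|x) with significance p = erfc(|LLR|/√(2nσ²)).
Lifetime distributions (exponent ≈ −2 at criticality) and size–duration
scaling ⟨s⟩ ∝ T^{1/c} use the same machinery.

**Ground truth.** A driven branching network (binary units, fixed random
fan-out, per-edge transmission σ/fan_out, one-bin delay) generates spike
rasters at tunable branching parameter σ, and a linear forward model
(exponential kernel + uniform noise, scaled ×√2 and ×2 at the 167 ms and
88 ms frame intervals) renders them into surrogate ΔR/R traces, so every
stage of the pipeline is testable against known parameters.

## Worked example

```bash
python examples/01_branching_avalanches.py
```

```
1825 cascades in 41.7 h of simulated activity
size exponent alpha = -1.544 (D_KS = 0.042, n = 551)
lifetime exponent = -1.940 (n = 387)
branching parameter sigma = 0.979 over 1825 cascades
```

A critical (σ = 1) branching network of 64 units is simulated under
sparse spontaneous drive, cascades are detected as runs of active bins,
and the KS fits recover the two critical exponents: sizes near −1.5,
lifetimes near −2, with the two-bin participation-ratio estimator
returning σ̂ ≈ 1. The other examples cover the calcium forward/inverse
chain (`02`), single-unit irregularity (`03`, IBI CV ≈ 1.7 versus 1.0
for a rate-matched independent model), the shuffle control (`04`, LLR
flips from power law to exponential), and the end-to-end pipeline
(`05`). A thin CLI mirrors the API:

```bash
avkit simulate --units 64 --bins 600000 --sigma 1.0 --seed 7 -o raster.csv
avkit avalanches --in lambda.csv --thr auto -o catalog.csv
avkit fit --in catalog.csv --field s_lambda
```

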
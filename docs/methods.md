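# Methods

This note records the models, estimators, parameter choices, and known
limitations behind `avkit`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The branching-network generator

`simulate_branching_raster` implements a driven branching process on a
fixed random graph: `n_units` binary units each project to `fan_out`
fixed, randomly chosen targets; every spike independently triggers each
target in the next bin with probability σ/`fan_out`, and spontaneous
("ancestor") spikes occur independently with probability `drive_rate`
per unit per bin. A unit is binary per bin — it spikes if it receives at
least one trigger or a spontaneous event. This saturating rule is what
gives the finite network its avalanche-size cut-off; an additive-count
rule would make the critical mean cascade size infinite. At σ = 1 the
model produces the branching-process exponents: cascade sizes ~ s^−1.5,
lifetimes ~ T^−2, both verified in the suite by parameter recovery.

Parameters and defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_units` | 64 | population size; sets the saturation scale |
| `fan_out` | 8 | out-degree; offspring ~ Binomial(8, σ/8) |
| `sigma_target` | 1.0 | branching parameter (critical point) |
| `drive_rate` | 5e-5 | ancestor probability per unit per bin |
| `dt_gen` | 0.004 s | generative bin width (a pure label; the dynamics are bin-width invariant) |
| `seed` | 0 | all randomness; identical configs → bit-identical rasters |

The drive sets the cascade-overlap ("merging") probability: a cascade of
duration T bins gains an unrelated ancestor with probability
≈ T·n_units·drive_rate. At 5e-5 this stays in the low percent range for
all but the longest cascades. We measured the effect directly by
comparing raster-level cluster statistics against isolated
single-ancestor cascades on the same graph: at a drive of 1e-4 merging
inflates a spurious bump in the lifetime distribution near T ≈ 20–40
generations and biases the fitted lifetime exponent; at 5e-5 the
distributions agree with the isolated-cascade oracle over the fitted
range. Cascade separation relies on this low drive only; there is no
explicit silencing between cascades.

There is no refractoriness, synaptic weight structure, or plasticity;
the generator reproduces cascade *statistics*, not biophysics. Real
recordings additionally contain slow state modulation (arousal,
movement) that the stationary drive does not emulate — passing tests
therefore validate the estimators, not the claim that cortex has no
slower dynamics.

### Generation time and frame time

In the imaging analysis the branching estimator treats consecutive Δt
frames as parent/offspring generations, so the natural correspondence is
one propagation generation per frame. The acceptance experiments
simulate with `dt_gen = 0.25 s` for this reason. Exponents, σ, and the
interburst CV are invariant to the bin-width label; what matters is that
the analysis bin equals the propagation generation. Rebinning a
fine-generation raster 62:1 instead collapses each cascade into one or
two bins and reduces single-unit event trains to thinned-Poisson
processes (CV → 1); measured and documented in the ledger experiments.

## Calcium forward model

Spikes at 100 Hz are convolved with k(t) = A·e^(−t/τ)·1[t ≥ 0],
A = 0.05 ΔR/R per AP and τ = 1.5 s; uniform noise of half-width 0.08 is
added (×√2 at Δt = 167 ms, ×2 at 88 ms, mimicking line-skipping), and
the trace is block-averaged to the target frame interval. The clean part
is exactly linear in the spike train (superposition asserted to float
tolerance). Gaussian noise of matched variance is available via
`noise_kind="gaussian"`. Saturation, bleaching, and movement artifacts
are out of scope.

## Deconvolution

`deconvolve` solves

  min_{λ ≥ 0}  ½‖y − k_τ ∗ (A·λ)‖²/σ̂² + λ_pen·Σλ_t

with L-BFGS-B (FFT convolution mat-vecs, ≤ 500 iterations,
ftol 1e-12). σ̂ is the SD of trace samples below the single-AP amplitude
(ΔR/R < 0.05, falling back to the full trace when fewer than 10 samples
qualify) and λ_pen = 1/(prior_rate·Δt) is the exponential-prior weight
for an a-priori rate of 1 Hz. Because A is the per-AP amplitude, λ is in
AP units: a noiseless single-AP transient yields integrated λ ≈ 1
(asserted within 5%). The all-zero solution is feasible, so the
reconstruction error never exceeds that of predicting no spikes. The
grouped-mean λ-vs-AP-count relation is linear with R² ≥ 0.99 at all
three frame intervals and the slope varies < 10% across them.

**Low-pass.** The 3Δt "width" of the pre-deconvolution Gaussian filter
is interpreted as full width at half maximum (σ ≈ 1.27 bins), applied
with reflect padding so a constant trace is preserved exactly.

**Decay-constant selection** deconvolves each ROI at every τ on the grid
(default Δt·{1..15}) and accumulates the squared error between the
low-passed trace and the identically low-passed reconstruction, so the
compared signals share the processing chain. Selection is exact at
τ = 1.5 s (6Δt at the reference frame rate) across seeds and accurate to
one grid step at the short end (τ ≈ 3Δt), where uniform within-bin spike
timing blurs the decay; we measured this one-step limit under every
error convention (raw vs smoothed, matched vs pure kernels).

**ROI filter.** λ_avg/Δt < 0.016 s⁻¹ (≈ 1 AP/min) removes silent ROIs;
the threshold applies to raw λ before any event thresholding.

## Event statistics

Interburst intervals are maximal runs of bins with λ ≤ λ_thr
(default 0.5, i.e. half an AP per bin); event bins are λ > λ_thr, so the
two partitions are complementary. Runs touching the recording edges are
censored — their true duration is unknown. CV = SD/mean of IBI
durations; P_q is the fraction of bins below threshold; burst strength
is the mean λ over event bins. Pairwise correlations are Pearson R, with
a 25 µm-binned distance profile when centroids are available (bin width
configurable; the value is a convention, not estimated). The
autocorrelation decay exponent β regresses log mean-ACF on log lag over
lags Δt…10 s restricted to positive ACF values.

## Avalanche detection

Bin concatenation: active bins (≥ 1 ROI above λ_thr) concatenate into
clusters; edge-touching runs are censored by default (an off switch
exists for exact bookkeeping tests). λ_thr is scanned over 0.1–8
(40 logarithmic points) and the cluster-rate argmax is used; on dense
deconvolved rasters the maximum is interior, as low thresholds merge
everything and high thresholds leave nothing. The branching parameter is
the mean second-to-first-bin participation ratio with single-bin
cascades counted as extinctions (0) — required for unbiased recovery of
a branching process's σ; an all-consecutive-pairs variant is exposed but
not default. Population thresholding zeroes sub-λ_thr entries, forms
λ^pop_t = Σ_ROI λ_t, and scans θ over 50 quantile levels of the nonzero
λ^pop for the cascade-count maximum. The rate-preserving shuffle
permutes time bins independently per ROI, exactly preserving each ROI's
value multiset (and hence Λ).

## Power-law inference

Continuous doubly truncated models on [s_min, s_max]: the power law
c·s^α with c = (α+1)/(s_max^{α+1} − s_min^{α+1}) (logarithmic
normalisation at α = −1, branch switch at |α+1| < 1e-9), and the
exponential c·e^{−γs}. KS fitting scans α ∈ [−4, −1.01] in steps of 0.01
with bounded local refinement (ties → smaller |α|); D_KS uses both
one-sided gaps of the empirical CDF at the sample points. The
exponential MLE solves the truncated-mean equation by bracketed Brent
root finding (stable shifted parameterisation for either sign of γ);
the power-law MLE is a bounded 1-D likelihood maximisation. The LLR uses
the per-sample variance σ² and p = erfc(|LLR|/√(2nσ²)); the favoured
family requires the matching LLR sign and p below 0.05. Samples above
s_max (the cut-off region) are excluded from fits. Recovery tolerances
verified at n = 10⁴: |α̂ − α| < 0.05 (KS) and < 0.03 (MLE) for
α ∈ {−1.2, −1.5, −1.8}; wrong-family LLR decisions < 5% at n = 10³.

### Discrete counts and continuous models

Cascade event counts s_k and lifetimes-in-bins are integers; a
continuous density cannot carry their atoms (34% of critical cascades
have s_k = 1), which pins D_KS at the atom mass and lets the MLE diverge
onto s_min. Two standard remedies are provided and used where counts are
fitted:

* `select_s_min=True` chooses the lower bound by KS minimisation over
  integer candidates, requiring the fitted tail to retain ≥ 20% of the
  samples (the constraint keeps the scan out of the noisy extreme tail,
  where finite-network saturation steepens the distribution);
* `dequantize_counts` spreads each integer uniformly over its unit bin
  before likelihood comparisons.

Size fits use the tail scan on raw counts (sizes span ~3 decades, so the
scan settles at s_min ≈ 10 with ~25% of cascades retained). Lifetimes
span fewer decades and their dequantised distribution approaches the
asymptotic T^−2 only gradually, so the lifetime protocol
continuity-corrects and fixes the lower bound at 8 generations
(~20–25% of cascades in the tail); both protocols were validated by
recovery of the known σ = 1 exponents across independent seeds, not
tuned to any reported value.

At generative resolution the predicted size limit Λ = N·λ_avg^pop is
degenerate (per-generation rates ~1e-3 make Λ ≪ typical sizes), so
generative-resolution fits bound the support by the observed maximum;
Λ is meaningful — and used by the pipeline — when the 75th percentile of
observed sizes lies below it, with the chosen rule recorded in the
summary.

## Pipeline and problem sizes

`run_pipeline` composes deconvolution (when given traces), ROI
filtering, spike statistics, both cluster definitions, fits, and the
shuffle control; all randomness flows from one seed and identical
input + seed gives a byte-identical summary JSON (floats at full repr
precision; CSV at 10 significant digits).

The acceptance experiments use: a 64-unit critical network for 1.8M
generations (≈ 5,500 cascades, ~5 s of compute); 30 surrogate ROIs of
240 s each for the τ grid (~15 s); 10 spike trains of 150 s per frame
interval for the linearity check. These sizes put sampling error well
inside the stated tolerances while keeping the whole suite around one
minute.

## Known limitations

* The generator's supercritical regime (σ > 1) self-sustains on the
  recurrent graph rather than producing separated large cascades; regime
  contrasts therefore compare uncensored giant clusters, qualitatively
  mirroring disinhibition.
* Continuous-model fits of discrete counts require the corrections above;
  applying the default (s_min = smallest observed) path to raw counts
  reproduces the atom pathology by design.
* Decay-constant selection is grid-limited to one step at τ ≲ 4Δt.
* The IBI CV exceeds 1 only when the analysis bin matches the
  propagation generation (as in the imaging analysis); heavy temporal
  coarse-graining Poissonises single-unit event trains.
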
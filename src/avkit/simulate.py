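"""Synthetic spike rasters and surrogate calcium traces.

Two generators stand in for in vivo recordings:

* a driven branching network — ``n_units`` binary units on a fixed random
  graph with out-degree ``fan_out``; spontaneous ("ancestor") spikes occur
  independently with probability ``drive_rate`` per unit per bin, and each
  spike triggers each of its targets in the next bin with probability
  ``sigma_target / fan_out``. The branching parameter σ tunes the dynamics
  from subcritical (σ < 1) through critical (σ = 1, avalanche sizes
  ~ s^−1.5, lifetimes ~ T^−2) to supercritical (σ > 1). One generative
  bin is one propagation generation; coarser analysis bins are obtained
  afterwards by block summation. The default drive is low enough that
  cascades are separated by quiescent bins.

* a linear calcium forward model — spikes are convolved with an
  exponentially decaying impulse response (5% ΔR/R instantaneous peak per
  action potential, decay τ = 1.5 s), sampled at 100 Hz, corrupted with
  uniform noise (±8% half-width at Δt = 250 ms, scaled ×√2 at 167 ms and
  ×2 at 88 ms to mimic line-skipping), then block-averaged down to the
  target frame interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .containers import CalciumTraceSet, SpikeRaster

__all__ = [
    "SimConfig", "ForwardModelParams",
    "simulate_branching_raster", "simulate_poisson_raster",
    "spikes_to_calcium", "raster_to_traces",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the driven branching network.

    Defaults give a critical network of 64 units with a spontaneous drive
    of 5e-5 per unit per bin. The drive sets the ancestor rate
    (n_units · drive_rate ≈ 0.0032 per bin); it is kept low so that the
    chance of a second cascade starting while one is running — which
    would merge the two clusters and contaminate size and lifetime
    statistics — stays in the low percent range even for long cascades.
    """

    n_units: int = 64
    n_bins: int = 100_000
    dt_gen: float = 0.004
    sigma_target: float = 1.0
    drive_rate: float = 5e-5
    fan_out: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 2 or self.n_bins < 1:
            raise ValueError("need n_units >= 2 and n_bins >= 1")
        if not self.dt_gen > 0:
            raise ValueError("dt_gen must be positive")
        if self.sigma_target < 0:
            raise ValueError("sigma_target must be >= 0")
        if not 0.0 <= self.drive_rate <= 1.0:
            raise ValueError("drive_rate must be in [0, 1]")
        if not 1 <= self.fan_out <= self.n_units - 1:
            raise ValueError("fan_out must be in [1, n_units - 1]")
        if self.sigma_target / self.fan_out > 1.0:
            raise ValueError(
                f"per-edge transmission probability sigma/fan_out = "
                f"{self.sigma_target / self.fan_out:.3f} exceeds 1")


def simulate_branching_raster(config: SimConfig) -> SpikeRaster:
    """Simulate the driven branching network; bit-identical for equal configs.

    Units are binary per bin (a unit spikes if it receives at least one
    trigger or a spontaneous event), which caps one generation at
    ``n_units`` participants and gives the finite network its avalanche
    size cut-off.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p_edge = cfg.sigma_target / cfg.fan_out

    # fixed random fan-out targets, self-connections excluded
    targets = np.empty((cfg.n_units, cfg.fan_out), dtype=np.int64)
    for u in range(cfg.n_units):
        others = np.delete(np.arange(cfg.n_units), u)
        targets[u] = rng.choice(others, size=cfg.fan_out, replace=False)

    counts = np.zeros((cfg.n_units, cfg.n_bins), dtype=np.uint8)

    # Bernoulli spontaneous field, sampled sparsely: per-bin ancestor counts
    # then distinct unit labels for the (rare) occupied bins.
    k_spont = rng.binomial(cfg.n_units, cfg.drive_rate, size=cfg.n_bins)
    spont_bins = np.flatnonzero(k_spont)
    for b in spont_bins:
        units = rng.choice(cfg.n_units, size=k_spont[b], replace=False)
        counts[units, b] = 1

    if spont_bins.size == 0 or cfg.sigma_target == 0:
        return SpikeRaster(counts, cfg.dt_gen)

    # event-driven sweep: idle stretches jump straight to the next ancestor
    ptr = 0
    t = int(spont_bins[0])
    last = cfg.n_bins - 1
    while t < last:
        active = np.flatnonzero(counts[:, t])
        if active.size == 0:
            while ptr < spont_bins.size and spont_bins[ptr] <= t:
                ptr += 1
            if ptr == spont_bins.size:
                break
            t = int(spont_bins[ptr])
            continue
        tg = targets[active].ravel()
        hits = tg[rng.random(tg.size) < p_edge]
        if hits.size:
            counts[hits, t + 1] = 1
        t += 1
    return SpikeRaster(counts, cfg.dt_gen)


def simulate_poisson_raster(rates, n_bins: int, dt: float,
                            seed: int = 0) -> SpikeRaster:
    """Independent-unit null model: Poisson counts with mean rate·dt per bin."""
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates[:, None] * dt, size=(rates.size, n_bins))
    return SpikeRaster(counts, dt)


@dataclass(frozen=True)
class ForwardModelParams:
    """Linear spike→fluorescence model with resolution-dependent noise."""

    peak_per_ap: float = 0.05        # instantaneous ΔR/R peak per action potential
    tau: float = 1.5                 # exponential decay constant, s
    sample_rate_hz: float = 100.0    # rate at which the clean trace is synthesised
    noise_level: float = 0.08        # uniform-noise half-width at the reference Δt
    noise_scale_factors: dict = field(default_factory=lambda: {
        0.250: 1.0,
        0.167: math.sqrt(2.0),
        0.088: 2.0,
    })
    noise_kind: str = "uniform"      # "uniform" (default) or "gaussian"

    def __post_init__(self):
        if not (self.peak_per_ap > 0 and self.tau > 0):
            raise ValueError("peak_per_ap and tau must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.noise_kind not in ("uniform", "gaussian"):
            raise ValueError("noise_kind must be 'uniform' or 'gaussian'")

    def noise_scale_for(self, dt_target: float) -> float:
        for key, fac in self.noise_scale_factors.items():
            if abs(dt_target - key) <= 1e-3:
                return fac
        return 1.0


def _exp_kernel(tau: float, dt: float, n: int, peak: float) -> np.ndarray:
    t = np.arange(n) * dt
    return peak * np.exp(-t / tau)


def spikes_to_calcium(train, params: ForwardModelParams, dt_target: float,
                      seed: int = 0) -> np.ndarray:
    """Surrogate ΔR/R trace for a single unit's spike counts at 100 Hz.

    Steps: exponential-kernel convolution at the native sample rate,
    additive noise (half-width ``noise_level`` scaled for ``dt_target``),
    then block-averaging down to ``dt_target``. The clean part is linear
    in the spike train.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 1:
        raise ValueError("train must be 1-D")
    fs = params.sample_rate_hz
    if dt_target < 1.0 / fs - 1e-12:
        raise ValueError("dt_target below the native sample interval")
    n = train.size
    kernel = _exp_kernel(params.tau, 1.0 / fs, n, params.peak_per_ap)
    clean = fftconvolve(train, kernel)[:n]
    if params.noise_level > 0:
        rng = np.random.default_rng(seed)
        amp = params.noise_level * params.noise_scale_for(dt_target)
        if params.noise_kind == "uniform":
            noisy = clean + rng.uniform(-amp, amp, size=n)
        else:
            # matched variance: uniform(-a, a) has SD a/sqrt(3)
            noisy = clean + rng.normal(0.0, amp / math.sqrt(3.0), size=n)
    else:
        noisy = clean
    factor = int(round(dt_target * fs))
    if factor <= 1:
        return noisy
    m = (n // factor) * factor
    return noisy[:m].reshape(-1, factor).mean(axis=1)


def raster_to_traces(raster: SpikeRaster, params: ForwardModelParams,
                     dt_target: float, seed: int = 0) -> CalciumTraceSet:
    """Forward-model every unit of a spike raster into a ΔR/R trace set.

    Spikes are placed on the model's native 100 Hz grid by their bin start
    times, so rasters at any ``dt`` can be rendered.
    """
    fs = params.sample_rate_hz
    n_hi = int(math.ceil(raster.n_bins * raster.dt * fs))
    rng = np.random.default_rng(seed)
    traces = []
    bin_times = np.arange(raster.n_bins) * raster.dt
    hi_idx = np.minimum((bin_times * fs).astype(int), n_hi - 1)
    for u in range(raster.n_units):
        train = np.zeros(n_hi)
        np.add.at(train, hi_idx, raster.counts[u])
        traces.append(spikes_to_calcium(train, params, dt_target,
                                        seed=int(rng.integers(2 ** 31))))
    return CalciumTraceSet(np.asarray(traces), dt_target,
                           roi_coords=raster.unit_coords, is_drr=True)
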
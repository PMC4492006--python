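"""Single-neuron and pairwise statistics of the rate estimate λ.

Covers the irregularity measures used to characterise ongoing activity:
normalised-rate distributions λ_norm = λ/λ_avg, quiescence probability
P_q, interburst intervals (IBIs: maximal runs of bins with λ ≤ λ_thr)
and their coefficient of variation (CV > 1 ⇒ more irregular than a
Poisson process), autocorrelation decay with its power-law exponent β,
pairwise Pearson correlations with an inter-ROI distance profile, and
windowed stationarity checks.

Conventions: IBI bins satisfy λ ≤ λ_thr while event bins satisfy
λ > λ_thr (complementary, no bin is both); quiescent runs touching the
recording edges are censored because their true duration is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._segments import find_runs, interior_runs
from .containers import RateRaster

__all__ = [
    "IbiStats", "CorrStats", "NormalizedRateDistribution", "StationarityProfile",
    "normalized_rate_distribution", "quiescence_probability", "ibi_statistics",
    "population_ibi_cv", "autocorrelation_decay", "pairwise_correlation",
    "stationarity_profile",
]

DEFAULT_LAM_THR = 0.5


@dataclass(frozen=True)
class NormalizedRateDistribution:
    lam_norm: np.ndarray
    density: np.ndarray
    edges: np.ndarray


def normalized_rate_distribution(lam, n_bins: int = 50) -> NormalizedRateDistribution:
    """Distribution of λ_norm = λ/λ_avg (mean normalised to 1)."""
    lam = np.asarray(lam, dtype=float)
    avg = lam.mean()
    if not avg > 0:
        raise ValueError("lam_avg must be positive to normalise")
    lam_norm = lam / avg
    density, edges = np.histogram(lam_norm, bins=n_bins, density=True)
    return NormalizedRateDistribution(lam_norm, density, edges)


def quiescence_probability(lam, lam_thr: float = DEFAULT_LAM_THR) -> float:
    """P_q: fraction of bins with λ below the event threshold."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        raise ValueError("empty series")
    return float(np.mean(lam < lam_thr))


@dataclass(frozen=True)
class IbiStats:
    ibis_bins: np.ndarray      # run lengths in bins (edge runs censored)
    ibis_s: np.ndarray         # durations in seconds
    ibi_norm: np.ndarray       # IBI / mean(IBI)
    cv: float                  # SD/mean of IBI durations
    p_q: float
    lam_thr_used: float
    burst_strength: float      # mean λ over bins with λ > λ_thr

    @property
    def n_ibis(self) -> int:
        return self.ibis_bins.size


def ibi_statistics(lam, lam_thr: float = DEFAULT_LAM_THR,
                   dt: float = 0.25) -> IbiStats:
    """Interburst-interval statistics of one λ series.

    IBIs are maximal runs of bins with λ ≤ λ_thr; runs touching the
    series edges are discarded. The CV needs at least two IBIs.
    """
    lam = np.asarray(lam, dtype=float)
    quiet = lam <= lam_thr
    starts, lengths = find_runs(quiet)
    _, lengths = interior_runs(starts, lengths, lam.size)
    if lengths.size < 2:
        raise ValueError(
            f"found {lengths.size} interior IBIs; CV needs at least 2")
    ibis_s = lengths * dt
    mean = ibis_s.mean()
    cv = float(ibis_s.std() / mean)
    supra = lam > lam_thr
    burst = float(lam[supra].mean()) if supra.any() else float("nan")
    return IbiStats(lengths, ibis_s, ibis_s / mean, cv,
                    quiescence_probability(lam, lam_thr), lam_thr, burst)


def population_ibi_cv(raster: RateRaster, lam_thr: float = DEFAULT_LAM_THR,
                      min_ibis: int = 2) -> tuple[float, np.ndarray]:
    """Mean CV of IBIs over ROIs with at least ``min_ibis`` intervals."""
    cvs = []
    for row in raster.lam:
        try:
            st = ibi_statistics(row, lam_thr, raster.dt)
        except ValueError:
            continue
        if st.n_ibis >= min_ibis:
            cvs.append(st.cv)
    cvs = np.asarray(cvs)
    if cvs.size == 0:
        raise ValueError("no ROI has enough IBIs for a CV")
    return float(cvs.mean()), cvs


@dataclass
class CorrStats:
    pairwise_r: np.ndarray | None = None
    distance_bin_centers: np.ndarray | None = None
    distance_mean_r: np.ndarray | None = None
    autocorr_lags_s: np.ndarray | None = None
    autocorr: np.ndarray | None = None
    beta: float | None = None


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    # FFT autocorrelation (zero-padded to avoid circular wrap)
    x = x - x.mean()
    denom = float(x @ x)
    nfft = 1 << int(np.ceil(np.log2(2 * x.size)))
    fx = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(fx * np.conj(fx), nfft)[:nlags + 1]
    return ac / denom


def autocorrelation_decay(raster: RateRaster, max_lag: float = 10.0) -> CorrStats:
    """ROI-averaged autocorrelation of λ and its power-law decay exponent β.

    β is minus the slope of log(autocorr) vs log(lag) over lags from Δt to
    ``max_lag``, restricted to lags where the mean autocorrelation is
    positive (the log is undefined otherwise). Zero-variance ROIs are
    excluded with a warning.
    """
    nlags = int(round(max_lag / raster.dt))
    nlags = min(nlags, raster.n_bins - 1)
    acs, skipped = [], 0
    for row in raster.lam:
        if row.std() == 0:
            skipped += 1
            continue
        acs.append(_acf(row, nlags))
    if skipped:
        warnings.warn(f"excluded {skipped} zero-variance ROI(s) from the "
                      "autocorrelation average")
    if not acs:
        raise ValueError("all ROIs have zero variance")
    mean_ac = np.mean(acs, axis=0)
    lags_s = np.arange(nlags + 1) * raster.dt
    pos = mean_ac[1:] > 0
    beta = None
    if pos.sum() >= 2:
        slope, _ = np.polyfit(np.log(lags_s[1:][pos]),
                              np.log(mean_ac[1:][pos]), 1)
        beta = float(-slope)
    return CorrStats(autocorr_lags_s=lags_s, autocorr=mean_ac, beta=beta)


def pairwise_correlation(raster: RateRaster,
                         distance_bin_um: float = 25.0) -> CorrStats:
    """Pearson R between all ROI pairs, plus a binned distance profile.

    Zero-variance ROIs yield NaN rows/columns (pairs marked missing).
    The distance profile averages R in bins of inter-ROI centroid
    distance (default 25 µm width) when coordinates are available.
    """
    if raster.n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    sd = raster.lam.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(raster.lam)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    stats = CorrStats(pairwise_r=r)
    if raster.roi_coords is not None:
        iu = np.triu_indices(raster.n_rois, k=1)
        d = np.linalg.norm(raster.roi_coords[iu[0]] - raster.roi_coords[iu[1]],
                           axis=1)
        rv = r[iu]
        ok = np.isfinite(rv)
        d, rv = d[ok], rv[ok]
        if d.size:
            n_bins = int(np.ceil((d.max() + 1e-9) / distance_bin_um))
            idx = np.minimum((d / distance_bin_um).astype(int), n_bins - 1)
            centers = (np.arange(n_bins) + 0.5) * distance_bin_um
            means = np.full(n_bins, np.nan)
            for b in range(n_bins):
                sel = idx == b
                if sel.any():
                    means[b] = rv[sel].mean()
            stats.distance_bin_centers = centers
            stats.distance_mean_r = means
    return stats


@dataclass(frozen=True)
class StationarityProfile:
    t_centers: np.ndarray
    mean_rate: np.ndarray
    mean_rate_norm: np.ndarray      # normalised by the first window
    mean_r: np.ndarray
    mean_r_norm: np.ndarray


def stationarity_profile(raster: RateRaster,
                         window: float = 30.0) -> StationarityProfile:
    """Windowed mean λ and mean pairwise R, normalised by the first window."""
    wbins = int(round(window / raster.dt))
    n_win = raster.n_bins // wbins
    if n_win < 2:
        raise ValueError("recording must span at least 2 windows")
    rates, rs, centers = [], [], []
    for w in range(n_win):
        seg = raster.lam[:, w * wbins:(w + 1) * wbins]
        rates.append(float(seg.mean()))
        centers.append((w + 0.5) * wbins * raster.dt)
        if raster.n_rois >= 2:
            sd = seg.std(axis=1)
            if (sd > 0).sum() >= 2:
                with np.errstate(invalid="ignore", divide="ignore"):
                    rr = np.corrcoef(seg[sd > 0])
                iu = np.triu_indices(rr.shape[0], k=1)
                rs.append(float(np.nanmean(rr[iu])))
            else:
                rs.append(float("nan"))
        else:
            rs.append(float("nan"))
    rates = np.asarray(rates)
    rs = np.asarray(rs)
    if rates[0] == 0:
        raise ValueError("first-window mean rate is zero; cannot normalise")
    r_norm = rs / rs[0] if np.isfinite(rs[0]) and rs[0] != 0 else np.full_like(rs, np.nan)
    return StationarityProfile(np.asarray(centers), rates, rates / rates[0],
                               rs, r_norm)
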
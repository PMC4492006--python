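"""Core in-memory containers shared across the pipeline.

Three array-backed containers move through the analysis:

* :class:`SpikeRaster` — integer spike counts per unit per time bin
  (ground truth from the simulator, or binned spike trains).
* :class:`CalciumTraceSet` — per-ROI fluorescence ratio traces (raw ratio
  ``R`` or baseline-normalised ``ΔR/R``).
* :class:`RateRaster` — the pipeline's central matrix: the nonnegative
  instantaneous firing-rate estimate ``λ`` per ROI per bin, in units
  calibrated so that one action potential contributes integrated λ ≈ 1
  in its bin.

All containers carry the bin/frame interval ``dt`` in seconds and
optional ROI/unit centroid coordinates in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SpikeRaster", "RateRaster", "CalciumTraceSet"]


def _check_coords(coords, n: int):
    if coords is None:
        return None
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n, 2):
        raise ValueError(f"coords must have shape ({n}, 2), got {coords.shape}")
    return coords


def _block_sum(a: np.ndarray, factor: int) -> np.ndarray:
    """Sum consecutive blocks of `factor` columns; a trailing partial block is dropped."""
    if factor < 1:
        raise ValueError("rebin factor must be >= 1")
    n = (a.shape[1] // factor) * factor
    return a[:, :n].reshape(a.shape[0], -1, factor).sum(axis=2)


@dataclass
class SpikeRaster:
    """Spike counts per unit and time bin.

    Parameters
    ----------
    counts : ndarray of int, shape (n_units, n_bins)
        Nonnegative spike counts.
    dt : float
        Bin width in seconds.
    unit_coords : ndarray, shape (n_units, 2), optional
        Unit centroids in µm.
    """

    counts: np.ndarray
    dt: float
    unit_coords: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D [unit x bin]")
        if not np.issubdtype(self.counts.dtype, np.integer):
            c = np.asarray(self.counts)
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.unit_coords = _check_coords(self.unit_coords, self.counts.shape[0])

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    def rebin(self, factor: int) -> "SpikeRaster":
        """Coarsen time resolution by summing blocks of `factor` bins."""
        return SpikeRaster(_block_sum(self.counts, factor), self.dt * factor,
                           self.unit_coords)

    def to_rate(self) -> "RateRaster":
        """View counts as a rate raster (λ = spikes per bin)."""
        return RateRaster(self.counts.astype(float), self.dt, self.unit_coords)


@dataclass
class RateRaster:
    """Instantaneous firing-rate estimate λ per ROI and time bin.

    λ is nonnegative and dimensionless per bin; with the default
    calibration one action potential in a bin contributes integrated
    λ ≈ 1, so ``lam_avg / dt`` is an estimate of the firing rate in Hz.
    """

    lam: np.ndarray
    dt: float
    roi_coords: np.ndarray | None = None

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.ndim != 2:
            raise ValueError("lam must be 2-D [roi x bin]")
        if self.lam.size and (self.lam < 0).any():
            raise ValueError("lam must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.roi_coords = _check_coords(self.roi_coords, self.lam.shape[0])

    @property
    def n_rois(self) -> int:
        return self.lam.shape[0]

    @property
    def n_bins(self) -> int:
        return self.lam.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    @property
    def lam_avg(self) -> np.ndarray:
        """Per-ROI mean λ over all bins (sub-threshold bins included)."""
        return self.lam.mean(axis=1)

    @property
    def lam_avg_pop(self) -> float:
        """Population-mean rate: mean over ROIs of lam_avg."""
        return float(self.lam_avg.mean()) if self.n_rois else float("nan")

    @property
    def is_empty(self) -> bool:
        return self.n_rois == 0

    def rebin(self, factor: int) -> "RateRaster":
        return RateRaster(_block_sum(self.lam, factor), self.dt * factor,
                          self.roi_coords)

    def select(self, idx) -> "RateRaster":
        coords = self.roi_coords[idx] if self.roi_coords is not None else None
        return RateRaster(self.lam[idx], self.dt, coords)


@dataclass
class CalciumTraceSet:
    """Per-ROI fluorescence ratio time series.

    ``ratio`` holds either the raw two-channel ratio R (cpVenus/ECFP) or,
    after baseline normalisation, ΔR/R = (R − R0)/R0 with R0 the per-ROI
    median of R (``is_drr`` tells which). All ROIs share one frame
    interval ``dt``.
    """

    ratio: np.ndarray
    dt: float
    roi_coords: np.ndarray | None = None
    r0: np.ndarray | None = None
    is_drr: bool = False

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.ratio.ndim != 2:
            raise ValueError("ratio must be 2-D [roi x frame]")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.roi_coords = _check_coords(self.roi_coords, self.ratio.shape[0])

    @property
    def n_rois(self) -> int:
        return self.ratio.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[1]

    def copy_with(self, **kw) -> "CalciumTraceSet":
        return replace(self, **kw)
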
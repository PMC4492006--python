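"""Spatiotemporal cluster (avalanche) detection on rate rasters.

A time bin is *active* when at least one ROI exceeds the event threshold
(λ > λ_thr); maximal runs of active bins, flanked by quiescent bins, form
clusters. Per cluster the catalog records the participation count per
bin, the size in rate units s_λ = Σλ over suprathreshold entries, the
event count s_k, and the lifetime T = n_bins·Δt. Sizes are normalised by
the predicted cluster size limit Λ = N·λ_avg^pop. The module also
provides the cluster-rate threshold scan, the two-bin branching-parameter
estimator, population-rate thresholding as an alternative cascade
definition, a rate-preserving shuffle control, and logarithmic binning
for visualisation.

Note on the flanking convention: clusters are bounded by *empty* bins in
which every ROI is sub-threshold (λ ≤ λ_thr); suprathreshold entries
(λ > λ_thr) define participation. The two conventions are complementary,
so no bin is both quiescent and active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._segments import find_runs, interior_runs
from .containers import RateRaster

__all__ = [
    "Cluster", "AvalancheCatalog", "BranchingEstimate", "ThresholdScan",
    "PopThresholdResult", "LogBinnedPdf",
    "detect_clusters", "scan_threshold", "branching_parameter",
    "population_threshold_clusters", "shuffle_raster", "log_bin_pdf",
    "default_threshold_grid",
]


@dataclass(frozen=True)
class Cluster:
    start_bin: int
    n_bins: int
    per_bin_participation: np.ndarray  # suprathreshold ROI-events per bin
    s_lambda: float                    # Σλ over suprathreshold entries
    s_k: int                           # count of suprathreshold entries
    lifetime_s: float                  # n_bins · Δt


@dataclass
class AvalancheCatalog:
    clusters: list
    lam_thr: float
    dt: float
    n_rois: int
    lam_avg_pop: float
    duration_s: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def size_limit(self) -> float:
        """Predicted cluster size limit Λ = N · λ_avg^pop."""
        return self.n_rois * self.lam_avg_pop

    @property
    def sizes_lambda(self) -> np.ndarray:
        return np.array([c.s_lambda for c in self.clusters])

    @property
    def sizes_k(self) -> np.ndarray:
        return np.array([c.s_k for c in self.clusters], dtype=int)

    @property
    def s_norm(self) -> np.ndarray:
        """Sizes normalised by the size limit Λ."""
        return self.sizes_lambda / self.size_limit

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([c.lifetime_s for c in self.clusters])

    @property
    def cluster_rate(self) -> float:
        return self.n_clusters / self.duration_s


def default_threshold_grid(lo: float = 0.1, hi: float = 8.0,
                           n: int = 40) -> np.ndarray:
    """Logarithmically spaced λ_thr grid over the scanned range 0.1–8."""
    return np.geomspace(lo, hi, n)


def detect_clusters(raster: RateRaster, lam_thr: float,
                    censor_edges: bool = True) -> AvalancheCatalog:
    """Concatenate consecutive active bins into avalanches.

    Runs touching the recording edges are censored by default (their true
    extent is unknown); pass ``censor_edges=False`` for exact bookkeeping
    against brute-force counts.
    """
    if lam_thr < 0:
        raise ValueError("lam_thr must be >= 0")
    above = raster.lam > lam_thr
    active = above.any(axis=0)
    starts, lengths = find_runs(active)
    if censor_edges:
        starts, lengths = interior_runs(starts, lengths, raster.n_bins)
    clusters = []
    for a, ln in zip(starts, lengths):
        sub = above[:, a:a + ln]
        part = sub.sum(axis=0)
        s_k = int(part.sum())
        s_lam = float(raster.lam[:, a:a + ln][sub].sum())
        clusters.append(Cluster(int(a), int(ln), part.astype(int), s_lam,
                                s_k, ln * raster.dt))
    return AvalancheCatalog(clusters, lam_thr, raster.dt, raster.n_rois,
                            raster.lam_avg_pop, raster.duration)


@dataclass(frozen=True)
class ThresholdScan:
    thr_grid: np.ndarray
    cluster_rate: np.ndarray
    lam_thr_max: float | None  # None when no threshold yields any cluster


def scan_threshold(raster: RateRaster, thr_grid=None,
                   censor_edges: bool = True) -> ThresholdScan:
    """Cluster rate as a function of λ_thr; λ_thr^max maximises it.

    Ties resolve to the smallest threshold. On an all-zero raster no
    threshold produces clusters and ``lam_thr_max`` is None.
    """
    grid = np.asarray(default_threshold_grid() if thr_grid is None
                      else thr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    rates = np.array([
        detect_clusters(raster, thr, censor_edges).cluster_rate
        for thr in grid])
    if not rates.any():
        return ThresholdScan(grid, rates, None)
    i = int(np.argmax(rates))  # first occurrence -> smallest threshold on ties
    return ThresholdScan(grid, rates, float(grid[i]))


@dataclass(frozen=True)
class BranchingEstimate:
    sigma: float
    n_cascades_used: int


def branching_parameter(catalog: AvalancheCatalog,
                        all_pairs: bool = False) -> BranchingEstimate:
    """σ = mean descendant/ancestor ratio over cascades.

    By default the ratio uses the first (ancestor) and second
    (descendant) bins of each cascade; single-bin cascades are
    extinctions and contribute 0, which keeps the estimator unbiased for
    a branching process. ``all_pairs=True`` averages the ratio over every
    consecutive bin pair within each cascade instead.
    """
    if catalog.n_clusters == 0:
        raise ValueError("empty catalog: branching parameter undefined")
    ratios = []
    for c in catalog.clusters:
        p = c.per_bin_participation
        if c.n_bins == 1:
            ratios.append(0.0)
        elif all_pairs:
            ratios.append(float(np.mean(p[1:] / p[:-1])))
        else:
            ratios.append(float(p[1] / p[0]))
    return BranchingEstimate(float(np.mean(ratios)), catalog.n_clusters)


@dataclass(frozen=True)
class PopThresholdResult:
    catalog: AvalancheCatalog
    theta_star: float
    theta_grid: np.ndarray
    n_cascades: np.ndarray


def population_threshold_clusters(raster: RateRaster, lam_thr: float,
                                  theta_grid=None, n_theta: int = 50,
                                  censor_edges: bool = True) -> PopThresholdResult:
    """Cascades from thresholding the integrated population rate λ^pop.

    λ entries at or below λ_thr are zeroed, the population vector
    λ^pop_t = Σ_ROI λ_t is formed, and cascades are maximal runs with
    λ^pop > θ with size Σλ^pop over the run. θ is scanned (by default
    over 50 quantile levels of the nonzero λ^pop) and the θ maximising
    the number of cascades is returned.
    """
    lam0 = np.where(raster.lam > lam_thr, raster.lam, 0.0)
    pop = lam0.sum(axis=0)
    if theta_grid is None:
        nz = pop[pop > 0]
        if nz.size == 0:
            theta_grid = np.array([0.0])
        else:
            qs = np.linspace(0.0, 1.0, n_theta + 2)[1:-1]
            theta_grid = np.unique(np.quantile(nz, qs))
    theta_grid = np.asarray(theta_grid, dtype=float)

    def cascades_at(theta):
        starts, lengths = find_runs(pop > theta)
        if censor_edges:
            starts, lengths = interior_runs(starts, lengths, raster.n_bins)
        return starts, lengths

    counts = np.array([cascades_at(th)[0].size for th in theta_grid])
    i = int(np.argmax(counts)) if counts.size else 0
    theta_star = float(theta_grid[i])
    starts, lengths = cascades_at(theta_star)
    active = lam0 > 0
    clusters = []
    for a, ln in zip(starts, lengths):
        part = active[:, a:a + ln].sum(axis=0)
        s_lam = float(pop[a:a + ln].sum())
        clusters.append(Cluster(int(a), int(ln), part.astype(int), s_lam,
                                int(part.sum()), ln * raster.dt))
    catalog = AvalancheCatalog(clusters, lam_thr, raster.dt, raster.n_rois,
                               raster.lam_avg_pop, raster.duration)
    return PopThresholdResult(catalog, theta_star, theta_grid, counts)


def shuffle_raster(raster: RateRaster, seed: int = 0) -> RateRaster:
    """Rate-preserving control: permute time bins independently per ROI.

    The per-ROI multiset of λ values (hence λ_avg and Λ) is exactly
    preserved while spatiotemporal correlations are destroyed.
    """
    rng = np.random.default_rng(seed)
    lam = np.empty_like(raster.lam)
    for i in range(raster.n_rois):
        lam[i] = raster.lam[i, rng.permutation(raster.n_bins)]
    return RateRaster(lam, raster.dt, raster.roi_coords)


@dataclass(frozen=True)
class LogBinnedPdf:
    edges: np.ndarray
    centers: np.ndarray   # geometric bin centres
    counts: np.ndarray
    density: np.ndarray   # counts / (n · bin width)


def log_bin_pdf(sizes, n_bins: int = 30) -> LogBinnedPdf:
    """Logarithmically binned probability density of positive sizes."""
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("no sizes to bin")
    if (s <= 0).any():
        raise ValueError("sizes must be positive for logarithmic binning")
    lo, hi = float(s.min()), float(s.max())
    if lo == hi:
        hi = lo * (1.0 + 1e-9)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[-1] *= 1.0 + 1e-12  # include the maximum in the last bin
    counts, _ = np.histogram(s, bins=edges)
    widths = np.diff(edges)
    density = counts / (s.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return LogBinnedPdf(edges, centers, counts, density)
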
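"""Cluster detection, threshold scan, branching estimator, controls."""

import numpy as np
import pytest

from avkit import powerlaw as pl
from avkit.avalanches import (branching_parameter, default_threshold_grid,
                              detect_clusters, log_bin_pdf,
                              population_threshold_clusters, scan_threshold,
                              shuffle_raster)
from avkit.containers import RateRaster


def _raster(lam, dt=0.25):
    return RateRaster(np.asarray(lam, dtype=float), dt)


# ---------------------------------------------------------------------------
# detection


def test_single_suprathreshold_entry():
    cat = detect_clusters(_raster([[0, 0, 2.0, 0, 0]]), 0.5)
    assert cat.n_clusters == 1
    c = cat.clusters[0]
    assert (c.s_lambda, c.s_k, c.lifetime_s) == (2.0, 1, 0.25)
    assert c.per_bin_participation.tolist() == [1]


def test_active_pattern_two_clusters_uncensored():
    lam = [[2.0, 2.0, 0.0, 2.0]]
    cat = detect_clusters(_raster(lam), 0.5, censor_edges=False)
    assert sorted(c.n_bins for c in cat.clusters) == [1, 2]
    # censored: both runs touch an edge
    assert detect_clusters(_raster(lam), 0.5).n_clusters == 0


def test_entry_conservation_matches_bruteforce(rng):
    lam = rng.exponential(0.4, (6, 500))
    thr = 0.5
    cat = detect_clusters(RateRaster(lam, 0.25), thr, censor_edges=False)
    assert int(cat.sizes_k.sum()) == int((lam > thr).sum())
    # censored mode counts only entries inside interior runs
    cat_c = detect_clusters(RateRaster(lam, 0.25), thr)
    assert cat_c.sizes_k.sum() <= cat.sizes_k.sum()


def test_cluster_size_inequality_and_lambda(rng):
    lam = rng.exponential(0.5, (8, 300))
    cat = detect_clusters(RateRaster(lam, 0.25), 0.5)
    for c in cat.clusters:
        assert c.s_lambda >= 0.5 * c.s_k
        assert c.s_k == c.per_bin_participation.sum()
        assert c.lifetime_s == pytest.approx(c.n_bins * 0.25)
    assert cat.size_limit == pytest.approx(8 * cat.lam_avg_pop)


def test_raising_threshold_shrinks_containing_cluster(rng):
    lam = rng.exponential(0.8, (5, 400))
    lo = detect_clusters(RateRaster(lam, 0.25), 0.5, censor_edges=False)
    hi = detect_clusters(RateRaster(lam, 0.25), 1.5, censor_edges=False)

    def cluster_of(cat, b):
        for c in cat.clusters:
            if c.start_bin <= b < c.start_bin + c.n_bins:
                return c
        return None

    rois, bins = np.nonzero(lam > 1.5)
    for b in bins[:50]:
        c_lo, c_hi = cluster_of(lo, b), cluster_of(hi, b)
        assert c_lo is not None and c_hi is not None
        assert c_hi.s_k <= c_lo.s_k


# ---------------------------------------------------------------------------
# threshold scan


def test_scan_trivial_cases(rng):
    lam = rng.exponential(0.5, (4, 200))
    scan = scan_threshold(RateRaster(lam, 0.25), [lam.max() + 1.0])
    assert scan.cluster_rate[0] == 0.0 and scan.lam_thr_max is None
    one = scan_threshold(RateRaster(lam, 0.25), [0.7])
    assert one.lam_thr_max == 0.7
    with pytest.raises(ValueError):
        scan_threshold(RateRaster(lam, 0.25), [])


def test_scan_all_zero_raster_flagged():
    scan = scan_threshold(_raster(np.zeros((3, 100))))
    assert scan.lam_thr_max is None


def test_scan_interior_maximum_on_dense_deconvolved_raster(dense_chain):
    """Cluster rate peaks at an intermediate λ_thr on in vivo-like data."""
    grid = default_threshold_grid(0.1, 8.0, 20)
    scan = scan_threshold(dense_chain["raster"], grid)
    assert scan.lam_thr_max is not None
    assert grid[0] < scan.lam_thr_max < grid[-1]


# ---------------------------------------------------------------------------
# branching parameter


def test_branching_parameter_examples():
    lam = [[0, 2, 2, 0, 0, 2, 0], [0, 2, 2, 0, 0, 0, 0],
           [0, 0, 2, 0, 0, 0, 0], [0, 0, 2, 0, 0, 0, 0.0]]
    cat = detect_clusters(_raster(lam), 0.5)
    # clusters: participation [2, 4] (sigma 2) and [1] (extinction, 0)
    est = branching_parameter(cat)
    assert est.sigma == pytest.approx((2.0 + 0.0) / 2)
    assert est.n_cascades_used == 2
    all_single = detect_clusters(_raster([[0, 2, 0, 2, 0.0]]), 0.5)
    assert branching_parameter(all_single).sigma == 0.0
    with pytest.raises(ValueError):
        branching_parameter(detect_clusters(_raster(np.zeros((2, 5))), 0.5))


def test_branching_parameter_critical_recovery(critical_catalog):
    est = branching_parameter(critical_catalog)
    assert est.sigma == pytest.approx(1.0, abs=0.1)
    assert est.n_cascades_used >= 5000


# ---------------------------------------------------------------------------
# population thresholding


def test_population_threshold_single_cascade():
    res = population_threshold_clusters(_raster([[0, 3.0, 0]]), 1.0,
                                        theta_grid=[1.0])
    assert res.catalog.n_clusters == 1
    assert res.catalog.clusters[0].s_lambda == pytest.approx(3.0)


def test_population_threshold_above_max_empty(rng):
    lam = rng.exponential(0.5, (4, 100))
    res = population_threshold_clusters(RateRaster(lam, 0.25), 0.5,
                                        theta_grid=[lam.sum(0).max() + 1])
    assert res.catalog.n_clusters == 0


def test_population_threshold_matches_run_sum_oracle(rng):
    lam = rng.exponential(0.5, (6, 400))
    thr, theta = 0.5, 2.0
    res = population_threshold_clusters(RateRaster(lam, 0.25), thr,
                                        theta_grid=[theta],
                                        censor_edges=False)
    lam0 = np.where(lam > thr, lam, 0.0)
    pop = lam0.sum(0)
    # brute-force scan of runs with pop > theta
    sizes = []
    cur, inside = 0.0, False
    for v in pop:
        if v > theta:
            cur += v
            inside = True
        elif inside:
            sizes.append(cur)
            cur, inside = 0.0, False
    if inside:
        sizes.append(cur)
    np.testing.assert_allclose(sorted(res.catalog.sizes_lambda),
                               sorted(sizes))


# ---------------------------------------------------------------------------
# shuffle control


def test_shuffle_preserves_per_roi_values(rng):
    lam = rng.exponential(1.0, (5, 300))
    raster = RateRaster(lam, 0.25)
    sh = shuffle_raster(raster, seed=4)
    for i in range(5):
        np.testing.assert_allclose(np.sort(sh.lam[i]), np.sort(lam[i]))
    assert sh.lam_avg_pop == pytest.approx(raster.lam_avg_pop)
    assert not np.array_equal(sh.lam, lam)


def test_shuffle_single_bin_unchanged(rng):
    lam = rng.random((4, 1))
    np.testing.assert_array_equal(shuffle_raster(RateRaster(lam, 0.25),
                                                 7).lam, lam)


def test_shuffle_destroys_power_law(critical_raster):
    """Rate-preserving shuffling flips the LLR to favour the exponential."""
    raster = critical_raster.to_rate()
    sh = shuffle_raster(raster, seed=99)
    cat = detect_clusters(sh, 0.5)
    sizes = pl.dequantize_counts(cat.sizes_k.astype(float), seed=1)
    res = pl.llr_test(sizes[sizes > 0])
    assert res.llr < 0
    assert res.favored_model == "exponential"


# ---------------------------------------------------------------------------
# logarithmic binning


def test_log_bin_pdf_counts_and_degenerate(rng):
    s = rng.pareto(1.5, 500) + 1.0
    b = log_bin_pdf(s)
    assert b.counts.sum() == 500
    assert b.edges.size == 31
    single = log_bin_pdf(np.full(10, 4.2))
    assert (single.counts > 0).sum() == 1
    with pytest.raises(ValueError):
        log_bin_pdf(np.array([0.0, 1.0]))


def test_log_bin_pdf_slope_recovers_exponent(rng):
    x = pl.sample_truncated_powerlaw(-1.5, 1.0, 1000.0, 200_000, rng)
    b = log_bin_pdf(x, n_bins=30)
    sel = b.counts > 50
    slope, _ = np.polyfit(np.log(b.centers[sel]), np.log(b.density[sel]), 1)
    assert slope == pytest.approx(-1.5, abs=0.1)


# ---------------------------------------------------------------------------
# size-measure consistency on the full chain


def test_size_lambda_proportional_to_sk_on_chain(dense_chain):
    """s_λ tracks s_k·λ_avg^pop linearly across clusters (R² ≥ 0.98)."""
    raster = dense_chain["raster"]
    scan = scan_threshold(raster, default_threshold_grid(0.1, 8.0, 20))
    cat = detect_clusters(raster, scan.lam_thr_max)
    x = cat.sizes_k.astype(float) * cat.lam_avg_pop
    y = cat.sizes_lambda
    slope, ic = np.polyfit(x, y, 1)
    pred = slope * x + ic
    r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    assert cat.n_clusters > 100
    assert r2 >= 0.98
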
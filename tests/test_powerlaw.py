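"""Truncated power-law / exponential inference against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from avkit import powerlaw as pl


# ---------------------------------------------------------------------------
# normalisation and densities


@pytest.mark.parametrize("alpha,s_min,s_max", [
    (-1.5, 1.0, 100.0),
    (-2.0, 0.5, 20.0),
    (-1.0, 1.0, 50.0),     # logarithmic branch
    (-1.0001, 2.0, 30.0),  # near the branch point
    (0.0, 1.0, 2.0),
])
def test_powerlaw_normalisation_matches_quadrature(alpha, s_min, s_max):
    c = pl._pl_norm(alpha, s_min, s_max)
    integral, _ = quad(lambda s: c * s ** alpha, s_min, s_max)
    assert integral == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("gamma,s_min,s_max", [(1.3, 1.0, 40.0),
                                               (-0.4, 2.0, 10.0),
                                               (5.0, 0.5, 3.0)])
def test_exponential_normalisation_matches_quadrature(gamma, s_min, s_max):
    fit = pl.ExponentialFit(gamma, float("nan"), s_min, s_max, 0)
    integral, _ = quad(fit.pdf, s_min, s_max)
    assert integral == pytest.approx(1.0, rel=1e-9)
    # cdf endpoints
    assert fit.cdf(s_min) == pytest.approx(0.0, abs=1e-12)
    assert fit.cdf(s_max) == pytest.approx(1.0, rel=1e-12)


def test_loglik_definition_and_uniform_limit():
    fit = pl.PowerLawFit(-1.5, pl._pl_norm(-1.5, 1, 100), 1.0, 100.0, 0.0, 1)
    s = 7.3
    assert pl.loglik(fit, [s]) == pytest.approx(np.log(fit.c * s ** -1.5))
    # alpha = 0 on [1, 2] is the uniform density 1: log-likelihood 0
    uniform = pl.PowerLawFit(0.0, pl._pl_norm(0.0, 1, 2), 1.0, 2.0, 0.0, 3)
    assert pl.loglik(uniform, [1.2, 1.5, 1.9]) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="index"):
        pl.loglik(uniform, [1.5, 2.5])


def test_loglik_matches_quadrature_normalised_density(rng):
    # density implied by logpdf integrates to 1 for random parameter draws
    for _ in range(5):
        alpha = -rng.uniform(1.05, 3.0)
        s_min = rng.uniform(0.5, 2.0)
        s_max = s_min * rng.uniform(5, 50)
        fit = pl.PowerLawFit(alpha, pl._pl_norm(alpha, s_min, s_max),
                             s_min, s_max, 0.0, 1)
        integral, _ = quad(lambda s: np.exp(fit.logpdf(s)), s_min, s_max)
        assert integral == pytest.approx(1.0, rel=1e-8)


# ---------------------------------------------------------------------------
# KS distance


def test_ks_distance_regular_quantile_construction(rng):
    fit = pl.PowerLawFit(-1.5, pl._pl_norm(-1.5, 1, 100), 1.0, 100.0, 0.0, 0)
    n = 1000
    samples = fit.ppf((np.arange(n) + 0.5) / n)
    assert pl.ks_distance(samples, fit) <= 1.0 / n + 1e-12


def test_ks_distance_matches_bruteforce_scan(rng):
    fit = pl.PowerLawFit(-1.8, pl._pl_norm(-1.8, 1, 50), 1.0, 50.0, 0.0, 0)
    x = np.sort(fit.ppf(rng.random(200)))
    # brute force: both one-sided gaps at every sample point
    n = x.size
    d = 0.0
    for i, xi in enumerate(x):
        cm = float(fit.cdf(xi))
        d = max(d, abs(cm - (i + 1) / n), abs(cm - i / n))
    assert pl.ks_distance(x, fit) == pytest.approx(d, abs=1e-12)


def test_ks_distance_empty_error():
    fit = pl.PowerLawFit(-1.5, 1.0, 1.0, 10.0, 0.0, 0)
    with pytest.raises(ValueError):
        pl.ks_distance([], fit)


# ---------------------------------------------------------------------------
# parameter recovery (inverse-CDF sampling oracle)


@pytest.mark.parametrize("alpha", [-1.2, -1.5, -1.8])
def test_exponent_recovery_ks_and_mle(alpha):
    rng = np.random.default_rng(hash(alpha) % 2 ** 31)
    x = pl.sample_truncated_powerlaw(alpha, 1.0, 100.0, 10_000, rng)
    ks = pl.fit_powerlaw_ks(x, s_min=1.0, s_max=100.0)
    mle = pl.fit_powerlaw_mle(x, s_min=1.0, s_max=100.0)
    assert abs(ks.alpha - alpha) < 0.05
    assert abs(mle.alpha - alpha) < 0.03


@pytest.mark.parametrize("gamma", [0.5, 2.0])
def test_exponential_rate_recovery(gamma, rng):
    x = pl.sample_truncated_exponential(gamma, 1.0, 30.0, 20_000, rng)
    fit = pl.fit_exponential_mle(x, s_min=1.0, s_max=30.0)
    assert fit.gamma_rate == pytest.approx(gamma, rel=0.05)


def test_fitted_model_passes_its_own_ks_check(rng):
    # D_KS of data drawn from the fitted model stays below the 5% critical
    # value in at least 90% of replicates
    crit = 1.358 / np.sqrt(10_000)
    ok = 0
    for rep in range(20):
        x = pl.sample_truncated_powerlaw(-1.5, 1.0, 100.0, 10_000, rng)
        fit = pl.fit_powerlaw_ks(x, s_min=1.0, s_max=100.0)
        ok += fit.d_ks < crit
    assert ok >= 18


def test_degenerate_samples_error():
    with pytest.raises(ValueError):
        pl.fit_powerlaw_ks(np.full(100, 3.0))
    with pytest.raises(ValueError):
        pl.fit_lifetime_distribution(np.full(50, 0.25), 0.25)


# ---------------------------------------------------------------------------
# LLR model comparison


def test_llr_favors_generating_family(rng):
    x = pl.sample_truncated_powerlaw(-1.5, 1.0, 100.0, 10_000, rng)
    r = pl.llr_test(x, s_min=1.0, s_max=100.0)
    assert r.llr > 0 and r.p_value < 0.05 and r.favored_model == "power_law"
    y = pl.sample_truncated_exponential(0.8, 1.0, 100.0, 10_000, rng)
    r2 = pl.llr_test(y, s_min=1.0, s_max=100.0)
    assert r2.llr < 0 and r2.p_value < 0.05 and r2.favored_model == "exponential"


def test_llr_requires_enough_samples():
    with pytest.raises(ValueError):
        pl.llr_test([1.0])
    with pytest.raises(ValueError):
        pl.llr_test(np.linspace(1, 5, 9))


def test_llr_decision_error_rate_below_five_percent(rng):
    """Wrong-family decisions are rare at n = 1000 (both directions)."""
    wrong = 0
    n_sets = 200
    for rep in range(n_sets):
        x = pl.sample_truncated_powerlaw(-1.5, 1.0, 100.0, 1000, rng)
        if pl.llr_test(x, s_min=1.0, s_max=100.0).favored_model == "exponential":
            wrong += 1
    assert wrong / n_sets < 0.05
    wrong = 0
    for rep in range(n_sets):
        y = pl.sample_truncated_exponential(0.8, 1.0, 100.0, 1000, rng)
        if pl.llr_test(y, s_min=1.0, s_max=100.0).favored_model == "power_law":
            wrong += 1
    assert wrong / n_sets < 0.05


# ---------------------------------------------------------------------------
# lifetimes, scaling, helpers


def test_lifetime_fit_rejects_non_multiples():
    with pytest.raises(ValueError):
        pl.fit_lifetime_distribution([0.25, 0.3], 0.25)


def test_size_duration_scaling_exact_laws():
    class Cat:
        def __init__(self, t, s):
            self.lifetimes = t
            self.sizes_lambda = s

    t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
    sc = pl.size_duration_scaling(Cat(t, t ** 2))
    assert sc.inv_c_slope == pytest.approx(2.0, abs=1e-12)
    assert sc.c_scaling == pytest.approx(0.5, abs=1e-12)
    sc1 = pl.size_duration_scaling(Cat(t, t.copy()))
    assert sc1.c_scaling == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        pl.size_duration_scaling(Cat(np.full(5, 2.0), t))


def test_dequantize_counts_bounded_jitter(rng):
    v = rng.integers(1, 50, size=1000).astype(float)
    d = pl.dequantize_counts(v, seed=5)
    assert np.all(np.abs(d - v) <= 0.5)
    assert np.round(d).tolist() == v.tolist()


def test_select_s_min_recovers_tail_exponent(rng):
    # contaminate a clean power-law tail with off-law small events
    tail = pl.sample_truncated_powerlaw(-1.5, 10.0, 1000.0, 5000, rng)
    bulk = rng.uniform(1.0, 10.0, 5000)
    fit = pl.fit_powerlaw_ks(np.concatenate([tail, bulk]), select_s_min=True,
                             min_tail_frac=0.2)
    assert fit.s_min >= 5.0
    assert fit.alpha == pytest.approx(-1.5, abs=0.1)
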
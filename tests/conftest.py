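"""Shared synthetic fixtures.

The expensive simulations are session-scoped: one long critical
branching run at generation-per-frame resolution (cascade statistics),
and one short dense run pushed through the full calcium forward/inverse
chain (threshold scan, size-measure consistency).
"""

import numpy as np
import pytest

from avkit.avalanches import detect_clusters
from avkit.calcium import DeconvParams, deconvolve_set, lowpass_gaussian
from avkit.simulate import (ForwardModelParams, SimConfig,
                            raster_to_traces, simulate_branching_raster)

CRITICAL_CFG = SimConfig(n_units=64, n_bins=1_800_000, dt_gen=0.25,
                         sigma_target=1.0, drive_rate=5e-5, fan_out=8,
                         seed=2024)

SUBCRITICAL_CFG = SimConfig(n_units=64, n_bins=400_000, dt_gen=0.25,
                            sigma_target=0.5, drive_rate=2e-4, fan_out=8,
                            seed=2024)


@pytest.fixture(scope="session")
def critical_raster():
    """σ = 1 branching raster with ≥ 5,000 well-separated cascades."""
    return simulate_branching_raster(CRITICAL_CFG)


@pytest.fixture(scope="session")
def critical_catalog(critical_raster):
    return detect_clusters(critical_raster.to_rate(), 0.5)


@pytest.fixture(scope="session")
def subcritical_catalog():
    return detect_clusters(
        simulate_branching_raster(SUBCRITICAL_CFG).to_rate(), 0.5)


@pytest.fixture(scope="session")
def dense_chain():
    """Dense critical raster run through the calcium forward/inverse chain.

    40 units at 80% active-bin occupancy, rendered to ΔR/R with the
    default forward model and deconvolved back — an in vivo-like λ raster
    with continuous values.
    """
    cfg = SimConfig(n_units=40, n_bins=3000, dt_gen=0.25, sigma_target=1.0,
                    drive_rate=8e-3, fan_out=8, seed=21)
    spikes = simulate_branching_raster(cfg)
    traces = raster_to_traces(spikes, ForwardModelParams(), 0.25, seed=22)
    smooth = traces.copy_with(ratio=lowpass_gaussian(traces.ratio, traces.dt))
    raster = deconvolve_set(smooth, DeconvParams())
    return {"spikes": spikes, "traces": traces, "raster": raster}


@pytest.fixture
def rng():
    return np.random.default_rng(123)
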
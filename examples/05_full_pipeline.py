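"""End-to-end: synthetic traces through the whole analysis pipeline.

A dense critical raster is rendered into noisy ΔR/R traces, then the
pipeline deconvolves, filters ROIs, scans the event threshold, detects
avalanches by both bin concatenation and population thresholding, fits
the competing size models, and runs the shuffle control — writing every
product plus a machine-readable summary.
"""

import json

from avkit import ForwardModelParams, SimConfig, simulate_branching_raster
from avkit.pipeline import PipelineConfig, run_pipeline
from avkit.simulate import raster_to_traces

cfg = SimConfig(n_units=40, n_bins=3000, dt_gen=0.25, sigma_target=1.0,
                drive_rate=8e-3, fan_out=8, seed=21)
spikes = simulate_branching_raster(cfg)
traces = raster_to_traces(spikes, ForwardModelParams(), dt_target=0.25,
                          seed=22)

summary = run_pipeline(PipelineConfig(outdir="pipeline_out", seed=7,
                                      min_rate=0.0), traces)
print(json.dumps({k: summary[k] for k in
                  ("n_rois", "lam_thr", "n_clusters", "sigma",
                   "size_fit", "shuffle_control")}, indent=2))

# lam_thr is the cluster-rate-maximising threshold; size_fit reports the
# truncated power-law exponent and LLR verdict for the detected cascade
# sizes. The shuffle control destroys the power-law preference: on this
# short recording the verdict drops to undecided/exponential (long
# recordings flip it decisively, see example 04).
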
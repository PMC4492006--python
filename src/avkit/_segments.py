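"""Run-length utilities for boolean time-bin masks."""

from __future__ import annotations

import numpy as np


def find_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (starts, lengths) of maximal runs of True in a 1-D boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1:
        raise ValueError("mask must be 1-D")
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return starts, ends - starts


def interior_runs(starts: np.ndarray, lengths: np.ndarray,
                  n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Drop runs that touch either edge of the recording (censored runs)."""
    keep = (starts > 0) & (starts + lengths < n_bins)
    return starts[keep], lengths[keep]
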
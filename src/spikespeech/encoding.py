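"""Time-to-first-spike encoding of normalized MFSC maps.

Each input neuron (one per time-frequency bin) emits at most one spike per
sample; its latency carries the bin's intensity — the higher the intensity,
the earlier the spike.  Zero-intensity bins stay silent.  Only the order of
spikes matters downstream (the STDP rule compares timings, not intervals),
so the number of encoding steps trades temporal resolution against
simulation cost.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SILENT", "DEFAULT_N_STEPS", "encode_first_spike", "raster_to_frames"]

#: Marker for a neuron that never fires during the encoding window.
SILENT = -1

#: Default encoding-window length in simulation steps.
DEFAULT_N_STEPS = 30


def encode_first_spike(norm_map: np.ndarray, n_steps: int = DEFAULT_N_STEPS) -> np.ndarray:
    """Convert a [0, 1] intensity map into a latency raster.

    Spike time is ``round((1 - intensity) * (n_steps - 1))``: intensity 1
    fires at step 0, intensities near 0 fire at the last step, and exact
    zeros are SILENT.  Monotone: higher intensity never fires later.

    Returns
    -------
    ndarray of int, same shape as ``norm_map``
        Spike step in [0, n_steps - 1], or SILENT (-1).
    """
    m = np.asarray(norm_map, dtype=float)
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    if m.min() < 0.0 or m.max() > 1.0:
        raise ValueError("intensities outside [0, 1]; normalize the map first")
    raster = np.rint((1.0 - m) * (n_steps - 1)).astype(int)
    raster[m == 0.0] = SILENT
    return raster


def raster_to_frames(raster: np.ndarray, n_steps: int = DEFAULT_N_STEPS) -> np.ndarray:
    """Replay a latency raster as a clock-driven sequence of binary frames.

    Frame ``t`` has a 1 exactly where ``raster == t``; summed over the
    window, each neuron contributes at most one spike.

    Returns
    -------
    ndarray of uint8, shape (n_steps, *raster.shape)
    """
    r = np.asarray(raster)
    if r.max(initial=SILENT) >= n_steps:
        raise ValueError("raster contains spike times beyond the encoding window")
    frames = np.zeros((n_steps,) + r.shape, dtype=np.uint8)
    for t in range(n_steps):
        frames[t] = r == t
    return frames
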
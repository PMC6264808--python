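"""Synthetic spectro-temporal datasets with position-locked local features.

Spoken words carry features that are local in time — a prefix and a suffix
occupy different positions and sound different.  The generator emulates
exactly that structure directly in MFSC space: each class is a template
map whose temporal segments each contain one smooth band-limited ridge (a
formant-like blob) at a class-and-segment-specific frequency.  Samples
add Gaussian amplitude noise and a small integer time jitter per segment.

By default the classes share one inventory of spectral ridges and differ
only in the temporal *arrangement* of those ridges (a cyclic
pattern-to-segment assignment).  Summed over time the classes are then
indistinguishable, so a network that pools away position (global weight
sharing) is confounded while locally shared weights separate the classes
— the property the local-vs-global comparison tests.

Audio synthesis is deliberately skipped: the network consumes MFSC maps,
and acoustic realism is orthogonal to every mechanism under test.  A
sine-sweep helper is provided for end-to-end front-end checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mfsc import AudioClip

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "make_templates",
    "sample_dataset",
    "nearest_template_accuracy",
    "sine_sweep_clip",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic dataset generator.

    ``n_segments`` temporal segments each carry one pattern;
    ``pattern_bandwidth`` is the ridge's frequency extent in bands
    (Gaussian full width); ``time_jitter`` is the maximum per-segment
    integer frame shift.  ``distinct_segments`` restricts class identity
    to the listed segments (classes share the remaining segments); by
    default classes differ in every segment via the cyclic assignment.
    """

    n_classes: int = 4
    n_per_class: int = 60
    n_frames: int = 41
    n_bands: int = 40
    n_segments: int = 4
    pattern_bandwidth: int = 5
    amplitude_noise_sd: float = 0.1
    time_jitter: int = 1
    seed: int = 0
    distinct_segments: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.pattern_bandwidth > self.n_bands:
            raise ValueError("pattern_bandwidth exceeds the number of bands")
        if self.n_segments * self.segment_len > self.n_frames:
            raise ValueError("segments do not fit the frame axis")
        if self.time_jitter > self.segment_len // 2:
            raise ValueError("jitter too large: patterns would leave their segment")

    @property
    def segment_len(self) -> int:
        return self.n_frames // self.n_segments


@dataclass
class SynthDataset:
    """Generated maps with labels and the ground-truth templates.

    ``templates`` (n_classes x n_frames x n_bands) are the noise-free
    class maps — the oracle for receptive-field recovery checks.
    """

    maps: np.ndarray
    labels: np.ndarray
    templates: np.ndarray
    spec: SynthSpec = field(repr=False, default=None)


def _pattern_slot(spec: SynthSpec, class_id: int, segment: int) -> int:
    """Which spectral ridge class ``class_id`` places in ``segment``."""
    if spec.distinct_segments is None or segment in spec.distinct_segments:
        return (class_id + segment) % spec.n_classes
    return segment % spec.n_classes  # shared background pattern


def _segment_patch(spec: SynthSpec, slot: int) -> np.ndarray:
    """The ridge patch for one slot: (segment_len, n_bands), peak 1."""
    L = spec.segment_len
    margin = spec.time_jitter
    centers = (np.arange(spec.n_classes) + 0.5) * spec.n_bands / spec.n_classes
    bands = np.arange(spec.n_bands)
    freq = np.exp(-0.5 * ((bands - centers[slot]) / (spec.pattern_bandwidth / 2.0)) ** 2)
    envelope = np.zeros(L)
    core = L - 2 * margin
    envelope[margin : margin + core] = np.hanning(core + 2)[1:-1]
    return envelope[:, None] * freq[None, :]


def make_templates(spec: SynthSpec) -> np.ndarray:
    """Noise-free class templates, deterministic under the spec.

    Each class is its per-segment ridges laid onto a zero background;
    distinct classes differ in at least one segment by construction.
    """
    L = spec.segment_len
    templates = np.zeros((spec.n_classes, spec.n_frames, spec.n_bands))
    for c in range(spec.n_classes):
        for g in range(spec.n_segments):
            patch = _segment_patch(spec, _pattern_slot(spec, c, g))
            templates[c, g * L : (g + 1) * L, :] = patch
    return templates


def sample_dataset(spec: SynthSpec) -> SynthDataset:
    """Draw a balanced labeled dataset around the class templates.

    Each map places the class's segment patterns at an integer time shift
    drawn uniformly from [-time_jitter, +time_jitter] per segment, adds
    i.i.d. Gaussian amplitude noise, and clips to >= 0.
    """
    rng = np.random.default_rng(spec.seed)
    templates = make_templates(spec)
    L = spec.segment_len
    n_total = spec.n_classes * spec.n_per_class
    maps = np.zeros((n_total, spec.n_frames, spec.n_bands))
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    for i, c in enumerate(labels):
        for g in range(spec.n_segments):
            patch = _segment_patch(spec, _pattern_slot(spec, int(c), g))
            shift = int(rng.integers(-spec.time_jitter, spec.time_jitter + 1))
            start = g * L + shift
            lo, hi = max(start, 0), min(start + L, spec.n_frames)
            maps[i, lo:hi, :] += patch[lo - start : hi - start, :]
        maps[i] += rng.normal(0.0, spec.amplitude_noise_sd, size=maps[i].shape)
    np.clip(maps, 0.0, None, out=maps)
    return SynthDataset(maps=maps, labels=labels, templates=templates, spec=spec)


def nearest_template_accuracy(dataset: SynthDataset) -> float:
    """Accuracy of nearest-template (Euclidean) classification of raw maps.

    Calibration check that the task is learnable but not degenerate.
    """
    flat = dataset.maps.reshape(len(dataset.maps), -1)
    tmpl = dataset.templates.reshape(len(dataset.templates), -1)
    d2 = ((flat[:, None, :] - tmpl[None, :, :]) ** 2).sum(axis=2)
    return float(np.mean(np.argmin(d2, axis=1) == dataset.labels))


def sine_sweep_clip(
    f0: float,
    f1: float,
    duration: float,
    sample_rate: float = 8000.0,
    label=None,
) -> AudioClip:
    """A linear sine sweep, for end-to-end front-end tests."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * duration))
    return AudioClip(samples=np.sin(phase), sample_rate=sample_rate, label=label)
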
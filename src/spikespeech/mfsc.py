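"""Mel-frequency spectral coefficient (MFSC) front end.

Variable-length utterances are converted into fixed-size time x frequency
maps of log mel-filterbank energies.  MFSC is MFCC without the final DCT:
power spectrum -> mel-scaled triangular filterbank -> logarithm.  Skipping
the DCT preserves spectral locality, which the convolutional layer needs.

Time-warp invariance of the output shape is obtained by adapting the
analysis window to the clip: the hop is ``(len - win) / (n_frames - 1)``
with ``win = 2 * hop`` (50% overlap), so every clip yields exactly
``n_frames`` frames regardless of duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "read_wav",
    "mel_filterbank",
    "compute_mfsc",
    "normalize_map",
    "DEFAULT_N_FRAMES",
    "DEFAULT_N_BANDS",
]

logger = logging.getLogger("spikespeech")

#: Default map geometry: 41 frames x 40 mel bands (input dimension 1640).
DEFAULT_N_FRAMES = 41
DEFAULT_N_BANDS = 40

#: Energy floor applied before the log so silent bins stay finite.
DEFAULT_ENERGY_FLOOR = 1e-10


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and an optional class label.

    Attributes
    ----------
    samples
        1-D float array of amplitudes (dimensionless).
    sample_rate
        Sampling frequency in Hz; must be positive.
    label
        Optional class identifier carried along for supervised readouts.
    """

    samples: np.ndarray
    sample_rate: float
    label: object | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size < 1:
            raise ValueError("AudioClip needs at least one sample")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.sample_rate


def read_wav(path, label=None) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    16-bit integer PCM is rescaled to [-1, 1]; multi-channel audio is
    averaged down to mono.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=data.astype(float), sample_rate=float(rate), label=label)


def _hz_to_mel(f):
    # HTK mel scale
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, n_fft: int, sample_rate: float) -> np.ndarray:
    """Triangular mel filterbank on the HTK scale, covering 0 to Nyquist.

    Returns
    -------
    ndarray of shape (n_bands, n_fft // 2 + 1)
        Each row is one triangular filter over the positive-frequency bins.
    """
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(nyquist), n_bands + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.linspace(0.0, nyquist, n_fft // 2 + 1)

    fbank = np.zeros((n_bands, bin_freqs.size))
    for b in range(n_bands):
        lo, mid, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - mid, 1e-12)
        fbank[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fbank


def compute_mfsc(
    clip: AudioClip,
    n_frames: int = DEFAULT_N_FRAMES,
    n_bands: int = DEFAULT_N_BANDS,
    energy_floor: float | None = DEFAULT_ENERGY_FLOOR,
) -> np.ndarray:
    """Compute a fixed-size MFSC map from a waveform of any duration.

    The analysis window length is chosen per clip so that exactly
    ``n_frames`` half-overlapping frames tile the signal; the pipeline per
    frame is Hann window -> power spectrum -> mel triangular filterbank ->
    natural log (no DCT).

    Parameters
    ----------
    clip
        Input waveform.
    n_frames
        Number of time frames M of the output map.
    n_bands
        Number of mel bands N of the output map.
    energy_floor
        Lower clamp on filterbank energies before the log.  ``None``
        disables the floor, in which case zero-energy frames raise.

    Returns
    -------
    ndarray of shape (n_frames, n_bands)
        Log mel energies; finite everywhere.
    """
    x = clip.samples
    if n_frames < 1 or n_bands < 1:
        raise ValueError("n_frames and n_bands must be >= 1")
    if x.size < n_frames:
        raise ValueError(
            f"clip too short: {x.size} samples cannot yield {n_frames} analysis windows"
        )

    # hop = (len - win) / (n_frames - 1) with win = 2*hop  =>  hop = len/(n_frames+1)
    hop = x.size / (n_frames + 1)
    win = max(int(round(2 * hop)), 2)
    n_fft = 1 << (win - 1).bit_length()
    window = np.hanning(win)
    fbank = mel_filterbank(n_bands, n_fft, clip.sample_rate)

    out = np.empty((n_frames, n_bands))
    for i in range(n_frames):
        start = min(int(round(i * hop)), x.size - win) if x.size >= win else 0
        frame = x[start : start + win]
        if frame.size < win:  # very short clips: zero-pad the tail
            frame = np.pad(frame, (0, win - frame.size))
        spec = np.abs(np.fft.rfft(frame * window, n=n_fft)) ** 2
        energies = fbank @ spec
        if energy_floor is None:
            if np.any(energies <= 0):
                raise ValueError(
                    "zero filterbank energy encountered and no energy floor configured"
                )
        else:
            energies = np.maximum(energies, energy_floor)
        out[i] = np.log(energies)
    return out


def normalize_map(mfsc_map: np.ndarray, floor_quantile: float = 0.1) -> np.ndarray:
    """Min–max rescale one MFSC map to [0, 1], flooring the quietest entries.

    Entries at or below the ``floor_quantile`` quantile are set to 0 and will
    be treated as silent by the first-spike encoder.  Normalization is per
    sample: the latency code needs a bounded intensity scale and each
    utterance supplies its own dynamic range.

    A constant map (max == min) normalizes to all zeros with a warning.
    """
    m = np.asarray(mfsc_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("MFSC map contains non-finite values")
    if not 0.0 <= floor_quantile < 1.0:
        raise ValueError(f"floor_quantile must be in [0, 1), got {floor_quantile}")

    lo, hi = m.min(), m.max()
    if hi == lo:
        warnings.warn("constant MFSC map normalizes to all zeros", stacklevel=2)
        return np.zeros_like(m)
    scaled = (m - lo) / (hi - lo)
    if floor_quantile > 0.0:
        scaled[m <= np.quantile(m, floor_quantile)] = 0.0
    return scaled
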
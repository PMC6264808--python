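"""Convolutional spiking network: IF dynamics, local weight sharing, STDP.

The convolutional layer is a bank of integrate-and-fire neurons.  A neuron
at (feature map m, temporal position p) sees the input patch of
``win_len`` consecutive frames starting at ``p * stride``, spanning all
frequency bands.  Its membrane potential follows

    V(t) = V(t-1) + W^T . S(t-1)

where S is the binary spike frame of the previous step.  On reaching
threshold the neuron fires once, is reset and frozen for the rest of the
sample, and laterally inhibits all other maps at the same position — at
most one spike per position per sample.

Weights are shared *locally*: the position axis is divided into
``n_sections`` non-overlapping sections, and all positions of one map
within a section use the same ``win_len x n_bands`` weight matrix.  With
``n_sections = 1`` this reduces to conventional global weight sharing.
Local sharing lets different time periods of a word (prefix vs suffix)
learn separate spectro-temporal features.

Learning is unsupervised, with a simplified soft-bounded STDP rule that
ignores exact time differences (the latency code compresses each sample
into a short window, so only spike order is meaningful):

    dw = +a_plus  * w * (1 - w)   if the input spiked before the neuron,
    dw = -a_minus * w * (1 - w)   otherwise (late spike or no spike).

The w(1-w) factor keeps every weight in [0, 1].  An STDP competition
(earliest-firing winners, with neighborhood and cross-map blocking) makes
maps specialize on distinct features.

The pooling layer is fixed: non-firing accumulators with unit weights, one
per (map, section); their final potentials equal the spike counts of their
section and are the network's output representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import SILENT

__all__ = [
    "ConvConfig",
    "StdpParams",
    "ForwardResult",
    "TrainResult",
    "init_weights",
    "forward_sample",
    "select_stdp_winners",
    "stdp_update",
    "train",
    "pool_dataset",
]


@dataclass(frozen=True)
class ConvConfig:
    """Geometry and neuron parameters of the convolutional layer.

    Defaults are the spoken-digit configuration: 50 maps over a 41 x 40
    input, 6-frame windows with stride 1 (36 positions), 9 sections of
    length 4, firing threshold 23, weights initialized N(0.8, 0.05^2).
    """

    n_maps: int = 50
    win_len: int = 6
    stride: int = 1
    n_sections: int = 9
    v_thresh: float = 23.0
    v_rest: float = 0.0
    init_mean: float = 0.8
    init_sd: float = 0.05
    n_frames: int = 41
    n_bands: int = 40

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.v_thresh <= self.v_rest:
            raise ValueError("v_thresh must exceed v_rest")
        if (self.n_frames - self.win_len) % self.stride:
            raise ValueError("window/stride do not tile the input frames")
        if self.n_positions % self.n_sections:
            raise ValueError(
                f"{self.n_positions} conv positions not divisible by "
                f"{self.n_sections} sections"
            )

    @property
    def n_positions(self) -> int:
        """Number of temporal positions P of each feature map."""
        return (self.n_frames - self.win_len) // self.stride + 1

    @property
    def section_len(self) -> int:
        """Positions per section."""
        return self.n_positions // self.n_sections

    @property
    def output_dim(self) -> int:
        """Dimension of the pooled output, n_maps * n_sections."""
        return self.n_maps * self.n_sections

    def section_of(self, positions) -> np.ndarray:
        """Section index for each position."""
        return np.asarray(positions) // self.section_len


@dataclass(frozen=True)
class StdpParams:
    """STDP learning rates and competition/stopping controls.

    ``a_plus``/``a_minus`` are the potentiation and depression rates.
    ``neighborhood_radius`` is the half-width (in positions) of the
    same-map STDP blocking zone around a winner; the default equals the
    section length so a section's shared weights receive at most one
    update per sample.  Training stops when the accumulated elementwise
    weight drift over the last ``stop_window`` samples falls below
    ``stop_delta``, or after ``max_epochs`` passes over the data.  The
    default ``stop_window`` of None means one epoch: training ceases when
    a full pass over the data moves no weight by more than ``stop_delta``
    — at soft-bounded rates of a few 1e-3 per event this is the scale on
    which "the weights have stopped changing" is meaningful.
    """

    a_plus: float = 0.004
    a_minus: float = 0.003
    stop_delta: float = 0.01
    neighborhood_radius: int = 4
    stop_window: int | None = None
    max_epochs: int = 20

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("learning rates must be non-negative")
        if self.stop_delta <= 0:
            raise ValueError("stop_delta must be positive")


@dataclass
class ForwardResult:
    """Spiking activity of one sample pass.

    ``fired_at`` holds each conv neuron's fire step on the membrane-update
    clock (input spikes at step t are delivered at update step t+1), or
    SILENT.  ``fire_potential`` is the membrane potential at the moment of
    crossing (0 for silent neurons).  ``pooling`` counts spikes per
    (map, section) — the final potentials of the pooling neurons.
    """

    fired_at: np.ndarray
    fire_potential: np.ndarray
    pooling: np.ndarray


@dataclass
class TrainResult:
    bank: np.ndarray
    delta_history: list = field(default_factory=list)
    drift_history: list = field(default_factory=list)
    n_samples_seen: int = 0
    converged: bool = False


def init_weights(cfg: ConvConfig, seed) -> np.ndarray:
    """Gaussian-initialized weight bank, clipped to [0, 1].

    Returns an array of shape (n_maps, n_sections, win_len, n_bands):
    one shared weight matrix per (feature map, section).
    """
    rng = np.random.default_rng(seed)
    shape = (cfg.n_maps, cfg.n_sections, cfg.win_len, cfg.n_bands)
    return np.clip(rng.normal(cfg.init_mean, cfg.init_sd, size=shape), 0.0, 1.0)


def _check_bank(bank: np.ndarray, cfg: ConvConfig) -> np.ndarray:
    bank = np.asarray(bank, dtype=float)
    expect = (cfg.n_maps, cfg.n_sections, cfg.win_len, cfg.n_bands)
    if bank.shape != expect:
        raise ValueError(f"weight bank shape {bank.shape} != expected {expect}")
    return bank


def _patch_times(raster: np.ndarray, cfg: ConvConfig) -> np.ndarray:
    """Input spike times per conv position: shape (P, win_len, n_bands)."""
    return sliding_window_view(raster, (cfg.win_len, cfg.n_bands))[:: cfg.stride, 0]


def forward_sample(raster: np.ndarray, bank: np.ndarray, cfg: ConvConfig) -> ForwardResult:
    """Clock-driven pass of one latency raster through conv + pooling.

    Spikes at input step t are integrated at update step t+1.  When one or
    more maps cross threshold at a position in the same step, the one with
    the highest potential (ties: lowest map index) fires; the position is
    then inhibited — all maps there are frozen for the rest of the sample.
    All membrane state is per-call, so the between-samples reset to
    ``v_rest`` is automatic.
    """
    raster = np.asarray(raster)
    if raster.shape != (cfg.n_frames, cfg.n_bands):
        raise ValueError(
            f"raster shape {raster.shape} != ({cfg.n_frames}, {cfg.n_bands})"
        )
    bank = _check_bank(bank, cfg)

    P = cfg.n_positions
    pst = _patch_times(raster, cfg)  # (P, win, N)
    sections = cfg.section_of(np.arange(P))

    last_spike = int(raster.max(initial=SILENT))
    fired_at = np.full((cfg.n_maps, P), SILENT, dtype=int)
    fire_pot = np.zeros((cfg.n_maps, P))
    if last_spike >= 0:
        # increments[p, s, m]: drive delivered to (m, p) at update step s+1,
        # as a batched matmul of per-position spike one-hots with the
        # position's shared weights
        flat_pst = pst.reshape(P, -1)
        onehot = (
            flat_pst[:, None, :] == np.arange(last_spike + 1)[None, :, None]
        ).astype(float)
        w_pos = bank[:, sections].reshape(cfg.n_maps, P, -1).transpose(1, 2, 0)
        increments = onehot @ w_pos  # (P, S, n_maps)

        v = np.full((cfg.n_maps, P), cfg.v_rest)
        alive = np.ones((cfg.n_maps, P), dtype=bool)
        for s in range(last_spike + 1):
            v += increments[:, s, :].T * alive
            crossed = alive & (v >= cfg.v_thresh)
            if not crossed.any():
                continue
            for p in np.nonzero(crossed.any(axis=0))[0]:
                maps = np.nonzero(crossed[:, p])[0]
                winner = maps[int(np.argmax(v[maps, p]))]
                fired_at[winner, p] = s + 1
                fire_pot[winner, p] = v[winner, p]
                v[winner, p] = cfg.v_rest
                alive[:, p] = False  # lateral inhibition freezes the position

    spiked = fired_at != SILENT
    pooling = np.zeros((cfg.n_maps, cfg.n_sections), dtype=int)
    np.add.at(pooling, (np.arange(cfg.n_maps)[:, None], sections[None, :]), spiked)
    return ForwardResult(fired_at=fired_at, fire_potential=fire_pot, pooling=pooling)


def select_stdp_winners(
    fired_at: np.ndarray,
    fire_potential: np.ndarray,
    params: StdpParams,
    cfg: ConvConfig,
) -> list[tuple[int, int, int]]:
    """Greedy STDP competition over the spiking conv neurons.

    Candidates are visited earliest-first (ties: highest crossing
    potential, then lowest map, then lowest position).  An accepted winner
    blocks STDP at positions within ``neighborhood_radius`` in its own map
    and at its exact position in every map, until the next sample.
    """
    n_maps, P = fired_at.shape
    ms, ps = np.nonzero(fired_at != SILENT)
    if ms.size == 0:
        return []
    order = sorted(
        range(ms.size),
        key=lambda i: (fired_at[ms[i], ps[i]], -fire_potential[ms[i], ps[i]], ms[i], ps[i]),
    )
    pos_blocked = np.zeros(P, dtype=bool)
    map_pos_blocked = np.zeros((n_maps, P), dtype=bool)
    winners: list[tuple[int, int, int]] = []
    r = params.neighborhood_radius
    for i in order:
        m, p = int(ms[i]), int(ps[i])
        if pos_blocked[p] or map_pos_blocked[m, p]:
            continue
        winners.append((m, p, int(fired_at[m, p])))
        pos_blocked[p] = True
        map_pos_blocked[m, max(0, p - r) : p + r + 1] = True
    return winners


def stdp_update(
    bank: np.ndarray,
    raster: np.ndarray,
    winners: list[tuple[int, int, int]],
    params: StdpParams,
    cfg: ConvConfig,
) -> tuple[np.ndarray, float]:
    """Apply the soft-bounded STDP rule for each winner's shared weights.

    For a winner firing at update step t_i, every synapse of its
    (map, section) matrix is potentiated if its input neuron spiked before
    t_i and depressed otherwise — including silent inputs, which carry
    evidence of feature absence.  Winners in different sections/maps touch
    disjoint matrices; updates are applied sequentially.

    Returns the updated bank and the maximum |dw| applied (0 if no
    winners).
    """
    bank = _check_bank(bank, cfg).copy()
    raster = np.asarray(raster)
    max_delta = 0.0
    for m, p, t_i in winners:
        if t_i == SILENT:
            raise ValueError(f"winner ({m}, {p}) did not fire")
        s = int(cfg.section_of(p))
        start = p * cfg.stride
        pst = raster[start : start + cfg.win_len, :]
        causal = (pst != SILENT) & (pst < t_i)
        w = bank[m, s]
        dw = np.where(causal, params.a_plus, -params.a_minus) * w * (1.0 - w)
        bank[m, s] = w + dw
        max_delta = max(max_delta, float(np.abs(dw).max(initial=0.0)))
    return bank, max_delta


def train(
    dataset,
    cfg: ConvConfig,
    params: StdpParams,
    seed,
    bank: np.ndarray | None = None,
) -> TrainResult:
    """Unsupervised STDP training over a sequence of latency rasters.

    Each pass: forward simulate, run the STDP competition, update the
    winners' shared weights.  Labels are never consulted.  Sample order is
    reshuffled every epoch under ``seed``.  Training stops when the
    accumulated elementwise weight drift over the last ``stop_window``
    samples (default: one epoch) drops below ``stop_delta`` — the weights
    have effectively stopped moving — or at the ``max_epochs`` cap.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    if bank is None:
        bank = init_weights(cfg, rng.integers(2**31))
    else:
        bank = _check_bank(bank, cfg).copy()

    window = params.stop_window if params.stop_window is not None else len(dataset)
    result = TrainResult(bank=bank)
    snapshot = bank.copy()
    since_snapshot = 0
    for _epoch in range(params.max_epochs):
        order = rng.permutation(len(dataset))
        for idx in order:
            raster = dataset[idx]
            fw = forward_sample(raster, result.bank, cfg)
            winners = select_stdp_winners(fw.fired_at, fw.fire_potential, params, cfg)
            result.bank, delta = stdp_update(result.bank, raster, winners, params, cfg)
            result.delta_history.append(delta)
            result.n_samples_seen += 1
            since_snapshot += 1
            if since_snapshot >= window:
                drift = float(np.abs(result.bank - snapshot).max())
                result.drift_history.append(drift)
                snapshot = result.bank.copy()
                since_snapshot = 0
                if drift < params.stop_delta:
                    result.converged = True
                    return result
    return result


def pool_dataset(dataset, bank: np.ndarray, cfg: ConvConfig) -> np.ndarray:
    """Run the frozen network over a dataset; stack flattened pooling vectors.

    Plasticity is off by construction (forward passes never modify the
    bank).  Returns an int matrix of shape (n_samples, n_maps * n_sections).
    """
    bank = _check_bank(bank, cfg)
    rows = [forward_sample(r, bank, cfg).pooling.ravel() for r in dataset]
    return np.asarray(rows, dtype=int)
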
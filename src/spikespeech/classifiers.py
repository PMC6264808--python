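"""Readouts over pooled spike counts: linear SVM and tempotron.

The network's output is a vector of pooling-neuron potentials (spike
counts per feature map x section).  Two linear readouts are provided:

* :class:`LinearReadout` — a conventional linear decision function over
  the raw count vectors, delegating to a linear SVM.
* the tempotron — a spike-based linear classifier.  Count vectors are
  first re-encoded as input spike latencies (higher count, earlier
  spike); each class neuron sums PSP kernels of its afferents' spikes and
  the class whose neuron reaches the highest peak potential wins.  During
  training only the two error cases update weights: a target neuron whose
  peak fails to reach threshold is potentiated, a non-target neuron whose
  peak exceeds threshold is depressed, each afferent in proportion to its
  PSP at the peak time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .encoding import SILENT

__all__ = [
    "TempotronModel",
    "counts_to_latencies",
    "psp_kernel",
    "tempotron_potential",
    "tempotron_train",
    "tempotron_predict",
    "LinearReadout",
]

#: Default number of steps when re-encoding counts as latencies.
DEFAULT_READOUT_STEPS = 30


def counts_to_latencies(x: np.ndarray, n_steps: int = DEFAULT_READOUT_STEPS) -> np.ndarray:
    """First-spike encode a non-negative count vector.

    Counts are min–max normalized per sample and mapped to latencies with
    the same rule as the input encoder: the largest count spikes at step
    0, smaller counts later.  Zero counts are SILENT.  A uniform nonzero
    vector is treated as all-maximal (every afferent spikes at step 0); an
    all-zero vector is all-SILENT with a warning.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    lat = np.full(x.shape, SILENT, dtype=int)
    nz = x > 0
    if not nz.any():
        warnings.warn("all-zero count vector encodes as all-SILENT", stacklevel=2)
        return lat
    lo, hi = x.min(), x.max()
    if hi == lo:
        lat[nz] = 0
        return lat
    intensity = (x - lo) / (hi - lo)
    lat[nz] = np.rint((1.0 - intensity[nz]) * (n_steps - 1)).astype(int)
    return lat


@dataclass
class TempotronModel:
    """One-vs-all tempotron: per-class weights plus PSP-kernel parameters.

    The PSP kernel is K(dt) = v0 * (exp(-dt/tau_m) - exp(-dt/tau_s)) for
    dt >= 0, with v0 fixed so the kernel peaks at 1.  ``t_window`` is the
    decision window in steps; it should extend past the last possible
    input spike by a few membrane time constants so late spikes can still
    drive a peak.
    """

    weights: np.ndarray
    tau_m: float = 15.0
    tau_s: float = 15.0 / 4.0
    threshold: float = 1.0
    lr: float = 0.05
    t_window: int = 75
    classes_: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("need tau_m > tau_s > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def v0(self) -> float:
        """Kernel normalization so max_t K(t) = 1."""
        t_peak = (self.tau_m * self.tau_s / (self.tau_m - self.tau_s)) * np.log(
            self.tau_m / self.tau_s
        )
        return 1.0 / (np.exp(-t_peak / self.tau_m) - np.exp(-t_peak / self.tau_s))

    @classmethod
    def init(cls, n_classes: int, n_afferents: int, seed=0, **kwargs) -> "TempotronModel":
        rng = np.random.default_rng(seed)
        w = rng.normal(0.0, 1e-3, size=(n_classes, n_afferents))
        return cls(weights=w, **kwargs)


def psp_kernel(model: TempotronModel, dt) -> np.ndarray:
    """Normalized postsynaptic-potential kernel, zero for dt < 0."""
    dt = np.asarray(dt, dtype=float)
    out = model.v0 * (np.exp(-dt / model.tau_m) - np.exp(-dt / model.tau_s))
    return np.where(dt >= 0.0, out, 0.0)


def _psp_matrix(model: TempotronModel, latencies: np.ndarray) -> np.ndarray:
    """PSP of each afferent at each step of the window: (D, t_window)."""
    t = np.arange(model.t_window)
    dt = t[None, :] - latencies[:, None].astype(float)
    psp = psp_kernel(model, dt)
    psp[latencies == SILENT] = 0.0
    return psp


def tempotron_potential(model: TempotronModel, class_k: int, latencies: np.ndarray, t) -> np.ndarray:
    """Membrane potential of class neuron ``class_k`` at time(s) ``t``.

    Linear in the weights; zero before the first input spike.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dt = t[None, :] - latencies[:, None].astype(float)
    psp = psp_kernel(model, dt)
    psp[latencies == SILENT] = 0.0
    v = model.weights[class_k] @ psp
    return v if v.size > 1 else float(v[0])


def tempotron_train(
    X: np.ndarray,
    y: np.ndarray,
    model: TempotronModel,
    epochs: int = 100,
    seed=0,
    n_steps: int = DEFAULT_READOUT_STEPS,
) -> TempotronModel:
    """One-vs-all tempotron learning over a count dataset.

    Per sample and class neuron, the potential peak over the window is
    located; weights move only on the two error cases (missed target
    fire / spurious non-target fire), each afferent by ``lr * K(t* - t_i)``
    — so SILENT afferents are never updated.  Sample order is reshuffled
    every epoch under ``seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if model.classes_ is None:
        model.classes_ = classes
    class_index = {c: k for k, c in enumerate(model.classes_)}
    rng = np.random.default_rng(seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lats = np.vstack([counts_to_latencies(row, n_steps) for row in X])
    # PSP traces depend only on the (fixed) input latencies — cache per sample
    psps = [_psp_matrix(model, lat) for lat in lats]
    for _ in range(epochs):
        order = rng.permutation(len(X))
        any_error = False
        for i in order:
            psp = psps[i]  # (D, T)
            v = model.weights @ psp  # (n_classes, T)
            t_star = np.argmax(v, axis=1)
            v_max = v[np.arange(v.shape[0]), t_star]
            target = class_index[y[i]]
            for k in range(v.shape[0]):
                if k == target and v_max[k] <= model.threshold:
                    model.weights[k] += model.lr * psp[:, t_star[k]]
                    any_error = True
                elif k != target and v_max[k] > model.threshold:
                    model.weights[k] -= model.lr * psp[:, t_star[k]]
                    any_error = True
        if not any_error:
            break
    return model


def tempotron_predict(
    model: TempotronModel, X: np.ndarray, n_steps: int = DEFAULT_READOUT_STEPS
) -> np.ndarray:
    """Argmax-of-peak decoding: the class whose neuron peaks highest wins.

    Ties resolve to the lowest class index.  Independent of the threshold.
    """
    X = np.atleast_2d(np.asarray(X))
    if model.classes_ is None:
        raise ValueError("model has no classes; train it first")
    preds = []
    for row in X:
        lat = counts_to_latencies(row, n_steps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            psp = _psp_matrix(model, lat)
        peaks = (model.weights @ psp).max(axis=1) if psp.any() else np.zeros(len(model.weights))
        preds.append(model.classes_[int(np.argmax(peaks))])
    return np.asarray(preds)


class LinearReadout:
    """Linear decision function over pooled counts (linear SVM reference).

    Any linear classifier satisfies the contract; this wrapper delegates
    to :class:`sklearn.svm.LinearSVC` with default regularization.
    """

    def __init__(self, **svm_kwargs):
        svm_kwargs.setdefault("dual", "auto")
        self._svm = LinearSVC(**svm_kwargs)

    def fit(self, X, y) -> "LinearReadout":
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes to fit a readout")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._svm.fit(np.asarray(X, dtype=float), y)
        return self

    def predict(self, X) -> np.ndarray:
        return self._svm.predict(np.atleast_2d(np.asarray(X, dtype=float)))
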
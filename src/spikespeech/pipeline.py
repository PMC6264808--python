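"""Three-stage evaluation protocol and experiment orchestration.

Stage 1 — the spiking network is trained by STDP on the training set with
labels withheld.  Stage 2 — plasticity off, the frozen network encodes
the training set and a readout is fitted on the pooled spike counts plus
labels.  Stage 3 — the frozen network encodes the test set and the
readout's predictions are scored.

Reports carry accuracy, a row-normalized confusion matrix, output
dimensionality and sparsity statistics, the weight-drift history of
training, and a manifest (config, seed, content hashes) so a run is fully
reproducible: same config + seed means a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from . import network
from .classifiers import LinearReadout, TempotronModel, tempotron_predict, tempotron_train
from .encoding import DEFAULT_N_STEPS, encode_first_spike
from .mfsc import normalize_map
from .network import ConvConfig, StdpParams
from .synth import SynthDataset, SynthSpec, sample_dataset

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "compare_sharing",
    "template_recovery",
]

logger = logging.getLogger("spikespeech")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs: sub-configs, readout choice, split.

    ``classifier`` is "svm", "tempotron", or "both".  The split is
    stratified by class at ``split_ratio`` train fraction (7:3 default).
    """

    conv: ConvConfig = field(default_factory=ConvConfig)
    stdp: StdpParams = field(default_factory=StdpParams)
    n_steps: int = DEFAULT_N_STEPS
    floor_quantile: float = 0.1
    classifier: str = "svm"
    tempotron_lr: float = 0.05
    tempotron_epochs: int = 100
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.classifier not in ("svm", "tempotron", "both"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _prepare_rasters(maps, cfg: ExperimentConfig) -> list[np.ndarray]:
    return [
        encode_first_spike(normalize_map(m, cfg.floor_quantile), cfg.n_steps)
        for m in maps
    ]


def run_experiment(
    cfg: ExperimentConfig,
    data: SynthDataset | tuple,
    split: tuple | None = None,
) -> dict:
    """Run the full three-stage protocol on labeled MFSC maps.

    ``data`` is a :class:`SynthDataset` or a ``(maps, labels)`` pair.
    ``split`` optionally fixes the (train_indices, test_indices) pair;
    by default a class-stratified split at ``split_ratio`` is drawn under
    the experiment seed.  Returns a JSON-serializable report.  Any stage
    failure is re-raised with a stage tag so pipeline errors are
    attributable.
    """
    if isinstance(data, SynthDataset):
        maps, labels = data.maps, data.labels
    else:
        maps, labels = data
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)

    stage = "prepare"
    try:
        rasters = _prepare_rasters(maps, cfg)
        if split is not None:
            idx_train, idx_test = np.asarray(split[0]), np.asarray(split[1])
        else:
            idx_train, idx_test = train_test_split(
                np.arange(len(labels)),
                train_size=cfg.split_ratio,
                stratify=labels,
                random_state=cfg.seed % (2**32),
                shuffle=True,
            )
        train_rasters = [rasters[i] for i in idx_train]
        test_rasters = [rasters[i] for i in idx_test]
        y_train, y_test = labels[idx_train], labels[idx_test]

        stage = "stdp-training"
        # stage 1: unsupervised — labels are not passed in
        result = network.train(train_rasters, cfg.conv, cfg.stdp, seed=cfg.seed)
        logger.info(
            "STDP training: %d samples, converged=%s, final drift=%s",
            result.n_samples_seen,
            result.converged,
            result.drift_history[-1] if result.drift_history else None,
        )

        stage = "pooling-and-fit"
        X_train = network.pool_dataset(train_rasters, result.bank, cfg.conv)
        X_test = network.pool_dataset(test_rasters, result.bank, cfg.conv)

        readouts = {}
        names = ("svm", "tempotron") if cfg.classifier == "both" else (cfg.classifier,)
        for name in names:
            if name == "svm":
                model = LinearReadout().fit(X_train, y_train)
                y_pred = model.predict(X_test)
            else:
                model = TempotronModel.init(
                    n_classes=len(np.unique(y_train)),
                    n_afferents=X_train.shape[1],
                    seed=cfg.seed,
                    lr=cfg.tempotron_lr,
                    t_window=cfg.n_steps + 45,
                )
                tempotron_train(
                    X_train, y_train, model, epochs=cfg.tempotron_epochs, seed=cfg.seed
                )
                y_pred = tempotron_predict(model, X_test)
            cm = confusion_matrix(y_test, y_pred).astype(float)
            cm /= np.maximum(cm.sum(axis=1, keepdims=True), 1e-12)
            readouts[name] = {
                "accuracy": float(np.mean(y_pred == y_test)),
                "confusion_matrix": cm.round(6).tolist(),
            }

        stage = "report"
        active = (X_test > 0).mean(axis=1)
        report = {
            "readouts": readouts,
            "accuracy": readouts[names[0]]["accuracy"],
            "output_dim": cfg.conv.output_dim,
            "input_dim": cfg.conv.n_frames * cfg.conv.n_bands,
            "dim_reduction_pct": 100.0
            * (1.0 - cfg.conv.output_dim / (cfg.conv.n_frames * cfg.conv.n_bands)),
            "sparsity": {
                "mean_active_fraction": float(active.mean()),
                "max_active_fraction": float(active.max()),
            },
            "stdp": {
                "n_samples_seen": result.n_samples_seen,
                "converged": result.converged,
                "drift_history": [round(d, 8) for d in result.drift_history],
                "mean_abs_delta": float(np.mean(result.delta_history)),
            },
            "n_train": len(idx_train),
            "n_test": len(idx_test),
            "manifest": {
                "config": _config_dict(cfg),
                "seed": cfg.seed,
                "data_hash": _hash(maps),
                "labels_hash": _hash(labels),
                "bank_hash": _hash(result.bank),
            },
        }
        return report
    except Exception as exc:  # tag the failing stage for diagnosability
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d))  # plain types only


def compare_sharing(
    cfg: ExperimentConfig,
    spec: SynthSpec,
    map_counts,
    n_seeds: int = 5,
) -> pd.DataFrame:
    """Local vs global weight sharing at several feature-map counts.

    For each count the full experiment runs twice — with the configured
    multi-section layout (local sharing) and with a single section
    (global sharing) — over ``n_seeds`` seeds each.  Returns a tidy
    DataFrame with mean and sd accuracy per (map count, strategy) cell.
    """
    map_counts = list(map_counts)
    if not map_counts:
        raise ValueError("map_counts must be non-empty")
    rows = []
    for n_maps in map_counts:
        for strategy, n_sections in (("local", cfg.conv.n_sections), ("global", 1)):
            accs = []
            for k in range(n_seeds):
                seed = cfg.seed + k
                conv = ConvConfig(
                    **{
                        **asdict(cfg.conv),
                        "n_maps": int(n_maps),
                        "n_sections": int(n_sections),
                    }
                )
                run_cfg = ExperimentConfig(
                    **{**asdict_shallow(cfg), "conv": conv, "seed": seed}
                )
                data = sample_dataset(
                    SynthSpec(**{**asdict(spec), "seed": spec.seed + k})
                )
                accs.append(run_experiment(run_cfg, data)["accuracy"])
            rows.append(
                {
                    "n_maps": int(n_maps),
                    "sharing": strategy,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                    "n_seeds": n_seeds,
                }
            )
    return pd.DataFrame(rows)


def asdict_shallow(cfg: ExperimentConfig) -> dict:
    """ExperimentConfig fields with sub-configs left as objects."""
    return {
        "conv": cfg.conv,
        "stdp": cfg.stdp,
        "n_steps": cfg.n_steps,
        "floor_quantile": cfg.floor_quantile,
        "classifier": cfg.classifier,
        "tempotron_lr": cfg.tempotron_lr,
        "tempotron_epochs": cfg.tempotron_epochs,
        "split_ratio": cfg.split_ratio,
        "seed": cfg.seed,
    }


def template_recovery(
    bank: np.ndarray,
    cfg: ConvConfig,
    dataset: SynthDataset,
) -> np.ndarray:
    """Best Pearson correlation of learned weights with each class-segment
    pattern.

    For every (class, segment) the template's ridge is slid in
    ``win_len``-frame windows across the segment and correlated with every
    learned (map, section) weight matrix; the maximum r is reported.
    Values near 1 mean some section's shared weights became a detector of
    that pattern.  Shape: (n_classes, n_segments).
    """
    spec = dataset.spec
    L = spec.segment_len
    scores = np.full((spec.n_classes, spec.n_segments), -1.0)
    flat_bank = bank.reshape(-1, cfg.win_len * cfg.n_bands)
    centered = flat_bank - flat_bank.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0  # constant weight matrices have undefined correlation
    for c in range(spec.n_classes):
        for g in range(spec.n_segments):
            for off in range(0, L - cfg.win_len + 1):
                start = g * L + off
                window = dataset.templates[c, start : start + cfg.win_len, :].ravel()
                if window.std() == 0:
                    continue
                w = window - window.mean()
                w /= np.linalg.norm(w)
                r = np.zeros(len(flat_bank))
                r[valid] = (centered[valid] @ w) / norms[valid]
                scores[c, g] = max(scores[c, g], float(r.max()))
    return scores
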
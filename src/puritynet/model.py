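"""The purity regression model: definition, training loop, guarded inference,
and single-file serialization.

The network is a multilayer perceptron mapping the log-transformed TPM values
of the feature panel to a single purity estimate: input -> 32 -> 16 -> 1 with
ReLU hidden activations, dropout (p=0.4) on the input layer during training,
and no output activation. It is trained with Adam (lr 3e-5, weight decay 1e-5)
on L1 loss over batches of 64 freshly simulated pseudobulks until convergence:
a sliding mean of the last 25 batch losses is tracked, the weights with the
lowest sliding mean seen so far are snapshotted, and training stops once that
minimum has not improved for 200 consecutive batches.

At inference raw outputs are clipped to [0, 1]. Inputs missing more than 1% of
panel genes trigger a warning; at 20% or more the model refuses to predict,
because missing genes are zero-filled and bias the estimate downward.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import mlp
from .corpus import SingleCellCorpus, eligible_samples
from .features import FeatureSet
from .matrix import CountMatrix, GeneLengths, ValidationError
from .normalize import model_input_transform
from .simulate import SimulationConfig, simulate_batch

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class MissingGeneError(ValidationError):
    """Too many panel genes are absent from the input matrix."""


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters (defaults as published)."""

    hidden_sizes: list[int] = field(default_factory=lambda: [32, 16])
    input_dropout: float = 0.4
    learning_rate: float = 3e-5
    weight_decay: float = 1e-5
    batch_size: int = 64
    window: int = 25
    patience: int = 200
    max_batches: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden_sizes must be non-empty positive")
        if not (0 <= self.input_dropout < 1):
            raise ValidationError("input_dropout must be in [0, 1)")
        if self.window < 1 or self.patience < self.window:
            raise ValidationError("need window >= 1 and patience >= window")


@dataclass
class TrainingLog:
    """Per-batch losses, sliding-window means, and why training stopped."""

    losses: list[float] = field(default_factory=list)
    window_means: list[float] = field(default_factory=list)  # from batch index window-1
    best_batch: int = -1
    best_window_mean: float = float("inf")
    stop_reason: str = ""


@dataclass
class PurityModel:
    """Trained network plus the feature panel and config it was trained with."""

    feature_set: FeatureSet
    layers: list[mlp.Linear]
    config: ModelConfig
    training_log: TrainingLog | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(self.feature_set), *self.config.hidden_sizes, 1]

    @property
    def n_parameters(self) -> int:
        return mlp.parameter_count(self.sizes)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Eval-mode forward (dropout off, deterministic); no clipping."""
        preds, _ = forward_eval(self.layers, X)
        return preds


def forward_eval(layers: list[mlp.Linear], X: np.ndarray) -> tuple[np.ndarray, dict]:
    return mlp.forward(layers, X, input_dropout=0.0, training=False)


def init_model(features: FeatureSet, cfg: ModelConfig, rng: np.random.Generator) -> PurityModel:
    """Seeded fan-in-uniform initialization of the purity network."""
    sizes = [len(features), *cfg.hidden_sizes, 1]
    return PurityModel(feature_set=features, layers=mlp.init_layers(sizes, rng), config=cfg)


def train(
    corpus: SingleCellCorpus,
    features: FeatureSet,
    lengths: GeneLengths,
    sim_cfg: SimulationConfig,
    cfg: ModelConfig,
) -> tuple[PurityModel, TrainingLog]:
    """Train on an endless stream of freshly simulated pseudobulk batches.

    Two independent seeded generators are used: ``sim_cfg.seed`` drives the
    pseudobulk simulation and ``cfg.seed`` drives weight initialization and
    dropout masks, so the same seeds always reproduce the same model.
    Returns the snapshot with the lowest 25-batch sliding-mean loss.
    """
    eligible = eligible_samples(corpus, sim_cfg.min_cells_per_class)
    sim_rng = np.random.default_rng(sim_cfg.seed)
    model_rng = np.random.default_rng(cfg.seed)
    model = init_model(features, cfg, model_rng)
    opt = mlp.Adam(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    log = TrainingLog()
    best_layers = mlp.copy_layers(model.layers)
    since_best = 0
    batch = 0
    while True:
        X, y = simulate_batch(corpus, features, lengths, sim_cfg, sim_rng, eligible)
        preds, cache = mlp.forward(
            model.layers, X, input_dropout=cfg.input_dropout, training=True, rng=model_rng
        )
        loss = mlp.l1_loss(y, preds)
        if not np.isfinite(loss):
            raise ValidationError(f"non-finite training loss at batch {batch}")
        grads = mlp.backward_l1(model.layers, cache, y)
        opt.step(model.layers, grads)
        log.losses.append(loss)
        batch += 1
        if batch >= cfg.window:
            wmean = float(np.mean(log.losses[-cfg.window:]))
            log.window_means.append(wmean)
            if wmean < log.best_window_mean:
                log.best_window_mean = wmean
                log.best_batch = batch - 1
                best_layers = mlp.copy_layers(model.layers)
                since_best = 0
            else:
                since_best += 1
            if since_best >= cfg.patience:
                log.stop_reason = f"no new minimum sliding mean for {cfg.patience} batches"
                break
        if cfg.max_batches is not None and batch >= cfg.max_batches:
            log.stop_reason = f"reached max_batches={cfg.max_batches}"
            break
        if batch % 500 == 0:
            logger.info(
                "batch %d: loss %.4f, best window mean %.4f (batch %d)",
                batch, loss, log.best_window_mean, log.best_batch,
            )
    model.layers = best_layers
    model.training_log = log
    logger.info(
        "training stopped after %d batches (%s); best window mean %.4f at batch %d",
        batch, log.stop_reason, log.best_window_mean, log.best_batch,
    )
    return model, log


def predict(
    model: PurityModel,
    m: CountMatrix,
    lengths: GeneLengths,
    warn_missing: float = 0.01,
    max_missing: float = 0.20,
) -> tuple[np.ndarray, list[str]]:
    """Guarded inference on a raw bulk count matrix.

    Transforms ``m`` to model inputs against the model's feature panel, runs a
    deterministic eval-mode forward pass, and clips the outputs to [0, 1].
    Missing panel genes are zero-filled: above ``warn_missing`` a warning is
    emitted (the estimates will be biased low), at or above ``max_missing`` the
    model refuses to run.
    """
    transformed, missing_fraction = model_input_transform(m, model.feature_set, lengths)
    if missing_fraction >= max_missing:
        raise MissingGeneError(
            f"{missing_fraction:.1%} of the {len(model.feature_set)} panel genes are "
            f"missing from the input (limit {max_missing:.0%}); predictions would be "
            "unreliable, refusing to run"
        )
    notes: list[str] = []
    if missing_fraction > warn_missing:
        msg = (
            f"{missing_fraction:.1%} of panel genes missing from the input "
            f"(> {warn_missing:.0%}); purity will be underestimated"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    X = transformed.values.T  # columns -> rows
    if not np.isfinite(X).all():
        raise ValidationError("non-finite model inputs")
    raw = model.forward(X)
    return np.clip(raw, 0.0, 1.0), notes


def save_model(model: PurityModel, path: str | Path) -> None:
    """Write a versioned single-file JSON artifact.

    Floats are serialized via their shortest round-trip representation, so a
    load-then-predict reproduces pre-save predictions exactly.
    """
    obj = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_set": {
            "gene_ids": model.feature_set.gene_ids,
            "provenance": model.feature_set.provenance,
        },
        "config": asdict(model.config),
        "layers": [{"W": l.W.tolist(), "b": l.b.tolist()} for l in model.layers],
    }
    if model.training_log is not None:
        obj["training"] = {
            "n_batches": len(model.training_log.losses),
            "best_batch": model.training_log.best_batch,
            "best_window_mean": model.training_log.best_window_mean,
            "stop_reason": model.training_log.stop_reason,
        }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path: str | Path) -> PurityModel:
    path = Path(path)
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not a valid model artifact ({exc})") from exc
    version = obj.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"{path}: model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    for key in ("feature_set", "config", "layers"):
        if key not in obj:
            raise ValidationError(f"{path}: artifact missing {key!r}")
    features = FeatureSet(
        gene_ids=obj["feature_set"]["gene_ids"],
        provenance=obj["feature_set"].get("provenance", {}),
    )
    cfg = ModelConfig(**obj["config"])
    layers = [
        mlp.Linear(np.array(l["W"], dtype=np.float64), np.array(l["b"], dtype=np.float64))
        for l in obj["layers"]
    ]
    model = PurityModel(feature_set=features, layers=layers, config=cfg)
    if model.sizes != [len(features), *cfg.hidden_sizes, 1] or any(
        l.W.shape != (fi, fo)
        for l, fi, fo in zip(layers, model.sizes[:-1], model.sizes[1:])
    ):
        raise ValidationError(f"{path}: layer shapes inconsistent with config")
    return model
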
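"""Evaluation metrics for purity regression.

Four standard agreement measures between true and predicted purity vectors:
mean absolute error (MAE), root mean squared error (RMSE), Pearson
correlation, and Lin's concordance correlation coefficient (CCC),

    CCC = 2*cov(y, yhat) / (var(y) + var(yhat) + (mean(y) - mean(yhat))^2),

with population (1/n) moments. CCC penalizes both scatter and location/scale
shift, so |CCC| <= |Pearson| always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import CountMatrix, GeneLengths, ValidationError
from .model import PurityModel, predict


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValidationError("empty vectors")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error ``(1/n) sum |y_i - yhat_i|``."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error ``sqrt((1/n) sum (y_i - yhat_i)^2)``."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson(y, yhat) -> float:
    """Product-moment correlation; undefined (error) for constant vectors."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValidationError("pearson requires n >= 2")
    dy = y - y.mean()
    dz = yhat - yhat.mean()
    denom = np.sqrt((dy**2).sum() * (dz**2).sum())
    if denom == 0:
        raise ValidationError("pearson undefined for a constant vector")
    return float((dy * dz).sum() / denom)


def ccc(y, yhat) -> float:
    """Lin's concordance correlation coefficient with 1/n moments."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValidationError("ccc requires n >= 2")
    my, mz = y.mean(), yhat.mean()
    vy = np.mean((y - my) ** 2)
    vz = np.mean((yhat - mz) ** 2)
    cov = np.mean((y - my) * (yhat - mz))
    denom = vy + vz + (my - mz) ** 2
    if denom == 0:
        raise ValidationError("ccc undefined: both vectors constant with equal means")
    return float(2 * cov / denom)


@dataclass
class MetricsReport:
    """Summary of one evaluation run; correlations are None when undefined."""

    mae: float
    rmse: float
    pearson: float | None
    ccc: float | None
    n: int
    dataset_name: str = ""

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset_name,
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "pearson": self.pearson,
            "ccc": self.ccc,
        }


def compute_report(y, yhat, dataset_name: str = "") -> MetricsReport:
    """All four metrics at once; correlations fall back to None with a warning
    when undefined (single sample or constant vector)."""
    y, yhat = _pair(y, yhat)
    try:
        r = pearson(y, yhat)
    except ValidationError as exc:
        warnings.warn(f"pearson undefined: {exc}", stacklevel=2)
        r = None
    try:
        c = ccc(y, yhat)
    except ValidationError as exc:
        warnings.warn(f"ccc undefined: {exc}", stacklevel=2)
        c = None
    return MetricsReport(
        mae=mae(y, yhat), rmse=rmse(y, yhat), pearson=r, ccc=c,
        n=int(y.size), dataset_name=dataset_name,
    )


def evaluate(
    model: PurityModel,
    pseudobulks: CountMatrix,
    labels,
    lengths: GeneLengths,
    dataset_name: str = "",
    **predict_kwargs,
) -> tuple[MetricsReport, "np.ndarray"]:
    """Predict purity for labeled pseudobulks and score against the labels.

    ``labels`` must be aligned to ``pseudobulks.column_ids``. Returns the
    report and the per-column predictions.
    """
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if labels.size != pseudobulks.n_columns:
        raise ValidationError(
            f"{labels.size} labels for {pseudobulks.n_columns} columns"
        )
    preds, _ = predict(model, pseudobulks, lengths, **predict_kwargs)
    return compute_report(labels, preds, dataset_name), preds
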
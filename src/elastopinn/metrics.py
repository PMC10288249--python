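"""Prediction-vs-truth error measures: MAE, MRE, relative-error maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorReport", "mae", "mre", "relative_error_map", "error_report"]


def _check(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error, in the field's units."""
    pred, truth = _check(pred, truth)
    return float(np.abs(pred - truth).mean())


def mre(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean relative error in percent: 100 * mean(|pred - truth| / truth).

    Requires a strictly positive truth field (the measure diverges as
    the truth approaches zero, which is why zero Poisson's ratios are
    excluded from the phantoms).
    """
    pred, truth = _check(pred, truth)
    if np.any(truth <= 0):
        raise ValueError("mre requires strictly positive truth values")
    return float(100.0 * (np.abs(pred - truth) / truth).mean())


def relative_error_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pointwise 100 * |pred - truth| / truth (%)."""
    pred, truth = _check(pred, truth)
    if np.any(truth <= 0):
        raise ValueError("relative error map requires positive truth values")
    return 100.0 * np.abs(pred - truth) / truth


@dataclass
class ErrorReport:
    mae: float
    mre: float
    relative_error: np.ndarray  # (%) grid


def error_report(pred: np.ndarray, truth: np.ndarray) -> ErrorReport:
    return ErrorReport(
        mae=mae(pred, truth),
        mre=mre(pred, truth),
        relative_error=relative_error_map(pred, truth),
    )
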
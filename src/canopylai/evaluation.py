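"""Accuracy metrics, measured-vs-estimated diagnostics and LAI mapping.

Metrics: R^2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared error),
MAE = mean absolute error (both in LAI units).  The measured-vs-estimated
regression line (estimates on measurements) diagnoses attenuation: a
slope below 1 means the model overestimates low LAI and underestimates
high LAI relative to the 1:1 line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PATCH_SIZE
from .raster import BandStack
from .indices import compute_vi, VI_NAMES
from .texture import texture_maps


@dataclass
class EvalReport:
    """Accuracy summary of one model on one sample set."""

    r2: float
    rmse: float
    mae: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "mae": self.mae,
            "slope": self.slope, "intercept": self.intercept, "n": self.n,
        }


def metrics(y, y_hat, strict_printed_r2: bool = False) -> EvalReport:
    """R^2, RMSE, MAE and the estimated-on-measured regression line.

    ``strict_printed_r2=True`` reports SS_res/SS_tot instead of
    1 - SS_res/SS_tot (an audit mode; note that that ratio is small for a
    *good* fit, so it is not a coefficient of determination).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or len(y) < 2:
        raise ValueError("y and y_hat must be equal-length vectors with n >= 2")
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: measured values are constant")
    ratio = ss_res / ss_tot
    r2 = ratio if strict_printed_r2 else 1.0 - ratio
    rmse = float(np.sqrt(ss_res / len(y)))
    mae = float(np.mean(np.abs(y - y_hat)))
    slope, intercept = fit_line(y, y_hat)
    return EvalReport(r2=r2, rmse=rmse, mae=mae, slope=slope, intercept=intercept, n=len(y))


def fit_line(y, y_hat) -> tuple[float, float]:
    """Least-squares line of estimates on measurements (slope, intercept)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) < 2 or np.ptp(y) == 0:
        raise ValueError("line fit needs n >= 2 and non-constant measured values")
    res = stats.linregress(y, y_hat)
    return float(res.slope), float(res.intercept)


def compare_models(pred_a, pred_b) -> dict:
    """Agreement between two models' predictions on the same samples.

    Returns the R^2 (squared Pearson correlation, symmetric), and the
    slope/intercept of the least-squares fit of b on a.
    """
    a = np.asarray(pred_a, dtype=float).ravel()
    b = np.asarray(pred_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("prediction vectors must be aligned and equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("agreement undefined for constant predictions")
    res = stats.linregress(a, b)
    return {
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": len(a),
    }


def agreement_report(predictions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise agreement table over a dict of named prediction vectors."""
    rows = []
    names = list(predictions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            entry = compare_models(predictions[a], predictions[b])
            rows.append({"model_a": a, "model_b": b, **entry})
    return pd.DataFrame(rows)


def feature_planes(
    stack: BandStack, feature_names, glcm_config=None
) -> dict[str, np.ndarray]:
    """Scene-wide planes for a mixed list of VI and texture feature names."""
    vi_names = [n for n in feature_names if n in VI_NAMES]
    tex_names = [n for n in feature_names if n not in VI_NAMES]
    planes = {n: compute_vi(n, stack) for n in vi_names}
    if tex_names:
        maps = texture_maps(stack, glcm_config)
        unknown = [n for n in tex_names if n not in maps]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        planes.update({n: maps[n] for n in tex_names})
    return {n: planes[n] for n in feature_names}


def render_lai_map(model, stack: BandStack, feature_names=None, glcm_config=None,
                   stride: int = PATCH_SIZE) -> np.ndarray:
    """Scene-wide LAI estimate from a fitted model.

    Feature models (PLSR/RF) predict per pixel from scene-wide feature
    planes; pixels with any masked feature are NaN.  The CNN predicts one
    value per sliding 32x32 tile (default stride 32, i.e. non-overlapping
    tiles), standardized with its stored training state; overlapping
    tiles are averaged, and uncovered border pixels are NaN.
    """
    from .models import CNNRegressor

    if isinstance(model, CNNRegressor):
        return _render_cnn_map(model, stack, stride)
    if feature_names is None:
        raise ValueError("feature models need the feature_names used at training time")
    planes = feature_planes(stack, feature_names, glcm_config)
    h, w = stack.shape
    design = np.column_stack([planes[n].ravel() for n in feature_names])
    valid = np.isfinite(design).all(axis=1)
    out = np.full(h * w, np.nan)
    if valid.any():
        out[valid] = np.asarray(model.predict(design[valid])).ravel()
    return out.reshape(h, w)


def _render_cnn_map(model, stack: BandStack, stride: int) -> np.ndarray:
    h, w = stack.shape
    size = PATCH_SIZE
    values = stack.values.copy()
    values[stack.mask] = np.nan
    acc = np.zeros((h, w))
    cover = np.zeros((h, w))
    origins = [
        (r, c)
        for r in range(0, h - size + 1, stride)
        for c in range(0, w - size + 1, stride)
    ]
    tiles, keep = [], []
    for r, c in origins:
        tile = values[r : r + size, c : c + size, :]
        if np.isfinite(tile).all():
            tiles.append(tile)
            keep.append((r, c))
    if tiles:
        preds = model.predict(np.stack(tiles))
        for (r, c), pred in zip(keep, preds):
            acc[r : r + size, c : c + size] += pred
            cover[r : r + size, c : c + size] += 1
    out = np.full((h, w), np.nan)
    covered = cover > 0
    out[covered] = acc[covered] / cover[covered]
    return out
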
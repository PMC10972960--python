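"""Windowed gray-level co-occurrence (GLCM) texture features.

Texture is computed per pixel from the gray-level co-occurrence matrix of
the pixel's surrounding window (default 3x3, reflect-padded) at the
45-degree offset (drow, dcol) = (-1, +1), counted symmetrically.  Eight
Haralick statistics per band over five bands yield 40 texture feature
planes, named ``<band>_<stat>`` (``red_mean``, ``nir_cor``, ...).

Two code paths exist on purpose:

* :func:`glcm_from_window` + :func:`haralick_stats` — the direct,
  enumerate-the-pairs definition on one window, used as the reference;
* :func:`texture_maps` — a vectorized sliding-window implementation that
  never materializes per-pixel Q x Q matrices (all eight statistics are
  moments or collision counts of the window's co-occurring level pairs),
  exactly equal to the reference path per pixel.

Statistic definitions, with P the normalized GLCM, mu/sigma its marginal
mean/SD:  mean = mu_i; var = sum (i-mu_i)^2 P; hom = sum P / (1+(i-j)^2);
con = sum (i-j)^2 P; dis = sum |i-j| P; ent = -sum P ln P (0 ln 0 := 0);
sec = sum P^2; cor = sum (i-mu_i)(j-mu_j) P / (sigma_i sigma_j), defined
as 0 when either marginal SD is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import GLCMConfig
from .raster import BANDS, BandStack, QuadratSet, quadrat_mean

TEXTURE_STATS = ("mean", "var", "hom", "con", "dis", "ent", "sec", "cor")


def quantize(plane: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of a float plane into integer levels [0, Q-1].

    Binning is computed over the full plane (scene-wide scaling); a
    constant plane maps to level 0; NaN pixels map to -1 (invalid).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    plane = np.asarray(plane, dtype=float)
    finite = np.isfinite(plane)
    if not finite.any():
        raise ValueError("cannot quantize an empty or fully-masked plane")
    lo, hi = plane[finite].min(), plane[finite].max()
    out = np.full(plane.shape, -1, dtype=np.int64)
    if hi == lo:
        out[finite] = 0
        return out
    scaled = (plane[finite] - lo) / (hi - lo) * levels
    out[finite] = np.minimum(scaled.astype(np.int64), levels - 1)
    return out


def glcm_from_window(window_levels: np.ndarray, config: GLCMConfig | None = None) -> np.ndarray:
    """Normalized Q x Q co-occurrence matrix of one quantized window.

    Counts every level pair at offset (-1, +1) whose both endpoints lie
    inside the window; with ``symmetric=True`` the transposed pair is
    counted as well.  Pairs touching an invalid level (< 0) are skipped.
    """
    config = config or GLCMConfig()
    L = np.asarray(window_levels, dtype=np.int64)
    w = config.window
    if L.shape != (w, w):
        raise ValueError(f"expected a {w}x{w} window, got shape {L.shape}")
    q = config.levels
    counts = np.zeros((q, q), dtype=float)
    drow, dcol = config.angle_offset
    for r in range(w):
        for c in range(w):
            r2, c2 = r + drow, c + dcol
            if not (0 <= r2 < w and 0 <= c2 < w):
                continue
            i, j = L[r, c], L[r2, c2]
            if i < 0 or j < 0:
                continue
            counts[i, j] += 1
            if config.symmetric:
                counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("window has no valid co-occurring pixel pairs")
    return counts / total


def haralick_stats(P: np.ndarray) -> dict[str, float]:
    """The eight texture statistics of a normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=float)
    q = P.shape[0]
    i = np.arange(q)[:, None]
    j = np.arange(q)[None, :]
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float(((i - mu_i) ** 2 * P).sum())
    var_j = float(((j - mu_j) ** 2 * P).sum())
    diff = i - j
    con = float((diff**2 * P).sum())
    dis = float((np.abs(diff) * P).sum())
    hom = float((P / (1 + diff**2)).sum())
    nz = P > 0
    ent = float(-(P[nz] * np.log(P[nz])).sum())
    sec = float((P**2).sum())
    denom = np.sqrt(var_i * var_j)
    if denom > 0:
        cor = float(((i - mu_i) * (j - mu_j) * P).sum() / denom)
    else:
        cor = 0.0
    return {
        "mean": mu_i,
        "var": var_i,
        "hom": hom,
        "con": con,
        "dis": dis,
        "ent": ent,
        "sec": sec,
        "cor": cor,
    }


def _pair_samples(levels: np.ndarray, config: GLCMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stack the co-occurring level pairs of every pixel's window.

    Returns (S_i, S_j) of shape (2K, H, W) — for each pixel, the 2K
    symmetric (i, j) samples of its window's GLCM, where K = (w-1)^2 is
    the number of directed pairs at offset (-1, +1) inside a w x w window.
    """
    w = config.window
    half = w // 2
    h, wd = levels.shape
    padded = np.pad(levels, half, mode="reflect")
    I_parts, J_parts = [], []
    for wr in range(1, w):
        for wc in range(0, w - 1):
            I_parts.append(padded[wr : wr + h, wc : wc + wd])
            J_parts.append(padded[wr - 1 : wr - 1 + h, wc + 1 : wc + 1 + wd])
    I = np.stack(I_parts)
    J = np.stack(J_parts)
    if config.symmetric:
        return np.concatenate([I, J]), np.concatenate([J, I])
    return I, J


def _stats_from_samples(S_i: np.ndarray, S_j: np.ndarray) -> dict[str, np.ndarray]:
    """All eight statistics per pixel from the (2K, H, W) pair samples.

    Moments (mean, var, con, dis, hom, cor) are sample averages; sec and
    ent need the cell probabilities, recovered from pairwise collision
    counts among the 2K samples (c_a = multiplicity of sample a's cell):
    sec = sum_cells p^2 = sum_a c_a / (2K)^2 and
    ent = -sum_cells p ln p = -(1/2K) sum_a ln(c_a / 2K).
    """
    m = S_i.shape[0]
    Sif = S_i.astype(np.float64)
    Sjf = S_j.astype(np.float64)
    mean = Sif.mean(axis=0)  # symmetric => mu_i == mu_j
    var = ((Sif - mean) ** 2).mean(axis=0)
    diff = Sif - Sjf
    con = (diff**2).mean(axis=0)
    dis = np.abs(diff).mean(axis=0)
    hom = (1.0 / (1.0 + diff**2)).mean(axis=0)
    cov = ((Sif - mean) * (Sjf - mean)).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(var > 0, cov / var, 0.0)

    counts = np.zeros_like(Sif)
    for a in range(m):
        eq = (S_i[a] == S_i) & (S_j[a] == S_j)
        counts[a] = eq.sum(axis=0)
    sec = counts.sum(axis=0) / m**2
    ent = -np.log(counts / m).sum(axis=0) / m
    return {
        "mean": mean, "var": var, "hom": hom, "con": con,
        "dis": dis, "ent": ent, "sec": sec, "cor": cor,
    }


def texture_maps(stack: BandStack, config: GLCMConfig | None = None) -> dict[str, np.ndarray]:
    """Per-pixel texture planes for every band: 8 stats x 5 bands = 40.

    Each plane has the scene's shape (reflect padding at edges).  Masking
    is contagious: a pixel whose window touches any masked input pixel is
    NaN in every texture plane of that band.
    """
    config = config or GLCMConfig()
    out: dict[str, np.ndarray] = {}
    for name in BANDS:
        plane = stack.band(name)
        invalid = ~np.isfinite(plane)
        levels = quantize(plane, config.levels)
        if invalid.any():
            # fill so the vectorized path runs, then mask every window that
            # touched an invalid pixel
            filled = levels.copy()
            filled[filled < 0] = 0
            touched = ndimage.maximum_filter(invalid.astype(np.uint8), size=config.window) > 0
            levels = filled
        else:
            touched = None
        stats = _stats_from_samples(*_pair_samples(levels, config))
        for stat in TEXTURE_STATS:
            plane_out = stats[stat]
            if touched is not None:
                plane_out = plane_out.copy()
                plane_out[touched] = np.nan
            out[f"{name}_{stat}"] = plane_out
    return out


def texture_feature_table(
    stack: BandStack,
    quadrats: QuadratSet,
    selected_names=None,
    config: GLCMConfig | None = None,
    size: int = 32,
) -> pd.DataFrame:
    """Per-quadrat means of texture planes, one column per ``band_stat``."""
    maps = texture_maps(stack, config)
    names = list(maps) if selected_names is None else list(selected_names)
    unknown = [n for n in names if n not in maps]
    if unknown:
        raise KeyError(f"unknown texture feature names: {unknown}")
    data = {n: quadrat_mean(maps[n], quadrats, size=size) for n in names}
    return pd.DataFrame(data, index=pd.Index(quadrats.ids, name="id"))
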
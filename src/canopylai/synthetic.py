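"""Synthetic multispectral canopy scenes with a known LAI field.

The generator emulates the sampling design of a UAV variety-trial survey:
a spatially smooth LAI field with rectangular plot-to-plot offsets
(different varieties), per-band reflectance that saturates with canopy
density, a sinusoidal ridge/row texture that closes over as LAI grows,
additive sensor noise, and quadrats on a jittered grid whose "measured"
LAI is the footprint mean plus optical-instrument noise.

Every output is a pure function of (config, optics): two calls with the
same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import BandOptics, ConfigurationError, PATCH_SIZE, SceneConfig
from .raster import BANDS, BandStack, QuadratSet

_EDGE_MARGIN = PATCH_SIZE // 2


def _rng(config: SceneConfig, stage: str) -> np.random.Generator:
    # one independent stream per stage, derived from the scene seed via a
    # process-stable hash of the stage name
    import zlib

    return np.random.default_rng([zlib.crc32(stage.encode()) % (2**31), config.seed])


def generate_lai_field(config: SceneConfig) -> np.ndarray:
    """Generate a smooth LAI field rescaled exactly onto ``config.lai_range``.

    Gaussian-smoothed white noise (correlation length ``smoothness_px``)
    plus constant offsets on a rectangular plot grid gives both smooth
    within-plot gradients and plot-to-plot variety contrast.  The field is
    affinely rescaled so its min/max hit the configured range exactly; a
    degenerate range (lo == hi) yields a constant field.  ``lai_skew > 0``
    thins out the high-LAI tail (field surveys typically contain fewer
    dense-canopy samples).
    """
    h, w = config.height_px, config.width_px
    rng = _rng(config, "lai_field")
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), config.smoothness_px, mode="reflect")

    # per-plot variety offsets on a rectangular grid
    ps = max(1, config.plot_size_px)
    n_pr, n_pc = -(-h // ps), -(-w // ps)
    offsets = rng.normal(0.0, config.plot_offset_sd, size=(n_pr, n_pc))
    plot_plane = np.kron(offsets, np.ones((ps, ps)))[:h, :w]
    # soften plot edges slightly so quadrat footprints are not bimodal
    field = base / max(base.std(), 1e-12) + ndimage.gaussian_filter(plot_plane, 2.0, mode="reflect")

    if config.lai_skew > 0:
        # monotone transform compressing the upper tail
        u = (field - field.min()) / max(np.ptp(field), 1e-12)
        field = u ** (1.0 + config.lai_skew)

    lo, hi = config.lai_range
    span = field.max() - field.min()
    if span < 1e-15 or lo == hi:
        return np.full((h, w), (lo + hi) / 2.0)
    return lo + (field - field.min()) * (hi - lo) / span


def reflectance_from_lai(
    lai: np.ndarray, optics: BandOptics | None = None, config: SceneConfig | None = None
) -> BandStack:
    """Render a 5-band reflectance stack from a true LAI field.

    The noise-free core per band is the saturating exponential
    ``rho = rho_inf + (rho_soil - rho_inf) exp(-k * LAI_eff)``.  Ridge/row
    texture enters as a sinusoidal modulation of the *effective* LAI
    (rows carry locally more canopy than furrows), so bare soil stays
    exactly at soil reflectance, the dense-canopy asymptote is untouched,
    and the texture amplitude fades as the canopy closes — texture
    features therefore carry genuine LAI information.  I.i.d. Gaussian
    sensor noise is added last and the result clipped to [0, 1].
    """
    optics = optics or BandOptics()
    config = config or SceneConfig(height_px=lai.shape[0], width_px=lai.shape[1])
    lai = np.asarray(lai, dtype=float)
    h, w = lai.shape

    cols = np.arange(w)
    ridge = np.sin(2 * np.pi * cols / config.ridge_period_px)[None, :]
    lai_eff = np.clip(lai * (1.0 + config.ridge_amplitude * ridge), 0.0, None)

    rng = _rng(config, "sensor_noise")
    stack = np.empty((h, w, len(BANDS)))
    for bi, name in enumerate(BANDS):
        rho_soil = optics.soil[name]
        rho_inf = optics.asymptote[name]
        k = optics.extinction[name]
        plane = rho_inf + (rho_soil - rho_inf) * np.exp(-k * lai_eff)
        if config.noise_sd > 0:
            plane = plane + rng.normal(0.0, config.noise_sd, size=plane.shape)
        stack[:, :, bi] = plane
    gt = (0.0, config.gsd_m, 0.0, 0.0, 0.0, config.gsd_m)
    return BandStack(values=np.clip(stack, 0.0, 1.0), geotransform=gt)


def sample_quadrats(lai: np.ndarray, config: SceneConfig) -> QuadratSet:
    """Place quadrats on a jittered grid and measure their LAI.

    Centers sit on a near-regular grid (one per cell, jittered inside the
    cell) so quadrats are evenly distributed and their 32x32 windows never
    overlap or cross the scene edge.  Measured LAI is the true-field mean
    over the window plus Gaussian measurement noise; non-positive draws
    are redrawn so every measured LAI is > 0.
    """
    h, w = lai.shape
    usable_h, usable_w = h, w
    n = config.n_quadrats

    # choose a grid at least as large as n with near-square cells >= patch size
    best = None
    for rows in range(1, usable_h // PATCH_SIZE + 1):
        cols = -(-n // rows)
        if cols * PATCH_SIZE > usable_w or rows * cols < n:
            continue
        cell_h, cell_w = usable_h // rows, usable_w // cols
        score = abs(cell_h - cell_w)
        if best is None or score < best[0]:
            best = (score, rows, cols)
    if best is None:
        raise ConfigurationError(
            f"cannot place {n} quadrats of {PATCH_SIZE}px in a {h}x{w} scene"
        )
    _, rows, cols = best
    cell_h, cell_w = usable_h // rows, usable_w // cols

    rng = _rng(config, "quadrats")
    centers = []
    for i in range(rows):
        for j in range(cols):
            # jitter keeps the full window inside the cell => no overlap
            r_lo = i * cell_h + _EDGE_MARGIN
            r_hi = i * cell_h + cell_h - _EDGE_MARGIN
            c_lo = j * cell_w + _EDGE_MARGIN
            c_hi = j * cell_w + cell_w - _EDGE_MARGIN
            r = int(rng.integers(r_lo, max(r_lo + 1, r_hi)))
            c = int(rng.integers(c_lo, max(c_lo + 1, c_hi)))
            centers.append((r, c))
    keep = rng.choice(len(centers), size=n, replace=False)
    keep.sort()
    centers = np.asarray(centers)[keep]

    half = PATCH_SIZE // 2
    lai_true = np.array(
        [lai[r - half : r + half, c - half : c + half].mean() for r, c in centers]
    )
    measured = lai_true.copy()
    if config.lai_meas_sd > 0:
        measured = lai_true + rng.normal(0.0, config.lai_meas_sd, size=n)
        for _ in range(100):
            bad = measured <= 0
            if not bad.any():
                break
            measured[bad] = lai_true[bad] + rng.normal(0.0, config.lai_meas_sd, size=bad.sum())
        measured = np.where(measured > 0, measured, lai_true)
    ids = np.arange(1, n + 1)
    return QuadratSet(
        ids=ids, centers=centers, lai_measured=measured, lai_true=lai_true, gsd_m=config.gsd_m
    )


def make_scene(
    config: SceneConfig, optics: BandOptics | None = None
) -> tuple[BandStack, np.ndarray, QuadratSet]:
    """Generate (reflectance stack, true LAI field, quadrats) in one call."""
    lai = generate_lai_field(config)
    stack = reflectance_from_lai(lai, optics, config)
    quadrats = sample_quadrats(lai, config)
    return stack, lai, quadrats
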
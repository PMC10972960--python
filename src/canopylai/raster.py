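"""Band stacks, raster I/O, patch extraction and quadrat aggregation.

Conventions (used everywhere in the package):

* pixel indices are 0-based, row-major;
* a quadrat patch of even size ``s`` centered at ``(r, c)`` is the half-open
  window ``[r - s//2, r + s//2) x [c - s//2, c + s//2)``;
* invalid pixels are carried both as a boolean mask and as NaN in float
  planes, and are excluded from every statistic.

Rasters are written as multi-band float32 TIFFs; the affine geotransform,
band names and nodata value travel in a JSON ``ImageDescription`` tag so a
write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import BAND_ORDER, PATCH_SIZE

BANDS = BAND_ORDER

DEFAULT_NODATA = -9999.0

#: identity geotransform (x-origin, x-pixel-size, 0, y-origin, 0, y-pixel-size)
IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


class RasterFormatError(ValueError):
    """Raised for rasters that violate the 5-band contract."""


class SamplingError(ValueError):
    """Raised when quadrats cannot be sampled from a raster."""


@dataclass
class BandStack:
    """A 5-band reflectance raster with geotransform and validity mask.

    ``values`` has shape (H, W, 5) in the fixed band order
    (blue, green, red, rededge, nir); ``mask`` is True where a pixel is
    invalid (nodata).
    """

    values: np.ndarray
    geotransform: tuple = IDENTITY_TRANSFORM
    mask: np.ndarray | None = None
    band_names: tuple = BANDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != len(BANDS):
            raise RasterFormatError(
                f"expected an H x W x {len(BANDS)} band stack, got shape {self.values.shape}"
            )
        if tuple(self.band_names) != BANDS:
            raise RasterFormatError(f"band order must be {BANDS}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values).all(axis=2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise RasterFormatError("mask shape must match raster shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a float plane with NaN at masked pixels."""
        plane = self.values[:, :, BANDS.index(name)].copy()
        plane[self.mask] = np.nan
        return plane

    def bands(self) -> dict[str, np.ndarray]:
        return {name: self.band(name) for name in BANDS}


@dataclass
class QuadratSet:
    """Ground-truth quadrats: id, pixel center, measured (and true) LAI."""

    ids: np.ndarray
    centers: np.ndarray  # (N, 2) array of (row, col)
    lai_measured: np.ndarray
    lai_true: np.ndarray | None = None
    gsd_m: float = 1.0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.centers = np.asarray(self.centers, dtype=int)
        self.lai_measured = np.asarray(self.lai_measured, dtype=float)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise SamplingError("quadrat ids must be unique")
        if self.centers.shape != (len(self.ids), 2):
            raise SamplingError("centers must be an (N, 2) array of (row, col)")
        if self.lai_true is not None:
            self.lai_true = np.asarray(self.lai_true, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "row_px": self.centers[:, 0],
                "col_px": self.centers[:, 1],
                "x_m": self.centers[:, 1] * self.gsd_m,
                "y_m": self.centers[:, 0] * self.gsd_m,
                "lai_measured": self.lai_measured,
            }
        )
        if self.lai_true is not None:
            df["lai_true"] = self.lai_true
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, gsd_m: float = 1.0) -> "QuadratSet":
        df = pd.read_csv(path)
        return cls(
            ids=df["id"].to_numpy(),
            centers=df[["row_px", "col_px"]].to_numpy(),
            lai_measured=df["lai_measured"].to_numpy(),
            lai_true=df["lai_true"].to_numpy() if "lai_true" in df else None,
            gsd_m=gsd_m,
        )


@dataclass
class PatchSet:
    """32x32x5 image patches aligned with a QuadratSet."""

    patches: np.ndarray  # (N, size, size, 5)
    lai: np.ndarray
    ids: np.ndarray
    source_ids: np.ndarray | None = field(default=None)  # provenance through augmentation

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.lai = np.asarray(self.lai, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.patches.ndim != 4 or self.patches.shape[3] != len(BANDS):
            raise RasterFormatError("patches must have shape (N, size, size, 5)")
        if not (len(self.patches) == len(self.lai) == len(self.ids)):
            raise RasterFormatError("patches, lai and ids must align")
        if self.source_ids is None:
            self.source_ids = self.ids.copy()

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def size(self) -> int:
        return self.patches.shape[1]

    def subset(self, index) -> "PatchSet":
        return PatchSet(
            self.patches[index], self.lai[index], self.ids[index], self.source_ids[index]
        )


def write_raster(values, geotransform, path, band_names=None, nodata=DEFAULT_NODATA) -> None:
    """Write a single- or multi-band float32 raster TIFF.

    NaN pixels are stored as ``nodata``; the geotransform, band names and
    nodata value are embedded as JSON metadata.
    """
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if band_names is None:
        band_names = [f"band_{i + 1}" for i in range(arr.shape[2])]
    out = arr.copy()
    out[~np.isfinite(out)] = nodata
    meta = {
        "geotransform": list(geotransform),
        "band_names": list(band_names),
        "nodata": nodata,
    }
    tifffile.imwrite(
        str(path),
        np.moveaxis(out, 2, 0),  # band-major pages
        description=json.dumps(meta),
        photometric="minisblack",
    )


def _read_raster(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return np.moveaxis(arr, 0, 2).astype(np.float64), meta


def read_scene(path) -> BandStack:
    """Read a 5-band reflectance scene written by :func:`write_raster`."""
    values, meta = _read_raster(path)
    if values.shape[2] != len(BANDS):
        raise RasterFormatError(
            f"expected {len(BANDS)} bands, found {values.shape[2]} in {path}"
        )
    nodata = meta.get("nodata", DEFAULT_NODATA)
    mask = np.isclose(values, nodata).any(axis=2)
    values = values.copy()
    values[mask] = np.nan
    geotransform = tuple(meta.get("geotransform", IDENTITY_TRANSFORM))
    return BandStack(values=values, geotransform=geotransform, mask=mask)


def read_plane(path) -> np.ndarray:
    """Read a single-band raster as a float plane with NaN nodata."""
    values, meta = _read_raster(path)
    plane = values[:, :, 0]
    nodata = meta.get("nodata", DEFAULT_NODATA)
    plane[np.isclose(plane, nodata)] = np.nan
    return plane


def _window_bounds(center: tuple[int, int], size: int) -> tuple[int, int, int, int]:
    r, c = int(center[0]), int(center[1])
    half = size // 2
    return r - half, r + size - half, c - half, c + size - half


def extract_patches(stack: BandStack, quadrats: QuadratSet, size: int = PATCH_SIZE) -> PatchSet:
    """Cut the size x size window centered on each quadrat out of the stack.

    Masked pixels become NaN inside the patches.  Quadrats whose window
    would cross the raster edge raise :class:`SamplingError` naming the
    offending ids.
    """
    h, w = stack.shape
    bad = []
    for qid, center in zip(quadrats.ids, quadrats.centers):
        r0, r1, c0, c1 = _window_bounds(center, size)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            bad.append(qid)
    if bad:
        raise SamplingError(f"quadrat window crosses the raster edge for ids: {bad}")
    values = stack.values.copy()
    values[stack.mask] = np.nan
    patches = np.empty((len(quadrats), size, size, len(BANDS)))
    for i, center in enumerate(quadrats.centers):
        r0, r1, c0, c1 = _window_bounds(center, size)
        patches[i] = values[r0:r1, c0:c1, :]
    return PatchSet(patches=patches, lai=quadrats.lai_measured.copy(), ids=quadrats.ids.copy())


def quadrat_mean(plane, quadrats: QuadratSet, size: int = PATCH_SIZE) -> np.ndarray:
    """Mean of a feature plane over each quadrat's window, NaN excluded.

    A fully-invalid window raises ``ValueError`` naming the quadrat id.
    """
    plane = np.asarray(plane, dtype=float)
    h, w = plane.shape
    out = np.empty(len(quadrats))
    for i, (qid, center) in enumerate(zip(quadrats.ids, quadrats.centers)):
        r0, r1, c0, c1 = _window_bounds(center, size)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise SamplingError(f"quadrat window crosses the raster edge for id {qid}")
        window = plane[r0:r1, c0:c1]
        valid = np.isfinite(window)
        if not valid.any():
            raise ValueError(f"quadrat {qid}: window is fully masked, mean undefined")
        out[i] = window[valid].mean()
    return out
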
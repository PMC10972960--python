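"""The 23-entry vegetation-index library.

Each index is an arithmetic combination of the five band reflectances
(B, G, R, RE, NIR) and/or the chromatic coordinates
``r = R/(R+G+B)``, ``g = G/(R+G+B)``, ``b = B/(R+G+B)``.

Pixels where a formula is undefined (zero denominator, masked input) are
NaN in the output plane, and NaN pixels are dropped from quadrat means —
degenerate pixels are masked, never clipped, so they cannot bias a
quadrat-level feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import BandStack, QuadratSet, quadrat_mean


class UnknownIndexError(KeyError):
    """Raised for a vegetation-index name outside the registry."""


def _safe_divide(num, den):
    """Element-wise num/den with zero denominators mapped to NaN."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.isfinite(den) & (den != 0)
    np.divide(num, den, out=out, where=ok)
    out[~ok] = np.nan
    return out


def chromatic_coords(stack_or_bands):
    """Chromatic coordinates (r, g, b): each visible band over R+G+B.

    Pixels with R+G+B == 0 are NaN; wherever defined, r + g + b == 1.
    """
    bands = stack_or_bands.bands() if isinstance(stack_or_bands, BandStack) else stack_or_bands
    total = bands["red"] + bands["green"] + bands["blue"]
    r = _safe_divide(bands["red"], total)
    g = _safe_divide(bands["green"], total)
    b = _safe_divide(bands["blue"], total)
    return r, g, b


def _vars(bands):
    """Band planes + chromatic coordinates under their formula symbols."""
    r, g, b = chromatic_coords(bands)
    return {
        "B": bands["blue"],
        "G": bands["green"],
        "R": bands["red"],
        "RE": bands["rededge"],
        "NIR": bands["nir"],
        "r": r,
        "g": g,
        "b": b,
    }


def _exg(v):
    return 2 * v["g"] - v["r"] - v["b"]


def _exr(v):
    return 1.4 * v["r"] - v["g"]


def _cive(v):
    return 0.441 * v["r"] - 0.811 * v["g"] + 0.385 * v["b"] + 18.78745


def _veg(v):
    return _safe_divide(v["g"], v["r"] ** 0.667 * v["b"] ** 0.333)


_REGISTRY = {
    "NDVI": lambda v: _safe_divide(v["NIR"] - v["R"], v["NIR"] + v["R"]),
    "ExB": lambda v: 1.4 * v["b"] - v["g"],
    "ExG": _exg,
    "ExR": _exr,
    "ExGR": lambda v: _exg(v) - _exr(v),
    "MExG": lambda v: 1.262 * v["g"] - 0.884 * v["r"] - 0.311 * v["b"],
    "VDVI": lambda v: _safe_divide(2 * v["g"] - v["r"] - v["b"], 2 * v["g"] + v["r"] + v["b"]),
    "CIVE": _cive,
    "NGRDI": lambda v: _safe_divide(v["g"] - v["r"], v["g"] + v["r"]),
    "BGRI": lambda v: _safe_divide(v["b"], v["g"]),
    "RGRI": lambda v: _safe_divide(v["r"], v["g"]),
    "VEG": _veg,
    "COM1": lambda v: _exg(v) + _cive(v) + (_exg(v) - _exr(v)) + _veg(v),
    "COM2": lambda v: 0.36 * _exg(v) + 0.47 * _cive(v) + 0.17 * _veg(v),
    "RVI": lambda v: _safe_divide(v["NIR"], v["R"]),
    "DVI": lambda v: v["NIR"] - v["R"],
    "GNDVI": lambda v: _safe_divide(v["NIR"] - v["G"], v["NIR"] + v["G"]),
    "BNDVI": lambda v: _safe_divide(v["NIR"] - v["B"], v["NIR"] + v["B"]),
    "RDVI": lambda v: _safe_divide(v["NIR"] - v["R"], np.sqrt(np.clip(v["NIR"] + v["R"], 0, None))),
    "NDRE": lambda v: _safe_divide(v["NIR"] - v["RE"], v["NIR"] + v["RE"]),
    "EVI": lambda v: _safe_divide(2.5 * (v["NIR"] - v["R"]), v["NIR"] + 6 * v["R"] - 7.5 * v["B"] + 1),
    # LCI with the red-band denominator; see lci_variant for the red-edge form
    "LCI": lambda v: _safe_divide(v["NIR"] - v["RE"], v["NIR"] + v["R"]),
    "OSAVI": lambda v: _safe_divide(v["NIR"] - v["R"], v["NIR"] + v["R"] + 0.16),
}

VI_NAMES = tuple(_REGISTRY)

#: normalized-difference indices bounded in [-1, 1] for nonnegative bands
NORMALIZED_DIFFERENCE_VIS = ("NDVI", "GNDVI", "BNDVI", "NDRE", "NGRDI", "VDVI")

#: simple ratio indices, positive for positive bands
RATIO_VIS = ("RVI", "BGRI", "RGRI", "VEG")


def compute_vi(name: str, stack: BandStack, lci_variant: str = "red") -> np.ndarray:
    """Compute one vegetation-index plane from a 5-band stack.

    ``lci_variant`` selects the LCI denominator: ``"red"`` (NIR+R, the
    default) or ``"rededge"`` (NIR+RE, the form common elsewhere in the
    literature).
    """
    if name not in _REGISTRY:
        raise UnknownIndexError(
            f"unknown vegetation index {name!r}; valid names: {sorted(_REGISTRY)}"
        )
    v = _vars(stack.bands() if isinstance(stack, BandStack) else stack)
    if name == "LCI" and lci_variant == "rededge":
        return _safe_divide(v["NIR"] - v["RE"], v["NIR"] + v["RE"])
    return _REGISTRY[name](v)


def vi_feature_table(
    stack: BandStack, quadrats: QuadratSet, names=VI_NAMES, size: int = 32
) -> pd.DataFrame:
    """Per-quadrat mean of each requested index, one column per index.

    Rows are indexed by quadrat id in QuadratSet order; aggregation
    delegates to :func:`canopylai.raster.quadrat_mean` so masked pixels
    are excluded.
    """
    data = {name: quadrat_mean(compute_vi(name, stack), quadrats, size=size) for name in names}
    return pd.DataFrame(data, index=pd.Index(quadrats.ids, name="id"))
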
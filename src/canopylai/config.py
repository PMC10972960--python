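"""Configuration dataclasses shared across the pipeline.

All configs are plain dataclasses that validate on construction and
round-trip losslessly through flat YAML mappings (``to_dict``/``from_dict``).
A single integer seed fans out deterministically to every stochastic stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


# Canonical band order used everywhere: blue, green, red, red edge, near infrared.
BAND_ORDER = ("blue", "green", "red", "rededge", "nir")

PATCH_SIZE = 32  # side length in pixels of a quadrat patch


@dataclass
class SceneConfig:
    """Geometry and noise of a synthetic multispectral canopy scene.

    The defaults emulate the study design the package targets: a ~3.7 cm
    ground sampling distance orthomosaic of a variety-trial wheat field,
    234 quadrats of 1x1 m sampled as 32x32-pixel patches, LAI roughly in
    [0.5, 6.5], and modest sensor and LAI-measurement noise.
    """

    height_px: int = 480
    width_px: int = 640
    gsd_m: float = 0.037
    lai_range: tuple[float, float] = (0.5, 6.5)
    smoothness_px: float = 25.0
    n_quadrats: int = 234
    ridge_period_px: int = 8
    ridge_amplitude: float = 0.25
    plot_size_px: int = 80
    plot_offset_sd: float = 0.8
    noise_sd: float = 0.01
    lai_meas_sd: float = 0.15
    lai_skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ConfigurationError("scene dimensions must be positive")
        lo, hi = self.lai_range
        if not (0 < lo <= hi <= 10):
            raise ConfigurationError("lai_range must satisfy 0 < lo <= hi <= 10")
        if self.n_quadrats <= 0:
            raise ConfigurationError("n_quadrats must be positive")
        n_windows = (self.height_px // PATCH_SIZE) * (self.width_px // PATCH_SIZE)
        if self.n_quadrats > n_windows:
            raise ConfigurationError(
                f"cannot place {self.n_quadrats} non-overlapping {PATCH_SIZE}x"
                f"{PATCH_SIZE} quadrats in a {self.height_px}x{self.width_px} scene "
                f"(max {n_windows})"
            )
        if self.ridge_period_px <= 0:
            raise ConfigurationError("ridge_period_px must be positive")
        if self.noise_sd < 0 or self.lai_meas_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lai_range"] = list(self.lai_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        d = dict(d)
        if "lai_range" in d:
            d["lai_range"] = tuple(d["lai_range"])
        return cls(**d)


@dataclass
class BandOptics:
    """Per-band canopy optics for the saturating-exponential reflectance model.

    Noise-free reflectance follows a Beer-Lambert canopy closure:
    ``rho_b(LAI) = rho_inf_b + (rho_soil_b - rho_inf_b) * exp(-k_b * LAI)``,
    so each band relaxes monotonically from bare-soil reflectance toward a
    dense-canopy asymptote at a band-specific extinction rate.  The defaults
    encode wheat-like behaviour: near-infrared reflectance rises with LAI,
    red falls sharply (chlorophyll absorption), and all bands saturate at
    high LAI.
    """

    soil: Mapping[str, float] = field(
        default_factory=lambda: {
            "blue": 0.06, "green": 0.10, "red": 0.15, "rededge": 0.20, "nir": 0.25,
        }
    )
    asymptote: Mapping[str, float] = field(
        default_factory=lambda: {
            "blue": 0.02, "green": 0.07, "red": 0.03, "rededge": 0.32, "nir": 0.50,
        }
    )
    extinction: Mapping[str, float] = field(
        default_factory=lambda: {
            "blue": 0.60, "green": 0.55, "red": 0.65, "rededge": 0.50, "nir": 0.45,
        }
    )

    def __post_init__(self) -> None:
        for name in BAND_ORDER:
            for table, label in ((self.soil, "soil"), (self.asymptote, "asymptote")):
                if name not in table:
                    raise ConfigurationError(f"missing {label} reflectance for band {name!r}")
                if not (0 <= table[name] <= 1):
                    raise ConfigurationError(f"{label} reflectance for {name!r} outside [0, 1]")
            if self.extinction.get(name, 0) <= 0:
                raise ConfigurationError(f"extinction k must be > 0 for band {name!r}")
        if self.asymptote["nir"] <= self.soil["nir"]:
            raise ConfigurationError("NIR reflectance must increase with LAI (asymptote > soil)")
        if self.asymptote["red"] >= self.soil["red"]:
            raise ConfigurationError("red reflectance must decrease with LAI (asymptote < soil)")

    @classmethod
    def strongly_saturating(cls) -> "BandOptics":
        """Optics with roughly doubled extinction coefficients.

        Reflectance then plateaus by LAI ~ 3, so most of the LAI range
        lies in the saturated regime — the canopy-closure condition under
        which nonlinear models outperform linear ones.
        """
        return cls(
            extinction={
                "blue": 1.3, "green": 1.2, "red": 1.4, "rededge": 1.1, "nir": 1.0,
            }
        )

    def to_dict(self) -> dict:
        return {
            "soil": dict(self.soil),
            "asymptote": dict(self.asymptote),
            "extinction": dict(self.extinction),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BandOptics":
        return cls(**{k: dict(v) for k, v in d.items()})


@dataclass
class GLCMConfig:
    """Windowed gray-level co-occurrence parameters.

    ``angle_offset`` is fixed at the 45-degree convention: pixel offset
    (drow, dcol) = (-1, +1), i.e. up-and-right in row/col space; with
    ``symmetric=True`` each pair is also counted transposed.
    """

    window: int = 3
    levels: int = 32
    symmetric: bool = True

    #: co-occurrence offset for the 45-degree direction
    angle_offset: tuple[int, int] = (-1, 1)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd integer >= 3")
        if not (2 <= self.levels <= 256):
            raise ConfigurationError("levels must be in [2, 256]")
        if self.angle_offset != (-1, 1):
            raise ConfigurationError("only the 45-degree offset (-1, +1) is supported")

    def to_dict(self) -> dict:
        return {"window": self.window, "levels": self.levels, "symmetric": self.symmetric}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GLCMConfig":
        return cls(**dict(d))


@dataclass
class SplitSpec:
    """Train/validation/test bookkeeping for the study design.

    70% of the quadrats form the train+validation pool and 30% the test
    set; after sixfold augmentation the pool is split 80/20 into CNN train
    and validation sets.  All counts use round-half-up so n=234 reproduces
    the chain 164/70 -> 984 -> 787/197.
    """

    trainval_fraction: float = 0.70
    cnn_train_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.trainval_fraction, self.cnn_train_fraction):
            if not (0 < f < 1):
                raise ConfigurationError("split fractions must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SplitSpec":
        return cls(**dict(d))


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up."""
    import math

    return int(math.floor(x + 0.5))


def save_config(config, path) -> None:
    """Write any config dataclass to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(cls, path):
    """Load a config dataclass of type ``cls`` from a YAML file."""
    with open(path) as fh:
        return cls.from_dict(yaml.safe_load(fh))
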
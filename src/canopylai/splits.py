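"""Sample splitting, sixfold augmentation and per-band standardization.

The bookkeeping reproduces the study design exactly: with 234 quadrats,
a seeded 70/30 shuffle gives 164 train+validation and 70 test samples
(round-half-up); rotations (90, 180, 270 degrees) and horizontal/vertical
flips expand the train+validation pool sixfold to 984 patches, which an
80/20 split divides into 787 training and 197 validation frames.  Test
patches are never augmented.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .config import SplitSpec, round_half_up
from .raster import PatchSet


class DegenerateBandError(ValueError):
    """Raised when a band has zero variance on the standardization pool."""


def split_samples(ids, spec: SplitSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint/exhaustive split of ids into (trainval, test).

    The train+validation count is round-half-up(n * trainval_fraction);
    n=234 at the default 0.70 gives 164 / 70.
    """
    spec = spec or SplitSpec()
    ids = np.asarray(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_trainval = round_half_up(n * spec.trainval_fraction)
    order = np.random.default_rng(spec.seed).permutation(n)
    return ids[order[:n_trainval]], ids[order[n_trainval:]]


#: augmentation transforms in output order (label-preserving isometries)
AUGMENTATIONS = ("original", "rot90", "rot180", "rot270", "hflip", "vflip")

_TRANSFORMS = {
    "original": lambda p: p,
    "rot90": lambda p: np.rot90(p, 1, axes=(1, 2)),
    "rot180": lambda p: np.rot90(p, 2, axes=(1, 2)),
    "rot270": lambda p: np.rot90(p, 3, axes=(1, 2)),
    "hflip": lambda p: p[:, :, ::-1, :],  # mirror columns
    "vflip": lambda p: p[:, ::-1, :, :],  # mirror rows
}


def augment_patches(patches: PatchSet) -> PatchSet:
    """Sixfold expansion: original + 3 rotations + 2 flips.

    Labels are copied; ``source_ids`` records which quadrat each augmented
    copy came from so leakage across a later split can be audited.
    """
    p = patches.patches
    if p.shape[1] != p.shape[2]:
        raise ValueError(f"rotation augmentation needs square patches, got {p.shape[1:3]}")
    stacks = [np.ascontiguousarray(_TRANSFORMS[name](p)) for name in AUGMENTATIONS]
    new_ids = np.concatenate(
        [np.array([f"{qid}:{name}" for qid in patches.ids]) for name in AUGMENTATIONS]
    )
    return PatchSet(
        patches=np.concatenate(stacks),
        lai=np.tile(patches.lai, len(AUGMENTATIONS)),
        ids=new_ids,
        source_ids=np.tile(patches.source_ids, len(AUGMENTATIONS)),
    )


class PatchStandardizer(TransformerMixin, BaseEstimator):
    """Per-band standardization fitted on the training pool only.

    ``fit`` computes each band's mean and standard deviation over all
    pixels of all patches in the pool; ``transform`` applies the stored
    constants (so test data keeps the training-frame scaling), and
    ``inverse_transform`` undoes it exactly.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.band_mean_ = X.mean(axis=(0, 1, 2))
        self.band_std_ = X.std(axis=(0, 1, 2))
        if np.any(self.band_std_ < 1e-12):
            bad = np.where(self.band_std_ < 1e-12)[0].tolist()
            raise DegenerateBandError(f"zero standard deviation for band index(es) {bad}")
        return self

    def transform(self, X):
        check_is_fitted(self, "band_mean_")
        return (np.asarray(X, dtype=float) - self.band_mean_) / self.band_std_

    def inverse_transform(self, X):
        check_is_fitted(self, "band_mean_")
        return np.asarray(X, dtype=float) * self.band_std_ + self.band_mean_


def standardize_bands(patches: np.ndarray, state: PatchStandardizer | None = None):
    """Functional wrapper: standardize patch pixels per band.

    With ``state=None`` a new :class:`PatchStandardizer` is fitted on
    ``patches`` (the training pool); otherwise the given fitted state is
    applied unchanged.  Returns (standardized array, state).
    """
    if state is None:
        state = PatchStandardizer().fit(patches)
    return state.transform(patches), state
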
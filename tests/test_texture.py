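"""GLCM texture: quantization, window matrices, Haralick statistics, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopylai.config import GLCMConfig
from canopylai.raster import BandStack
from canopylai.texture import (
    TEXTURE_STATS,
    glcm_from_window,
    haralick_stats,
    quantize,
    texture_feature_table,
    texture_maps,
)


def test_quantize_examples():
    plane = np.array([[0.0, 1.0], [1.0, 0.0]])
    np.testing.assert_array_equal(quantize(plane, 2), [[0, 1], [1, 0]])
    np.testing.assert_array_equal(quantize(np.full((3, 3), 0.4), 8), 0)


def test_quantize_uniform_ramp_gives_balanced_bins():
    plane = np.linspace(0, 1, 400).reshape(20, 20)
    levels = quantize(plane, 4)
    counts = np.bincount(levels.ravel(), minlength=4)
    assert np.all(np.abs(counts - 100) <= 1)


def test_quantize_rejects_empty_plane():
    with pytest.raises(ValueError):
        quantize(np.full((4, 4), np.nan), 8)


def test_glcm_hand_enumeration():
    """3x3 binary window: the four 45-degree pairs enumerated by hand.

    Window [[0,0,1],[0,1,1],[1,1,1]] has directed pairs (origin -> up-right):
    (1,0)->(0,1)=(0,0); (1,1)->(0,2)=(1,1); (2,0)->(1,1)=(1,1); (2,1)->(1,2)=(1,1);
    symmetric counting doubles each, so P(0,0)=2/8, P(1,1)=6/8.
    """
    window = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
    P = glcm_from_window(window, GLCMConfig(levels=2))
    assert P[0, 0] == pytest.approx(0.25)
    assert P[1, 1] == pytest.approx(0.75)
    assert P[0, 1] == 0 and P[1, 0] == 0


def test_glcm_constant_window_single_cell():
    P = glcm_from_window(np.full((3, 3), 5), GLCMConfig(levels=8))
    assert P[5, 5] == 1.0
    assert P.sum() == 1.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_glcm_normalized_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    window = rng.integers(0, 8, size=(3, 3))
    P = glcm_from_window(window, GLCMConfig(levels=8))
    assert P.sum() == pytest.approx(1.0)
    np.testing.assert_array_equal(P, P.T)


def test_haralick_constant_window_conventions():
    P = glcm_from_window(np.full((3, 3), 2), GLCMConfig(levels=4))
    stats = haralick_stats(P)
    assert stats["con"] == 0 and stats["dis"] == 0 and stats["var"] == 0
    assert stats["hom"] == 1 and stats["sec"] == 1 and stats["ent"] == 0
    assert stats["cor"] == 0  # zero-variance convention
    assert stats["mean"] == 2


def test_haralick_two_cell_hand_oracle():
    """P(0,0)=1/4, P(1,1)=3/4: moments computed by hand."""
    P = np.zeros((2, 2))
    P[0, 0], P[1, 1] = 0.25, 0.75
    stats = haralick_stats(P)
    assert stats["mean"] == pytest.approx(0.75)
    assert stats["var"] == pytest.approx(0.1875)
    assert stats["con"] == 0
    assert stats["sec"] == pytest.approx(0.0625 + 0.5625)
    assert stats["cor"] == pytest.approx(1.0)
    assert stats["ent"] == pytest.approx(-(0.25 * np.log(0.25) + 0.75 * np.log(0.75)))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_haralick_bounds_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    q = int(rng.integers(2, 9))
    P = rng.random((q, q))
    P = (P + P.T) / 2
    P /= P.sum()
    stats = haralick_stats(P)
    assert stats["sec"] <= 1 + 1e-12
    assert stats["ent"] <= np.log(q * q) + 1e-12
    assert stats["con"] >= 0 and stats["dis"] >= 0 and stats["var"] >= 0
    assert 0 < stats["hom"] <= 1 + 1e-12
    assert -1 - 1e-9 <= stats["cor"] <= 1 + 1e-9
    assert stats["dis"] ** 2 <= stats["con"] + 1e-12  # Cauchy-Schwarz


def test_texture_maps_inventory_and_shape(random_stack):
    stack = random_stack(h=12, w=12, seed=1)
    maps = texture_maps(stack)
    assert len(maps) == 40
    assert set(maps) == {
        f"{band}_{stat}"
        for band in ("blue", "green", "red", "rededge", "nir")
        for stat in TEXTURE_STATS
    }
    for plane in maps.values():
        assert plane.shape == (12, 12)


def test_texture_maps_match_per_window_oracle(random_stack):
    """Every interior pixel equals direct window GLCM + Haralick stats."""
    stack = random_stack(h=10, w=10, seed=2)
    config = GLCMConfig()
    maps = texture_maps(stack, config)
    for band in ("red", "nir"):
        levels = quantize(stack.band(band), config.levels)
        for r in range(1, 9):
            for c in range(1, 9):
                ref = haralick_stats(
                    glcm_from_window(levels[r - 1 : r + 2, c - 1 : c + 2], config)
                )
                for stat, expected in ref.items():
                    assert maps[f"{band}_{stat}"][r, c] == pytest.approx(
                        expected, abs=1e-9
                    ), (band, stat, r, c)


def test_constant_stack_texture_degenerates():
    stack = BandStack(np.full((16, 16, 5), 0.3))
    maps = texture_maps(stack)
    assert np.all(maps["red_con"] == 0)
    assert np.all(maps["red_hom"] == 1)
    assert np.all(maps["nir_sec"] == 1)
    assert np.all(maps["green_ent"] == 0)


def test_gray_level_shift_invariance():
    """Shifting all levels by a constant moves mean only."""
    rng = np.random.default_rng(3)
    window = rng.integers(0, 4, size=(3, 3))
    config = GLCMConfig(levels=16)
    base = haralick_stats(glcm_from_window(window, config))
    shifted = haralick_stats(glcm_from_window(window + 5, config))
    assert shifted["mean"] == pytest.approx(base["mean"] + 5)
    for stat in ("con", "dis", "hom", "sec", "ent", "cor"):
        assert shifted[stat] == pytest.approx(base[stat]), stat


def test_texture_matches_skimage_on_full_plane():
    """Cross-check against scikit-image's GLCM on a whole-plane matrix.

    skimage's graycomatrix with offset distance 1 at angle 45 degrees and
    symmetric counting is the same object as ours computed over one big
    window; contrast/dissimilarity/homogeneity/ASM/correlation agree.
    """
    skimage_feature = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(4)
    img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
    # skimage's angle convention measures from the +x axis with rows growing
    # downward, so its 3*pi/4 offset (+1, -1) is the mirror image of our
    # (-1, +1); with symmetric counting the two GLCMs coincide.
    G = skimage_feature.graycomatrix(
        img, distances=[1], angles=[3 * np.pi / 4], levels=8, symmetric=True, normed=True
    )[:, :, 0, 0]
    # run our reference path over the full image as one big "window",
    # padding to the next odd size with invalid (-1) levels that are skipped
    cfg = GLCMConfig(window=13, levels=8)
    padded = np.full((13, 13), -1)
    padded[:12, :12] = img
    ours = glcm_from_window(padded, cfg)
    np.testing.assert_allclose(ours, G, atol=1e-12)
    stats = haralick_stats(ours)
    props = {
        "con": "contrast", "dis": "dissimilarity", "hom": "homogeneity",
        "sec": "ASM", "cor": "correlation",
    }
    for stat, prop in props.items():
        expected = skimage_feature.graycoprops(G[:, :, None, None], prop)[0, 0]
        assert stats[stat] == pytest.approx(expected, abs=1e-10), stat


def test_masked_pixels_contaminate_windows(random_stack):
    stack = random_stack(h=12, w=12, seed=5)
    values = stack.values.copy()
    values[6, 6, :] = np.nan
    masked = BandStack(values)
    maps = texture_maps(masked)
    plane = maps["red_con"]
    assert np.isnan(plane[5:8, 5:8]).all()  # the 3x3 neighborhood
    assert np.isfinite(plane[0, 0])


def test_texture_feature_table_columns(small_scene):
    _, stack, _, quadrats = small_scene
    table = texture_feature_table(stack, quadrats, ["red_mean", "nir_cor"])
    assert list(table.columns) == ["red_mean", "nir_cor"]
    assert len(table) == len(quadrats)
    with pytest.raises(KeyError):
        texture_feature_table(stack, quadrats, ["red_bogus"])
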
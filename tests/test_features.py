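"""Texture descriptors against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbsd.features import (
    KIRSCH_MASKS,
    LBP_OFFSETS,
    FeatureStack,
    LBPContext,
    LDPContext,
    StatContext,
    concat_features,
    deep_features,
    extract_features,
    grid_structural_map,
    kirsch_responses,
    lbp_code,
    lbp_code_map,
    ldp_code_map,
    statistical_maps,
)


def _reflect(i: int, n: int) -> int:
    # edge-repeating mirror, the padding convention of every descriptor map
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - 1 - i
    return i


def lbp_oracle(img: np.ndarray, y: int, x: int) -> int:
    h, w = img.shape
    code = 0
    for d, (dy, dx) in enumerate(LBP_OFFSETS):
        if img[_reflect(y + dy, h), _reflect(x + dx, w)] >= img[y, x]:
            code |= 1 << d
    return code


def grid_map_oracle(img: np.ndarray) -> np.ndarray:
    """Independent double loop: every cell pixel is its own LBP center."""
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            codes = [
                lbp_oracle(img, _reflect(y + dy, h), _reflect(x + dx, w))
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
            ]
            out[y, x] = np.mean(codes)
    return out


class TestLBPCode:
    def test_uniform_patch_all_bits_set(self):
        assert lbp_code(np.full((3, 3), 5.0)) == 255

    def test_strict_center_maximum_gives_zero(self):
        patch = np.full((3, 3), 4.0)
        patch[1, 1] = 9.0
        assert lbp_code(patch) == 0

    def test_hand_worked_bit_pattern(self):
        # neighbors in bit order [6,4,4,4,4,4,4,6] around center 5 -> 2^0+2^7
        patch = np.zeros((3, 3))
        patch[1, 1] = 5
        for (dy, dx), v in zip(LBP_OFFSETS, [6, 4, 4, 4, 4, 4, 4, 6]):
            patch[1 + dy, 1 + dx] = v
        assert lbp_code(patch) == 129

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            lbp_code(np.zeros((4, 4)))


class TestGridStructuralMap:
    def test_constant_image_maps_to_255(self):
        out = grid_structural_map(np.full((8, 8), 0.5))
        assert np.array_equal(out, np.full((8, 8), 255.0))

    def test_matches_bruteforce_oracle_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            img = rng.random((8, 8))
            np.testing.assert_allclose(
                grid_structural_map(img), grid_map_oracle(img), atol=1e-10
            )

    def test_bounded_by_cell_code_extremes(self, rng):
        img = rng.random((16, 16))
        codes = lbp_code_map(img)
        out = grid_structural_map(img)
        assert (out >= codes.min()).all() and (out <= codes.max()).all()

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            grid_structural_map(np.zeros((8, 8, 3)))

    def test_shift_invariance_of_codes(self, rng):
        img = rng.random((12, 12))
        np.testing.assert_allclose(
            grid_structural_map(img), grid_structural_map(img + 0.37), atol=1e-9
        )


class TestKirsch:
    def test_masks_sum_to_zero(self):
        assert (KIRSCH_MASKS.sum(axis=(1, 2)) == 0).all()

    def test_constant_image_zero_response(self):
        resp = kirsch_responses(np.full((8, 8), 0.3))
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)

    def test_vertical_edge_strongest_east_west(self):
        img = np.zeros((5, 5))
        img[:, 3:] = 1.0  # vertical step edge
        resp = kirsch_responses(img)
        on_edge = np.abs(resp[:, :, 2]).max(axis=1)  # column at the step
        assert {int(np.argmax(on_edge))} <= {0, 4}  # east or west mask wins

    def test_linearity(self, rng):
        img = rng.random((10, 10))
        np.testing.assert_allclose(
            kirsch_responses(3.5 * img), 3.5 * kirsch_responses(img), atol=1e-9
        )


class TestLDPCodeMap:
    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_popcount_equals_m_everywhere(self, rng, m):
        img = rng.random((16, 16))
        codes = ldp_code_map(img, LDPContext(m=m))
        pop = np.vectorize(lambda c: bin(c).count("1"))(codes)
        assert (pop == m).all()

    def test_constant_image_tie_rule_gives_code_7(self):
        codes = ldp_code_map(np.full((8, 8), 0.5), LDPContext(m=3))
        assert np.array_equal(codes, np.full((8, 8), 7))

    def test_hand_ranked_code(self):
        # responses [9,1,8,2,7,3,0,4] -> top 3 at orientations {0,2,4} -> 21
        resp = np.array([9.0, 1, 8, 2, 7, 3, 0, 4])
        order = np.argsort(-resp, kind="stable")[:3]
        assert sum(1 << int(o) for o in order) == 21

    def test_shift_invariance(self, rng):
        img = rng.random((12, 12))
        assert np.array_equal(ldp_code_map(img), ldp_code_map(img + 0.2))

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError, match="m"):
            LDPContext(m=0)


class TestStatisticalMaps:
    def test_constant_image_all_maps_constant(self):
        maps = statistical_maps(np.full((8, 8), 100 / 255))
        for m in maps.values():
            np.testing.assert_allclose(m, 100 / 255, atol=1e-12)

    def test_hand_counted_window(self):
        win = np.array([[1, 2, 2], [3, 3, 3], [4, 4, 5]]) / 255.0
        maps = statistical_maps(win)
        assert maps["stat_mean"][1, 1] * 255 == pytest.approx(3.0)
        assert maps["stat_median"][1, 1] * 255 == pytest.approx(3.0)
        assert maps["stat_mode"][1, 1] * 255 == pytest.approx(3.0)

    def test_mode_tie_resolves_to_smallest(self):
        # center window holds {1,1,2,2,3}-style tie after padding
        win = np.array([[1, 1, 2], [2, 3, 3], [1, 2, 3]]) / 255.0
        maps = statistical_maps(win)
        # window at center has values 1,1,2,2,3,3,1,2,3: counts 1:3, 2:3, 3:3
        assert maps["stat_mode"][1, 1] * 255 == pytest.approx(1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            StatContext(window=4)


class TestDeepFeatures:
    def test_deterministic(self, rng):
        img = rng.random((128, 128))
        a = deep_features(img)
        b = deep_features(img)
        assert np.array_equal(a, b)

    def test_channel_count_and_shape(self, rng):
        out = deep_features(rng.random((128, 128)), k=8)
        assert out.shape == (8, 128, 128)

    def test_vgg16_without_weights_errors(self, rng):
        with pytest.raises(FileNotFoundError, match="offline"):
            deep_features(rng.random((128, 128)), backbone="vgg16")

    def test_unknown_backbone_rejected(self, rng):
        with pytest.raises(ValueError, match="backbone"):
            deep_features(rng.random((128, 128)), backbone="resnet")


class TestConcatFeatures:
    def _parts(self, rng):
        shape = (128, 128)
        return (
            rng.random(shape) * 255,
            rng.integers(0, 255, shape).astype(float),
            {k: rng.random(shape) for k in ("stat_mean", "stat_median", "stat_mode")},
            rng.random((8, *shape)),
        )

    def test_channel_count(self, rng):
        stack = concat_features(*self._parts(rng))
        assert stack.data.shape == (13, 128, 128)
        assert stack.names[:5] == ["lbp", "ldp", "stat_mean", "stat_median", "stat_mode"]

    def test_constant_channel_normalizes_to_zero(self, rng):
        lbp, ldp, stat, deep = self._parts(rng)
        lbp = np.full((128, 128), 7.0)
        stack = concat_features(lbp, ldp, stat, deep)
        assert (stack.data[0] == 0).all()

    def test_channels_in_unit_interval(self, rng):
        stack = concat_features(*self._parts(rng))
        assert stack.data.min() >= 0 and stack.data.max() <= 1

    def test_shape_mismatch_names_offender(self, rng):
        lbp, ldp, stat, deep = self._parts(rng)
        stat["stat_mode"] = np.zeros((64, 64))
        with pytest.raises(ValueError, match="stat_mode"):
            concat_features(lbp, ldp, stat, deep)

    def test_roundtrip_save_load(self, rng, tmp_path):
        stack = concat_features(*self._parts(rng))
        p = tmp_path / "stack.npz"
        stack.save(p)
        back = FeatureStack.load(p)
        assert np.array_equal(back.data, stack.data)
        assert back.names == stack.names


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_ldp_popcount_property(seed):
    """Every pixel of every random image carries exactly m set bits."""
    img = np.random.default_rng(seed).random((8, 8))
    codes = ldp_code_map(img, LDPContext(m=3))
    assert all(bin(c).count("1") == 3 for c in codes.ravel())


def test_extract_features_stack_contract(rng):
    stack = extract_features(rng.random((128, 128)))
    assert stack.data.shape == (13, 128, 128)
    assert stack.provenance["ldp"] == {"m": 3}
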
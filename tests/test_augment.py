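"""Thresholding, erasing and the random-erasing baseline."""

import numpy as np
import pytest

from ageaug import (AttentionMapSet, ErasingPolicy, REPolicy, ThresholdSpec,
                    age_transform, apply_erasing, attention_to_mask,
                    random_erasing)
from ageaug.augment import BinaryMask, save_mask_png


def mass_fraction_oracle(grid, value):
    """Independent prefix-sum oracle: smallest top-k set with mass >= value."""
    flat = grid.reshape(-1)
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order]) / flat.sum()
    for k in range(1, flat.size + 1):
        if csum[k - 1] >= value - 1e-12:
            return set(order[:k])
    return set(order)


class TestThresholdSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(strategy="mass_fraction", value=0.0),
        dict(strategy="quantile", value=1.5),
        dict(strategy="absolute", value=-1.0),
        dict(strategy="bogus", value=0.5),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdSpec(**kwargs)


class TestAttentionToMask:
    def test_one_hot_grid_retains_only_hot_cell(self):
        grid = np.zeros((4, 4))
        grid[2, 1] = 1.0
        for v in (0.1, 0.6, 1.0):
            mask = attention_to_mask(grid, ThresholdSpec("mass_fraction", v))
            assert mask.cells.sum() == 1 and mask.cells[2, 1]

    def test_uniform_grid_cumulative_count(self):
        grid = np.full((2, 2), 0.25)
        mask = attention_to_mask(grid, ThresholdSpec("mass_fraction", 0.6))
        assert mask.cells.sum() == 3

    def test_sorted_prefix_example(self):
        grid = np.array([[0.5, 0.3], [0.15, 0.05]])
        mask = attention_to_mask(grid, ThresholdSpec("mass_fraction", 0.6))
        assert mask.cells.sum() == 2
        assert mask.cells[0, 0] and mask.cells[0, 1]

    @pytest.mark.parametrize("value", [0.3, 0.6, 0.9])
    @pytest.mark.parametrize("seed", range(10))
    def test_mass_fraction_matches_oracle_and_is_minimal(self, value, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((5, 5))
        grid /= grid.sum()
        mask = attention_to_mask(grid, ThresholdSpec("mass_fraction", value))
        retained = set(np.flatnonzero(mask.cells.reshape(-1)))
        assert retained == mass_fraction_oracle(grid, value)
        flat = grid.reshape(-1)
        assert flat[list(retained)].sum() >= value - 1e-12
        if len(retained) > 1:
            smallest = min(retained, key=lambda i: flat[i])
            rest = retained - {smallest}
            assert flat[list(rest)].sum() < value

    def test_quantile_retains_at_least_argmax(self):
        grid = np.full((3, 3), 1 / 9.0)  # all ties: strict quantile keeps none
        mask = attention_to_mask(grid, ThresholdSpec("quantile", 0.5))
        assert mask.cells.sum() >= 1

    def test_absolute_falls_back_to_argmax(self):
        grid = np.full((2, 2), 0.25)
        mask = attention_to_mask(grid, ThresholdSpec("absolute", 0.9))
        assert mask.cells.sum() == 1

    def test_all_zero_grid_rejected(self):
        with pytest.raises(ValueError):
            attention_to_mask(np.zeros((3, 3)), ThresholdSpec())


class TestApplyErasing:
    def test_all_retain_is_identity(self, rng):
        img = rng.random((8, 8))
        out = apply_erasing(img, np.ones((8, 8), dtype=bool), 0.5)
        assert np.array_equal(out, img)

    def test_elementwise_example(self):
        img = np.array([[0.2, 0.4], [0.6, 0.8]])
        mask = np.array([[True, False], [False, True]])
        out = apply_erasing(img, mask, 0.0)
        assert np.array_equal(out, [[0.2, 0.0], [0.0, 0.8]])

    def test_input_not_modified_and_idempotent(self, rng):
        img = rng.random((8, 8))
        ref = img.copy()
        mask = rng.random((8, 8)) > 0.5
        mask[0, 0] = True
        once = apply_erasing(img, mask, 0.3)
        twice = apply_erasing(once, mask, 0.3)
        assert np.array_equal(img, ref)
        assert np.array_equal(once, twice)
        assert np.array_equal(once[mask], img[mask])  # retained fidelity

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_erasing(rng.random((4, 4)), np.ones((2, 2), dtype=bool), 0.0)


@pytest.fixture
def uniformish_attention(rng):
    maps = rng.random((6, 4, 4)) + 1.0
    maps /= maps.reshape(6, -1).sum(axis=1)[:, None, None]
    return AttentionMapSet(maps=maps, layer=1)


class TestAgeTransform:
    def test_p_zero_is_identity(self, uniformish_attention, rng):
        img = rng.random((32, 32))
        policy = ErasingPolicy(head_index=1, probability=0.0)
        for _ in range(5):
            assert np.array_equal(
                age_transform(img, uniformish_attention, policy, rng), img)

    def test_p_one_equals_apply_erasing(self, uniformish_attention, rng):
        img = rng.random((32, 32))
        policy = ErasingPolicy(head_index=2, probability=1.0, fill_value=0.0)
        out = age_transform(img, uniformish_attention, policy,
                            np.random.default_rng(0))
        mask = attention_to_mask(uniformish_attention.head(2),
                                 policy.threshold).upsample(32)
        assert np.array_equal(out, apply_erasing(img, mask, 0.0))

    def test_head_out_of_range_rejected(self, uniformish_attention, rng):
        with pytest.raises(ValueError):
            age_transform(rng.random((32, 32)), uniformish_attention,
                          ErasingPolicy(head_index=7), rng)

    def test_never_adds_new_intensities(self, uniformish_attention, rng):
        img = np.round(rng.random((32, 32)), 2)
        policy = ErasingPolicy(head_index=3, probability=1.0, fill_value=0.0)
        out = age_transform(img, uniformish_attention, policy, rng)
        assert set(np.unique(out)) <= set(np.unique(img)) | {0.0}


class TestRandomErasing:
    def test_p_zero_identity(self, rng):
        img = rng.random((32, 32))
        assert np.array_equal(random_erasing(img, REPolicy(probability=0.0), rng),
                              img)

    @pytest.mark.parametrize("fill_mode", ["random", "constant"])
    def test_rectangle_geometry_within_policy_bounds(self, fill_mode):
        policy = REPolicy(probability=1.0, fill_mode=fill_mode, fill_value=0.5)
        rng = np.random.default_rng(1)
        img = np.zeros((32, 32)) - 1.0  # fill values never collide with -1
        lo, hi = policy.area_range
        alo, ahi = policy.aspect_range
        for _ in range(1000):
            out = random_erasing(img, policy, rng)
            changed = out != img
            rows = np.flatnonzero(changed.any(axis=1))
            cols = np.flatnonzero(changed.any(axis=0))
            h, w = len(rows), len(cols)
            assert changed.sum() == h * w  # a solid rectangle
            assert lo <= h * w / img.size <= hi
            assert alo <= h / w <= ahi

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            REPolicy(area_range=(0.0, 0.4))
        with pytest.raises(ValueError):
            REPolicy(aspect_range=(-1.0, 1.0))


def test_mask_png_export(tmp_path, rng):
    mask = BinaryMask(cells=rng.random((16, 16)) > 0.4, resolution_tag="pixel")
    save_mask_png(mask, tmp_path / "mask.png")
    assert (tmp_path / "mask.png").exists()
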
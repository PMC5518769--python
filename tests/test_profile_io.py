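"""Preprocessing: seed-surface extraction, thresholding, flattening, assembly."""

import numpy as np
import pytest
import warnings

from gparcel.profile_io import (ProfileMatrix, SeedSet, Volume,
                                assemble_profiles, binarise_flatten,
                                binarise_pv_map, downsample,
                                drop_zero_columns, extract_perimeter,
                                load_profiles, load_seedset, mask_seeds,
                                save_profiles, save_seedset, threshold_profile,
                                unflatten)
from gparcel.similarity import cosine_similarity_matrix

from conftest import make_pm


def brute_force_perimeter(mask, connectivity):
    """Independent oracle: scan every voxel's neighbours explicitly."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    out = []
    shape = mask.shape
    for x, y, z in np.argwhere(mask):
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                out.append((x, y, z))
                break
            if not mask[nx, ny, nz]:
                out.append((x, y, z))
                break
    return np.array(out, dtype=int).reshape(-1, 3)


class TestExtractPerimeter:
    def test_isolated_voxel_is_its_own_perimeter(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1
        seeds = extract_perimeter(Volume(data))
        assert seeds.coords.tolist() == [[2, 2, 2]]

    def test_solid_cube_has_26_perimeter_voxels(self):
        data = np.zeros((7, 7, 7))
        data[2:5, 2:5, 2:5] = 1
        seeds = extract_perimeter(Volume(data), connectivity=6)
        assert len(seeds) == 26
        assert [3, 3, 3] not in seeds.coords.tolist()

    def test_empty_mask_gives_empty_seedset(self):
        assert len(extract_perimeter(Volume(np.zeros((4, 4, 4))))) == 0

    def test_non_binary_mask_rejected_naming_values(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 2.5
        with pytest.raises(ValueError, match="2.5"):
            extract_perimeter(Volume(data))

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, connectivity, seed):
        r = np.random.default_rng(seed)
        mask = r.random((8, 9, 7)) < 0.4
        got = extract_perimeter(Volume(mask.astype(int)), connectivity).coords
        expected = brute_force_perimeter(mask, connectivity)
        order = np.lexsort(expected.T[::-1]) if len(expected) else []
        assert np.array_equal(got, expected[order])

    def test_order_is_lexicographic(self):
        data = np.ones((3, 3, 3))
        coords = extract_perimeter(Volume(data)).coords
        assert np.array_equal(coords, coords[np.lexsort(coords.T[::-1])])


class TestMaskSeeds:
    def test_mask_keeps_inside_half_in_order(self):
        seeds = SeedSet(coords=[(i, 0, 0) for i in range(6)])
        mask = np.zeros((6, 1, 1))
        mask[:3] = 1
        out = mask_seeds(seeds, Volume(mask))
        assert out.coords.tolist() == [[0, 0, 0], [1, 0, 0], [2, 0, 0]]

    def test_empty_mask_gives_empty_seedset(self):
        seeds = SeedSet(coords=[(0, 0, 0)])
        assert len(mask_seeds(seeds, Volume(np.zeros((2, 2, 2))))) == 0

    def test_grid_mismatch_rejected(self):
        seeds = SeedSet(coords=[(0, 0, 0)], affine=np.diag([2, 2, 2, 1]))
        with pytest.raises(ValueError, match="grid"):
            mask_seeds(seeds, Volume(np.ones((2, 2, 2))))


class TestThresholdProfile:
    def test_hand_worked_example(self):
        vol = Volume(np.array([0, 0.05, 1, 200]).reshape(4, 1, 1))
        out = threshold_profile(vol, fraction=0.0005)  # threshold = 0.1
        assert out.data.ravel().tolist() == [0, 0, 1, 200]

    def test_fraction_zero_is_identity(self, rng):
        data = rng.random((4, 4, 4))
        out = threshold_profile(Volume(data), fraction=0.0)
        assert np.array_equal(out.data, data)

    def test_all_zero_volume_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = threshold_profile(Volume(np.zeros((2, 2, 2))), 0.0005)
        assert not out.data.any()

    def test_idempotent_and_support_shrinks(self, rng):
        vol = Volume(rng.random((5, 5, 5)))
        once = threshold_profile(vol, 0.3)
        twice = threshold_profile(once, 0.3)
        assert np.array_equal(once.data, twice.data)
        assert ((once.data > 0) <= (vol.data > 0)).all()
        assert once.data.max() == vol.data.max()  # the maximum survives


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        vol = Volume(rng.random((4, 4, 4)))
        out = downsample(vol, 1)
        assert np.array_equal(out.data, vol.data)
        assert np.array_equal(out.affine, vol.affine)

    def test_single_voxel_survives_block_max(self):
        data = np.zeros((4, 4, 4))
        data[3, 0, 2] = 1
        out = downsample(Volume(data), 2)
        assert out.data.shape == (2, 2, 2)
        assert out.data.sum() == 1
        assert out.data[1, 0, 1] == 1  # the block that contained the voxel

    def test_constant_volume_stays_constant(self):
        out = downsample(Volume(np.full((6, 6, 6), 3.0)), 2)
        assert out.data.shape == (3, 3, 3)
        assert (out.data == 3.0).all()

    def test_affine_voxel_size_scales(self):
        vol = Volume(np.zeros((4, 4, 4)), affine=np.diag([1.875, 1.875, 2.1, 1]))
        out = downsample(vol, 2)
        assert np.allclose(np.diag(out.affine)[:3], [3.75, 3.75, 4.2])

    def test_factor_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample(Volume(np.zeros((2, 2, 2))), 3)


class TestFlattenAssemble:
    def test_binarise_counts_and_order(self):
        data = np.zeros((2, 1, 1))
        data[1, 0, 0] = 3.7
        assert binarise_flatten(Volume(data)).tolist() == [0, 1]

    def test_x_varies_fastest(self):
        data = np.zeros((2, 2, 1))
        data[1, 0, 0] = 1  # x=1,y=0 -> flat index 1 under x-fastest order
        assert binarise_flatten(Volume(data)).tolist() == [0, 1, 0, 0]

    def test_flatten_unflatten_round_trip(self, rng):
        data = (rng.random((3, 4, 5)) > 0.6).astype(float)
        row = binarise_flatten(Volume(data))
        back = unflatten(row, np.arange(row.size), (3, 4, 5))
        assert np.array_equal(back > 0, data > 0)

    def test_assemble_shapes_and_errors(self):
        rows = [np.zeros(8), np.ones(8), np.zeros(8)]
        pm = assemble_profiles(rows, ["a", "b", "c"], (2, 2, 2))
        assert pm.values.shape == (3, 8)
        with pytest.raises(ValueError, match="empty"):
            assemble_profiles([], [], (2, 2, 2))
        with pytest.raises(ValueError, match="ragged"):
            assemble_profiles([np.zeros(8), np.zeros(7)], ["a", "b"], (2, 2, 2))


class TestDropZeroColumns:
    def test_zero_column_removed_and_mapped(self):
        values = np.ones((2, 5))
        values[:, 2] = 0
        pm = make_pm(values)
        out = drop_zero_columns(pm)
        assert out.m == 4
        assert 2 not in out.column_map
        assert np.array_equal(out.values.sum(axis=1), pm.values.sum(axis=1))

    def test_no_zero_columns_is_identity(self, rng):
        pm = make_pm(rng.random((3, 6)) + 0.1)
        out = drop_zero_columns(pm)
        assert np.array_equal(out.values, pm.values)

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            out = drop_zero_columns(make_pm(np.zeros((2, 3))))
        assert out.m == 0

    def test_cosine_similarity_unchanged(self, rng):
        base = (rng.random((5, 12)) > 0.5).astype(float)
        base[:, [3, 7]] = 0
        base[0, 0] = base[4, 1] = 1  # no zero rows
        pm = make_pm(base)
        s_before = cosine_similarity_matrix(pm).values
        s_after = cosine_similarity_matrix(drop_zero_columns(pm)).values
        assert np.allclose(s_before, s_after, atol=1e-12)


class TestPersistence:
    def test_seedset_round_trip(self, tmp_path):
        seeds = SeedSet(coords=[(1, 2, 3), (4, 5, 6)],
                        affine=np.diag([1.875, 1.875, 2.1, 1]), label="p01")
        save_seedset(seeds, tmp_path / "seeds.tsv")
        back = load_seedset(tmp_path / "seeds.tsv")
        assert np.array_equal(back.coords, seeds.coords)
        assert np.allclose(back.affine, seeds.affine)
        assert back.label == "p01"

    def test_profiles_round_trip(self, tmp_path, rng):
        pm = make_pm((rng.random((4, 8)) > 0.5).astype(float), grid_shape=(2, 2, 2))
        save_profiles(pm, tmp_path / "p.mtx")
        back = load_profiles(tmp_path / "p.mtx")
        assert np.allclose(back.values, pm.values)
        assert np.array_equal(back.column_map, pm.column_map)
        assert back.grid_shape == pm.grid_shape

    def test_pv_map_binarised_with_no_threshold(self):
        data = np.array([0.0, 1e-9, 0.4, 1.0]).reshape(4, 1, 1)
        out = binarise_pv_map(Volume(data))
        assert out.data.ravel().tolist() == [0, 1, 1, 1]
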
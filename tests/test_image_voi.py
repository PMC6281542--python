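"""VOI atlas handling, regional means and SUVR computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from centikit.image_voi import (
    VOIAtlas,
    VolumeGrid,
    batch_suvr,
    compute_suvr,
    load_atlas,
    load_volume,
    read_suvr_table,
    regional_mean,
    save_mask,
    write_suvr_table,
)


def box_mask(shape, sl):
    m = np.zeros(shape, dtype=bool)
    m[sl] = True
    return m


@pytest.fixture
def simple_atlas():
    shape = (6, 6, 6)
    return VOIAtlas(
        grid_shape=shape,
        regions={
            "CTX": box_mask(shape, np.s_[0:3, :, :]),
            "WC": box_mask(shape, np.s_[4:6, :, :]),
        },
    )


class TestLoadAtlas:
    def test_two_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        a[:2, 0, 0] = 1
        a[0, 1, :2] = 1
        a[0, 2, :2] = 1
        a[0, 3, :2] = 1
        b = np.zeros((4, 4, 4))
        b[2:, 3, 3] = 1
        b[3, 1, :2] = 1
        b[3, 2, :2] = 1
        b[2, 2, :2] = 1
        atlas = load_atlas([("ctx", a), ("wc", b)])
        assert atlas.names == ["ctx", "wc"]
        assert atlas["ctx"].sum() == 8
        assert atlas["wc"].sum() == 8
        assert not (atlas["ctx"] & atlas["wc"]).any()

    def test_probabilistic_mask_thresholded_at_half(self):
        vals = np.array([0.0, 0.3, 0.7, 1.0])
        prob = np.tile(vals, 16).reshape(4, 4, 4)
        atlas = load_atlas([("r", prob)])
        assert atlas["r"].sum() == (prob > 0.5).sum()  # brute-force count

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(5, 5, 5\).*\(4, 4, 4\)"):
            load_atlas([("a", np.ones((4, 4, 4))), ("b", np.ones((5, 5, 5)))])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            load_atlas([("a", np.zeros((4, 4, 4)))])

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_atlas([("a", np.ones((2, 2, 2))), ("a", np.ones((2, 2, 2)))])


class TestRegionalMean:
    def test_uniform_volume(self):
        vol = np.ones((4, 4, 4))
        mask = box_mask((4, 4, 4), np.s_[1:3, 1:3, 1:3])
        assert regional_mean(vol, mask) == 1.0

    def test_two_selected_voxels(self):
        vol = np.arange(1, 9, dtype=float).reshape(2, 2, 2)
        mask = (vol == 1) | (vol == 8)
        assert regional_mean(vol, mask) == 4.5

    def test_nan_voxels_excluded(self):
        vol = np.full((3, 1, 1), np.nan)
        vol[0, 0, 0] = 2.0
        vol[1, 0, 0] = 2.0
        mask = np.ones((3, 1, 1), dtype=bool)
        with pytest.warns(UserWarning, match="non-finite"):
            assert regional_mean(vol, mask) == 2.0

    def test_all_nonfinite_in_mask_is_error(self):
        vol = np.ones((2, 2, 2))
        vol[0, 0, 0] = np.nan
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="non-finite"):
            regional_mean(vol, mask)

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            regional_mean(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.normal(5, 2, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        total, count = 0.0, 0
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    if mask[i, j, k]:
                        total += vol[i, j, k]
                        count += 1
        assert regional_mean(vol, mask) == pytest.approx(total / count, abs=1e-12)


class TestComputeSuvr:
    def test_ratio_of_regional_means(self, simple_atlas):
        vol = np.ones((6, 6, 6))
        vol[simple_atlas["CTX"]] = 2.0
        assert compute_suvr(vol, simple_atlas) == pytest.approx(2.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_invariant_under_global_rescaling(self, scale):
        shape = (6, 6, 6)
        atlas = VOIAtlas(
            grid_shape=shape,
            regions={
                "CTX": box_mask(shape, np.s_[0:3, :, :]),
                "WC": box_mask(shape, np.s_[4:6, :, :]),
            },
        )
        rng = np.random.default_rng(7)
        vol = rng.uniform(0.5, 3.0, shape)
        base = compute_suvr(vol, atlas)
        assert compute_suvr(vol * scale, atlas) == pytest.approx(base, rel=1e-12)

    def test_scaled_by_37_unchanged(self, simple_atlas, rng):
        vol = rng.uniform(0.5, 3.0, (6, 6, 6))
        assert compute_suvr(vol * 37, simple_atlas) == pytest.approx(
            compute_suvr(vol, simple_atlas), rel=1e-12
        )

    def test_missing_region_is_error(self, simple_atlas):
        with pytest.raises(KeyError, match="pons"):
            compute_suvr(np.ones((6, 6, 6)), simple_atlas, target="pons")

    def test_nonpositive_reference_is_error(self, simple_atlas):
        vol = np.ones((6, 6, 6))
        vol[simple_atlas["WC"]] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            compute_suvr(vol, simple_atlas)


class TestBatchSuvr:
    @staticmethod
    def meta(sid):
        return {"subject_id": sid, "group": "YHC", "tracer": "PiB",
                "session": "single"}

    def test_three_valid_scans(self, simple_atlas):
        scans = [(self.meta(f"s{i}"), np.ones((6, 6, 6))) for i in range(3)]
        result = batch_suvr(scans, simple_atlas)
        assert result.ok
        assert list(result.table["subject_id"]) == ["s0", "s1", "s2"]

    def test_mismatched_grid_reported_not_dropped_silently(self, simple_atlas):
        scans = [
            (self.meta("ok1"), np.ones((6, 6, 6))),
            (self.meta("bad"), np.ones((5, 5, 5))),
            (self.meta("ok2"), np.ones((6, 6, 6))),
        ]
        result = batch_suvr(scans, simple_atlas)
        assert len(result.table) == 2
        assert result.failures[0][0] == "bad"

    def test_empty_scan_list(self, simple_atlas):
        result = batch_suvr([], simple_atlas)
        assert result.ok and result.table.empty


class TestNiftiIO:
    def test_atlas_round_trip(self, tmp_path, rng):
        masks = {
            "CTX": rng.random((8, 8, 8)) > 0.6,
            "WC": box_mask((8, 8, 8), np.s_[0:2, 0:4, 0:4]),
        }
        paths = []
        for name, mask in masks.items():
            p = tmp_path / f"{name}.nii.gz"
            save_mask(mask, p)
            paths.append((name, p))
        atlas = load_atlas(paths)
        for name, mask in masks.items():
            np.testing.assert_array_equal(atlas[name], mask)

    def test_volume_round_trip_keeps_values(self, tmp_path, rng):
        from centikit.image_voi import save_volume

        vol = VolumeGrid(rng.uniform(0.1, 5, (6, 6, 6)).astype(np.float32))
        p = tmp_path / "v.nii"
        save_volume(vol, p)
        loaded = load_volume(p)
        np.testing.assert_allclose(loaded.voxels, vol.voxels, rtol=1e-6)

    def test_differing_affines_warn(self, simple_atlas):
        vol = VolumeGrid(np.ones((6, 6, 6)), affine=np.eye(4))
        shifted = VOIAtlas(
            grid_shape=simple_atlas.grid_shape,
            regions=simple_atlas.regions,
            affine=np.eye(4) + 0.01,
        )
        with pytest.warns(UserWarning, match="affine"):
            compute_suvr(vol, shifted)


class TestSuvrTableCSV:
    def test_round_trip(self, tmp_path):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b"],
                "group": ["YHC", "YHC", "AD"],
                "tracer": ["PiB", "flutemetamol", "PiB"],
                "session": ["single"] * 3,
                "suvr": [1.0123456, 1.5, 2.25],
            }
        )
        p = tmp_path / "t.csv"
        write_suvr_table(table, p)
        loaded = read_suvr_table(p)
        np.testing.assert_allclose(loaded["suvr"], table["suvr"], atol=1e-6)

    def test_duplicate_key_rejected(self, tmp_path):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "group": ["YHC"] * 2,
                "tracer": ["PiB"] * 2,
                "session": ["single"] * 2,
                "suvr": [1.0, 1.1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            write_suvr_table(table, tmp_path / "t.csv")


class TestVolumeGridInvariants:
    def test_rejects_2d(self):
        with pytest.raises(ValueError, match="3-D"):
            VolumeGrid(np.ones((4, 4)))

    def test_rejects_all_nan(self):
        with pytest.raises(ValueError, match="finite"):
            VolumeGrid(np.full((2, 2, 2), np.nan))

    def test_rejects_nonpositive_voxel_size(self):
        with pytest.raises(ValueError, match="positive"):
            VolumeGrid(np.ones((2, 2, 2)), voxel_size_mm=(2.0, 0.0, 2.0))
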
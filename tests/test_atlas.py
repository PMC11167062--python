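"""Atlas loading, groupings, volumes, lesion overlap and intact-ROI selection."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import braingap as bg
from braingap.atlas import (
    RegionGrouping,
    SparingProfile,
    ValidationError,
    full_sparing,
    intact_rois,
    lesion_overlap,
    roi_gm_volumes,
)
from conftest import make_fixture_table


def write_nifti(path, data, voxel_dims=(1.0, 1.0, 1.0)):
    affine = np.diag(list(voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


class TestLoadAtlas:
    def test_minimal_two_roi_atlas(self, tmp_path):
        grid = np.zeros((8, 8, 8), dtype=np.int16)
        grid[:4] = 1
        grid[4:] = 2
        write_nifti(tmp_path / "labels.nii", grid)
        pd.DataFrame(
            {"roi_id": [1, 2], "name": ["a", "b"], "hemisphere": ["left", "right"]}
        ).to_csv(tmp_path / "lookup.tsv", sep="\t", index=False)
        atlas = bg.load_atlas(tmp_path / "labels.nii", tmp_path / "lookup.tsv")
        assert len(atlas.roi_table) == 2
        assert atlas.voxel_counts().tolist() == [256, 256]

    def test_label_missing_from_lookup_rejected(self, tmp_path):
        grid = np.zeros((4, 4, 4), dtype=np.int16)
        grid[0] = 1
        grid[1] = 2
        write_nifti(tmp_path / "labels.nii", grid)
        pd.DataFrame(
            {"roi_id": [1], "name": ["a"], "hemisphere": ["left"]}
        ).to_csv(tmp_path / "lookup.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="absent from lookup"):
            bg.load_atlas(tmp_path / "labels.nii", tmp_path / "lookup.tsv")

    def test_fractional_labels_rejected(self, tmp_path):
        grid = np.full((4, 4, 4), 0.5, dtype=np.float32)
        write_nifti(tmp_path / "labels.nii", grid)
        pd.DataFrame(
            {"roi_id": [1], "name": ["a"], "hemisphere": ["left"]}
        ).to_csv(tmp_path / "lookup.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="non-integer"):
            bg.load_atlas(tmp_path / "labels.nii", tmp_path / "lookup.tsv")

    def test_duplicate_roi_ids_rejected(self):
        table = pd.DataFrame(
            {"roi_id": [1, 1], "name": ["a", "b"], "hemisphere": ["left", "left"]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            bg.AtlasDefinition(np.ones((2, 2, 2), dtype=int), (1, 1, 1), table)

    def test_fixture_atlas_round_trips_through_files(self, tmp_path, fixture_atlas):
        write_nifti(tmp_path / "labels.nii", fixture_atlas.labels, fixture_atlas.voxel_dims)
        fixture_atlas.roi_table.to_csv(tmp_path / "lookup.tsv", sep="\t", index=False)
        loaded = bg.load_atlas(tmp_path / "labels.nii", tmp_path / "lookup.tsv")
        assert len(loaded.roi_table) == 16
        assert (loaded.roi_table["hemisphere"] == "left").sum() == 8
        np.testing.assert_array_equal(loaded.labels, fixture_atlas.labels)


class TestGroupings:
    def test_packaged_counts_match_standard_breakdown(self):
        atlas = bg.packaged_synthetic_atlas()
        groupings = {g.name: len(g) for g in bg.default_groupings(atlas)}
        assert groupings["left_hemisphere"] == 94
        assert groupings["right_hemisphere"] == 94
        assert groupings["left_domain_general"] == groupings["right_domain_general"] == 8
        assert groupings["left_language_specific"] == groupings["right_language_specific"] == 9
        assert groupings["left_frontal"] == 16 and groupings["left_temporal"] == 13
        assert groupings["left_parietal"] == 6 and groupings["left_occipital"] == 5
        assert len(atlas.roi_table) == 189

    def test_unknown_roi_name_rejected(self, tmp_path, fixture_atlas):
        config = tmp_path / "regions.yaml"
        config.write_text("regions:\n  custom:\n    left: [no_such_parcel]\n")
        with pytest.raises(ValidationError, match="no_such_parcel"):
            bg.load_region_groupings(config, fixture_atlas)

    def test_named_groupings_resolve_in_order(self, tmp_path, fixture_atlas):
        config = tmp_path / "regions.yaml"
        config.write_text(
            "regions:\n  custom:\n    left: [parcel_3, parcel_1]\n    right: [parcel_2]\n"
        )
        groupings = bg.load_region_groupings(config, fixture_atlas)
        assert [g.name for g in groupings] == ["left_custom", "right_custom"]
        assert groupings[0].roi_ids == (3, 1)


class TestRoiVolumes:
    def test_uniform_fraction_arithmetic(self):
        # one ROI of 100 voxels at 1 mm^3, gm fraction 1, tiv 1000 -> 0.1
        grid = np.zeros((10, 10, 10), dtype=np.int16)
        grid.reshape(-1)[:100] = 1
        atlas = bg.AtlasDefinition(
            grid, (1, 1, 1),
            pd.DataFrame({"roi_id": [1], "name": ["a"], "hemisphere": ["left"]}),
        )
        vols = roi_gm_volumes(np.ones_like(grid, dtype=float), atlas, tiv=1000.0)
        assert vols[1] == pytest.approx(0.1, abs=1e-12)

    def test_zero_gm_gives_zero_volumes(self, fixture_atlas):
        vols = roi_gm_volumes(
            np.zeros(fixture_atlas.labels.shape), fixture_atlas, tiv=1.0e6
        )
        assert (vols == 0).all()

    def test_matches_bruteforce_voxel_loop(self, fixture_atlas):
        rng = np.random.default_rng(3)
        gm = rng.uniform(0, 1, fixture_atlas.labels.shape)
        tiv = 1.5e6
        vols = roi_gm_volumes(gm, fixture_atlas, tiv)
        vv = fixture_atlas.voxel_volume
        for roi in fixture_atlas.roi_ids:
            expected = 0.0
            for idx in np.ndindex(fixture_atlas.labels.shape):
                if fixture_atlas.labels[idx] == roi:
                    expected += gm[idx] * vv
            assert vols[roi] == pytest.approx(expected / tiv, abs=1e-9)

    def test_shape_mismatch_and_bad_tiv_rejected(self, fixture_atlas):
        with pytest.raises(ValidationError, match="grid"):
            roi_gm_volumes(np.zeros((2, 2, 2)), fixture_atlas, tiv=1.0)
        with pytest.raises(ValidationError, match="tiv"):
            roi_gm_volumes(np.zeros(fixture_atlas.labels.shape), fixture_atlas, tiv=0.0)

    def test_precomputed_table_input(self, fixture_atlas):
        table = {int(r): 100.0 for r in fixture_atlas.roi_ids}
        vols = roi_gm_volumes(table, fixture_atlas, tiv=1000.0)
        assert vols.to_numpy() == pytest.approx(0.1)


class TestLesionOverlap:
    def test_empty_mask_spares_everything(self, fixture_atlas):
        profile = lesion_overlap(np.zeros(fixture_atlas.labels.shape, dtype=np.uint8), fixture_atlas)
        assert (profile.spared_fraction == 1.0).all()
        assert profile.lesion_volume == 0.0

    def test_mask_equal_to_roi_support_removes_it(self, fixture_atlas):
        roi = int(fixture_atlas.roi_ids[2])
        mask = fixture_atlas.labels == roi
        profile = lesion_overlap(mask, fixture_atlas)
        assert profile.spared_fraction[roi] == 0.0
        others = profile.spared_fraction.drop(roi)
        assert (others == 1.0).all()
        n_vox = int(mask.sum())
        assert profile.lesion_volume == pytest.approx(n_vox * fixture_atlas.voxel_volume)

    def test_half_lesioned_roi_matches_voxel_count_loop(self):
        grid = np.zeros((4, 4, 4), dtype=np.int16)
        grid[0, 0, :4] = 3  # 4-voxel ROI
        atlas = bg.AtlasDefinition(
            grid, (1, 1, 1),
            pd.DataFrame({"roi_id": [3], "name": ["a"], "hemisphere": ["left"]}),
        )
        mask = np.zeros_like(grid, dtype=np.uint8)
        mask[0, 0, :2] = 1
        profile = lesion_overlap(mask, atlas)
        spared_loop = sum(
            1 for idx in np.ndindex(grid.shape) if grid[idx] == 3 and not mask[idx]
        )
        assert profile.spared_fraction[3] == spared_loop / 4 == 0.5

    def test_random_mask_matches_bruteforce_exactly(self, fixture_atlas):
        rng = np.random.default_rng(9)
        mask = rng.random(fixture_atlas.labels.shape) < 0.3
        profile = lesion_overlap(mask, fixture_atlas)
        for roi in fixture_atlas.roi_ids:
            support = fixture_atlas.labels == roi
            expected = (support & ~mask).sum() / support.sum()
            assert profile.spared_fraction[roi] == expected  # exact integer ratio

    def test_float_mask_binarized_above_half(self, fixture_atlas):
        mask = np.zeros(fixture_atlas.labels.shape)
        mask[0, 0, 0] = 0.6
        mask[0, 0, 1] = 0.4
        profile = lesion_overlap(mask, fixture_atlas)
        assert profile.lesion_volume == pytest.approx(fixture_atlas.voxel_volume)

    def test_invalid_masks_rejected(self, fixture_atlas):
        with pytest.raises(ValidationError, match="binary"):
            lesion_overlap(np.full(fixture_atlas.labels.shape, 2, dtype=int), fixture_atlas)
        with pytest.raises(ValidationError, match="grid"):
            lesion_overlap(np.zeros((3, 3, 3), dtype=np.uint8), fixture_atlas)

    def test_lesioned_volume_conservation(self, fixture_atlas):
        # sum over ROIs of (1 - spared) * ROI volume == lesioned tissue inside labels
        rng = np.random.default_rng(21)
        mask = (rng.random(fixture_atlas.labels.shape) < 0.2) & (fixture_atlas.labels > 0)
        profile = lesion_overlap(mask, fixture_atlas)
        roi_vol = fixture_atlas.voxel_counts() * fixture_atlas.voxel_volume
        lesioned_in_rois = ((1 - profile.spared_fraction) * roi_vol).sum()
        assert lesioned_in_rois == pytest.approx(mask.sum() * fixture_atlas.voxel_volume)


class TestIntactRois:
    def grouping(self):
        return RegionGrouping(name="left_custom", side="left", roi_ids=(1, 2, 3, 4, 5, 6, 7, 8))

    def profile(self, fractions):
        return SparingProfile(
            participant_id="x",
            spared_fraction=pd.Series(fractions),
            lesion_volume=0.0,
        )

    def test_inclusive_at_exactly_99_percent(self):
        profile = self.profile({r: (0.99 if r == 1 else 1.0) for r in range(1, 9)})
        assert 1 in intact_rois(profile, self.grouping())

    def test_just_below_threshold_excluded(self):
        profile = self.profile({r: (0.989 if r == 1 else 1.0) for r in range(1, 9)})
        assert 1 not in intact_rois(profile, self.grouping())

    def test_six_of_eight_lesioned_leaves_two(self):
        fractions = {r: 0.0 for r in range(1, 7)}
        fractions.update({7: 1.0, 8: 1.0})
        assert intact_rois(self.profile(fractions), self.grouping()) == [7, 8]

    def test_preserves_grouping_order(self):
        grouping = RegionGrouping(name="left_custom", side="left", roi_ids=(5, 2, 8))
        profile = self.profile({r: 1.0 for r in range(1, 9)})
        assert intact_rois(profile, grouping) == [5, 2, 8]

    @given(
        fractions=st.lists(st.floats(0, 1), min_size=8, max_size=8),
        lo=st.floats(0.01, 0.99),
        hi=st.floats(0.01, 1.0),
    )
    def test_monotone_in_threshold(self, fractions, lo, hi):
        """Raising the sparing threshold can only shrink the intact set."""
        if lo > hi:
            lo, hi = hi, lo
        profile = self.profile(dict(zip(range(1, 9), fractions)))
        at_hi = set(intact_rois(profile, self.grouping(), hi))
        at_lo = set(intact_rois(profile, self.grouping(), lo))
        assert at_hi <= at_lo

    def test_invalid_threshold_rejected(self):
        profile = self.profile({r: 1.0 for r in range(1, 9)})
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                intact_rois(profile, self.grouping(), bad)

    def test_full_sparing_profile(self, fixture_atlas):
        profile = full_sparing(fixture_atlas, "c1")
        assert (profile.spared_fraction == 1.0).all()
        assert profile.lesion_volume == 0.0
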
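"""Synthetic-cohort generator: generative law, determinism, serialization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import braingap as bg
from braingap.atlas import ValidationError
from braingap.cohort import resolve_roi_params
from conftest import FIXTURE_BEHAVIOR, fixture_config, noiseless_config


class TestControls:
    def test_noiseless_volumes_lie_on_configured_line(self, fixture_atlas):
        config = noiseless_config(n_controls=10)
        baseline, slopes = resolve_roi_params(config, fixture_atlas)
        for p in bg.generate_controls(config, fixture_atlas):
            expected = baseline + slopes * p.age
            np.testing.assert_allclose(p.roi_volumes.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_same_seed_reproduces_cohort_exactly(self, fixture_atlas):
        config = fixture_config(n_controls=12)
        a = bg.generate_controls(config, fixture_atlas)
        b = bg.generate_controls(config, fixture_atlas)
        for x, y in zip(a, b):
            assert (x.id, x.age, x.sex, x.education, x.handedness) == (
                y.id, y.age, y.sex, y.education, y.handedness
            )
            np.testing.assert_array_equal(x.roi_volumes.to_numpy(), y.roi_volumes.to_numpy())

    def test_ols_recovers_configured_slopes_within_3_se(self, fixture_atlas):
        config = fixture_config(n_controls=200, seed=13)
        _, slopes = resolve_roi_params(config, fixture_atlas)
        controls = bg.generate_controls(config, fixture_atlas)
        ages = np.array([p.age for p in controls])
        X = np.column_stack([np.ones(len(ages)), ages])
        for roi in fixture_atlas.roi_ids:
            y = np.array([p.roi_volumes[roi] for p in controls])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(ages) - 2
            sigma2 = res[0] / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert abs(beta[1] - slopes[roi]) < 3 * se

    def test_ages_within_configured_range(self, fixture_atlas):
        config = fixture_config(age_range=(30.0, 40.0))
        for p in bg.generate_controls(config, fixture_atlas):
            assert 30.0 <= p.age <= 40.0


class TestPatients:
    def test_null_patients_exchangeable_with_controls(self, fixture_atlas):
        """Offset 0 and no lesions: patient volumes follow the control law."""
        config = fixture_config(
            n_controls=200,
            n_patients=200,
            premature_offset_years=0.0,
            lesion=bg.LesionSpec(radius_range_mm=(0.0, 0.0)),
            seed=17,
        )
        controls = bg.generate_controls(config, fixture_atlas)
        patients = bg.generate_patients(config, fixture_atlas)
        for roi in fixture_atlas.roi_ids[:4]:
            c = [p.roi_volumes[roi] for p in controls]
            s = [p.roi_volumes[roi] for p in patients]
            assert sps.ks_2samp(c, s).pvalue > 0.001

    def test_lesion_never_increases_volume(self, fixture_atlas):
        config = fixture_config(seed=23)
        null_lesion = dataclasses.replace(config, lesion=bg.LesionSpec(radius_range_mm=(0.0, 0.0)))
        lesioned = bg.generate_patients(config, fixture_atlas)
        counterfactual = bg.generate_patients(null_lesion, fixture_atlas)
        for a, b in zip(lesioned, counterfactual):
            assert (a.roi_volumes.to_numpy() <= b.roi_volumes.to_numpy() + 1e-15).all()

    def test_lesions_confined_to_left_hemisphere(self, fixture_atlas):
        config = fixture_config(seed=29)
        left = np.isin(
            fixture_atlas.labels, fixture_atlas.roi_ids_for_hemisphere("left")
        )
        for p in bg.generate_patients(config, fixture_atlas):
            assert not (p.lesion_mask & ~left).any()
            profile = bg.lesion_overlap(p.lesion_mask, fixture_atlas)
            assert p.lesion_volume == profile.lesion_volume

    def test_explicit_center_outside_left_labels_rejected(self, fixture_atlas):
        config = fixture_config(
            lesion=bg.LesionSpec(radius_range_mm=(4.0, 8.0), centers=((19, 19, 19),))
        )
        with pytest.raises(ValidationError, match="left-hemisphere"):
            bg.generate_patients(config, fixture_atlas)

    def test_total_left_coverage_forces_exclusion(self, fixture_atlas, fixture_groupings):
        # a lesion covering the whole left hemisphere leaves no intact ROI
        config = noiseless_config(n_patients=1)
        patients = bg.generate_patients(config, fixture_atlas)
        left = np.isin(
            fixture_atlas.labels, fixture_atlas.roi_ids_for_hemisphere("left")
        )
        p = dataclasses.replace(patients[0], lesion_mask=left,
                                lesion_volume=float(left.sum()) * fixture_atlas.voxel_volume)
        profile = bg.lesion_overlap(p.lesion_mask, fixture_atlas, p.id)
        grouping = [g for g in fixture_groupings if g.name == "left_domain_general"][0]
        assert bg.intact_rois(profile, grouping) == []


class TestBehavior:
    def _results_for(self, patients, gap=2.0, n_rois=4):
        rows = []
        for p in patients:
            rows.append(
                {
                    "participant_id": p.id,
                    "region": "left_domain_general",
                    "braingap": gap,
                    "excluded": False,
                    "n_rois": n_rois,
                    "roi_ids_used": tuple(p.roi_volumes.index[:n_rois]),
                }
            )
        return pd.DataFrame(rows)

    def test_constant_model_gives_constant_scores(self, fixture_atlas):
        coeffs = {s: bg.BehaviorCoeffs(93.8, 0, 0, 0, 0, 0) for s in FIXTURE_BEHAVIOR}
        config = fixture_config(behavior=coeffs)
        patients = bg.generate_patients(config, fixture_atlas)
        patients = bg.generate_behavior(patients, self._results_for(patients), config)
        assert all(p.behavior["aq"] == 93.8 for p in patients)

    def test_scores_clipped_to_0_100(self, fixture_atlas):
        coeffs = {s: bg.BehaviorCoeffs(150.0, 0, 0, 0, 0, 0) for s in FIXTURE_BEHAVIOR}
        config = fixture_config(behavior=coeffs)
        patients = bg.generate_patients(config, fixture_atlas)
        patients = bg.generate_behavior(patients, self._results_for(patients), config)
        assert all(p.behavior["aq"] == 100.0 for p in patients)

    def test_missing_gap_is_an_error_unless_excluded(self, fixture_atlas):
        config = fixture_config()
        patients = bg.generate_patients(config, fixture_atlas)
        results = self._results_for(patients).iloc[:-1]
        with pytest.raises(ValidationError, match="no 'left_domain_general' result"):
            bg.generate_behavior(patients, results, config)
        # excluded region: silently yields no behavior instead
        results = self._results_for(patients)
        results.loc[results.index[-1], "excluded"] = True
        out = bg.generate_behavior(patients, results, config)
        assert out[-1].behavior is None and out[0].behavior is not None


class TestSerialization:
    def test_round_trip_preserves_participants(self, tmp_path, fixture_atlas):
        config = fixture_config(n_controls=3, n_patients=2)
        participants = bg.generate_controls(config, fixture_atlas) + bg.generate_patients(
            config, fixture_atlas
        )
        participants[-1] = dataclasses.replace(
            participants[-1], behavior={s: 50.0 for s in FIXTURE_BEHAVIOR}
        )
        bg.write_cohort(participants, tmp_path / "cohort", fixture_atlas)
        loaded, atlas = bg.read_cohort(tmp_path / "cohort")
        assert len(loaded) == 5
        np.testing.assert_array_equal(atlas.labels, fixture_atlas.labels)
        for orig, back in zip(participants, loaded):
            assert orig.id == back.id and orig.group == back.group
            assert back.age == pytest.approx(orig.age, abs=0)
            np.testing.assert_array_equal(
                orig.roi_volumes.to_numpy(), back.roi_volumes.to_numpy()
            )
            if orig.lesion_mask is not None:
                np.testing.assert_array_equal(orig.lesion_mask, back.lesion_mask)
            assert back.behavior == orig.behavior

    def test_missing_lesion_mask_file_is_descriptive_error(self, tmp_path, fixture_atlas):
        config = fixture_config(n_controls=2, n_patients=1)
        participants = bg.generate_controls(config, fixture_atlas) + bg.generate_patients(
            config, fixture_atlas
        )
        out = bg.write_cohort(participants, tmp_path / "cohort", fixture_atlas)
        (out / "masks" / "P000_lesion.nii").unlink()
        with pytest.raises(ValidationError, match="P000"):
            bg.read_cohort(out)

    def test_refuses_nonempty_dir_without_force(self, tmp_path, fixture_atlas):
        config = fixture_config(n_controls=2, n_patients=1)
        participants = bg.generate_controls(config, fixture_atlas) + bg.generate_patients(
            config, fixture_atlas
        )
        out = bg.write_cohort(participants, tmp_path / "cohort", fixture_atlas)
        with pytest.raises(ValidationError, match="force"):
            bg.write_cohort(participants, out, fixture_atlas)
        bg.write_cohort(participants, out, fixture_atlas, force=True)

    def test_tsv_bytes_stable_across_runs(self, tmp_path, fixture_atlas):
        config = fixture_config(n_controls=3, n_patients=2)
        payloads = []
        for run in ("a", "b"):
            participants = bg.generate_controls(config, fixture_atlas) + bg.generate_patients(
                config, fixture_atlas
            )
            out = bg.write_cohort(participants, tmp_path / run, fixture_atlas)
            payloads.append(
                (out / "controls.tsv").read_bytes()
                + (out / "patients.tsv").read_bytes()
                + (out / "masks" / "P000_lesion.nii").read_bytes()
            )
        assert payloads[0] == payloads[1]


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValidationError):
            bg.CohortConfig(n_controls=0)

    def test_age_range_ordered(self):
        with pytest.raises(ValidationError):
            bg.CohortConfig(age_range=(80.0, 20.0))

    def test_bad_lesion_radius_rejected(self):
        with pytest.raises(ValidationError):
            bg.LesionSpec(radius_range_mm=(5.0, 2.0))
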
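"""Monte-Carlo calibration checks for the pipeline's test statistics.

These routines re-run the *entire* pipeline — generation, whole-brain screen,
lesion-adaptive regional estimation, statistics — under a true null many
times, so that the finite-sample rejection rate of each test can be compared
with its nominal level.  They operate on a reduced 16-parcel grid atlas to
keep hundreds of replicates cheap.

Two nulls are provided:

* :func:`null_interaction_pvalues` — no premature-aging offset and no
  lesions, so stroke participants are exchangeable with controls and the
  group x hemisphere ANCOVA interaction holds at its nominal level.
  (A lesioned zero-offset cohort is *not* a sharp null: partial-volume loss
  inside 99-100%-spared ROIs is a real left-lateralized signal.)
* :func:`null_behavior_pvalues` — behavior generated with every coefficient
  zero (pure noise), so each behavior-regression predictor holds at its
  nominal level.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .atlas import RegionGrouping, full_sparing, lesion_overlap
from .cohort import (
    BehaviorCoeffs,
    BEHAVIOR_SCORES,
    CohortConfig,
    LesionSpec,
    demo_roi_table,
    generate_behavior,
    generate_controls,
    generate_patients,
    synthetic_atlas,
)
from .normative import fit_global_model, partition_controls, predict_global_age
from .regional import ConditioningWarning, estimate_cohort
from .stats import RegressionSpec, behavior_regression, build_gap_table, mixed_ancova

__all__ = ["null_interaction_pvalues", "null_behavior_pvalues"]


def _demo_setup():
    atlas = synthetic_atlas(demo_roi_table(), shape=(20, 20, 20), voxel_dims=(2.0, 2.0, 2.0))
    left = tuple(int(r) for r in atlas.roi_ids_for_hemisphere("left"))
    right = tuple(int(r) for r in atlas.roi_ids_for_hemisphere("right"))
    groupings = [
        RegionGrouping(name="left_domain_general", side="left", roi_ids=left),
        RegionGrouping(name="right_domain_general", side="right", roi_ids=right),
    ]
    return atlas, groupings


def _estimate(config, atlas, groupings):
    controls = generate_controls(config, atlas)
    patients = generate_patients(config, atlas)
    model = fit_global_model(controls)
    ages = {p.id: predict_global_age(model, p) for p in controls}
    partition = partition_controls(controls, ages)
    within_ids = set(partition.within_range_ids)
    within = [p for p in controls if p.id in within_ids]
    out_of_range = [p for p in controls if p.id not in within_ids]
    targets = out_of_range + patients
    sparings = {
        p.id: (
            lesion_overlap(p.lesion_mask, atlas, p.id)
            if p.lesion_mask is not None
            else full_sparing(atlas, p.id)
        )
        for p in targets
    }
    results, _ = estimate_cohort(targets, sparings, within, groupings)
    return controls, patients, targets, results


def null_interaction_pvalues(
    n_reps: int,
    seed: int,
    n_controls: int = 60,
    n_patients: int = 24,
) -> np.ndarray:
    """Interaction p-values from full pipeline runs under the exchangeable null."""
    atlas, groupings = _demo_setup()
    root = np.random.SeedSequence(entropy=seed, spawn_key=(97,))
    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConditioningWarning)
        for rep_seed in root.generate_state(n_reps):
            config = CohortConfig(
                n_controls=n_controls,
                n_patients=n_patients,
                premature_offset_years=0.0,
                lesion=LesionSpec(radius_range_mm=(0.0, 0.0)),
                seed=int(rep_seed % 2**31),
            )
            _, _, targets, results = _estimate(config, atlas, groupings)
            table = build_gap_table(results, targets, "domain_general")
            effects = mixed_ancova(table).set_index("term")
            pvals.append(float(effects.loc["group:hemisphere", "p"]))
    return np.asarray(pvals)


def null_behavior_pvalues(
    n_reps: int,
    seed: int,
    n_controls: int = 60,
    n_patients: int = 30,
) -> np.ndarray:
    """Behavior-regression predictor p-values when behavior is pure noise.

    One lesioned cohort provides the predictors (BrainGAP, gray-matter
    volume, lesion volume, age, ROI count); each replicate regenerates all
    behavior scores with zero coefficients and fresh noise, so every
    predictor p-value is a draw from its null distribution.
    """
    atlas, groupings = _demo_setup()
    null_coeffs = {s: BehaviorCoeffs(50.0, 0.0, 0.0, 0.0, 0.0, 6.0) for s in BEHAVIOR_SCORES}
    base = CohortConfig(
        n_controls=n_controls,
        n_patients=n_patients,
        premature_offset_years=0.0,
        behavior=null_coeffs,
        seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(101,)).generate_state(1)[0] % 2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConditioningWarning)
        _, patients, _, results = _estimate(base, atlas, groupings)
        rep_seeds = np.random.SeedSequence(entropy=seed, spawn_key=(103,)).generate_state(n_reps)
        pvals = []
        for rep_seed in rep_seeds:
            config = dataclasses.replace(base, seed=int(rep_seed % 2**31))
            scored = generate_behavior(patients, results, config)
            out = behavior_regression(scored, results, RegressionSpec())
            for table in out.tables.values():
                mask = table["predictor"] != "const"
                pvals.extend(table.loc[mask, "p"].tolist())
    return np.asarray(pvals)
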
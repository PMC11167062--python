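"""Shared fixtures: a small 16-ROI grid atlas and cohort factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import braingap as bg
from braingap.atlas import RegionGrouping
from braingap.cohort import demo_roi_table as make_fixture_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_atlas() -> bg.AtlasDefinition:
    """20x20x20 grid atlas with 16 ROIs, 8 per hemisphere."""
    return bg.synthetic_atlas(make_fixture_table(), shape=(20, 20, 20), voxel_dims=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def fixture_groupings(fixture_atlas) -> list[RegionGrouping]:
    """Hemisphere == domain-general on the fixture (all 8 ROIs per side)."""
    left = tuple(int(r) for r in fixture_atlas.roi_ids_for_hemisphere("left"))
    right = tuple(int(r) for r in fixture_atlas.roi_ids_for_hemisphere("right"))
    return [
        RegionGrouping(name="left_hemisphere", side="left", roi_ids=left),
        RegionGrouping(name="right_hemisphere", side="right", roi_ids=right),
        RegionGrouping(name="left_domain_general", side="left", roi_ids=left),
        RegionGrouping(name="right_domain_general", side="right", roi_ids=right),
    ]


#: behavior coefficients scaled for the fixture atlas, where mean ROI volume
#: fractions are ~0.06 rather than ~0.004 (no clipping in the usual range)
FIXTURE_BEHAVIOR = {
    "aq": bg.BehaviorCoeffs(20.0, -0.5, 600.0, -0.0008, -0.2, 6.0),
    "naming": bg.BehaviorCoeffs(18.0, -0.4, 650.0, -0.0007, -0.15, 6.0),
    "spontaneous_speech": bg.BehaviorCoeffs(25.0, -0.3, 500.0, -0.0006, -0.25, 6.0),
    "repetition": bg.BehaviorCoeffs(22.0, -0.45, 550.0, -0.0007, -0.18, 6.0),
    "comprehension": bg.BehaviorCoeffs(28.0, -0.6, 450.0, -0.0009, -0.12, 5.0),
}


def fixture_config(**overrides) -> bg.CohortConfig:
    defaults = dict(
        n_controls=60,
        n_patients=20,
        seed=11,
        behavior=FIXTURE_BEHAVIOR,
    )
    defaults.update(overrides)
    return bg.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort(fixture_atlas, fixture_groupings):
    """A lesioned fixture-scale cohort with behavior, simulated once."""
    cohort = bg.simulate_cohort(
        fixture_config(n_controls=80, n_patients=30, seed=5),
        atlas=fixture_atlas,
        groupings=fixture_groupings,
    )
    return cohort


def noiseless_config(**overrides) -> bg.CohortConfig:
    """All volume and brain-age noise off: volumes exactly on their age lines."""
    defaults = dict(noise_sd=0.0, brainage_sd=0.0)
    defaults.update(overrides)
    return fixture_config(**defaults)
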
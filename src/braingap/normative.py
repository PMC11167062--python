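"""Whole-brain brain-age surrogate and the within/out-of-range control split.

The analysis screens controls with a whole-brain brain-age model (in
practice often a pretrained external estimator): only controls whose
estimated whole-brain age falls within
5% of their chronological age ("within-range") are allowed to train the
regional normative models; the rest ("out-of-range") become the comparison
group.  That pretrained Gaussian-process model and its training corpus are
not redistributable, so this module provides a structural surrogate — PCA on
ROI gray-matter volumes retaining a configured variance fraction (default
0.80), followed by linear regression of age on the retained components — plus
a bypass: externally computed whole-brain ages can be supplied per participant
(``Participant.global_brain_age``) and the surrogate is then never fitted.

The 5% band is read as ``|brain_age - chronological_age| <= 0.05 *
chronological_age`` (inclusive): a brain age of 82 at chronological age 80
is within range, 85 is not.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import ValidationError
from .cohort import Participant

__all__ = [
    "GlobalAgeModel",
    "ControlPartition",
    "fit_global_model",
    "predict_global_age",
    "partition_controls",
    "DEFAULT_VARIANCE_FRACTION",
    "DEFAULT_TOLERANCE_FRACTION",
]

DEFAULT_VARIANCE_FRACTION = 0.80
DEFAULT_TOLERANCE_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class GlobalAgeModel:
    """PCA + linear-regression surrogate for whole-brain age."""

    roi_ids: tuple[int, ...]
    mean_volumes: np.ndarray  # feature means (p,)
    components: np.ndarray  # (k, p) principal axes
    explained_variance_ratio: np.ndarray  # full spectrum, descending
    variance_fraction: float  # configured retention target
    intercept: float
    coef: np.ndarray  # (k,) weights on component scores
    training_ids: tuple[str, ...]
    training_residuals: np.ndarray  # age - fitted, training order

    @property
    def n_components(self) -> int:
        return len(self.coef)

    @property
    def variance_retained(self) -> float:
        return float(self.explained_variance_ratio[: self.n_components].sum())


def _volume_matrix(
    participants: Sequence[Participant], roi_ids: Sequence[int]
) -> np.ndarray:
    rows = []
    for p in participants:
        v = p.roi_volumes.reindex(list(roi_ids))
        if v.isna().any():
            missing = list(v.index[v.isna()])[:5]
            raise ValidationError(f"participant {p.id} missing ROI volumes {missing}")
        rows.append(v.to_numpy(dtype=float))
    return np.asarray(rows)


def fit_global_model(
    controls: Sequence[Participant],
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> GlobalAgeModel:
    """Fit the surrogate on a control cohort.

    Principal components are ordered by explained variance and the smallest
    prefix whose cumulative explained-variance ratio reaches
    ``variance_fraction`` is retained (zero-variance directions are never
    retained, so constant features are handled by construction).
    Chronological age is then regressed on the retained component scores by
    ordinary least squares.
    """
    if len(controls) < 2:
        raise ValidationError("fitting the global model requires >= 2 controls")
    if not 0 < variance_fraction <= 1:
        raise ValidationError(f"variance_fraction must lie in (0, 1], got {variance_fraction}")
    roi_ids = tuple(int(r) for r in controls[0].roi_volumes.index)
    X = _volume_matrix(controls, roi_ids)
    ages = np.array([p.age for p in controls], dtype=float)

    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2 / max(len(controls) - 1, 1)
    total = var.sum()
    if total <= 0:
        # all features constant: no components, predict the mean age
        ratio = np.zeros_like(var)
        k = 0
    else:
        ratio = var / total
        nonzero = int((svals > svals[0] * 1e-12).sum())
        cum = np.cumsum(ratio)
        k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        k = min(k, nonzero)
    components = Vt[:k]
    scores = Xc @ components.T

    design = np.column_stack([np.ones(len(controls))] + ([scores] if k else []))
    beta, *_ = np.linalg.lstsq(design, ages, rcond=None)
    fitted = design @ beta
    return GlobalAgeModel(
        roi_ids=roi_ids,
        mean_volumes=mean,
        components=components,
        explained_variance_ratio=ratio,
        variance_fraction=float(variance_fraction),
        intercept=float(beta[0]),
        coef=beta[1:],
        training_ids=tuple(p.id for p in controls),
        training_residuals=ages - fitted,
    )


def predict_global_age(model: GlobalAgeModel, participant: Participant) -> float:
    """Estimate whole-brain age; affine in the full ROI volume vector.

    The global model describes an intact brain, so every ROI of the training
    feature set must be present.
    """
    v = participant.roi_volumes.reindex(list(model.roi_ids))
    if v.isna().any():
        missing = list(v.index[v.isna()])[:5]
        raise ValidationError(
            f"participant {participant.id} missing ROI volumes {missing}; "
            "the global model requires the full ROI vector"
        )
    scores = (v.to_numpy(dtype=float) - model.mean_volumes) @ model.components.T
    return float(model.intercept + scores @ model.coef)


@dataclasses.dataclass(frozen=True)
class ControlPartition:
    """Disjoint within-range / out-of-range split of the control cohort."""

    within_range_ids: tuple[str, ...]
    out_of_range_ids: tuple[str, ...]
    tolerance_fraction: float

    def __post_init__(self) -> None:
        if set(self.within_range_ids) & set(self.out_of_range_ids):
            raise ValidationError("partition sets must be disjoint")


def partition_controls(
    controls: Sequence[Participant],
    brain_ages: Mapping[str, float] | Sequence[float],
    tolerance_fraction: float = DEFAULT_TOLERANCE_FRACTION,
) -> ControlPartition:
    """Split controls into within-range and out-of-range sets.

    A control is within range iff ``|brain_age - age| <= tolerance_fraction *
    age`` (inclusive: a gap of exactly 5% of age stays within range).  Brain
    ages may come from :func:`predict_global_age` or from an external model.
    """
    if not 0 < tolerance_fraction < 1:
        raise ValidationError(f"tolerance_fraction must lie in (0, 1), got {tolerance_fraction}")
    if not isinstance(brain_ages, Mapping):
        if len(brain_ages) != len(controls):
            raise ValidationError("brain_ages length does not match controls")
        brain_ages = {p.id: float(b) for p, b in zip(controls, brain_ages)}
    within, outside = [], []
    for p in controls:
        if p.age <= 0:
            raise ValidationError(f"participant {p.id} has non-positive chronological age")
        if p.id not in brain_ages:
            raise ValidationError(f"no brain age supplied for control {p.id}")
        gap = abs(float(brain_ages[p.id]) - p.age)
        (within if gap <= tolerance_fraction * p.age else outside).append(p.id)
    return ControlPartition(
        within_range_ids=tuple(within),
        out_of_range_ids=tuple(outside),
        tolerance_fraction=float(tolerance_fraction),
    )


def partition_table(
    controls: Sequence[Participant],
    brain_ages: Mapping[str, float],
    partition: ControlPartition,
) -> pd.DataFrame:
    """Per-control gap and flag, for the partition TSV output."""
    rows = []
    within = set(partition.within_range_ids)
    for p in controls:
        ba = float(brain_ages[p.id])
        rows.append(
            {
                "participant_id": p.id,
                "age": p.age,
                "global_brain_age": ba,
                "gap": ba - p.age,
                "within_range": p.id in within,
            }
        )
    return pd.DataFrame(rows)
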
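"""Lesion-adaptive regional normative models, regional brain age and BrainGAP.

This is the core engine.  For one participant and one region (a named set of
ROIs), the ROIs at least 99% spared by the participant's lesion are selected;
chronological age is regressed by ordinary least squares on those ROIs'
gray-matter volumes across the within-range controls; the participant's own
volumes are entered into the fitted model to yield a regional brain age; and

    BrainGAP = brain age - chronological age,

positive values meaning the region looks older than the participant is
(premature regional aging).  Because every participant has a different lesion,
every participant gets their own control regression per region; a region with
zero intact ROIs is excluded (flagged, no model fit, no downstream rows).

Plain unpenalized OLS is used throughout: a single-ROI model then predicts an
age perfectly (anti)correlated with that ROI's volume, which is the property
the analysis relies on when interpreting volume-vs-brain-age correlations.
Rank-deficient or under-determined designs raise :class:`ModelFitError` —
never a silent pseudo-inverse fit.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import (
    DEFAULT_SPARING_THRESHOLD,
    RegionGrouping,
    SparingProfile,
    ValidationError,
    intact_rois,
)
from .cohort import Participant

__all__ = [
    "ModelFitError",
    "ConditioningWarning",
    "RegionalModel",
    "RegionalAgeResult",
    "braingap",
    "fit_regional_model",
    "predict_regional_age",
    "estimate_participant",
    "estimate_cohort",
    "results_table",
    "residual_diagnostics",
    "ResidualDiagnostics",
]


class ModelFitError(RuntimeError):
    """A regional control regression could not be fitted validly."""


class ConditioningWarning(UserWarning):
    """The design is fittable but poorly conditioned (few controls per ROI)."""


@dataclasses.dataclass(frozen=True)
class RegionalModel:
    """One participant-specific normative regression for one region."""

    participant_id: str
    region_name: str
    roi_ids_used: tuple[int, ...]
    coef: np.ndarray  # [intercept, one weight per ROI]
    control_residuals: np.ndarray  # actual age - fitted age, per within-range control
    control_ids: tuple[str, ...]

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids_used)


@dataclasses.dataclass(frozen=True)
class RegionalAgeResult:
    """Brain age and BrainGAP of one participant in one region."""

    participant_id: str
    region_name: str
    brain_age: float  # NaN when excluded
    braingap: float  # NaN when excluded
    n_rois: int
    excluded: bool
    roi_ids_used: tuple[int, ...]


def braingap(brain_age: float, chronological_age: float) -> float:
    """Brain-age gap: brain age minus chronological age, in years."""
    if not (math.isfinite(brain_age) and math.isfinite(chronological_age)):
        raise ValidationError("braingap requires finite ages")
    return float(brain_age) - float(chronological_age)


def fit_regional_model(
    within_range_controls: Sequence[Participant],
    roi_subset: Sequence[int],
    region_name: str,
    participant_id: str = "",
) -> RegionalModel:
    """OLS of chronological age on a ROI subset's volumes over controls.

    Requires ``#controls > #ROIs + 1`` and a full-column-rank design; both
    violations raise :class:`ModelFitError`.  When the fit is legal but there
    are fewer than three controls per ROI, a :class:`ConditioningWarning` is
    emitted (the whole-hemisphere models are in this near-saturated regime).
    """
    roi_subset = tuple(int(r) for r in roi_subset)
    if len(roi_subset) < 1:
        raise ModelFitError(f"{region_name}: empty ROI subset")
    n, p = len(within_range_controls), len(roi_subset)
    if n <= p + 1:
        raise ModelFitError(
            f"{region_name}: {n} within-range controls cannot identify a model "
            f"with {p} ROIs (need n > p + 1)"
        )
    X = np.empty((n, p + 1))
    X[:, 0] = 1.0
    for j, c in enumerate(within_range_controls):
        v = c.roi_volumes.reindex(list(roi_subset))
        if v.isna().any():
            raise ValidationError(f"control {c.id} missing volumes for {region_name}")
        X[j, 1:] = v.to_numpy(dtype=float)
    ages = np.array([c.age for c in within_range_controls], dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, ages, rcond=None)
    if rank < p + 1:
        raise ModelFitError(
            f"{region_name}: rank-deficient design (rank {rank} < {p + 1}); "
            "collinear or constant ROI volumes"
        )
    if n < 3 * p:
        warnings.warn(
            f"{region_name}: only {n} controls for {p} ROIs; "
            "coefficients are poorly conditioned",
            ConditioningWarning,
            stacklevel=2,
        )
    residuals = ages - X @ coef
    return RegionalModel(
        participant_id=participant_id,
        region_name=region_name,
        roi_ids_used=roi_subset,
        coef=coef,
        control_residuals=residuals,
        control_ids=tuple(c.id for c in within_range_controls),
    )


def predict_regional_age(
    model: RegionalModel, participant_roi_volumes: Mapping[int, float] | pd.Series
) -> float:
    """Affine evaluation of a fitted regional model at a participant's volumes."""
    vols = pd.Series(participant_roi_volumes).reindex(list(model.roi_ids_used))
    if vols.isna().any():
        missing = list(vols.index[vols.isna()])[:5]
        raise ValidationError(
            f"missing volumes {missing} for model {model.region_name!r}"
        )
    return float(model.coef[0] + vols.to_numpy(dtype=float) @ model.coef[1:])


def estimate_participant(
    participant: Participant,
    groupings: Sequence[RegionGrouping],
    sparing: SparingProfile,
    within_range_controls: Sequence[Participant],
    threshold: float = DEFAULT_SPARING_THRESHOLD,
    _cache: dict | None = None,
) -> tuple[list[RegionalAgeResult], dict[str, RegionalModel]]:
    """Estimate regional brain age for one participant across all groupings.

    For each grouping: select intact ROIs, fit the control regression (cached
    by (region, subset) so identical subsets share one fit), predict, and form
    the gap.  A region with zero intact ROIs yields an excluded result and no
    model.  Controls pass an all-spared profile, so every region uses its full
    ROI list for them.
    """
    results: list[RegionalAgeResult] = []
    models: dict[str, RegionalModel] = {}
    cache = _cache if _cache is not None else {}
    for grouping in groupings:
        rois = intact_rois(sparing, grouping, threshold)
        if not rois:
            results.append(
                RegionalAgeResult(
                    participant_id=participant.id,
                    region_name=grouping.name,
                    brain_age=float("nan"),
                    braingap=float("nan"),
                    n_rois=0,
                    excluded=True,
                    roi_ids_used=(),
                )
            )
            continue
        key = (grouping.name, tuple(rois))
        try:
            model = cache.get(key)
            if model is None:
                model = fit_regional_model(
                    within_range_controls, rois, grouping.name, participant.id
                )
                cache[key] = model
        except ModelFitError as err:
            raise ModelFitError(
                f"participant {participant.id}, region {grouping.name}: {err}"
            ) from err
        brain_age = predict_regional_age(model, participant.roi_volumes)
        results.append(
            RegionalAgeResult(
                participant_id=participant.id,
                region_name=grouping.name,
                brain_age=brain_age,
                braingap=braingap(brain_age, participant.age),
                n_rois=model.n_rois,
                excluded=False,
                roi_ids_used=tuple(rois),
            )
        )
        models[grouping.name] = model
    return results, models


def estimate_cohort(
    participants: Sequence[Participant],
    sparings: Mapping[str, SparingProfile],
    within_range_controls: Sequence[Participant],
    groupings: Sequence[RegionGrouping],
    threshold: float = DEFAULT_SPARING_THRESHOLD,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RegionalModel]]:
    """Regional estimation for many participants; shares fits across them."""
    cache: dict = {}
    all_results: list[RegionalAgeResult] = []
    all_models: dict[tuple[str, str], RegionalModel] = {}
    for p in participants:
        results, models = estimate_participant(
            p, groupings, sparings[p.id], within_range_controls, threshold, _cache=cache
        )
        all_results.extend(results)
        for region, model in models.items():
            all_models[(p.id, region)] = model
    return results_table(all_results), all_models


def results_table(results: Sequence[RegionalAgeResult]) -> pd.DataFrame:
    """Long results table; excluded regions stay as flagged rows (auditable)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "region": [r.region_name for r in results],
            "n_rois": [r.n_rois for r in results],
            "brain_age": [r.brain_age for r in results],
            "braingap": [r.braingap for r in results],
            "excluded": [r.excluded for r in results],
            "roi_ids_used": [r.roi_ids_used for r in results],
        }
    )


@dataclasses.dataclass(frozen=True)
class ResidualDiagnostics:
    """Dispersion of control residuals vs. number of ROIs used."""

    region_name: str
    table: pd.DataFrame  # participant_id, n_rois, residual_mean, residual_sd
    r_sd: float
    p_sd: float
    r_mean: float
    p_mean: float
    note: str = ""


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.any(~np.isfinite(y)):
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def residual_diagnostics(
    models_by_participant: Mapping[str, RegionalModel],
    region_name: str,
) -> ResidualDiagnostics:
    """Relate per-model control-residual dispersion to the ROI count.

    For each participant's model in the region, the mean and standard
    deviation of its in-sample control residuals are computed, then Pearson
    correlations of the ROI count with each are reported.  When every
    participant shares the same ROI count (or a dispersion column is
    degenerate) the correlation is reported as undefined (NaN) with a note,
    never an exception.
    """
    if len(models_by_participant) < 3:
        raise ValidationError(
            f"residual diagnostics for {region_name!r} need >= 3 fitted participants"
        )
    rows = []
    for pid, model in models_by_participant.items():
        res = model.control_residuals
        rows.append(
            {
                "participant_id": pid,
                "n_rois": model.n_rois,
                "residual_mean": float(res.mean()),
                "residual_sd": float(res.std(ddof=1)) if len(res) > 1 else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    n_rois = table["n_rois"].to_numpy(dtype=float)
    note = ""
    if np.ptp(n_rois) == 0:
        note = "all participants share the same ROI count; correlations undefined"
    r_sd, p_sd = _safe_pearson(n_rois, table["residual_sd"].to_numpy())
    means = table["residual_mean"].to_numpy()
    sds = table["residual_sd"].to_numpy()
    scale = np.nanmax(np.abs(sds)) if len(sds) else 0.0
    if np.all(np.abs(means) <= max(scale, 1.0) * 1e-9):
        # in-sample OLS residuals with an intercept have mean exactly zero;
        # correlating rounding noise would be meaningless
        means = np.zeros_like(means)
        note = (note + "; " if note else "") + (
            "residual means are zero by construction (intercept OLS); "
            "mean correlation undefined"
        )
    r_mean, p_mean = _safe_pearson(n_rois, means)
    return ResidualDiagnostics(
        region_name=region_name,
        table=table,
        r_sd=r_sd,
        p_sd=p_sd,
        r_mean=r_mean,
        p_mean=p_mean,
        note=note,
    )
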
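"""The statistical battery over regional BrainGAP results and behavior.

Stages (each a pure function of its input table):

* :func:`mixed_ancova` — 2 (group: out-of-range control vs stroke) x 2
  (hemisphere: left vs right, within-participant) ANCOVA on regional
  BrainGAP with chronological age, education, sex and handedness as
  covariates.
* :func:`group_ttest` — independent-samples t-test with descriptives.
* :func:`correlation_battery` — Pearson r/p per named comparison with a
  Bonferroni-adjusted alpha (0.05/7 for the left-vs-right family, 0.05/14
  for the age-vs-volume family).
* :func:`behavior_regression` — per behavioral score, OLS of the score on
  BrainGAP, regional gray-matter volume, lesion volume, age and the number
  of ROIs used, at the family-adjusted alpha 0.05/5 = 0.01.

The mixed ANCOVA is computed by the exact decomposition of the balanced
two-condition repeated-measures design: between-participant terms (group and
covariates) are tested by OLS on participant hemisphere means; the hemisphere
main effect and the group x hemisphere interaction are tested by OLS on the
left-minus-right differences with sum-coded group and centered covariates.
For this design the decomposition coincides with a participant-level
random-intercept model but yields exact finite-sample F tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .atlas import ValidationError
from .cohort import BEHAVIOR_SCORES, Participant, region_gm_volume
from .regional import ConditioningWarning

__all__ = [
    "build_gap_table",
    "mixed_ancova",
    "TTestResult",
    "group_ttest",
    "correlation_battery",
    "RegressionSpec",
    "BehaviorRegressionResult",
    "behavior_regression",
]

_COVARIATES = ("age", "education", "sex", "handedness")
_CATEGORICAL = {"sex", "handedness"}


def build_gap_table(
    results: pd.DataFrame,
    participants: Sequence[Participant],
    family: str = "domain_general",
) -> pd.DataFrame:
    """Long table of left/right BrainGAP rows for a region family.

    One row per participant x hemisphere; participants lacking a
    non-excluded result in either hemisphere contribute no rows (excluded
    regions never reach downstream statistics).  Controls are labelled
    ``out_of_range_control`` — within-range controls train the models and by
    construction cannot appear here.
    """
    by_id = {p.id: p for p in participants}
    usable = results[~results["excluded"]]
    rows = []
    for pid, sub in usable.groupby("participant_id", sort=False):
        if pid not in by_id:
            continue
        sub = sub.set_index("region")
        left, right = f"left_{family}", f"right_{family}"
        if left not in sub.index or right not in sub.index:
            continue
        p = by_id[pid]
        group = "stroke" if p.group == "stroke" else "out_of_range_control"
        for hemisphere, region in (("left", left), ("right", right)):
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "hemisphere": hemisphere,
                    "region": region,
                    "braingap": float(sub.loc[region, "braingap"]),
                    "age": p.age,
                    "education": p.education,
                    "sex": p.sex,
                    "handedness": p.handedness,
                }
            )
    return pd.DataFrame(rows)


def _anova_row(table: pd.DataFrame, label: str) -> tuple[float, float, float]:
    row = table.loc[label]
    return float(row["F"]), float(row["df"]), float(row["PR(>F)"])


def mixed_ancova(
    table: pd.DataFrame, covariates: Sequence[str] = _COVARIATES
) -> pd.DataFrame:
    """Mixed-design 2x2 ANCOVA on a long BrainGAP table.

    Returns one row per term — ``group``, each covariate, ``hemisphere``,
    ``group:hemisphere`` — with F, df1, df2 and p.  Requires both hemispheres
    for every participant and both group levels.
    """
    required = {"participant_id", "group", "hemisphere", "braingap"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"gap table missing columns {sorted(missing)}")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValidationError(
            f"mixed ANCOVA needs both group levels; only {groups} present"
        )
    wide = table.pivot_table(
        index="participant_id", columns="hemisphere", values="braingap"
    )
    if wide.isna().any().any() or not {"left", "right"} <= set(wide.columns):
        raise ValidationError("every participant needs both hemispheres")
    meta = table.drop_duplicates("participant_id").set_index("participant_id")
    data = pd.DataFrame(
        {
            "mean_gap": (wide["left"] + wide["right"]) / 2.0,
            "diff_gap": wide["left"] - wide["right"],
            "group": meta["group"],
        }
    )
    used_covariates = []
    for cov in covariates:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} missing from gap table")
        if cov in _CATEGORICAL and meta[cov].nunique() < 2:
            continue  # single observed level carries no information
        data[cov] = meta[cov]
        used_covariates.append(cov)

    def term(cov: str, coding: str = "") -> str:
        if cov in _CATEGORICAL:
            return f"C({cov}{coding})"
        return cov if not coding else f"{cov}_c"

    # Between-participant stratum: participant means
    between_formula = "mean_gap ~ C(group) + " + " + ".join(
        term(c) for c in used_covariates
    ) if used_covariates else "mean_gap ~ C(group)"
    between_fit = smf.ols(between_formula, data=data).fit()
    between_anova = anova_lm(between_fit, typ=2)

    # Within-participant stratum: left-right differences, sum-coded group and
    # centered covariates so the intercept is the hemisphere main effect.
    diff_data = data.copy()
    for cov in used_covariates:
        if cov not in _CATEGORICAL:
            diff_data[f"{cov}_c"] = diff_data[cov] - diff_data[cov].mean()
    diff_terms = ["C(group, Sum)"] + [term(c, ", Sum") for c in used_covariates]
    diff_fit = smf.ols("diff_gap ~ " + " + ".join(diff_terms), data=diff_data).fit()
    diff_anova = anova_lm(diff_fit, typ=2)
    df2_within = float(diff_fit.df_resid)

    rows = []
    f, df1, p = _anova_row(between_anova, "C(group)")
    rows.append(("group", f, df1, float(between_fit.df_resid), p))
    for cov in used_covariates:
        f, df1, p = _anova_row(between_anova, term(cov))
        rows.append((cov, f, df1, float(between_fit.df_resid), p))
    hemi = diff_fit.t_test("Intercept = 0")
    rows.append(
        ("hemisphere", float(hemi.tvalue[0, 0] ** 2), 1.0, df2_within, float(hemi.pvalue))
    )
    f, df1, p = _anova_row(diff_anova, "C(group, Sum)")
    rows.append(("group:hemisphere", f, df1, df2_within, p))
    return pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p"])


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def group_ttest(ages_a: Sequence[float], ages_b: Sequence[float]) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance) with descriptives."""
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs >= 2 observations")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        # degenerate: no variability anywhere
        t = 0.0 if a.mean() == b.mean() else float("inf") * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
    )


def correlation_battery(
    comparisons: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    base_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r/p per named comparison with a Bonferroni-adjusted alpha.

    The adjusted alpha is ``base_alpha / #comparisons`` and the significance
    flag marks exactly those comparisons with ``p < adjusted alpha``.
    Comparisons with fewer than 3 complete pairs are reported as undefined.
    The adjusted alpha is exposed as ``result.attrs["adjusted_alpha"]``.
    """
    if not comparisons:
        raise ValidationError("correlation battery needs at least one comparison")
    alpha = base_alpha / len(comparisons)
    rows = []
    for name, (x, y) in comparisons.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValidationError(f"comparison {name!r}: unequal lengths")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 3:
            rows.append((name, float("nan"), float("nan"), len(x), False, "fewer than 3 pairs"))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((name, float(r), float(p), len(x), bool(p < alpha), ""))
    out = pd.DataFrame(rows, columns=["comparison", "r", "p", "n", "significant", "note"])
    out.attrs["adjusted_alpha"] = alpha
    out.attrs["base_alpha"] = base_alpha
    return out


@dataclasses.dataclass(frozen=True)
class RegressionSpec:
    """Behavior-regression family: dependents, predictors, adjusted alpha."""

    dependents: tuple[str, ...] = BEHAVIOR_SCORES
    predictors: tuple[str, ...] = ("braingap", "gm_volume", "lesion_volume", "age", "n_rois")
    base_alpha: float = 0.05

    @property
    def alpha(self) -> float:
        """Family-adjusted per-test level, e.g. 0.05/5 = 0.01."""
        return self.base_alpha / len(self.dependents)


@dataclasses.dataclass(frozen=True)
class BehaviorRegressionResult:
    region: str
    alpha: float
    tables: dict[str, pd.DataFrame]  # score -> coefficient table
    data: pd.DataFrame
    notes: tuple[str, ...] = ()


def _predictor_frame(
    patients: Sequence[Participant], results: pd.DataFrame, region: str
) -> pd.DataFrame:
    rows = results[(results["region"] == region) & (~results["excluded"])]
    rows = rows.set_index("participant_id")
    data = []
    for p in patients:
        if p.id not in rows.index or p.behavior is None:
            continue
        row = rows.loc[p.id]
        entry = {
            "participant_id": p.id,
            "braingap": float(row["braingap"]),
            "gm_volume": region_gm_volume(p, list(row["roi_ids_used"])),
            "lesion_volume": p.lesion_volume,
            "age": p.age,
            "n_rois": float(row["n_rois"]),
        }
        entry.update({s: p.behavior.get(s, np.nan) for s in BEHAVIOR_SCORES})
        data.append(entry)
    return pd.DataFrame(data)


def behavior_regression(
    patients: Sequence[Participant],
    results: pd.DataFrame,
    spec: RegressionSpec = RegressionSpec(),
    region: str = "left_domain_general",
) -> BehaviorRegressionResult:
    """OLS of each behavioral score on the five regional predictors.

    Patients whose target region is excluded or who lack behavior are
    dropped.  Predictors that are constant across the remaining patients are
    removed (reported in ``notes``) rather than fitted against a singular
    design; a variance-inflation report is emitted as a
    :class:`ConditioningWarning` when any retained predictor has VIF > 10.
    """
    data = _predictor_frame(patients, results, region)
    notes: list[str] = []
    if len(data) < len(spec.predictors) + 2:
        raise ValidationError(
            f"behavior regression needs more patients ({len(data)}) than predictors"
        )
    predictors = []
    for name in spec.predictors:
        if np.ptp(data[name].to_numpy(dtype=float)) == 0:
            notes.append(f"predictor {name!r} is constant; dropped from the design")
        else:
            predictors.append(name)
    X = sm.add_constant(data[predictors].astype(float))
    vifs = {
        name: variance_inflation_factor(X.to_numpy(), j)
        for j, name in enumerate(X.columns)
        if name != "const"
    }
    if any(v > 10 for v in vifs.values()):
        warnings.warn(
            "collinear behavior predictors; VIF: "
            + ", ".join(f"{k}={v:.1f}" for k, v in vifs.items()),
            ConditioningWarning,
            stacklevel=2,
        )
    tables = {}
    for score in spec.dependents:
        y = data[score].astype(float)
        fit = sm.OLS(y, X, missing="drop").fit()
        tables[score] = pd.DataFrame(
            {
                "predictor": X.columns,
                "beta": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(),
                "t": fit.tvalues.to_numpy(),
                "p": fit.pvalues.to_numpy(),
                "significant": fit.pvalues.to_numpy() < spec.alpha,
            }
        )
    return BehaviorRegressionResult(
        region=region,
        alpha=spec.alpha,
        tables=tables,
        data=data,
        notes=tuple(notes),
    )
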
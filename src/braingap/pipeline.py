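"""End-to-end orchestration: simulate -> screen -> regional -> statistics."""

from __future__ import annotations

import dataclasses
import json
import pathlib
from collections.abc import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    AtlasDefinition,
    DEFAULT_SPARING_THRESHOLD,
    RegionGrouping,
    SparingProfile,
    ValidationError,
    full_sparing,
    lesion_overlap,
    load_region_groupings,
    packaged_groupings_path,
)
from .cohort import (
    CohortConfig,
    Participant,
    generate_behavior,
    generate_controls,
    generate_patients,
    packaged_synthetic_atlas,
)
from .normative import (
    DEFAULT_TOLERANCE_FRACTION,
    DEFAULT_VARIANCE_FRACTION,
    ControlPartition,
    fit_global_model,
    partition_controls,
    partition_table,
    predict_global_age,
)
from .regional import ResidualDiagnostics, estimate_cohort, residual_diagnostics
from .stats import (
    BehaviorRegressionResult,
    RegressionSpec,
    TTestResult,
    behavior_regression,
    build_gap_table,
    correlation_battery,
    group_ttest,
    mixed_ancova,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "SimulatedCohort",
    "default_groupings",
    "simulate_cohort",
    "run_analysis",
    "write_outputs",
]

REGION_FAMILIES = (
    "hemisphere",
    "language_specific",
    "domain_general",
    "frontal",
    "temporal",
    "parietal",
    "occipital",
)


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and stage toggles for a full analysis run."""

    sparing_threshold: float = DEFAULT_SPARING_THRESHOLD
    tolerance_fraction: float = DEFAULT_TOLERANCE_FRACTION
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION
    base_alpha: float = 0.05
    behavior_region: str = "left_domain_general"
    ancova_family: str = "domain_general"
    region_families: tuple[str, ...] = REGION_FAMILIES
    run_stats: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sparing_threshold <= 1:
            raise ValidationError("sparing_threshold must lie in (0, 1]")
        if not 0 < self.tolerance_fraction < 1:
            raise ValidationError("tolerance_fraction must lie in (0, 1)")
        if not 0 < self.variance_fraction <= 1:
            raise ValidationError("variance_fraction must lie in (0, 1]")
        if not 0 < self.base_alpha < 1:
            raise ValidationError("base_alpha must lie in (0, 1)")


@dataclasses.dataclass
class SimulatedCohort:
    participants: list[Participant]
    atlas: AtlasDefinition
    groupings: list[RegionGrouping]
    truth: dict


@dataclasses.dataclass
class AnalysisResult:
    partition: ControlPartition
    partition_frame: pd.DataFrame
    results: pd.DataFrame
    models: dict
    gap_table: pd.DataFrame
    ancova: pd.DataFrame | None
    age_ttest: TTestResult | None
    correlations_lr: pd.DataFrame | None
    correlations_age_volume: pd.DataFrame | None
    diagnostics: dict[str, ResidualDiagnostics]
    behavior: BehaviorRegressionResult | None
    report: dict


def default_groupings(atlas: AtlasDefinition) -> list[RegionGrouping]:
    """The packaged region groupings, validated against ``atlas``."""
    import importlib.resources

    with importlib.resources.as_file(packaged_groupings_path()) as path:
        return load_region_groupings(path, atlas)


def _filter_groupings(
    groupings: Sequence[RegionGrouping], families: Sequence[str]
) -> list[RegionGrouping]:
    wanted = [
        g
        for g in groupings
        if any(g.name == f"{side}_{fam}" for fam in families for side in ("left", "right"))
    ]
    if not wanted:
        raise ValidationError(f"no groupings match region families {list(families)}")
    return wanted


def simulate_cohort(
    config: CohortConfig,
    atlas: AtlasDefinition | None = None,
    groupings: Sequence[RegionGrouping] | None = None,
    analysis: AnalysisConfig | None = None,
) -> SimulatedCohort:
    """Generate a full cohort with behavior and a ground-truth sidecar.

    Behavior is generated from each patient's left domain-general BrainGAP as
    the default analysis settings would compute it (surrogate screen on the
    controls, lesion-adaptive regional fit on the within-range subset).
    """
    analysis = analysis or AnalysisConfig()
    if atlas is None:
        atlas = packaged_synthetic_atlas()
    groupings = list(groupings) if groupings is not None else default_groupings(atlas)
    controls = generate_controls(config, atlas)
    patients = generate_patients(config, atlas)

    model = fit_global_model(controls, analysis.variance_fraction)
    ages = {p.id: predict_global_age(model, p) for p in controls}
    partition = partition_controls(controls, ages, analysis.tolerance_fraction)
    within = [p for p in controls if p.id in set(partition.within_range_ids)]

    behavior_groupings = [g for g in groupings if g.name == config_region(analysis)]
    sparings = {
        p.id: lesion_overlap(p.lesion_mask, atlas, p.id) for p in patients
    }
    results, _ = estimate_cohort(
        patients, sparings, within, behavior_groupings, analysis.sparing_threshold
    )
    patients = generate_behavior(patients, results, config, region=config_region(analysis))

    truth = {
        "seed": config.seed,
        "premature_offset_years": config.premature_offset_years,
        "brainage_sd": config.brainage_sd,
        "noise_sd": config.noise_sd,
        "behavior_coeffs": {
            score: dataclasses.asdict(c) for score, c in config.behavior.items()
        },
        "behavior_region": config_region(analysis),
        "n_within_range": len(partition.within_range_ids),
        "n_out_of_range": len(partition.out_of_range_ids),
    }
    return SimulatedCohort(
        participants=controls + patients, atlas=atlas, groupings=groupings, truth=truth
    )


def config_region(analysis: AnalysisConfig) -> str:
    return analysis.behavior_region


def _regional_gm(results: pd.DataFrame, by_id: dict, region: str) -> pd.Series:
    """Mean gm volume over each participant's used ROIs in a region."""
    from .cohort import region_gm_volume

    sub = results[(results["region"] == region) & (~results["excluded"])]
    values = {
        row["participant_id"]: region_gm_volume(
            by_id[row["participant_id"]], list(row["roi_ids_used"])
        )
        for _, row in sub.iterrows()
    }
    return pd.Series(values)


def run_analysis(
    participants: Sequence[Participant],
    atlas: AtlasDefinition,
    groupings: Sequence[RegionGrouping] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisResult:
    """Run the complete analysis: screen, sparing, regional engine, statistics."""
    groupings = list(groupings) if groupings is not None else default_groupings(atlas)
    groupings = _filter_groupings(groupings, config.region_families)
    controls = [p for p in participants if p.group == "control"]
    patients = [p for p in participants if p.group == "stroke"]
    if len(controls) < 2:
        raise ValidationError("analysis requires at least 2 controls")

    # 1. whole-brain screen (bypass when external brain ages are supplied)
    if all(p.global_brain_age is not None for p in controls):
        ages = {p.id: float(p.global_brain_age) for p in controls}
    else:
        model = fit_global_model(controls, config.variance_fraction)
        ages = {p.id: predict_global_age(model, p) for p in controls}
    partition = partition_controls(controls, ages, config.tolerance_fraction)
    within_ids = set(partition.within_range_ids)
    within = [p for p in controls if p.id in within_ids]
    out_of_range = [p for p in controls if p.id not in within_ids]

    # 2. sparing: lesion overlap for patients, all-spared for controls
    sparings: dict[str, SparingProfile] = {}
    for p in patients:
        if p.lesion_mask is None:
            raise ValidationError(f"stroke participant {p.id} has no lesion mask")
        sparings[p.id] = lesion_overlap(p.lesion_mask, atlas, p.id)
    for p in out_of_range:
        sparings[p.id] = full_sparing(atlas, p.id)

    # 3. regional engine over out-of-range controls + patients
    targets = out_of_range + patients
    results, models = estimate_cohort(
        targets, sparings, within, groupings, config.sparing_threshold
    )

    report: dict = {
        "package_version": __version__,
        "n_controls": len(controls),
        "n_patients": len(patients),
        "n_within_range": len(within),
        "n_out_of_range": len(out_of_range),
        "n_excluded_by_region": results[results["excluded"]]
        .groupby("region")["participant_id"]
        .count()
        .to_dict(),
    }

    gap_table = build_gap_table(results, targets, config.ancova_family)
    ancova = age_ttest = corr_lr = corr_av = behavior = None
    diagnostics: dict[str, ResidualDiagnostics] = {}
    if config.run_stats:
        try:
            ancova = mixed_ancova(gap_table)
        except ValidationError as err:
            report["ancova_skipped"] = str(err)
        if len(out_of_range) >= 2 and len(patients) >= 2:
            age_ttest = group_ttest(
                [p.age for p in out_of_range], [p.age for p in patients]
            )

        by_id = {p.id: p for p in patients}
        patient_results = results[results["participant_id"].isin(by_id)]
        ba = patient_results[~patient_results["excluded"]].pivot_table(
            index="participant_id", columns="region", values="brain_age"
        )
        lr, av = {}, {}
        for family in config.region_families:
            left, right = f"left_{family}", f"right_{family}"
            if left in ba.columns and right in ba.columns:
                pair = ba[[left, right]].dropna()
                lr[f"{family}_left_vs_right"] = (pair[left], pair[right])
            for region in (left, right):
                if region not in ba.columns:
                    continue
                gm = _regional_gm(patient_results, by_id, region)
                common = ba[region].dropna().index.intersection(gm.index)
                av[f"{region}_age_vs_volume"] = (
                    ba.loc[common, region],
                    gm.loc[common],
                )
        if lr:
            corr_lr = correlation_battery(lr, config.base_alpha)
        if av:
            corr_av = correlation_battery(av, config.base_alpha)

        for region in (f"left_{config.ancova_family}", "left_hemisphere"):
            per_participant = {
                pid: m for (pid, reg), m in models.items() if reg == region and pid in by_id
            }
            if len(per_participant) >= 3:
                diagnostics[region] = residual_diagnostics(per_participant, region)

        if any(p.behavior for p in patients):
            try:
                behavior = behavior_regression(
                    patients,
                    results,
                    RegressionSpec(base_alpha=config.base_alpha),
                    region=config.behavior_region,
                )
            except ValidationError as err:
                report["behavior_skipped"] = str(err)

    if ancova is not None:
        inter = ancova.set_index("term").loc["group:hemisphere"]
        report["ancova_interaction"] = {"F": float(inter["F"]), "p": float(inter["p"])}
    return AnalysisResult(
        partition=partition,
        partition_frame=partition_table(controls, ages, partition),
        results=results,
        models=models,
        gap_table=gap_table,
        ancova=ancova,
        age_ttest=age_ttest,
        correlations_lr=corr_lr,
        correlations_age_volume=corr_av,
        diagnostics=diagnostics,
        behavior=behavior,
        report=report,
    )


def _tsv(frame: pd.DataFrame, path: pathlib.Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_outputs(
    result: AnalysisResult,
    out_dir,
    analysis_config: AnalysisConfig,
    extra_provenance: dict | None = None,
    force: bool = False,
) -> pathlib.Path:
    """Write all analysis outputs plus full provenance (config, seed, version)."""
    out = pathlib.Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"{out} exists and is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    results = result.results.copy()
    results["roi_ids_used"] = [
        ",".join(str(r) for r in rois) for rois in results["roi_ids_used"]
    ]
    _tsv(results, out / "regional_results.tsv")
    _tsv(result.partition_frame, out / "partition.tsv")
    coeffs = {
        f"{pid}/{region}": {
            "roi_ids": list(m.roi_ids_used),
            "coefficients": [float(c) for c in m.coef],
        }
        for (pid, region), m in result.models.items()
    }
    (out / "model_coefficients.json").write_text(json.dumps(coeffs, indent=1))
    if result.ancova is not None:
        _tsv(result.ancova, out / "ancova.tsv")
    if result.age_ttest is not None:
        (out / "age_ttest.json").write_text(
            json.dumps(dataclasses.asdict(result.age_ttest), indent=1)
        )
    if result.correlations_lr is not None:
        _tsv(result.correlations_lr, out / "correlations_left_right.tsv")
    if result.correlations_age_volume is not None:
        _tsv(result.correlations_age_volume, out / "correlations_age_volume.tsv")
    for region, diag in result.diagnostics.items():
        _tsv(diag.table, out / f"residual_dispersion_{region}.tsv")
    if result.behavior is not None:
        for score, table in result.behavior.tables.items():
            _tsv(table, out / f"behavior_{score}.tsv")
    (out / "report.json").write_text(json.dumps(_full_report(result), indent=1))
    provenance = dict(extra_provenance or {})
    provenance["analysis_config"] = dataclasses.asdict(analysis_config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    (out / "run_report.txt").write_text(_human_report(result))
    return out


def _full_report(result: AnalysisResult) -> dict:
    report = dict(result.report)
    for region, diag in result.diagnostics.items():
        report[f"dispersion_{region}"] = {
            "r_sd": None if np.isnan(diag.r_sd) else diag.r_sd,
            "p_sd": None if np.isnan(diag.p_sd) else diag.p_sd,
            "r_mean": None if np.isnan(diag.r_mean) else diag.r_mean,
            "p_mean": None if np.isnan(diag.p_mean) else diag.p_mean,
            "note": diag.note,
        }
    if result.behavior is not None:
        report["behavior_alpha"] = result.behavior.alpha
        report["behavior_notes"] = list(result.behavior.notes)
    return report


def _human_report(result: AnalysisResult) -> str:
    lines = ["braingap analysis run", "=" * 21, ""]
    r = result.report
    lines.append(f"controls: {r['n_controls']} "
                 f"(within-range {r['n_within_range']}, out-of-range {r['n_out_of_range']})")
    lines.append(f"stroke participants: {r['n_patients']}")
    if r.get("n_excluded_by_region"):
        lines.append("excluded (zero intact ROIs) by region:")
        for region, n in sorted(r["n_excluded_by_region"].items()):
            lines.append(f"  {region}: {n}")
    if result.ancova is not None:
        lines.append("")
        lines.append("mixed ANCOVA on domain-general BrainGAP:")
        for _, row in result.ancova.iterrows():
            lines.append(
                f"  {row['term']}: F({row['df1']:.0f},{row['df2']:.0f}) = "
                f"{row['F']:.3f}, p = {row['p']:.4g}"
            )
    if result.age_ttest is not None:
        t = result.age_ttest
        lines.append("")
        lines.append(
            f"age t-test (out-of-range controls vs stroke): t({t.df:.0f}) = {t.t:.3f}, "
            f"p = {t.p:.4g}; means {t.mean_a:.2f} vs {t.mean_b:.2f}"
        )
    for region, diag in result.diagnostics.items():
        lines.append(
            f"residual dispersion {region}: r(n_rois, sd) = {diag.r_sd:.3f} "
            f"(p = {diag.p_sd:.4g}), r(n_rois, mean) = {diag.r_mean:.3f} "
            f"(p = {diag.p_mean:.4g}) {diag.note}"
        )
    if result.behavior is not None:
        lines.append("")
        lines.append(
            f"behavior regressions in {result.behavior.region} "
            f"(alpha = {result.behavior.alpha:g}):"
        )
        for score, table in result.behavior.tables.items():
            sig = table[table["significant"]]["predictor"].tolist()
            sig = [s for s in sig if s != "const"]
            lines.append(f"  {score}: significant predictors: {', '.join(sig) or 'none'}")
    return "\n".join(lines) + "\n"
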
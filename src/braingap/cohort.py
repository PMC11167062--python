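"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the regional brain-age
analysis assumes: a normative control cohort whose per-ROI gray-matter
volumes decline linearly with age, and a stroke cohort with left-lateralized
lesions plus an injected premature-aging offset on left-hemisphere ROIs.

Generative model, per participant ``i`` and ROI ``r``::

    volume_ir = baseline_r + slope_r * effective_age_ir + Normal(0, noise_sd * baseline_r)
    effective_age_ir = age_i + delta_i            (controls; patients, right ROIs)
                     = age_i + delta_i + offset   (patients, left ROIs)

``delta_i`` is a per-subject brain-age deviation (how much older or younger
the whole brain looks than the birth certificate says); it is what makes some
controls fall outside the 5% whole-brain screening band.  Premature aging is
injected as an *age* offset, so the regional ground truth is literally
``chronological age + offset``.  Lesions erode left-hemisphere tissue:
per-ROI volumes are multiplied by the geometric spared fraction, and volumes
never exceed their unlesioned counterfactual.

All randomness flows from ``CohortConfig.seed`` through named
``numpy.random.SeedSequence`` spawn keys, so each participant's draws are
independent of how many other participants exist and of lesion settings.
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections.abc import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import (
    AtlasDefinition,
    RegionGrouping,
    ValidationError,
    lesion_overlap,
)

__all__ = [
    "BEHAVIOR_SCORES",
    "BehaviorCoeffs",
    "LesionSpec",
    "CohortConfig",
    "Participant",
    "synthetic_atlas",
    "packaged_synthetic_atlas",
    "resolve_roi_params",
    "generate_controls",
    "generate_patients",
    "generate_behavior",
    "region_gm_volume",
    "write_cohort",
    "read_cohort",
]

BEHAVIOR_SCORES = ("aq", "naming", "spontaneous_speech", "repetition", "comprehension")

_SEX_LEVELS = ("female", "male")
_SEX_PROBS = (0.55, 0.45)
_HAND_LEVELS = ("right", "left", "ambidextrous")
_HAND_PROBS = (0.90, 0.07, 0.03)

# SeedSequence spawn-key roots for the independent random streams
_KEY_PARAMS, _KEY_CONTROL, _KEY_PATIENT, _KEY_BEHAVIOR = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class BehaviorCoeffs:
    """Linear behavior model: score = intercept + b.x + Normal(0, noise_sd)."""

    intercept: float
    beta_gap: float
    beta_gm: float
    beta_lesion: float
    beta_age: float
    noise_sd: float


# Default WAB-R-style coefficient sets, scaled for the packaged atlas where
# mean region volume fractions are ~0.004.  Negative beta_gap / beta_lesion /
# beta_age: older-looking tissue, bigger lesions and older participants all
# score worse; positive beta_gm: preserved volume scores better.
DEFAULT_BEHAVIOR = {
    "aq": BehaviorCoeffs(30.0, -0.75, 15000.0, -0.0015, -0.25, 8.0),
    "naming": BehaviorCoeffs(25.0, -0.60, 16000.0, -0.0012, -0.20, 9.0),
    "spontaneous_speech": BehaviorCoeffs(35.0, -0.50, 13000.0, -0.0010, -0.30, 8.0),
    "repetition": BehaviorCoeffs(28.0, -0.70, 14000.0, -0.0013, -0.22, 9.0),
    "comprehension": BehaviorCoeffs(40.0, -0.90, 12000.0, -0.0018, -0.18, 7.0),
}


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """Spherical left-hemisphere lesions.

    Centers are sampled uniformly over left-hemisphere-labelled voxels unless
    given explicitly; radii (mm) uniform over ``radius_range_mm``.  The mask
    is the sphere intersected with left-hemisphere labels, so lesions never
    touch right-hemisphere or midline tissue.  ``radius_range_mm=(0, 0)``
    produces empty lesions.
    """

    radius_range_mm: tuple[float, float] = (4.0, 12.0)
    centers: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.radius_range_mm
        if lo < 0 or hi < lo:
            raise ValidationError(f"invalid lesion radius range {self.radius_range_mm}")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the emulated study: 232 controls and 89 left-hemisphere
    stroke survivors aged 20-80, an 8-year premature-aging offset injected
    into patients' left hemispheres, ROI atrophy of 0.2-0.5%/year of
    baseline volume, measurement noise of 1% of baseline (≈3 years of age
    equivalent per ROI), and a 3.5-year SD of per-subject brain-age
    deviation.
    """

    n_controls: int = 232
    n_patients: int = 89
    age_range: tuple[float, float] = (20.0, 80.0)
    roi_baseline_volumes: Mapping[int, float] | None = None
    roi_atrophy_slopes: Mapping[int, float] | None = None
    atrophy_rate_range: tuple[float, float] = (0.002, 0.005)  # fraction of baseline / year
    noise_sd: float = 0.01  # volume noise, fraction of baseline
    brainage_sd: float = 3.5  # SD of per-subject brain-age deviation, years
    premature_offset_years: float = 8.0
    lesion: LesionSpec = dataclasses.field(default_factory=LesionSpec)
    behavior: Mapping[str, BehaviorCoeffs] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR)
    )
    education_mean: float = 15.5
    education_sd: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_patients <= 0:
            raise ValidationError("participant counts must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError(f"age_range must satisfy min < max, got {self.age_range}")
        if self.noise_sd < 0 or self.brainage_sd < 0:
            raise ValidationError("noise scales must be non-negative")
        if self.roi_atrophy_slopes is not None and not all(
            np.isfinite(list(self.roi_atrophy_slopes.values()))
        ):
            raise ValidationError("atrophy slopes must be finite")


@dataclasses.dataclass(eq=False)
class Participant:
    """One synthetic (or loaded) participant."""

    id: str
    group: str  # "control" | "stroke"
    age: float
    sex: str
    education: float
    handedness: str
    tiv: float  # mm^3
    roi_volumes: pd.Series  # index roi_id, TIV-normalized
    lesion_mask: np.ndarray | None = None
    lesion_volume: float = 0.0
    behavior: dict[str, float] | None = None
    global_brain_age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "stroke"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.group == "control" and self.lesion_volume > 0:
            raise ValidationError("controls must have an empty lesion")
        if (pd.Series(self.roi_volumes) < 0).any():
            raise ValidationError("roi volumes must be >= 0")


# -- grid synthesis -----------------------------------------------------------


def demo_roi_table(n_per_side: int = 8) -> pd.DataFrame:
    """A minimal paired catalogue (``parcel_i`` left/right), for demos and tests."""
    rows = []
    for i in range(n_per_side):
        rows.append({"roi_id": i + 1, "name": f"parcel_{i + 1}", "hemisphere": "left"})
    for i in range(n_per_side):
        rows.append(
            {"roi_id": n_per_side + i + 1, "name": f"parcel_{i + 1}", "hemisphere": "right"}
        )
    return pd.DataFrame(rows)


def synthetic_atlas(
    roi_table: pd.DataFrame,
    shape: tuple[int, int, int] = (23, 22, 22),
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> AtlasDefinition:
    """Build a grid atlas realizing an ROI catalogue geometrically.

    The grid is split into a left slab (x low), an optional single-plane
    midline slab, and a right slab; each slab's voxels are divided into
    contiguous equal chunks, one per ROI of that hemisphere, in catalogue
    order.  Crude geometry, but it gives every ROI a support on which lesion
    overlap, partial sparing and volume computation are exact.
    """
    table = pd.DataFrame(roi_table)
    left_ids = table.loc[table["hemisphere"] == "left", "roi_id"].astype(int).tolist()
    right_ids = table.loc[table["hemisphere"] == "right", "roi_id"].astype(int).tolist()
    mid_ids = table.loc[table["hemisphere"] == "none", "roi_id"].astype(int).tolist()
    nx = shape[0]
    mid_width = 1 if mid_ids else 0
    half = (nx - mid_width) // 2
    if half < 1 or not left_ids or not right_ids:
        raise ValidationError("grid too small or catalogue lacks a hemisphere")

    labels = np.zeros(shape, dtype=np.int32)

    def fill(x_lo: int, x_hi: int, ids: Sequence[int]) -> None:
        zone = np.zeros((x_hi - x_lo,) + shape[1:], dtype=np.int32)
        flat = zone.reshape(-1)
        for chunk, roi in zip(np.array_split(np.arange(flat.size), len(ids)), ids):
            flat[chunk] = roi
        labels[x_lo:x_hi] = zone

    fill(0, half, left_ids)
    if mid_ids:
        fill(half, half + mid_width, mid_ids)
    fill(half + mid_width, nx, right_ids)
    return AtlasDefinition(labels=labels, voxel_dims=voxel_dims, roi_table=table)


def packaged_synthetic_atlas(
    shape: tuple[int, int, int] = (23, 22, 22),
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> AtlasDefinition:
    """Grid atlas realizing the packaged 189-parcel catalogue."""
    from .atlas import packaged_roi_table

    return synthetic_atlas(packaged_roi_table(), shape=shape, voxel_dims=voxel_dims)


# -- generative parameters ----------------------------------------------------


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def resolve_roi_params(
    config: CohortConfig, atlas: AtlasDefinition
) -> tuple[pd.Series, pd.Series]:
    """Per-ROI baseline volumes and atrophy slopes (explicit or derived).

    When not given explicitly, the baseline of each ROI is its geometric
    volume fraction of the labelled grid (so volumes are TIV-normalized and
    sum to ~1 at age 0), and the slope is ``-rate * baseline`` with per-ROI
    atrophy rates drawn once, deterministically from the seed.
    """
    ids = atlas.roi_ids
    if config.roi_baseline_volumes is not None:
        baseline = pd.Series(dict(config.roi_baseline_volumes)).reindex(ids).astype(float)
        if baseline.isna().any():
            raise ValidationError("roi_baseline_volumes missing atlas ROIs")
    else:
        counts = atlas.voxel_counts().astype(float)
        baseline = counts / counts.sum()
    if config.roi_atrophy_slopes is not None:
        slopes = pd.Series(dict(config.roi_atrophy_slopes)).reindex(ids).astype(float)
        if slopes.isna().any():
            raise ValidationError("roi_atrophy_slopes missing atlas ROIs")
    else:
        rng = _rng(config, _KEY_PARAMS)
        rates = rng.uniform(*config.atrophy_rate_range, size=len(ids))
        slopes = pd.Series(-rates, index=ids) * baseline
    return baseline.rename("baseline"), slopes.rename("slope")


def _demographics(rng: np.random.Generator, config: CohortConfig) -> dict:
    age = rng.uniform(*config.age_range)
    sex = _SEX_LEVELS[rng.choice(len(_SEX_LEVELS), p=_SEX_PROBS)]
    hand = _HAND_LEVELS[rng.choice(len(_HAND_LEVELS), p=_HAND_PROBS)]
    edu = float(np.clip(rng.normal(config.education_mean, config.education_sd), 8.0, 24.0))
    delta = rng.normal(0.0, config.brainage_sd) if config.brainage_sd > 0 else 0.0
    return {"age": float(age), "sex": sex, "handedness": hand, "education": edu, "delta": float(delta)}


def _volumes(
    rng: np.random.Generator,
    baseline: pd.Series,
    slopes: pd.Series,
    effective_age: pd.Series,
    noise_sd: float,
) -> pd.Series:
    noise = rng.normal(0.0, 1.0, size=len(baseline)) * noise_sd * baseline.to_numpy()
    vols = baseline.to_numpy() + slopes.to_numpy() * effective_age.to_numpy() + noise
    return pd.Series(np.clip(vols, 0.0, None), index=baseline.index, name="volume")


def generate_controls(config: CohortConfig, atlas: AtlasDefinition) -> list[Participant]:
    """Normative controls: ROI volumes on the configured age line plus noise."""
    baseline, slopes = resolve_roi_params(config, atlas)
    tiv = float(atlas.voxel_counts().sum()) * atlas.voxel_volume
    out = []
    for i in range(config.n_controls):
        demo = _demographics(_rng(config, _KEY_CONTROL, i, 0), config)
        eff = pd.Series(demo["age"] + demo["delta"], index=baseline.index)
        vols = _volumes(_rng(config, _KEY_CONTROL, i, 1), baseline, slopes, eff, config.noise_sd)
        out.append(
            Participant(
                id=f"C{i:03d}",
                group="control",
                age=demo["age"],
                sex=demo["sex"],
                education=demo["education"],
                handedness=demo["handedness"],
                tiv=tiv,
                roi_volumes=vols,
            )
        )
    return out


def _sphere_mask(
    atlas: AtlasDefinition, center: tuple[int, int, int], radius_mm: float
) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * d for n, d in zip(atlas.labels.shape, atlas.voxel_dims)),
        indexing="ij",
    )
    c = [center[k] * atlas.voxel_dims[k] for k in range(3)]
    dist2 = sum((g - ck) ** 2 for g, ck in zip(grids, c))
    return dist2 <= radius_mm**2


def generate_patients(config: CohortConfig, atlas: AtlasDefinition) -> list[Participant]:
    """Stroke cohort: left-lateralized lesions plus left premature aging.

    Left-hemisphere ROI volumes are generated at effective age
    ``age + delta + premature_offset_years``; right and midline ROIs at
    ``age + delta``.  The lesion then multiplies each ROI volume by its
    geometric spared fraction (lesioned tissue is removed before the ROI
    volume is read off).
    """
    baseline, slopes = resolve_roi_params(config, atlas)
    tiv = float(atlas.voxel_counts().sum()) * atlas.voxel_volume
    left_ids = set(atlas.roi_ids_for_hemisphere("left"))
    left_mask = np.isin(atlas.labels, list(left_ids))
    left_voxels = np.argwhere(left_mask)
    if config.lesion.centers is not None:
        for c in config.lesion.centers:
            if not left_mask[tuple(c)]:
                raise ValidationError(
                    f"lesion center {tuple(c)} is not inside left-hemisphere labels"
                )
    is_left = pd.Series(
        [r in left_ids for r in baseline.index], index=baseline.index, dtype=bool
    )
    out = []
    for i in range(config.n_patients):
        demo = _demographics(_rng(config, _KEY_PATIENT, i, 0), config)
        eff = pd.Series(demo["age"] + demo["delta"], index=baseline.index)
        eff[is_left] += config.premature_offset_years
        vols = _volumes(_rng(config, _KEY_PATIENT, i, 1), baseline, slopes, eff, config.noise_sd)

        lesion_rng = _rng(config, _KEY_PATIENT, i, 2)
        lo, hi = config.lesion.radius_range_mm
        if hi > 0:
            if config.lesion.centers is not None:
                center = tuple(config.lesion.centers[i % len(config.lesion.centers)])
            else:
                center = tuple(left_voxels[lesion_rng.integers(len(left_voxels))])
            radius = float(lesion_rng.uniform(lo, hi))
            mask = _sphere_mask(atlas, center, radius) & left_mask
        else:
            mask = np.zeros_like(left_mask)
        profile = lesion_overlap(mask, atlas, participant_id=f"P{i:03d}")
        vols = vols * profile.spared_fraction.reindex(vols.index)

        out.append(
            Participant(
                id=f"P{i:03d}",
                group="stroke",
                age=demo["age"],
                sex=demo["sex"],
                education=demo["education"],
                handedness=demo["handedness"],
                tiv=tiv,
                roi_volumes=vols,
                lesion_mask=mask,
                lesion_volume=profile.lesion_volume,
            )
        )
    return out


# -- behavior -----------------------------------------------------------------


def region_gm_volume(participant: Participant, roi_ids: Sequence[int]) -> float:
    """Mean TIV-normalized gray-matter volume over a set of ROIs."""
    if len(roi_ids) == 0:
        raise ValidationError("cannot average volume over an empty ROI set")
    return float(participant.roi_volumes.loc[list(roi_ids)].mean())


def generate_behavior(
    patients: Sequence[Participant],
    regional_results: pd.DataFrame,
    config: CohortConfig,
    region: str = "left_domain_general",
) -> list[Participant]:
    """Attach WAB-R-style scores generated from the stated linear model.

    ``score = intercept + b_gap*gap + b_gm*gm + b_lesion*lesion_volume +
    b_age*age + Normal(0, noise_sd)``, clipped to [0, 100].  ``gap`` is the
    participant's BrainGAP in ``region`` taken from ``regional_results``
    (columns ``participant_id``, ``region``, ``braingap``, ``excluded``,
    ``roi_ids_used``); ``gm`` is the mean volume over the ROIs that the
    regional model actually used.  Patients whose region is excluded (no
    intact ROIs) get no behavior; a patient missing from the results table
    entirely is an error.
    """
    rows = regional_results[regional_results["region"] == region].set_index("participant_id")
    out = []
    for i, p in enumerate(patients):
        if p.id not in rows.index:
            raise ValidationError(f"no {region!r} result for patient {p.id}")
        row = rows.loc[p.id]
        if bool(row["excluded"]):
            p = dataclasses.replace(p, behavior=None)
            out.append(p)
            continue
        gap = float(row["braingap"])
        gm = region_gm_volume(p, list(row["roi_ids_used"]))
        rng = _rng(config, _KEY_BEHAVIOR, i)
        behavior = {}
        for score in BEHAVIOR_SCORES:
            c = config.behavior[score]
            value = (
                c.intercept
                + c.beta_gap * gap
                + c.beta_gm * gm
                + c.beta_lesion * p.lesion_volume
                + c.beta_age * p.age
            )
            if c.noise_sd > 0:
                value += rng.normal(0.0, c.noise_sd)
            behavior[score] = float(np.clip(value, 0.0, 100.0))
        out.append(dataclasses.replace(p, behavior=behavior))
    return out


# -- serialization ------------------------------------------------------------

_BASE_COLUMNS = [
    "id",
    "group",
    "age",
    "sex",
    "education",
    "handedness",
    "tiv",
    "lesion_volume",
    "global_brain_age",
]


def _participants_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        row = {k: getattr(p, k) for k in _BASE_COLUMNS}
        for s in BEHAVIOR_SCORES:
            row[s] = p.behavior.get(s) if p.behavior else np.nan
        for roi, v in p.roi_volumes.items():
            row[f"vol_{int(roi)}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    participants: Sequence[Participant],
    out_dir,
    atlas: AtlasDefinition,
    force: bool = False,
) -> pathlib.Path:
    """Write a cohort directory: controls.tsv, patients.tsv, masks/, atlas files.

    Column order is fixed, floats are written at full precision, and lesion
    masks are stored as uncompressed NIfTI so that identical cohorts produce
    byte-identical directories.
    """
    out = pathlib.Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"{out} exists and is not empty (use force to overwrite)")
    (out / "masks").mkdir(parents=True, exist_ok=True)

    controls = [p for p in participants if p.group == "control"]
    patients = [p for p in participants if p.group == "stroke"]
    for name, group in (("controls.tsv", controls), ("patients.tsv", patients)):
        frame = _participants_frame(group)
        frame.to_csv(out / name, sep="\t", index=False, float_format="%.17g")

    affine = np.diag(list(atlas.voxel_dims) + [1.0])
    for p in patients:
        if p.lesion_mask is None:
            raise ValidationError(f"stroke participant {p.id} has no lesion mask to write")
        img = nib.Nifti1Image(p.lesion_mask.astype(np.uint8), affine)
        nib.save(img, out / "masks" / f"{p.id}_lesion.nii")
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine), out / "atlas.nii")
    atlas.roi_table.to_csv(out / "roi_lookup.tsv", sep="\t", index=False)
    return out


def read_cohort(cohort_dir) -> tuple[list[Participant], AtlasDefinition]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    from .atlas import load_atlas

    root = pathlib.Path(cohort_dir)
    for required in ("controls.tsv", "patients.tsv", "atlas.nii", "roi_lookup.tsv"):
        if not (root / required).exists():
            raise ValidationError(f"cohort directory {root} is missing {required}")
    atlas = load_atlas(root / "atlas.nii", root / "roi_lookup.tsv")

    participants: list[Participant] = []
    for name in ("controls.tsv", "patients.tsv"):
        frame = pd.read_csv(root / name, sep="\t", float_precision="round_trip")
        vol_cols = [c for c in frame.columns if c.startswith("vol_")]
        for _, row in frame.iterrows():
            vols = pd.Series(
                row[vol_cols].to_numpy(dtype=float),
                index=[int(c[4:]) for c in vol_cols],
                name="volume",
            )
            behavior = {s: float(row[s]) for s in BEHAVIOR_SCORES if pd.notna(row[s])}
            mask = None
            if row["group"] == "stroke":
                mask_path = root / "masks" / f"{row['id']}_lesion.nii"
                if not mask_path.exists():
                    raise ValidationError(
                        f"stroke participant {row['id']} has no lesion mask at {mask_path}"
                    )
                mask = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(bool)
            participants.append(
                Participant(
                    id=str(row["id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    education=float(row["education"]),
                    handedness=str(row["handedness"]),
                    tiv=float(row["tiv"]),
                    roi_volumes=vols,
                    lesion_mask=mask,
                    lesion_volume=float(row["lesion_volume"]),
                    behavior=behavior or None,
                    global_brain_age=(
                        float(row["global_brain_age"])
                        if pd.notna(row["global_brain_age"])
                        else None
                    ),
                )
            )
    return participants, atlas
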
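"""Atlas geometry: ROI catalogues, region groupings, volumes, lesion overlap.

This module is the geometric substrate of the regional brain-age pipeline.
An :class:`AtlasDefinition` couples a 3-D integer label image (0 = background,
``k > 0`` = ROI id) with a catalogue of ROIs (id, name, hemisphere).  Named
:class:`RegionGrouping` objects collect ROIs into the region families the
analysis operates on (hemispheres, domain-general, language-specific, the four
lobes, each split by side).  Lesion masks co-registered to the atlas grid are
reduced to per-ROI spared fractions (:func:`lesion_overlap`) from which the
intact-ROI subset of any region is selected (:func:`intact_rois`).

No resampling is performed anywhere: masks and gray-matter images must share
the atlas grid exactly, and mismatches are hard errors.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from collections.abc import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "AtlasDefinition",
    "RegionGrouping",
    "SparingProfile",
    "load_atlas",
    "load_region_groupings",
    "packaged_roi_table",
    "packaged_groupings_path",
    "roi_gm_volumes",
    "lesion_overlap",
    "full_sparing",
    "intact_rois",
    "DEFAULT_SPARING_THRESHOLD",
]

HEMISPHERES = ("left", "right", "none")

#: An ROI counts as intact when at least this fraction of its voxels falls
#: outside the lesion (inclusive comparison on exact voxel ratios).
DEFAULT_SPARING_THRESHOLD = 0.99

_ROI_COLUMNS = ("roi_id", "name", "hemisphere")


class ValidationError(ValueError):
    """An input violates a structural contract of the pipeline."""


@dataclasses.dataclass(frozen=True)
class AtlasDefinition:
    """A 3-D integer parcellation plus its ROI catalogue.

    Parameters
    ----------
    labels:
        3-D integer array; 0 is background, positive values are ROI ids.
    voxel_dims:
        Physical edge length of a voxel along each axis, in mm.
    roi_table:
        Table with columns ``roi_id`` (unique positive int), ``name`` and
        ``hemisphere`` (one of ``left``/``right``/``none``).  Every nonzero
        label present in the grid must appear in the table.
    """

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]
    roi_table: pd.DataFrame

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"label image must be 3-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("label image must be integer-valued")
        if labels.min() < 0:
            raise ValidationError("label image contains negative labels")
        object.__setattr__(self, "labels", labels)

        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(not np.isfinite(d) or d <= 0 for d in dims):
            raise ValidationError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")
        object.__setattr__(self, "voxel_dims", dims)

        table = pd.DataFrame(self.roi_table).copy()
        missing_cols = set(_ROI_COLUMNS) - set(table.columns)
        if missing_cols:
            raise ValidationError(f"roi_table missing columns: {sorted(missing_cols)}")
        table = table.loc[:, list(_ROI_COLUMNS)].reset_index(drop=True)
        table["roi_id"] = table["roi_id"].astype(int)
        if (table["roi_id"] <= 0).any():
            raise ValidationError("roi ids must be positive integers")
        if table["roi_id"].duplicated().any():
            dupes = sorted(table.loc[table["roi_id"].duplicated(), "roi_id"])
            raise ValidationError(f"duplicate roi ids in lookup: {dupes}")
        bad_hemi = set(table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        present = set(np.unique(labels)) - {0}
        unknown = present - set(table["roi_id"])
        if unknown:
            raise ValidationError(
                f"labels present in grid but absent from lookup: {sorted(unknown)[:10]}"
            )
        object.__setattr__(self, "roi_table", table)

    # -- convenience accessors -------------------------------------------------

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    @property
    def roi_ids(self) -> np.ndarray:
        """ROI ids in catalogue order."""
        return self.roi_table["roi_id"].to_numpy()

    def roi_ids_for_hemisphere(self, hemisphere: str) -> np.ndarray:
        return self.roi_table.loc[
            self.roi_table["hemisphere"] == hemisphere, "roi_id"
        ].to_numpy()

    def roi_id_for(self, name: str, hemisphere: str) -> int:
        """Resolve (name, hemisphere) to an ROI id."""
        hit = self.roi_table[
            (self.roi_table["name"] == name) & (self.roi_table["hemisphere"] == hemisphere)
        ]
        if hit.empty:
            raise ValidationError(f"ROI {name!r} ({hemisphere}) not in atlas catalogue")
        return int(hit["roi_id"].iloc[0])

    def voxel_counts(self) -> pd.Series:
        """Number of voxels per ROI (catalogue order)."""
        counts = np.bincount(self.labels.ravel(), minlength=int(self.roi_ids.max()) + 1)
        return pd.Series(counts[self.roi_ids], index=self.roi_ids, name="n_voxels")


@dataclasses.dataclass(frozen=True)
class RegionGrouping:
    """A named, ordered set of ROIs on one side (e.g. ``left_domain_general``)."""

    name: str
    side: str
    roi_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"grouping side must be left/right, got {self.side!r}")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValidationError(f"duplicate ROI ids in grouping {self.name!r}")
        if not self.roi_ids:
            raise ValidationError(f"grouping {self.name!r} is empty")
        object.__setattr__(self, "roi_ids", tuple(int(r) for r in self.roi_ids))

    def __len__(self) -> int:
        return len(self.roi_ids)


@dataclasses.dataclass(frozen=True)
class SparingProfile:
    """Per-ROI fraction of voxels outside a participant's lesion."""

    participant_id: str
    spared_fraction: pd.Series  # index: roi_id, values in [0, 1]
    lesion_volume: float  # mm^3

    def __post_init__(self) -> None:
        frac = pd.Series(self.spared_fraction).astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValidationError("spared fractions must lie in [0, 1]")
        if self.lesion_volume < 0:
            raise ValidationError("lesion volume must be >= 0")
        object.__setattr__(self, "spared_fraction", frac)


# -- loading ------------------------------------------------------------------


def _read_label_image(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.mod(data, 1) == 0):
            raise ValidationError(f"{path}: label image contains non-integer values")
        data = data.astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def load_atlas(label_image_path, roi_lookup_path) -> AtlasDefinition:
    """Load an atlas from a NIfTI label image and a TSV ROI lookup.

    The lookup must have columns ``roi_id``, ``name`` and ``hemisphere``.
    Labels present in the image but absent from the lookup are an error.
    """
    labels, zooms = _read_label_image(label_image_path)
    table = pd.read_csv(roi_lookup_path, sep="\t")
    return AtlasDefinition(labels=labels, voxel_dims=zooms, roi_table=table)


def load_region_groupings(config_path, atlas: AtlasDefinition) -> list[RegionGrouping]:
    """Load region groupings from a YAML config and validate against the atlas.

    Config layout::

        regions:
          domain_general:
            left:  [superior_frontal_gyrus, ...]
            right: [superior_frontal_gyrus, ...]

    Names are resolved against the atlas catalogue per side; an unknown name
    is a :class:`ValidationError`.  Groupings are returned in file order as
    ``{side}_{family}`` (e.g. ``left_domain_general``).
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "regions" not in config:
        raise ValidationError(f"{config_path}: expected a top-level 'regions' mapping")
    groupings: list[RegionGrouping] = []
    for family, sides in config["regions"].items():
        for side, names in sides.items():
            if side not in ("left", "right"):
                raise ValidationError(f"region {family!r}: unknown side {side!r}")
            roi_ids = tuple(atlas.roi_id_for(str(n), side) for n in names)
            groupings.append(RegionGrouping(name=f"{side}_{family}", side=side, roi_ids=roi_ids))
    return groupings


def packaged_roi_table() -> pd.DataFrame:
    """The packaged 189-parcel JHU-style catalogue (synthetic reconstruction).

    Region sizes match the standard grouping counts exactly (94 per
    hemisphere, 8 domain-general / 9 language-specific per side, lobes
    16/13/6/5); the individual parcel names are representative JHU-style
    names reconstructed for the packaged default, not an official release.
    """
    path = importlib.resources.files("braingap.data") / "jhu_synthetic_rois.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def packaged_groupings_path():
    """Filesystem path of the packaged region-grouping YAML."""
    return importlib.resources.files("braingap.data") / "jhu_synthetic_regions.yaml"


# -- geometry -----------------------------------------------------------------


def _check_grid(arr: np.ndarray, atlas: AtlasDefinition, what: str) -> None:
    if arr.shape != atlas.labels.shape:
        raise ValidationError(
            f"{what} grid {arr.shape} does not match atlas grid {atlas.labels.shape}; "
            "no resampling is performed"
        )


def roi_gm_volumes(gm_image_or_table, atlas: AtlasDefinition, tiv: float) -> pd.Series:
    """TIV-normalized gray-matter volume per ROI.

    ``gm_image_or_table`` is either a per-voxel gray-matter fraction image on
    the atlas grid (binary segmentations are the 0/1 special case) or a
    mapping/Series of precomputed per-ROI absolute volumes in mm^3.  The
    result is ``sum(gm fraction * voxel volume) / tiv`` per ROI — unit-free.
    """
    if tiv <= 0 or not np.isfinite(tiv):
        raise ValidationError(f"tiv must be a positive volume, got {tiv}")
    if isinstance(gm_image_or_table, (Mapping, pd.Series)):
        table = pd.Series(dict(gm_image_or_table), dtype=float)
        missing = set(atlas.roi_ids) - set(table.index)
        if missing:
            raise ValidationError(f"per-ROI volume table missing ids: {sorted(missing)[:10]}")
        if (table < 0).any():
            raise ValidationError("per-ROI volumes must be non-negative")
        return (table.reindex(atlas.roi_ids) / tiv).rename("volume")

    gm = np.asarray(gm_image_or_table, dtype=float)
    _check_grid(gm, atlas, "gray-matter image")
    if gm.min() < 0:
        raise ValidationError("gray-matter fractions must be non-negative")
    sums = np.bincount(
        atlas.labels.ravel(), weights=gm.ravel(), minlength=int(atlas.roi_ids.max()) + 1
    )
    vols = sums[atlas.roi_ids] * atlas.voxel_volume / tiv
    return pd.Series(vols, index=atlas.roi_ids, name="volume")


def _binarize_mask(mask: np.ndarray) -> np.ndarray:
    """Binarize a lesion mask; smoothed float masks cut at > 0.5."""
    if mask.dtype == bool:
        return mask
    if np.issubdtype(mask.dtype, np.integer):
        bad = set(np.unique(mask)) - {0, 1}
        if bad:
            raise ValidationError(f"integer lesion mask must be binary, found {sorted(bad)[:5]}")
        return mask.astype(bool)
    if np.issubdtype(mask.dtype, np.floating):
        if mask.min() < 0 or mask.max() > 1:
            raise ValidationError("float lesion mask values must lie in [0, 1]")
        return mask > 0.5
    raise ValidationError(f"unsupported lesion mask dtype {mask.dtype}")


def lesion_overlap(
    lesion_mask, atlas: AtlasDefinition, participant_id: str = ""
) -> SparingProfile:
    """Reduce a lesion mask to per-ROI spared fractions and lesion volume.

    ``spared_fraction[r]`` is the exact voxel ratio
    ``#(ROI-r voxels with mask 0) / #(ROI-r voxels)``; the lesion volume is
    the total number of mask voxels times the voxel volume (lesion voxels
    outside any ROI still count toward lesion volume).
    """
    mask = _binarize_mask(np.asarray(lesion_mask))
    _check_grid(mask, atlas, "lesion mask")
    labels = atlas.labels
    minlength = int(atlas.roi_ids.max()) + 1
    total = np.bincount(labels.ravel(), minlength=minlength)
    lesioned = np.bincount(labels[mask].ravel(), minlength=minlength)
    with np.errstate(invalid="ignore"):
        # exact integer ratio, not 1 - lesioned/total (last-ulp differences)
        spared = (total - lesioned) / total
    frac = pd.Series(spared[atlas.roi_ids], index=atlas.roi_ids)
    # ROIs with no voxels in the grid are untouched by any lesion
    frac = frac.fillna(1.0)
    return SparingProfile(
        participant_id=participant_id,
        spared_fraction=frac,
        lesion_volume=float(mask.sum()) * atlas.voxel_volume,
    )


def full_sparing(atlas: AtlasDefinition, participant_id: str = "") -> SparingProfile:
    """Profile of a participant with no lesion: every ROI fully spared."""
    return SparingProfile(
        participant_id=participant_id,
        spared_fraction=pd.Series(1.0, index=atlas.roi_ids),
        lesion_volume=0.0,
    )


def intact_rois(
    sparing: SparingProfile,
    grouping: RegionGrouping,
    threshold: float = DEFAULT_SPARING_THRESHOLD,
) -> list[int]:
    """ROIs of a grouping spared at least ``threshold`` by the lesion.

    The comparison is inclusive (``>=``) on exact voxel ratios, so an ROI
    spared exactly 99% is retained at the default threshold.  The returned
    list preserves grouping order and may be empty.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    frac = sparing.spared_fraction
    missing = [r for r in grouping.roi_ids if r not in frac.index]
    if missing:
        raise ValidationError(
            f"sparing profile lacks ROIs {missing[:5]} required by grouping {grouping.name!r}"
        )
    return [r for r in grouping.roi_ids if frac[r] >= threshold]
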
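"""ROI extraction, lobe aggregation and reference-region normalization.

Mean CBF is extracted per labelled region from a CBF map, gyri are
aggregated into lobes (voxel-count-weighted, i.e. equal to the direct mean
over the merged label set), and three reference values are built per
subject: cerebellum mean (cer), whole-brain white-matter mean (wm) and
whole-brain cortical gray matter (cgm, the unweighted average of the lobe
means).  Normalization divides every regional value by the subject's
reference value, cancelling any per-subject global scaling exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .dsc_quant import CBFMap

__all__ = [
    "RegionMapping",
    "roi_mean",
    "extract_roi_means",
    "aggregate_lobes",
    "reference_value",
    "build_roi_table",
    "normalize_table",
    "NORMALIZATIONS",
    "META_COLUMNS",
]

NORMALIZATIONS = ("cer", "wm", "cgm")
META_COLUMNS = ["subject_id", "group", "age", "normalization"]

CORTICAL_LOBES = ("frontal", "parietal", "temporal_lateral", "temporal_medial", "occipital")


@dataclass(frozen=True)
class RegionMapping:
    """Label lookup: label -> region name, region -> lobe and hemisphere.

    Built from a lookup table with columns label, name, lobe, hemisphere,
    tissue_class (cortical_gm | wm | cerebellum | artery).  Cerebellum, WM
    and artery are never members of a cortical lobe.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"label", "name", "lobe", "hemisphere", "tissue_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"lookup table missing columns {sorted(missing)}")
        cortical = self.table[self.table.tissue_class == "cortical_gm"]
        bad = cortical[~cortical.lobe.isin(CORTICAL_LOBES)]
        if len(bad):
            raise ConfigurationError(f"cortical labels with unknown lobe: {bad.name.tolist()}")
        noncortical = self.table[self.table.tissue_class != "cortical_gm"]
        overlap = noncortical[noncortical.lobe.isin(CORTICAL_LOBES)]
        if len(overlap):
            raise ConfigurationError(f"non-cortical labels assigned to cortical lobes: {overlap.name.tolist()}")

    @property
    def cortical(self) -> pd.DataFrame:
        return self.table[self.table.tissue_class == "cortical_gm"]

    @property
    def lobes(self) -> list[str]:
        """Cortical lobes present, in canonical order."""
        present = set(self.cortical.lobe)
        return [l for l in CORTICAL_LOBES if l in present]

    @property
    def hemispheres(self) -> list[str]:
        return sorted(set(self.cortical.hemisphere))

    def lobe_regions(self) -> list[str]:
        """Names of the hemisphere-lobe analysis regions, e.g. parietal_rh."""
        return [f"{lobe}_{h}" for lobe in self.lobes for h in self.hemispheres]

    def members(self, lobe: str, hemisphere: str) -> list[str]:
        sel = self.cortical[(self.cortical.lobe == lobe) & (self.cortical.hemisphere == hemisphere)]
        return sel.name.tolist()

    def labels_of_class(self, tissue_class: str) -> list[int]:
        return self.table.loc[self.table.tissue_class == tissue_class, "label"].tolist()

    def region_columns(self) -> list[str]:
        """ROI-table value columns: hemisphere-lobes plus cerebellum and wm."""
        return self.lobe_regions() + ["cerebellum", "wm"]


def roi_mean(cbf_map: CBFMap, labels: np.ndarray, label_id: int) -> float:
    """Mean CBF over the valid voxels carrying ``label_id``; NaN (with a
    warning) for an absent or all-invalid region."""
    sel = (np.asarray(labels) == label_id) & cbf_map.valid
    if not sel.any():
        warnings.warn(f"label {label_id}: no valid voxels, value is missing", stacklevel=2)
        return float("nan")
    return float(cbf_map.values[sel].mean())


def extract_roi_means(cbf_map: CBFMap, labels: np.ndarray, mapping: RegionMapping):
    """Per-region mean CBF and valid-voxel counts for every mapped label."""
    means, counts = {}, {}
    labels = np.asarray(labels)
    for _, row in mapping.table.iterrows():
        sel = (labels == row.label) & cbf_map.valid
        n = int(sel.sum())
        counts[row["name"]] = n
        if n == 0:
            warnings.warn(f"region {row['name']}: no valid voxels", stacklevel=2)
            means[row["name"]] = float("nan")
        else:
            means[row["name"]] = float(cbf_map.values[sel].mean())
    return means, counts


def aggregate_lobes(
    roi_means: dict, mapping: RegionMapping, roi_counts: dict
) -> dict:
    """Voxel-count-weighted aggregation of gyrus means into hemisphere-lobe
    means; identical to the direct mean over the merged label set."""
    out = {}
    for lobe in mapping.lobes:
        for hemi in mapping.hemispheres:
            members = mapping.members(lobe, hemi)
            if not members:
                continue
            missing = [m for m in members if m not in roi_means]
            if missing:
                raise ConfigurationError(f"unmapped cortical regions {missing}")
            w = np.array([roi_counts.get(m, 0) for m in members], dtype=float)
            v = np.array([roi_means[m] for m in members], dtype=float)
            usable = w > 0
            if not usable.any() or np.isnan(v[usable]).any():
                out[f"{lobe}_{hemi}"] = float("nan")
            else:
                out[f"{lobe}_{hemi}"] = float(np.average(v[usable], weights=w[usable]))
    return out


def reference_value(region_means: dict, mapping: RegionMapping, which: str) -> float:
    """Reference denominator: cerebellum mean, WM mean, or whole-brain
    cortical GM (hemisphere lobes averaged, then lobes averaged)."""
    if which == "cer":
        return float(region_means.get("cerebellum", float("nan")))
    if which == "wm":
        return float(region_means.get("wm", float("nan")))
    if which == "cgm":
        lobe_vals = []
        for lobe in mapping.lobes:
            hemi_vals = [region_means.get(f"{lobe}_{h}", float("nan")) for h in mapping.hemispheres]
            lobe_vals.append(float(np.mean(hemi_vals)))
        return float(np.mean(lobe_vals)) if lobe_vals else float("nan")
    raise ConfigurationError(f"unknown reference region {which!r}")


def build_roi_table(subject_rows: list[dict], mapping: RegionMapping) -> pd.DataFrame:
    """Assemble the absolute ROI table (one row per subject) from dicts
    holding the metadata and the hemisphere-lobe / cerebellum / wm means."""
    cols = META_COLUMNS + mapping.region_columns()
    df = pd.DataFrame(subject_rows)
    df["normalization"] = "absolute"
    return df[cols]


def normalize_table(table: pd.DataFrame, which: str, mapping: RegionMapping) -> pd.DataFrame:
    """Divide every region column by the per-subject reference value.

    Subjects with a missing or nonpositive reference are dropped with a
    warning.  The reference region normalized by itself is exactly 1.
    """
    if which not in NORMALIZATIONS:
        raise ConfigurationError(f"unknown normalization {which!r}; expected one of {NORMALIZATIONS}")
    region_cols = [c for c in table.columns if c not in META_COLUMNS]
    out = table.copy()
    if which == "cer":
        ref = out["cerebellum"].astype(float)
    elif which == "wm":
        ref = out["wm"].astype(float)
    else:
        lobe_means = []
        for lobe in mapping.lobes:
            hemi_cols = [f"{lobe}_{h}" for h in mapping.hemispheres]
            lobe_means.append(out[hemi_cols].astype(float).mean(axis=1))
        ref = pd.concat(lobe_means, axis=1).mean(axis=1)
    bad = ~(ref > 0)
    if bad.any():
        warnings.warn(
            f"{which}: dropping {int(bad.sum())} subject(s) with missing/zero reference "
            f"({out.loc[bad, 'subject_id'].tolist()})",
            stacklevel=2,
        )
        out = out[~bad].copy()
        ref = ref[~bad]
    out[region_cols] = out[region_cols].astype(float).div(ref, axis=0)
    out["normalization"] = which
    return out
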
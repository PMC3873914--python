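"""Pipeline orchestration: simulate -> quantify -> extract -> normalize -> compare.

One :class:`RunConfig` (optionally loaded from YAML) drives the whole run;
a fixed seed makes every output — including the report tables — exactly
reproducible.  Each stage writes its artifacts under the run directory and
the final manifest records per-file SHA-256 checksums of all text outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .dsc_quant import QuantOptions, compute_cbf_map
from .group_stats import compare_all
from .io import load_nifti, load_subject_arrays, save_nifti, save_subject, write_json, write_tsv
from .phantom import CohortSpec, default_cohort_spec, generate_cohort, lookup_table
from .roi_norm import (
    META_COLUMNS,
    NORMALIZATIONS,
    RegionMapping,
    aggregate_lobes,
    extract_roi_means,
    normalize_table,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "extract_subject_row"]

REPORT_FILES = {
    "bias_check": "bias_check.tsv",
    "group_comparisons": "group_comparisons.tsv",
    "cv_table": "cv_table.tsv",
    "variance_components": "variance_components.tsv",
}


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec
    quant: QuantOptions = field(default_factory=QuantOptions)
    normalizations: tuple[str, ...] = NORMALIZATIONS
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.normalizations) - set(NORMALIZATIONS)
        if unknown:
            raise ConfigurationError(f"unknown normalization(s) {sorted(unknown)}; valid: {NORMALIZATIONS}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        cohort_kw = dict(raw.get("cohort", {}))
        if "shape" in cohort_kw:
            cohort_kw["shape"] = tuple(cohort_kw["shape"])
        cohort = default_cohort_spec(seed=seed, **cohort_kw)
        quant = QuantOptions(**raw.get("quant", {}))
        return cls(
            cohort=cohort,
            quant=quant,
            normalizations=tuple(raw.get("normalizations", NORMALIZATIONS)),
            alpha=float(raw.get("alpha", 0.05)),
            seed=seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def extract_subject_row(cbf_map, labels, mapping: RegionMapping, meta: dict) -> dict:
    """One subject's ROI-table row: hemisphere-lobe means plus the
    cerebellum and WM reference regions (the artery is excluded)."""
    means, counts = extract_roi_means(cbf_map, labels, mapping)
    lobes = aggregate_lobes(means, mapping, counts)
    row = dict(meta)
    row.update(lobes)
    row["cerebellum"] = means.get("cerebellum", float("nan"))
    row["wm"] = means.get("wm", float("nan"))
    return row


def stage_simulate(config: RunConfig, rundir: Path) -> pd.DataFrame:
    subj_dir = rundir / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    subjects, manifest = generate_cohort(config.cohort)
    for subj in subjects:
        save_subject(subj, subj_dir)
    write_tsv(lookup_table(config.cohort.tissue_specs), rundir / "labels.tsv")
    write_json(manifest.to_dict(orient="records"), rundir / "cohort_manifest.json")
    write_tsv(manifest, rundir / "cohort_manifest.tsv")
    return manifest


def stage_quantify(config: RunConfig, rundir: Path, manifest: pd.DataFrame) -> None:
    subj_dir = rundir / "subjects"
    for _, rec in manifest.iterrows():
        sid = rec["subject_id"]
        try:
            signal, labels = load_subject_arrays(subj_dir, sid)
            cbf_map, aif = compute_cbf_map(signal, labels > 0, config.cohort.acq, config.quant)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage/subject
            raise RuntimeError(f"stage quantify failed for subject {sid}: {exc}") from exc
        np.save(subj_dir / f"{sid}_cbf_valid.npy", cbf_map.valid)
        save_nifti(cbf_map.values.astype(np.float32), subj_dir / f"{sid}_cbf.nii.gz")
        write_json(
            {
                "subject_id": sid,
                "n_aif_voxels": int(len(aif.voxel_indices)),
                "aif_voxels": aif.voxel_indices.tolist(),
                "aif_fit": None
                if aif.fit is None
                else {
                    "amplitude": aif.fit.amplitude,
                    "alpha": aif.fit.alpha,
                    "beta": aif.fit.beta,
                    "t0": aif.fit.t0,
                },
                "aif_curve": [float(v) for v in aif.curve],
            },
            subj_dir / f"{sid}_aif.json",
        )


def stage_extract(config: RunConfig, rundir: Path, manifest: pd.DataFrame) -> pd.DataFrame:
    from .dsc_quant import CBFMap

    subj_dir = rundir / "subjects"
    mapping = RegionMapping(pd.read_csv(rundir / "labels.tsv", sep="\t"))
    rows = []
    for _, rec in manifest.iterrows():
        sid = rec["subject_id"]
        values = load_nifti(subj_dir / f"{sid}_cbf.nii.gz")
        valid = np.load(subj_dir / f"{sid}_cbf_valid.npy")
        _, labels = load_subject_arrays(subj_dir, sid)
        cbf_map = CBFMap(values=values, valid=valid)
        meta = {
            "subject_id": sid,
            "group": rec["group"],
            "age": rec["age"],
            "normalization": "absolute",
        }
        rows.append(extract_subject_row(cbf_map, labels, mapping, meta))
    cols = META_COLUMNS + mapping.region_columns()
    table = pd.DataFrame(rows)[cols]
    write_tsv(table, rundir / "roi_absolute.tsv")
    return table


def stage_normalize(config: RunConfig, rundir: Path, absolute: pd.DataFrame) -> dict[str, pd.DataFrame]:
    mapping = RegionMapping(pd.read_csv(rundir / "labels.tsv", sep="\t"))
    tables = {"absolute": absolute}
    for which in config.normalizations:
        tab = normalize_table(absolute, which, mapping)
        write_tsv(tab, rundir / f"roi_norm_{which}.tsv")
        tables[which] = tab
    return tables


def stage_compare(config: RunConfig, rundir: Path, tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    mapping = RegionMapping(pd.read_csv(rundir / "labels.tsv", sep="\t"))
    reports = compare_all(tables, mapping, control=config.cohort.control_group, alpha=config.alpha)
    for key, fname in REPORT_FILES.items():
        write_tsv(reports[key], rundir / fname)
    return reports


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir`` and write the run manifest."""
    rundir = Path(out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = stage_simulate(config, rundir)
    stage_quantify(config, rundir, manifest)
    absolute = stage_extract(config, rundir, manifest)
    tables = stage_normalize(config, rundir, absolute)
    stage_compare(config, rundir, tables)

    checksums = {
        p.name: _sha256(p)
        for p in sorted(rundir.glob("*.tsv")) + sorted(rundir.glob("*.json"))
        if p.name != "run_manifest.json"
    }
    write_json(
        {
            "dscnorm_version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "normalizations": list(config.normalizations),
            "n_subjects": int(len(manifest)),
            "quant_options": asdict(config.quant),
            "checksums": checksums,
        },
        rundir / "run_manifest.json",
    )
    return rundir


def make_fixtures(scale: str = "tiny", seed: int = 0) -> CohortSpec:
    """Cohort specs for testing: ``tiny`` (3 subjects/group on 8x8x4
    volumes, seconds to run) or ``default`` (study-sized cohort)."""
    if scale == "tiny":
        return default_cohort_spec(
            seed=seed,
            group_sizes={"control": 3, "MCI": 3, "AD": 3},
            shape=(8, 8, 4),
        )
    if scale == "default":
        return default_cohort_spec(seed=seed)
    raise ConfigurationError(f"unknown fixture scale {scale!r}")
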
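"""NIfTI / TSV / JSON input-output helpers.

Voxel sizes follow the perfusion acquisition geometry (1.8 x 1.8 mm
in-plane, 5 mm slices); phantoms are generated pre-aligned, so a diagonal
affine is sufficient and no registration is performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SubjectDataset

__all__ = [
    "PWI_AFFINE",
    "save_nifti",
    "load_nifti",
    "save_subject",
    "load_subject_arrays",
    "write_tsv",
    "write_json",
]

PWI_AFFINE = np.diag([1.8, 1.8, 5.0, 1.0])


def save_nifti(data: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), PWI_AFFINE)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_subject(subj: SubjectDataset, outdir) -> dict[str, str]:
    """Write one subject's 4D PWI, label volume and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pwi": outdir / f"{subj.subject_id}_pwi.nii.gz",
        "labels": outdir / f"{subj.subject_id}_labels.nii.gz",
        "truth": outdir / f"{subj.subject_id}_truth.tsv",
    }
    save_nifti(subj.signal.astype(np.float32), paths["pwi"])
    save_nifti(subj.labels.astype(np.int16), paths["labels"])
    write_tsv(subj.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def load_subject_arrays(outdir, subject_id: str):
    outdir = Path(outdir)
    signal = load_nifti(outdir / f"{subject_id}_pwi.nii.gz")
    labels = load_nifti(outdir / f"{subject_id}_labels.nii.gz").astype(int)
    return signal, labels
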
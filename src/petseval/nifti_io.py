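"""NIfTI and table I/O.

Volumes are stored as float32 NIfTI with voxel spacing on the affine
diagonal; masks as uint8 0/1. Reads validate what writes guarantee:
spacing present and positive, mask values strictly binary.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from petseval.core import PETVolume, SegmentationMask
from petseval.phantom import PhantomRecord


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(volume: PETVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def read_volume(path) -> PETVolume:
    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: NIfTI header lacks positive voxel spacing")
    return PETVolume(np.asarray(img.dataobj, dtype=np.float64), tuple(spacing))


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def read_mask(path) -> SegmentationMask:
    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: NIfTI header lacks positive voxel spacing")
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path}: mask file is not binary (values {uniq[:6]})")
    return SegmentationMask(data.astype(bool), tuple(spacing))


def write_cohort(records: list[PhantomRecord], outdir) -> Path:
    """Write each record as volume+mask NIfTI plus a cohort truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_volume(rec.volume, outdir / f"{rec.case_id}_pet.nii.gz")
        write_mask(rec.truth_mask, outdir / f"{rec.case_id}_truth.nii.gz")
        rows.append(
            {
                "case_id": rec.case_id,
                "true_mtv_ml": rec.true_mtv,
                "true_tlg_g": rec.true_tlg,
                "scanner_id": rec.scanner_id,
                "seed": rec.spec.seed,
            }
        )
    truth_path = outdir / "cohort_truth.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    return truth_path
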
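"""File formats: NIfTI-1 volumes, motion text, subject tables, reports.

Volumes are written as uncompressed NIfTI-1 (`.nii`) with float32 data so
output files are byte-deterministic; nibabel reads `.nii.gz` inputs
transparently.  Motion traces are 6-column whitespace-delimited text (one
row per frame: 3 translations mm, 3 rotations rad), subject tables TSV
with a fixed header, FD series single-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Bold4D, MotionTrace, SCORE_NAMES
from .preprocess import FDSeries

SUBJECT_TABLE_COLUMNS = [
    "id", "group", "mci_subgroup", "age", "sex", "education", *SCORE_NAMES,
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def save_bold(bold: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(bold.voxel_size_mm))
    img.header.set_zooms((*bold.voxel_size_mm, bold.tr_s))
    nib.save(img, str(path))


def load_bold(path: str | Path) -> Bold4D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Bold4D(np.asarray(img.dataobj, dtype=np.float64),
                  tuple(float(z) for z in zooms[:3]), tr)


def save_volume(data: np.ndarray, path: str | Path,
                voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             _affine(voxel_size_mm)), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def save_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), motion.as_matrix(), fmt="%.8f")


def load_motion(path: str | Path) -> MotionTrace:
    m = np.loadtxt(str(path))
    return MotionTrace(m[:, :3], m[:, 3:])


def save_fd(fd: FDSeries, path: str | Path) -> None:
    pd.DataFrame({"fd_mm": fd.fd_mm}).to_csv(path, sep="\t", index=False)


def save_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SUBJECT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
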
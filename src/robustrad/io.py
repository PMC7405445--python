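"""NIfTI and table I/O with geometry validation.

Volumes are written one file per sequence plus an integer label file and the
white-matter / brain masks, with the voxel spacing carried in the NIfTI
affine (canonical axis order, physical mm).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    FormatError,
    GeometryError,
    LabelMap,
    MRIStudy,
    SEQUENCES,
    VolumeGrid,
)

_LABEL_FILE = "labels.nii.gz"
_WM_FILE = "wm_mask.nii.gz"
_BRAIN_FILE = "brain_mask.nii.gz"


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _spacing_of(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def write_study(study: MRIStudy, case_dir: str | Path) -> Path:
    """One NIfTI per sequence plus labels and masks."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.spacing)
    for seq, vol in study.sequences.items():
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), aff), case_dir / f"{seq}.nii.gz")
    nib.save(
        nib.Nifti1Image(study.labels.data.astype(np.int16), aff), case_dir / _LABEL_FILE
    )
    nib.save(
        nib.Nifti1Image(study.wm_mask.astype(np.uint8), aff), case_dir / _WM_FILE
    )
    nib.save(
        nib.Nifti1Image(study.brain_mask.astype(np.uint8), aff), case_dir / _BRAIN_FILE
    )
    return case_dir


def read_study(
    case_dir: str | Path,
    case_id: str | None = None,
    age: float = float("nan"),
    os_days: float = float("nan"),
    center: str = "unknown",
) -> MRIStudy:
    """Load and validate one case; grid mismatches are rejected with the
    offending spacings/shapes named."""
    case_dir = Path(case_dir)
    missing = [s for s in SEQUENCES if not (case_dir / f"{s}.nii.gz").exists()]
    if missing:
        raise FormatError(
            f"{case_dir}: missing sequences {missing}; required: {list(SEQUENCES)}"
        )
    imgs = {s: nib.load(case_dir / f"{s}.nii.gz") for s in SEQUENCES}
    ref_seq = SEQUENCES[0]
    ref_spacing = _spacing_of(imgs[ref_seq])
    ref_shape = imgs[ref_seq].shape
    for seq, img in imgs.items():
        if img.shape != ref_shape or not np.allclose(_spacing_of(img), ref_spacing):
            raise GeometryError(
                f"{seq}: shape {img.shape} spacing {_spacing_of(img)} does not match "
                f"{ref_seq}: shape {ref_shape} spacing {ref_spacing}"
            )
    sequences = {
        s: VolumeGrid(np.asanyarray(img.dataobj, dtype=np.float64), ref_spacing)
        for s, img in imgs.items()
    }
    lab_img = nib.load(case_dir / _LABEL_FILE)
    if lab_img.shape != ref_shape:
        raise GeometryError(
            f"labels: shape {lab_img.shape} does not match sequences {ref_shape}"
        )
    labels = LabelMap(np.asanyarray(lab_img.dataobj).astype(np.int16), ref_spacing)
    wm = np.asanyarray(nib.load(case_dir / _WM_FILE).dataobj).astype(bool)
    brain = np.asanyarray(nib.load(case_dir / _BRAIN_FILE).dataobj).astype(bool)
    return MRIStudy(
        case_id=case_id or case_dir.name,
        sequences=sequences,
        labels=labels,
        wm_mask=wm,
        brain_mask=brain,
        age=age,
        os_days=os_days,
        center=center,
    )


def write_cohort(
    studies: list[MRIStudy], clinical: pd.DataFrame, out_dir: str | Path
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for st in studies:
        write_study(st, out_dir / st.case_id)
    clinical.to_csv(out_dir / "clinical.csv", index=False)
    return out_dir


def read_cohort(cohort_dir: str | Path) -> tuple[list[MRIStudy], pd.DataFrame]:
    cohort_dir = Path(cohort_dir)
    clinical = pd.read_csv(cohort_dir / "clinical.csv")
    studies = []
    for row in clinical.itertuples(index=False):
        studies.append(
            read_study(
                cohort_dir / row.case_id,
                case_id=row.case_id,
                age=float(row.age),
                os_days=float(row.os_days),
                center=str(row.center),
            )
        )
    return studies, clinical
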
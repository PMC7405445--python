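"""Core containers shared by every pipeline stage.

All geometry is physical millimetres.  Volumes are stored axis-ordered
(x, y, z) with the third axis the axial (slice) direction; masks are boolean
arrays on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd


class GeometryError(ValueError):
    """Two volumes that must share a grid do not."""


class RegionError(ValueError):
    """An operation needs a non-empty region and got an empty one."""


class FormatError(ValueError):
    """Malformed label map / table / config."""


class CalibrationError(RuntimeError):
    """A perturbation calibration could not reach its target."""


SEQUENCES = ("T1", "T1c", "T2", "FLAIR")

#: integer codes of the four base tumour compartments in a LabelMap
LABEL_CODES = {"cet": 1, "net": 2, "nec": 3, "ed": 4}

REGION_NAMES = ("cet", "net", "nec", "ed", "wt", "core", "net_ncr", "net_ed")

FEATURE_FAMILIES = (
    "shape",
    "firstorder",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "GLDM",
    "geometry",
    "centroid",
    "deep",
    "clinical",
)

#: families computed from intensities (need a sequence)
INTENSITY_FAMILIES = ("firstorder", "GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM")


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacings must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeGrid | LabelMap") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def check_geometry(self, other: "VolumeGrid | LabelMap") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"grid mismatch: shape {self.shape} / spacing {self.spacing} vs "
                f"shape {other.shape} / spacing {other.spacing}"
            )

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing)


@dataclass
class LabelMap:
    """Integer compartment map on a VolumeGrid geometry.

    Codes follow :data:`LABEL_CODES`; 0 is background.  Codes are mutually
    exclusive by construction (one integer per voxel).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("label map must be integer-typed")
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D label map, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        known = set(LABEL_CODES.values()) | {0}
        present = set(np.unique(self.data).tolist())
        if not present <= known:
            raise FormatError(f"unknown label codes {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, name: str) -> np.ndarray:
        return self.data == LABEL_CODES[name]

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.spacing)


@dataclass
class MRIStudy:
    """One patient: four co-registered sequences, labels, masks, clinical data."""

    case_id: str
    sequences: dict[str, VolumeGrid]
    labels: LabelMap
    wm_mask: np.ndarray
    brain_mask: np.ndarray
    age: float
    os_days: float
    center: str = "unknown"

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCES if s not in self.sequences]
        if missing:
            raise FormatError(f"missing required sequences: {missing} (need {list(SEQUENCES)})")
        ref = self.sequences[SEQUENCES[0]]
        for name, vol in self.sequences.items():
            if not ref.same_geometry(vol):
                raise GeometryError(
                    f"sequence {name}: shape {vol.shape}/spacing {vol.spacing} does not "
                    f"match {SEQUENCES[0]}: shape {ref.shape}/spacing {ref.spacing}"
                )
        if self.labels.shape != ref.shape:
            raise GeometryError("label map grid does not match the sequences")
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.sequences[SEQUENCES[0]].spacing


class FeatureID(NamedTuple):
    """Structured feature identity: (sequence, region, family, name).

    ``sequence`` and ``region`` are ``"none"`` where the family does not use
    them (shape is intensity-free; geometry/centroid/clinical are global).
    """

    sequence: str
    region: str
    family: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "|".join(self)


class FeatureTable:
    """Cases x features matrix with structured feature IDs.

    Thin wrapper around a DataFrame whose columns are a 4-level MultiIndex
    (sequence, region, family, name) and whose index is the case id.
    """

    LEVELS = ("sequence", "region", "family", "name")

    def __init__(self, df: pd.DataFrame):
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 4:
            raise FormatError("FeatureTable needs a 4-level column MultiIndex")
        df = df.copy()
        df.columns = df.columns.set_names(self.LEVELS)
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature IDs: {dupes[:5]}")
        self.df = df

    @classmethod
    def from_records(cls, rows: Mapping[str, Mapping[FeatureID, float]]) -> "FeatureTable":
        """Build from {case_id: {FeatureID: value}}."""
        df = pd.DataFrame.from_dict(
            {cid: {tuple(fid): v for fid, v in feats.items()} for cid, feats in rows.items()},
            orient="index",
        )
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=cls.LEVELS)
        return cls(df)

    @property
    def case_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_ids(self) -> list[FeatureID]:
        return [FeatureID(*c) for c in self.df.columns]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_features(self) -> int:
        return self.df.shape[1]

    def subset(self, feature_ids: Iterable[FeatureID]) -> "FeatureTable":
        cols = [tuple(f) for f in feature_ids]
        return FeatureTable(self.df.loc[:, cols])

    def to_csv(self, path) -> None:
        self.df.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1, 2, 3], index_col=0)
        return cls(df)


def check_aligned(tables: Iterable[FeatureTable]) -> None:
    """Require identical case ids and feature IDs across tables."""
    tables = list(tables)
    ref = tables[0]
    for t in tables[1:]:
        if t.case_ids != ref.case_ids:
            raise FormatError("feature tables disagree on case ids")
        if list(t.df.columns) != list(ref.df.columns):
            raise FormatError("feature tables disagree on feature IDs")
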
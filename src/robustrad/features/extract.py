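"""Cohort-level feature extraction: the registry and the feature table.

The handcrafted bank per (sequence, region) totals 120 features: shape 26
(intensity-free, counted once per region), first-order 19, GLCM 24, GLRLM
16, GLSZM 16, NGTDM 5, GLDM 14.  Per case the table additionally holds the
7 enhancement-geometry features, the 8 centroid features (one per region)
and age; the deep stand-in (8192 per sequence x region) is off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import (
    FeatureID,
    FeatureTable,
    MRIStudy,
    REGION_NAMES,
    RegionError,
    SEQUENCES,
)
from ..regions import centroid_features, combine_labels
from .deep import DeepExtractorSpec, deep_features
from .discretize import DiscretizationSpec, discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .geometry import GEOMETRY_NAMES, enhancement_geometry
from .shape import SHAPE_NAMES, shape_features
from .texture import FAMILY_NAMES, texture_features_from_levels

log = logging.getLogger(__name__)

FAMILY_COUNTS = {
    "shape": 26,
    "firstorder": 19,
    "GLCM": 24,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
    "GLDM": 14,
}

TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM")


def registry_counts() -> dict[str, int]:
    """Actual family cardinalities from the name registries."""
    counts = {
        "shape": len(SHAPE_NAMES),
        "firstorder": len(FIRSTORDER_NAMES),
        **{fam: len(FAMILY_NAMES[fam]) for fam in TEXTURE_FAMILIES},
    }
    counts["total_per_sequence_region"] = sum(counts.values())
    counts["geometry"] = len(GEOMETRY_NAMES)
    counts["centroid"] = len(REGION_NAMES)
    return counts


@dataclass
class ExtractionConfig:
    """What to extract.  Defaults give the full handcrafted bank."""

    sequences: tuple[str, ...] = SEQUENCES
    regions: tuple[str, ...] = REGION_NAMES
    intensity_families: tuple[str, ...] = ("firstorder",) + TEXTURE_FAMILIES
    include_shape: bool = True
    include_geometry: bool = True
    include_centroids: bool = True
    include_age: bool = True
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    deep: DeepExtractorSpec | None = None  # None = deep features disabled


def extract_study_features(
    study: MRIStudy, config: ExtractionConfig
) -> dict[FeatureID, float]:
    """All configured features of one study; empty regions give NaN."""
    out: dict[FeatureID, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-region warnings handled via NaN
        regions = combine_labels(study.labels)
    spacing = study.spacing

    if config.include_shape:
        for region in config.regions:
            mask = regions[region]
            try:
                feats = shape_features(mask, spacing)
            except RegionError:
                feats = {n: np.nan for n in SHAPE_NAMES}
            for name, v in feats.items():
                out[FeatureID("none", region, "shape", name)] = v

    for seq in config.sequences:
        image = study.sequences[seq]
        for region in config.regions:
            mask = regions[region]
            empty = not mask.any()
            if not empty:
                levels, g = discretize(image, mask, config.discretization)
            if "firstorder" in config.intensity_families:
                feats = (
                    {n: np.nan for n in FIRSTORDER_NAMES}
                    if empty
                    else firstorder_features(image, mask, config.discretization)
                )
                for name, v in feats.items():
                    out[FeatureID(seq, region, "firstorder", name)] = v
            for fam in TEXTURE_FAMILIES:
                if fam not in config.intensity_families:
                    continue
                if empty:
                    feats = {n: np.nan for n in FAMILY_NAMES[fam]}
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        try:
                            feats = texture_features_from_levels(levels, g, fam)
                        except RegionError:
                            feats = {n: np.nan for n in FAMILY_NAMES[fam]}
                for name, v in feats.items():
                    out[FeatureID(seq, region, fam, name)] = v
            if config.deep is not None:
                vec = deep_features(image, mask, config.deep)
                for k, v in enumerate(vec):
                    out[FeatureID(seq, region, "deep", f"unit_{k:04d}")] = float(v)

    if config.include_geometry:
        for name, v in enhancement_geometry(regions, spacing).items():
            out[FeatureID("none", "cet", "geometry", name)] = v
    if config.include_centroids:
        for region, v in centroid_features(regions, study.brain_mask).items():
            out[FeatureID("none", region, "centroid", "offset")] = v
    if config.include_age:
        out[FeatureID("none", "none", "clinical", "age")] = study.age
    return out


def extract_feature_table(
    cohort: list[MRIStudy], config: ExtractionConfig | None = None
) -> FeatureTable:
    """One row per case.  Cases missing a configured sequence are skipped
    with a logged reason."""
    config = config or ExtractionConfig()
    rows: dict[str, dict[FeatureID, float]] = {}
    for study in cohort:
        missing = [s for s in config.sequences if s not in study.sequences]
        if missing:
            log.warning("skipping %s: missing sequences %s", study.case_id, missing)
            continue
        rows[study.case_id] = extract_study_features(study, config)
    return FeatureTable.from_records(rows)
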
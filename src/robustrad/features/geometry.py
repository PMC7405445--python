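"""Enhancement-geometry features (7) of the contrast-enhancing tumour.

These characterize the enhancing rim and its inner necrotic core: volumes,
equivalent-sphere rim width (difference of the equivalent radii of the total
and inner volumes), maximum 3-D diameter, surface area, and surface
regularity (surface area of the equal-volume sphere divided by the actual
surface area; 1 for a sphere, smaller for irregular surfaces).
"""

from __future__ import annotations

import math

import numpy as np

from ..regions import RegionSet
from .shape import _boundary_voxels, _max_pairwise, _mesh, _mesh_volume
from skimage import measure

GEOMETRY_NAMES = (
    "ce_volume",
    "inner_volume",
    "total_volume",
    "rim_width",
    "ce_maximum_3d_diameter",
    "ce_surface_area",
    "surface_regularity",
)


def _equivalent_radius(volume: float) -> float:
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0) if volume > 0 else 0.0


def enhancement_geometry(regions: RegionSet, spacing) -> dict[str, float]:
    """The 7 enhancement-geometry features, in mm / mm^2 / mm^3 units.

    An empty contrast-enhancement region yields missing values.
    """
    spacing = tuple(float(s) for s in spacing)
    voxvol = float(np.prod(spacing))
    cet = regions["cet"]
    nec = regions["nec"]
    if not cet.any():
        return {n: float("nan") for n in GEOMETRY_NAMES}

    ce_vol = float(cet.sum()) * voxvol
    inner_vol = float(nec.sum()) * voxvol
    total_vol = ce_vol + inner_vol
    rim = _equivalent_radius(total_vol) - _equivalent_radius(inner_vol)

    verts, faces = _mesh(cet, spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    mesh_vol = _mesh_volume(verts, faces)
    sphere_area = (36.0 * math.pi * mesh_vol**2) ** (1.0 / 3.0)
    bpts = _boundary_voxels(cet).astype(float) * np.asarray(spacing)
    return {
        "ce_volume": ce_vol,
        "inner_volume": inner_vol,
        "total_volume": total_vol,
        "rim_width": rim,
        "ce_maximum_3d_diameter": _max_pairwise(bpts),
        "ce_surface_area": area,
        "surface_regularity": sphere_area / area if area > 0 else float("nan"),
    }
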
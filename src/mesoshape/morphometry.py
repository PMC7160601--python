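"""3D reference morphometry of segmented voxel stacks and meshes.

Plays the role automated 3D image analysis plays for segmented microCT
cells: the volume and surface it reports are the reference every
lower-dimensional estimator is compared against.  Volume is exact voxel
counting; surface comes from a closed isosurface mesh extracted at the 0.5
level of the binary grid — voxel-face counting would overestimate smooth
surfaces by tens of percent and poison every bias comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from .shapes import VoxelVolume

__all__ = [
    "MorphometryResult",
    "OpenMeshError",
    "extract_objects",
    "measure_3d",
    "isosurface_mesh",
    "mesh_morphometry",
    "results_to_frame",
]

# Registered estimator tags; modules append on import.
METHOD_TAGS = {
    "voxel3d", "mesh3d", "cavalieri", "vsg",
    "geom_sphere", "geom_cylinder", "geom_capsule", "geom_prolate",
    "projection",
}


class OpenMeshError(ValueError):
    """Mesh is not watertight (open isosurface or boundary-touching object)."""


@dataclass
class MorphometryResult:
    """One (volume, surface) measurement of one object by one method."""

    object_id: str
    volume: float  # µm³
    surface: float  # µm²
    method: str
    sampling: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unregistered method tag {self.method!r}")


def results_to_frame(results) -> "pandas.DataFrame":
    """Tidy DataFrame of MorphometryResults (CSV output schema)."""
    import json

    import pandas as pd

    rows = [
        {
            "object_id": r.object_id,
            "method": r.method,
            "volume_um3": r.volume,
            "surface_um2": r.surface,
            "sampling_json": json.dumps(r.sampling, sort_keys=True, default=str),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def extract_objects(stack: VoxelVolume, min_voxels: int = 64) -> list[VoxelVolume]:
    """Split a labeled or binary stack into per-object padded sub-volumes.

    Objects are 26-connected foreground components (background is
    6-connected — the standard digital-topology pairing); components
    smaller than ``min_voxels`` are discarded.  Each sub-volume keeps its
    physical origin and a one-voxel background pad.
    """
    occ = stack.occupancy
    if occ.max() <= 1:
        labels, n = ndimage.label(occ > 0, structure=np.ones((3, 3, 3), dtype=bool))
    else:
        labels, n = occ.astype(np.int64), int(occ.max())
    objects = []
    slices = ndimage.find_objects(labels)
    for lab, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        mask = labels[slc] == lab
        if mask.sum() < min_voxels:
            continue
        sub = np.pad(mask.astype(np.uint8), 1)
        origin = tuple(
            stack.origin[i] + (slc[i].start - 1) * stack.spacing[i] for i in range(3)
        )
        objects.append(VoxelVolume(
            sub, stack.spacing, origin,
            shape_id=f"{stack.shape_id}:{lab}" if stack.shape_id else str(lab),
            label=lab,
        ))
    return objects


def isosurface_mesh(obj: VoxelVolume, level: float = 0.5,
                    sigma: float = 1.0) -> trimesh.Trimesh:
    """Closed triangle mesh of the foreground/background interface.

    Marching cubes at the given level of the occupancy field, with the
    physical per-axis spacing applied before any area or volume is summed.
    Requires a one-voxel background pad so the mesh closes.

    The binary field is anti-aliased with a Gaussian of ``sigma`` voxels
    before extraction: an isosurface of the raw 0/1 grid is a staircase
    whose area overestimates a smooth surface by ~9%, while the 0.5 level
    of the blurred field tracks the true interface to well under 1% once
    the narrowest feature spans a few voxels.  This is field anti-aliasing,
    not mesh smoothing (no vertex relaxation is ever applied).  Set
    ``sigma=0`` for the raw staircase isosurface.
    """
    if obj.touches_boundary():
        raise OpenMeshError(
            "object touches the grid boundary; pad with background before meshing"
        )
    field = np.pad(obj.occupancy.astype(np.float32), 4)
    if sigma > 0:
        blurred = ndimage.gaussian_filter(field, sigma)
        # tiny objects (about a voxel across) can blur entirely below the
        # level; fall back to the raw staircase isosurface for those
        if blurred.max() > level:
            field = blurred
    verts, faces, _, _ = skmeasure.marching_cubes(field, level=level, spacing=obj.spacing)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def measure_3d(obj: VoxelVolume) -> MorphometryResult:
    """Reference 3D measurement of a padded binary object.

    Volume is foreground voxel count × voxel volume (integer-exact up to
    one multiplication); surface is the total triangle area of the closed
    isosurface mesh at the 0.5 level.  No mesh smoothing is applied.
    """
    count = obj.foreground_count
    if count == 0:
        raise ValueError("empty object")
    mesh = isosurface_mesh(obj)
    return MorphometryResult(
        object_id=obj.shape_id,
        volume=count * obj.voxel_volume,
        surface=float(mesh.area),
        method="voxel3d",
        sampling={"spacing_um": list(obj.spacing), "n_voxels": count},
        provenance="voxel counting + isosurface mesh area",
    )


def mesh_morphometry(mesh: trimesh.Trimesh | str | Path) -> MorphometryResult:
    """Volume and surface of a watertight triangle mesh (vertex units µm).

    Surface is the sum of triangle areas; volume the absolute sum of
    signed tetrahedron volumes against the origin (translation-invariant
    by the divergence theorem).
    """
    if not isinstance(mesh, trimesh.Trimesh):
        loaded = trimesh.load(str(mesh), force="mesh")
        if not isinstance(loaded, trimesh.Trimesh):
            raise OpenMeshError(f"could not load a triangle mesh from {mesh}")
        mesh = loaded
    if not mesh.is_watertight:
        boundary = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
        raise OpenMeshError(
            f"mesh is not watertight: {len(boundary)} boundary edges"
        )
    return MorphometryResult(
        object_id=getattr(mesh, "metadata", {}).get("name", "mesh") or "mesh",
        volume=float(abs(mesh.volume)),
        surface=float(mesh.area),
        method="mesh3d",
        sampling={"n_faces": int(len(mesh.faces))},
        provenance="triangle mesh",
    )
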
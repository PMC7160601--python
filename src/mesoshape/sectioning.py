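"""2D sampling of voxelized cells: section stacks, random sections,
silhouette projections and per-profile shape metrics.

The section stack implements the systematic uniform random (SUR) design —
parallel planes at a fixed period with a random start offset — which is
what makes Cavalieri volume estimation unbiased.  "Random but evenly
spaced" sections are read as SUR throughout.  Sectioning is
nearest-slice: binary masks are never interpolated, so a section is always
an actual voxel slice and results are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

from .shapes import VoxelVolume

__all__ = [
    "SectionStack",
    "Projection",
    "ProfileMetrics",
    "section_stack",
    "random_section",
    "project",
    "profile_metrics",
    "rotate_about_z",
]

#: physical axis indices in (z, y, x) order
AXIS_Z, AXIS_Y, AXIS_X = 0, 1, 2


@dataclass
class SectionStack:
    """Ordered parallel binary sections with SUR sampling metadata.

    ``axis`` is the physical axis the section planes are perpendicular
    to; ``t`` the plane spacing (µm); ``offset`` the random start in
    [0, t) measured from the leading face of the object's tight foreground
    extent.  Empty (all-background) sections are retained — dropping them
    would bias Cavalieri volume estimates.
    """

    sections: list[np.ndarray]
    t: float
    axis: int
    offset: float
    pixel_size: float
    azimuth: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("section spacing t must be positive")
        if not (0 <= self.offset < self.t):
            raise ValueError("offset must lie in [0, t)")
        shapes = {s.shape for s in self.sections}
        if len(shapes) > 1:
            raise ValueError("all sections must share the same image shape")

    def __len__(self):
        return len(self.sections)

    def areas(self) -> np.ndarray:
        """Per-section profile area in µm²."""
        px2 = self.pixel_size**2
        return np.array([np.count_nonzero(s) * px2 for s in self.sections])


@dataclass
class Projection:
    """Orthogonal silhouette of an object along one axis."""

    silhouette: np.ndarray
    pixel_size: float
    axis: int


@dataclass(frozen=True)
class ProfileMetrics:
    """Planar measurements of one section or silhouette profile."""

    area: float  # µm²
    perimeter: float  # µm
    L: float  # maximum Feret diameter, µm
    W: float  # caliper width perpendicular to the L direction, µm
    r_eq: float  # equivalent-area circle radius sqrt(area/pi), µm

    @property
    def is_empty(self) -> bool:
        return self.area == 0


def _pixel_size(obj: VoxelVolume, axis: int) -> float:
    """In-plane pixel size; sectioning requires isotropic in-plane spacing."""
    inplane = [obj.spacing[i] for i in range(3) if i != axis]
    if not math.isclose(inplane[0], inplane[1], rel_tol=1e-9):
        raise ValueError("anisotropic in-plane spacing is not supported for sectioning")
    return inplane[0]


def _foreground_extent(obj: VoxelVolume, axis: int) -> tuple[int, int]:
    """Inclusive index range of slices containing foreground along `axis`."""
    proj = np.any(obj.occupancy, axis=tuple(i for i in range(3) if i != axis))
    idx = np.flatnonzero(proj)
    if idx.size == 0:
        raise ValueError("object has no foreground voxels")
    return int(idx[0]), int(idx[-1])


def _take_slice(obj: VoxelVolume, axis: int, index: int) -> np.ndarray:
    return np.take(obj.occupancy, index, axis=axis)


def rotate_about_z(obj: VoxelVolume, azimuth: float) -> VoxelVolume:
    """Rotate the object about the vertical (z) axis by `azimuth` radians.

    Nearest-neighbor resampling keeps the mask binary; the grid grows to
    contain the rotated object and is re-padded with background.
    """
    if azimuth == 0.0:
        return obj
    rot = ndimage.rotate(
        obj.occupancy, np.degrees(azimuth), axes=(1, 2),
        order=0, reshape=True, mode="constant", cval=0,
    )
    rot = np.pad(rot, 1)
    return VoxelVolume(rot.astype(np.uint8), obj.spacing, obj.origin,
                       shape_id=obj.shape_id, label=obj.label)


def section_stack(obj: VoxelVolume, n: int, axis: int = AXIS_Z,
                  seed=None, azimuth: float = 0.0) -> SectionStack:
    """Systematic uniform random stack of `n` parallel sections.

    The period is ``t = extent / n`` where extent is the object's tight
    foreground extent along `axis`; the start offset is drawn uniformly
    from [0, t).  Section k is the voxel slice containing plane coordinate
    ``u + k·t``.  An optional azimuthal pre-rotation about z supports the
    vertical-section design used for surface estimation.
    """
    if n < 1:
        raise ValueError("need at least one section")
    if azimuth != 0.0:
        obj = rotate_about_z(obj, azimuth)
    s = obj.spacing[axis]
    i0, i1 = _foreground_extent(obj, axis)
    n_slices = i1 - i0 + 1
    if n > n_slices:
        raise ValueError(f"requested {n} sections but only {n_slices} slices available")
    extent = n_slices * s
    t = extent / n
    rng = np.random.default_rng(seed)
    u = float(rng.uniform(0.0, t))
    sections = []
    for k in range(n):
        idx = i0 + int((u + k * t) / s)
        sections.append(_take_slice(obj, axis, min(idx, i1)))
    return SectionStack(sections, t=t, axis=axis, offset=u,
                        pixel_size=_pixel_size(obj, axis), azimuth=azimuth, seed=seed)


def random_section(obj: VoxelVolume, axis: int = AXIS_Z, seed=None) -> np.ndarray:
    """One section at a uniformly random plane through the object's tight
    foreground extent along `axis` (the Box-1 sampling design: the plane
    offset h is uniform over [-R, R] for a sphere of radius R)."""
    s = obj.spacing[axis]
    i0, i1 = _foreground_extent(obj, axis)
    extent = (i1 - i0 + 1) * s
    rng = np.random.default_rng(seed)
    h = float(rng.uniform(0.0, extent))
    idx = i0 + min(int(h / s), i1 - i0)
    return _take_slice(obj, axis, idx)


def project(obj: VoxelVolume, axis: int = AXIS_Z) -> Projection:
    """Orthogonal silhouette: a pixel is foreground iff any voxel along
    the projection ray is foreground (a digital stand-in for photographing
    macerated, isolated cells)."""
    if obj.foreground_count == 0:
        raise ValueError("cannot project an empty object")
    sil = np.any(obj.occupancy, axis=axis).astype(np.uint8)
    return Projection(sil, pixel_size=_pixel_size(obj, axis), axis=axis)


def _largest_component(img: np.ndarray) -> np.ndarray:
    labels, n = skmeasure.label(img > 0, connectivity=2, return_num=True)
    if n <= 1:
        return img > 0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _feret_LW(mask: np.ndarray) -> tuple[float, float]:
    """Length L and width W of a profile, in pixels.

    The measurement axis is the profile's major principal axis (from the
    second moments of the filled pixels); L is the caliper extent of the
    sub-pixel 0.5-level contour along that axis and W the extent
    perpendicular to it.  On pixelated profiles this is far more stable
    than taking the direction of the single farthest contour-point pair,
    whose jitter at flat tips tilts the width axis; for convex elongated
    profiles the two definitions agree to within a pixel.  For isotropic
    profiles (disc-like, degenerate orientation) the axis choice is
    immaterial and the lowest-angle axis is used.
    """
    padded = np.pad(mask.astype(np.uint8), 1)
    contours = skmeasure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return 0.0, 0.0
    pts = np.vstack(contours)
    if len(np.unique(np.round(pts, 6), axis=0)) < 3:
        return 1.0, 1.0  # single-pixel profile
    # principal orientation from second central moments of the filled pixels
    rr, cc = np.nonzero(padded)
    r0, c0 = rr.mean(), cc.mean()
    mrr = np.mean((rr - r0) ** 2)
    mcc = np.mean((cc - c0) ** 2)
    mrc = np.mean((rr - r0) * (cc - c0))
    # angle of the major axis in (row, col) coordinates; lowest-angle
    # tie-break when the moment tensor is isotropic
    if math.isclose(mrr, mcc, rel_tol=1e-9) and abs(mrc) < 1e-12:
        theta = 0.0
    else:
        theta = 0.5 * math.atan2(2 * mrc, mcc - mrr)
    axis_dir = np.array([-math.sin(theta), math.cos(theta)])
    perp = np.array([axis_dir[1], -axis_dir[0]])
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # collinear degenerate profile
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return float(d.max()), 1.0
    proj_a = hull @ axis_dir
    proj_p = hull @ perp
    L = float(proj_a.max() - proj_a.min())
    W = float(proj_p.max() - proj_p.min())
    if W > L:  # principal axis convention: L is the long side
        L, W = W, L
    return L, W


def profile_metrics(section: np.ndarray, pixel_size: float) -> ProfileMetrics:
    """Planar metrics of a binary profile.

    Area is pixel counting; perimeter uses the Crofton line-intercept
    estimate (rotation-robust, unlike naive boundary-pixel counting which
    overestimates by up to √2); L is the maximum Feret diameter of the
    largest 8-connected component and W the caliper width perpendicular to
    the L direction.  With multiple profile components only the largest is
    measured (single-cell assumption).  An empty section yields all-zero
    metrics.
    """
    if section.size == 0 or not np.any(section):
        return ProfileMetrics(0.0, 0.0, 0.0, 0.0, 0.0)
    comp = _largest_component(section)
    area = float(np.count_nonzero(comp)) * pixel_size**2
    perim = float(skmeasure.perimeter_crofton(comp, directions=4)) * pixel_size
    L_px, W_px = _feret_LW(comp)
    return ProfileMetrics(
        area=area,
        perimeter=perim,
        L=L_px * pixel_size,
        W=W_px * pixel_size,
        r_eq=math.sqrt(area / math.pi),
    )
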
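"""Synthetic cell shapes with known ground-truth morphometry.

Generates parametric solids emulating leaf mesophyll cells — elongated,
optionally tapered capsules for palisade cells, lobed bodies with
protrusions for spongy cells — plus the mathematical reference shapes
(sphere, capsule) used by classical geometric estimation methods.  Every
shape carries a ground truth: an exact closed form where one exists, or a
fine-grid isosurface measurement otherwise.

All lengths are in µm; volumes in µm³; surfaces in µm².  Voxel grids use
axis order (z, y, x) with z the stack axis; elongated shapes are built with
their long axis along z.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ShapeSpec",
    "GroundTruth",
    "VoxelVolume",
    "UnsupportedFamilyError",
    "ResolutionError",
    "analytic_morphometry",
    "voxelize",
    "make_benchmark_suite",
    "sphere_spec",
    "capsule_spec",
    "cylinder_spec",
    "prolate_spec",
    "trilobed_spec",
    "protruded_spec",
    "write_voxels",
    "read_voxels",
]

FAMILIES = ("sphere", "cylinder", "capsule", "prolate_spheroid", "lobed")


class UnsupportedFamilyError(ValueError):
    """No closed-form morphometry exists for this shape family."""


class ResolutionError(ValueError):
    """Voxel spacing too coarse to resolve the narrowest feature."""


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of one synthetic cell shape.

    Parameters by family (all µm):

    - ``sphere``: ``radius``
    - ``cylinder``: ``radius``, ``length`` (axis along z)
    - ``capsule``: ``radius``, ``length`` (tip-to-tip, requires
      ``length >= 2*radius``) and optional ``taper`` in (0, 1] — the
      tip-to-base radius ratio.  ``taper < 1`` gives a palisade-like
      rounded cone (no closed form; ground truth comes from a reference
      mesh).
    - ``prolate_spheroid``: semi-axes ``a >= b`` (``a`` along z)
    - ``lobed``: ``core`` (capsule params) plus ``protrusions``, a list of
      dicts with ``radius``, ``length``, ``attach`` (z, y, x) and
      ``direction`` (z, y, x); the body is the union of core and
      protrusion capsules.
    """

    shape_id: str
    family: str
    params: dict
    rng_seed: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        p = self.params
        if self.family == "sphere":
            _require_positive(p, "radius")
        elif self.family == "cylinder":
            _require_positive(p, "radius", "length")
        elif self.family == "capsule":
            _require_positive(p, "radius", "length")
            if p["length"] < 2 * p["radius"]:
                raise ValueError("capsule requires length >= 2*radius")
            taper = p.get("taper", 1.0)
            if not (0 < taper <= 1):
                raise ValueError("capsule taper must lie in (0, 1]")
        elif self.family == "prolate_spheroid":
            _require_positive(p, "a", "b")
            if p["a"] < p["b"]:
                raise ValueError("prolate spheroid requires a >= b")
        elif self.family == "lobed":
            core = p["core"]
            _require_positive(core, "radius", "length")
            if core["length"] < 2 * core["radius"]:
                raise ValueError("lobed core capsule requires length >= 2*radius")
            for prot in p.get("protrusions", []):
                _require_positive(prot, "radius", "length")
                if prot["length"] < 2 * prot["radius"]:
                    raise ValueError("protrusion capsule requires length >= 2*radius")
                attach = np.asarray(prot["attach"], dtype=float)
                if not _capsule_contains(attach[None, :], core["radius"], core["length"])[0]:
                    raise ValueError("protrusion attachment point must lie on or inside the core")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-membership test for (N, 3) physical coordinates (z, y, x)."""
        pts = np.asarray(points, dtype=float)
        p = self.params
        if self.family == "sphere":
            return np.einsum("ij,ij->i", pts, pts) <= p["radius"] ** 2
        if self.family == "cylinder":
            r2 = pts[:, 1] ** 2 + pts[:, 2] ** 2
            return (r2 <= p["radius"] ** 2) & (np.abs(pts[:, 0]) <= p["length"] / 2)
        if self.family == "capsule":
            taper = p.get("taper", 1.0)
            if taper == 1.0:
                return _capsule_contains(pts, p["radius"], p["length"])
            return _round_cone_contains(pts, p["radius"], p["radius"] * taper, p["length"])
        if self.family == "prolate_spheroid":
            a, b = p["a"], p["b"]
            return (pts[:, 0] / a) ** 2 + (pts[:, 1] ** 2 + pts[:, 2] ** 2) / b**2 <= 1.0
        # lobed: union of the core capsule and protrusion capsules
        core = p["core"]
        inside = _capsule_contains(pts, core["radius"], core["length"])
        for prot in p.get("protrusions", []):
            inside |= _segment_capsule_contains(
                pts, np.asarray(prot["attach"], float), np.asarray(prot["direction"], float),
                prot["radius"], prot["length"],
            )
        return inside

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight axis-aligned physical bounding box (lo, hi), each (z, y, x)."""
        p = self.params
        if self.family == "sphere":
            r = p["radius"]
            return -np.full(3, r), np.full(3, r)
        if self.family in ("cylinder", "capsule"):
            r, L = p["radius"], p["length"]
            lo = np.array([-L / 2, -r, -r])
            hi = np.array([L / 2, r, r])
            return lo, hi
        if self.family == "prolate_spheroid":
            a, b = p["a"], p["b"]
            return np.array([-a, -b, -b]), np.array([a, b, b])
        core = p["core"]
        r, L = core["radius"], core["length"]
        lo = np.array([-L / 2, -r, -r])
        hi = np.array([L / 2, r, r])
        for prot in p.get("protrusions", []):
            a0 = np.asarray(prot["attach"], float)
            u = _unit(np.asarray(prot["direction"], float))
            a1 = a0 + u * (prot["length"] - 2 * prot["radius"])
            pr = prot["radius"]
            lo = np.minimum(lo, np.minimum(a0, a1) - pr)
            hi = np.maximum(hi, np.maximum(a0, a1) + pr)
        return lo, hi

    def min_feature(self) -> float:
        """Diameter (µm) of the narrowest feature, for resolution checks."""
        p = self.params
        if self.family == "sphere":
            return 2 * p["radius"]
        if self.family in ("cylinder", "capsule"):
            d = 2 * p["radius"] * p.get("taper", 1.0)
            return min(d, p["length"])
        if self.family == "prolate_spheroid":
            return 2 * p["b"]
        radii = [p["core"]["radius"]] + [q["radius"] for q in p.get("protrusions", [])]
        return 2 * min(radii)


@dataclass(frozen=True)
class GroundTruth:
    """Reference volume and surface of a shape."""

    volume: float
    surface: float
    provenance: str  # "analytic" or "reference_mesh"

    def __post_init__(self):
        if self.volume <= 0 or self.surface <= 0:
            raise ValueError("ground-truth volume and surface must be positive")
        # isoperimetric inequality S^3 >= 36 pi V^2, with numerical slack
        if self.surface**3 < 36 * math.pi * self.volume**2 * (1 - 1e-3):
            raise ValueError("isoperimetric inequality violated: not a valid (V, S) pair")


@dataclass
class VoxelVolume:
    """Binary (or labeled) occupancy grid with physical voxel spacing.

    ``occupancy`` has axis order (z, y, x); ``spacing`` is the per-axis
    voxel edge length in µm and ``origin`` the physical coordinate of the
    center of voxel (0, 0, 0).
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape_id: str = ""
    label: int = 1

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    def touches_boundary(self) -> bool:
        occ = self.occupancy
        return bool(
            occ[0].any() or occ[-1].any()
            or occ[:, 0].any() or occ[:, -1].any()
            or occ[:, :, 0].any() or occ[:, :, -1].any()
        )


def _require_positive(params: dict, *keys: str) -> None:
    for k in keys:
        if k not in params:
            raise ValueError(f"missing parameter {k!r}")
        if params[k] <= 0:
            raise ValueError(f"parameter {k!r} must be strictly positive")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _capsule_contains(pts: np.ndarray, radius: float, length: float) -> np.ndarray:
    """Capsule along z, centered at origin, tip-to-tip length `length`."""
    half = length / 2 - radius
    z = np.clip(pts[:, 0], -half, half)
    d2 = (pts[:, 0] - z) ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2
    return d2 <= radius**2


def _segment_capsule_contains(pts, a0, direction, radius, length) -> np.ndarray:
    """Capsule whose segment starts at `a0` along `direction` (tip-to-tip length)."""
    u = _unit(direction)
    seg = max(length - 2 * radius, 0.0)
    t = np.clip((pts - a0) @ u, 0.0, seg)
    closest = a0[None, :] + t[:, None] * u[None, :]
    d2 = np.einsum("ij,ij->i", pts - closest, pts - closest)
    return d2 <= radius**2


def _round_cone_contains(pts, r_base, r_tip, length) -> np.ndarray:
    """Tapered capsule (round cone): hull of a base sphere of radius
    ``r_base`` and a tip sphere of radius ``r_tip``, tip-to-tip ``length``,
    axis along z with the wider end at negative z."""
    z1 = -length / 2 + r_base  # base sphere center
    z2 = length / 2 - r_tip  # tip sphere center
    h = z2 - z1
    if h <= 0:
        return _capsule_contains(pts, max(r_base, r_tip), length)
    d = np.hypot(pts[:, 1], pts[:, 2])
    zz = pts[:, 0] - z1
    b = (r_base - r_tip) / h
    a = math.sqrt(max(1.0 - b * b, 0.0))
    k = -b * d + a * zz
    dist = np.where(
        k < 0,
        np.hypot(d, zz) - r_base,
        np.where(k > a * h, np.hypot(d, zz - h) - r_tip, a * d + b * zz - r_base),
    )
    return dist <= 0.0


# ---------------------------------------------------------------------------
# Closed-form morphometry
# ---------------------------------------------------------------------------

def analytic_morphometry(spec: ShapeSpec) -> GroundTruth:
    """Exact volume and surface for families with a closed form.

    Capsule (spherocylinder) of radius r and tip-to-tip length L:
    ``V = πr²(L−2r) + (4/3)πr³``, ``S = 2πr(L−2r) + 4πr²``.  Prolate
    spheroid with semi-axes a > b and eccentricity ``e = sqrt(1 − b²/a²)``:
    ``V = (4/3)πab²``, ``S = 2πb²(1 + (a/(b·e))·arcsin e)``; a = b
    degenerates to the sphere formulas.  Lobed bodies (and tapered
    capsules) have no closed form — measure a fine voxelization with
    :func:`mesoshape.morphometry.mesh_morphometry` instead.
    """
    p = spec.params
    if spec.family == "lobed":
        raise UnsupportedFamilyError(
            "lobed shapes have no closed form; voxelize finely and use "
            "mesh_morphometry on the extracted isosurface"
        )
    if spec.family == "sphere":
        r = p["radius"]
        return GroundTruth(4 / 3 * math.pi * r**3, 4 * math.pi * r**2, "analytic")
    if spec.family == "cylinder":
        r, L = p["radius"], p["length"]
        return GroundTruth(math.pi * r**2 * L, 2 * math.pi * r * L + 2 * math.pi * r**2, "analytic")
    if spec.family == "capsule":
        if p.get("taper", 1.0) != 1.0:
            raise UnsupportedFamilyError(
                "tapered capsules have no closed form; use a reference mesh"
            )
        r, L = p["radius"], p["length"]
        cyl = L - 2 * r
        return GroundTruth(
            math.pi * r**2 * cyl + 4 / 3 * math.pi * r**3,
            2 * math.pi * r * cyl + 4 * math.pi * r**2,
            "analytic",
        )
    # prolate spheroid
    a, b = p["a"], p["b"]
    volume = 4 / 3 * math.pi * a * b**2
    if a == b:
        surface = 4 * math.pi * a**2
    else:
        e = math.sqrt(1 - b**2 / a**2)
        surface = 2 * math.pi * b**2 * (1 + a / (b * e) * math.asin(e))
    return GroundTruth(volume, surface, "analytic")


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def voxelize(spec: ShapeSpec, spacing: float) -> VoxelVolume:
    """Rasterize a shape onto an isotropic voxel grid.

    A voxel is foreground iff its center lies inside the implicit solid
    (matching how binary segmentations of real microCT scans behave).  The
    output is padded with at least one background voxel on every face so
    isosurface extraction always yields a closed mesh.  Deterministic for a
    fixed spec and spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    feat = spec.min_feature()
    if feat < 4 * spacing:
        raise ResolutionError(
            f"narrowest feature of {spec.shape_id or spec.family} is {feat:.3g} µm, "
            f"below 4 voxels at spacing {spacing:g} µm"
        )
    lo, hi = spec.bounding_box()
    start = lo - spacing  # one guaranteed pad voxel before the solid
    n = np.ceil((hi - lo + 2 * spacing) / spacing).astype(int) + 1
    zc, yc, xc = (start[i] + (np.arange(n[i]) + 0.5) * spacing for i in range(3))
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    occ = spec.contains(pts).reshape(n).astype(np.uint8)
    vol = VoxelVolume(
        occ, (spacing,) * 3,
        origin=tuple(start + 0.5 * spacing),
        shape_id=spec.shape_id,
    )
    if vol.touches_boundary():  # numerical safety; should not happen with a tight bbox
        occ = np.pad(occ, 1)
        vol = VoxelVolume(
            occ, (spacing,) * 3,
            origin=tuple(start - 0.5 * spacing),
            shape_id=spec.shape_id,
        )
    if vol.foreground_count == 0:
        raise ResolutionError("voxelization produced no foreground voxels")
    return vol


# ---------------------------------------------------------------------------
# Named shape constructors
# ---------------------------------------------------------------------------

def sphere_spec(radius: float = 10.0, shape_id: str = "sphere") -> ShapeSpec:
    return ShapeSpec(shape_id, "sphere", {"radius": radius})


def capsule_spec(radius: float = 5.0, length: float = 40.0, taper: float = 1.0,
                 shape_id: str = "capsule") -> ShapeSpec:
    return ShapeSpec(shape_id, "capsule", {"radius": radius, "length": length, "taper": taper})


def cylinder_spec(radius: float = 5.0, length: float = 40.0,
                  shape_id: str = "cylinder") -> ShapeSpec:
    return ShapeSpec(shape_id, "cylinder", {"radius": radius, "length": length})


def prolate_spec(a: float = 20.0, b: float = 5.0, shape_id: str = "prolate") -> ShapeSpec:
    return ShapeSpec(shape_id, "prolate_spheroid", {"a": a, "b": b})


def trilobed_spec(radius: float = 5.0, arm_length: float = 20.0,
                  shape_id: str = "trilobed") -> ShapeSpec:
    """Spongy-cell-like trilobed body: three capsule arms 120° apart in the
    (z, y) plane, joined at a central sphere-like core."""
    arms = []
    for angle in (90.0, 210.0, 330.0):
        th = math.radians(angle)
        arms.append({
            "radius": radius,
            "length": arm_length,
            "attach": (0.0, 0.0, 0.0),
            "direction": (math.sin(th), math.cos(th), 0.0),
        })
    core = {"radius": radius, "length": 2 * radius}  # degenerate capsule = sphere
    return ShapeSpec(shape_id, "lobed", {"core": core, "protrusions": arms})


def protruded_spec(core_radius: float = 6.0, core_length: float = 18.0,
                   protrusion_radius: float = 2.0, protrusion_length: float = 22.0,
                   n_protrusions: int = 4, rng_seed: int | None = 0,
                   shape_id: str = "protruded") -> ShapeSpec:
    """Spongy-cell-like body with long thin protrusions radiating from a
    capsule core (seeded jitter of protrusion placement)."""
    rng = np.random.default_rng(rng_seed)
    prots = []
    for i in range(n_protrusions):
        # evenly spread azimuths with a little jitter; tilt away from the axis
        az = 2 * math.pi * i / n_protrusions + rng.uniform(-0.3, 0.3)
        tilt = rng.uniform(math.radians(50), math.radians(90))
        direction = (
            math.cos(tilt) * (1 if i % 2 == 0 else -1),
            math.sin(tilt) * math.cos(az),
            math.sin(tilt) * math.sin(az),
        )
        zc = rng.uniform(-core_length / 4, core_length / 4)
        prots.append({
            "radius": protrusion_radius,
            "length": protrusion_length,
            "attach": (zc, 0.0, 0.0),
            "direction": direction,
        })
    return ShapeSpec(
        shape_id, "lobed",
        {"core": {"radius": core_radius, "length": core_length}, "protrusions": prots},
        rng_seed=rng_seed,
    )


@dataclass
class SuiteConfig:
    """Configuration of the synthetic benchmark suite."""

    spacing: float = 0.5  # µm, comparable to synchrotron microCT of leaves
    seed: int = 42
    families: tuple[str, ...] = ("sphere", "capsule", "palisade", "trilobed", "protruded")
    palisade_taper: float = 0.8  # tip/base diameter ratio of palisade-like cells


def make_benchmark_suite(config: SuiteConfig | None = None):
    """Build the benchmark suite: (spec, voxels, truth) triples.

    Emits one sphere and one capsule (the mathematical reference shapes),
    one tapered elongated capsule (palisade-like), one trilobed body and
    one body with long thin protrusions (spongy-like).  Ground truth is
    analytic where a closed form exists, otherwise measured from the
    isosurface mesh of a 2×-finer voxelization (provenance
    ``reference_mesh``).
    """
    from .morphometry import mesh_morphometry, isosurface_mesh

    cfg = config or SuiteConfig()
    builders = {
        "sphere": lambda: sphere_spec(10.0),
        "capsule": lambda: capsule_spec(5.0, 40.0),
        "palisade": lambda: capsule_spec(6.0, 50.0, taper=cfg.palisade_taper,
                                         shape_id="palisade"),
        "trilobed": lambda: trilobed_spec(5.0, 20.0),
        "protruded": lambda: protruded_spec(rng_seed=cfg.seed),
    }
    suite = []
    for name in cfg.families:
        spec = builders[name]()
        vox = voxelize(spec, cfg.spacing)
        try:
            truth = analytic_morphometry(spec)
        except UnsupportedFamilyError:
            fine = voxelize(spec, cfg.spacing / 2)
            res = mesh_morphometry(isosurface_mesh(fine))
            truth = GroundTruth(res.volume, res.surface, "reference_mesh")
        suite.append((spec, vox, truth))
    return suite


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O
# ---------------------------------------------------------------------------

def write_voxels(vol: VoxelVolume, path: str | Path) -> None:
    """Write a voxel volume as multipage TIFF (8-bit, foreground = 255)
    with a JSON sidecar holding spacing, origin and identity."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (vol.occupancy > 0).astype(np.uint8) * 255)
    sidecar = {
        "spacing_um": list(vol.spacing),
        "origin_um": list(vol.origin),
        "shape_id": vol.shape_id,
        "label": vol.label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_voxels(path: str | Path) -> VoxelVolume:
    """Read a multipage TIFF (+ optional JSON sidecar) as a VoxelVolume."""
    import tifffile

    path = Path(path)
    occ = (tifffile.imread(path) > 0).astype(np.uint8)
    if occ.ndim == 2:
        occ = occ[None]
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spacing = tuple(meta.get("spacing_um", (1.0, 1.0, 1.0)))
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return VoxelVolume(occ, spacing, origin, shape_id=meta.get("shape_id", path.stem))
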
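"""Benchmark driver: every estimator × every synthetic shape × replicates.

Runs the full comparison of 2D-based volume and surface estimators
against the 3D voxel reference on the synthetic cell suite, producing
tidy relative-difference records, summary tables and a band plot with the
±10% / ±25% accuracy bands conventionally drawn in such comparisons.

Replicates vary only the sampling randomness — section offset, cycloid
grid phase and azimuth — while shape voxelizations stay fixed, so the
observed spread isolates sampling noise from discretization.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import CycloidGrid, EstimatorConfig, estimate_all
from .morphometry import measure_3d, mesh_morphometry
from .shapes import SuiteConfig, VoxelVolume, make_benchmark_suite, read_voxels

__all__ = [
    "BenchmarkConfig",
    "run_benchmark",
    "summarize",
    "plot_fig1",
    "load_external_cells",
    "CELL_CLASSES",
]

log = logging.getLogger("mesoshape.benchmark")

#: shape_id → cell class of the synthetic suite
CELL_CLASSES = {
    "sphere": "mathematical",
    "capsule": "mathematical",
    "palisade": "palisade-like",
    "trilobed": "spongy-like",
    "protruded": "spongy-like",
}

RECORD_COLUMNS = [
    "shape_id", "cell_class", "method", "quantity", "reference", "estimate",
    "relative_difference", "n_sections", "replicate", "seed",
]


@dataclass
class BenchmarkConfig:
    """Full factorial benchmark configuration."""

    suite: SuiteConfig = field(default_factory=SuiteConfig)
    n_sections: tuple[int, ...] = (5, 20)
    replicates: int = 20
    seed: int = 0
    grid: CycloidGrid = field(default_factory=CycloidGrid)
    area_mode: str = "pixel"

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        suite = SuiteConfig(**raw.pop("suite", {}))
        grid = CycloidGrid(**raw.pop("grid", {}))
        return cls(suite=suite, grid=grid, **raw)


def _relative_difference(estimate: float, reference: float) -> float:
    """RD% = 100·(estimate − reference)/reference."""
    return 100.0 * (estimate - reference) / reference


def run_benchmark(config: BenchmarkConfig | None = None,
                  extra_objects: list[VoxelVolume] | None = None) -> pd.DataFrame:
    """Run shapes × methods × quantities × replicates; return tidy records.

    The reference for every relative difference is the 3D voxel
    measurement of the same object (volume by voxel counting, surface by
    isosurface area), mirroring comparisons against automated 3D image
    analysis.  Estimator failures yield records with NaN estimates and a
    status flag; the run continues.  Deterministic for a fixed master
    seed.
    """
    cfg = config or BenchmarkConfig()
    master = np.random.default_rng(cfg.seed)
    suite = make_benchmark_suite(cfg.suite)
    objects = [(spec.shape_id, vox) for spec, vox, _ in suite]
    for obj in extra_objects or []:
        objects.append((obj.shape_id, obj))

    rows = []
    for shape_id, vox in objects:
        t0 = time.perf_counter()
        reference = measure_3d(vox)
        cell_class = CELL_CLASSES.get(shape_id, "external")
        ref = {"volume": reference.volume, "surface": reference.surface}
        for n in cfg.n_sections:
            for rep in range(cfg.replicates):
                rep_seed = int(master.integers(0, 2**31 - 1))
                est_cfg = EstimatorConfig(n_sections=n, seed=rep_seed, grid=cfg.grid,
                                          area_mode=cfg.area_mode)
                try:
                    results = estimate_all(vox, est_cfg)
                except Exception as exc:  # keep the factorial grid running
                    log.warning("estimation failed on %s (n=%d rep=%d): %s",
                                shape_id, n, rep, exc)
                    rows.append({
                        "shape_id": shape_id, "cell_class": cell_class,
                        "method": "failed", "quantity": "volume",
                        "reference": ref["volume"], "estimate": float("nan"),
                        "relative_difference": float("nan"),
                        "n_sections": n, "replicate": rep, "seed": rep_seed,
                    })
                    continue
                for res in results:
                    for quantity in ("volume", "surface"):
                        est = getattr(res, quantity)
                        if math.isnan(est):
                            continue  # estimator does not report this quantity
                        rows.append({
                            "shape_id": shape_id, "cell_class": cell_class,
                            "method": res.method, "quantity": quantity,
                            "reference": ref[quantity], "estimate": est,
                            "relative_difference": _relative_difference(est, ref[quantity]),
                            "n_sections": n, "replicate": rep, "seed": rep_seed,
                        })
        log.info("benchmarked %s in %.1f s", shape_id, time.perf_counter() - t0)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per (method, quantity, n_sections, cell_class) summary of the RD
    distribution: mean, median, SD and the fraction of estimates inside
    the ±10% and ±25% accuracy bands."""
    if records.empty:
        return pd.DataFrame(columns=[
            "method", "quantity", "n_sections", "cell_class",
            "mean_rd", "median_rd", "sd_rd", "frac_within_10", "frac_within_25", "n",
        ])
    g = records.groupby(["method", "quantity", "n_sections", "cell_class"], sort=True)
    out = g["relative_difference"].agg(
        mean_rd="mean", median_rd="median", sd_rd="std", n="count",
        frac_within_10=lambda x: float(np.mean(np.abs(x) <= 10)),
        frac_within_25=lambda x: float(np.mean(np.abs(x) <= 25)),
    ).reset_index()
    return out


def plot_fig1(summary: pd.DataFrame, path) -> Path:
    """Dot chart of mean RD by method, one panel per quantity, with the
    ±10% (dark) and ±25% (light) accuracy bands shaded.  Writes SVG or
    PNG according to the file suffix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.empty:
        raise ValueError("cannot plot an empty summary")
    path = Path(path)
    quantities = sorted(summary["quantity"].unique())
    methods = sorted(summary["method"].unique())
    classes = sorted(summary["cell_class"].unique())
    colors = plt.get_cmap("tab10")
    fig, axes = plt.subplots(1, len(quantities), figsize=(6 * len(quantities), 5),
                             sharey=True, squeeze=False)
    for ax, quantity in zip(axes[0], quantities):
        sub = summary[summary["quantity"] == quantity]
        ax.axhspan(-25, 25, color="0.92", zorder=0)
        ax.axhspan(-10, 10, color="0.80", zorder=0)
        ax.axhline(0, color="k", lw=0.8)
        for ci, cls in enumerate(classes):
            s = sub[sub["cell_class"] == cls]
            x = [methods.index(m) for m in s["method"]]
            ax.scatter(x, s["mean_rd"], label=cls, color=colors(ci), zorder=3)
        ax.set_xticks(range(len(methods)), methods, rotation=45, ha="right")
        ax.set_title(quantity)
        ax.set_ylabel("relative difference from 3D value (%)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def load_external_cells(path, spacing: float = 0.5) -> list[VoxelVolume]:
    """Load user-supplied cells (labeled TIFF stacks or watertight meshes)
    into the benchmark path.  Meshes are voxelized at ``spacing`` µm.
    Unreadable or non-watertight files are skipped with a log entry; an
    empty or missing directory yields an empty list."""
    import trimesh

    from .morphometry import OpenMeshError

    root = Path(path)
    if not root.exists():
        return []
    objects: list[VoxelVolume] = []
    for f in sorted(root.iterdir()):
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                objects.append(read_voxels(f))
            elif f.suffix.lower() in (".obj", ".stl", ".ply"):
                mesh_morphometry(f)  # watertightness gate
                mesh = trimesh.load(str(f), force="mesh")
                vg = mesh.voxelized(spacing).fill()
                occ = np.pad(np.asarray(vg.matrix, dtype=np.uint8), 1)
                # trimesh voxel grids are (x, y, z); flip to (z, y, x)
                objects.append(VoxelVolume(occ.transpose(2, 1, 0), (spacing,) * 3,
                                           shape_id=f.stem))
        except (OpenMeshError, ValueError, OSError) as exc:
            log.warning("skipping %s: %s", f.name, exc)
    return objects
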
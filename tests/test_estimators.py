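"""Estimators: closed-form bias, model consistency, stereology, projection."""

import math

import numpy as np
import pytest

from mesoshape import (
    CycloidGrid,
    EstimationError,
    EstimatorConfig,
    ProfileMetrics,
    analytic_morphometry,
    capsule_spec,
    cavalieri_volume,
    cylinder_spec,
    estimate_all,
    geometric_capsule,
    geometric_cylinder,
    geometric_prolate,
    geometric_sphere,
    project,
    projection_estimate,
    prolate_spec,
    results_to_frame,
    section_stack,
    single_section_sphere_bias,
    sphere_spec,
    voxelize,
    vsg_surface,
)
from mesoshape.sectioning import profile_metrics


def disc_metrics(radius: float) -> ProfileMetrics:
    return ProfileMetrics(math.pi * radius**2, 2 * math.pi * radius,
                          2 * radius, 2 * radius, radius)


def _rasterized_profile(half_width_fn, length, pixel=0.025):
    """Binary image of the solid profile |y| <= f(x), x in [0, length]."""
    nx = int(round(length / pixel))
    x = (np.arange(nx) + 0.5) * pixel
    half = np.array([half_width_fn(xi) for xi in x])
    ny = int(2 * (half.max() / pixel + 2))
    y = (np.arange(ny) + 0.5) * pixel - ny * pixel / 2
    img = (np.abs(y)[:, None] <= half[None, :]).astype(np.uint8)
    return np.pad(img, 2), pixel


def test_single_section_sphere_bias_closed_form():
    rep = single_section_sphere_bias()
    assert rep.radius_ratio == pytest.approx(math.pi / 4, abs=1e-15)
    assert rep.volume_bias == pytest.approx(1 - (math.pi / 4) ** 3, abs=1e-15)
    assert rep.surface_bias == pytest.approx(1 - (math.pi / 4) ** 2, abs=1e-15)
    # the printed headline numbers: 0.79 R, 52% and 38%
    assert round(rep.radius_ratio, 2) == 0.79
    assert round(100 * rep.volume_bias) == 52
    assert round(100 * rep.surface_bias) == 38


class TestModelConsistency:
    """Each geometric model exactly recovers its matched shape from the
    exact axial mid-profile (discretization error only)."""

    def test_sphere_from_centered_disc(self):
        gt = analytic_morphometry(sphere_spec(10.0))
        res = geometric_sphere(disc_metrics(10.0))
        assert res.volume == pytest.approx(gt.volume, rel=1e-12)
        assert res.surface == pytest.approx(gt.surface, rel=1e-12)

    def test_cylinder_from_axial_rectangle(self):
        img, px = _rasterized_profile(lambda x: 5.0, 40.0)
        res = geometric_cylinder(profile_metrics(img, px))
        gt = analytic_morphometry(cylinder_spec(5.0, 40.0))
        assert res.volume == pytest.approx(gt.volume, rel=0.005)
        assert res.surface == pytest.approx(gt.surface, rel=0.005)

    def test_capsule_from_axial_stadium(self):
        r, L = 5.0, 40.0
        def half(x):
            if x < r:
                return math.sqrt(max(r**2 - (r - x) ** 2, 0.0))
            if x > L - r:
                return math.sqrt(max(r**2 - (x - (L - r)) ** 2, 0.0))
            return r
        img, px = _rasterized_profile(half, L)
        res = geometric_capsule(profile_metrics(img, px))
        gt = analytic_morphometry(capsule_spec(r, L))
        assert res.volume == pytest.approx(gt.volume, rel=0.005)
        assert res.surface == pytest.approx(gt.surface, rel=0.005)

    def test_prolate_from_axial_ellipse(self):
        a, b = 20.0, 5.0
        img, px = _rasterized_profile(
            lambda x: b * math.sqrt(max(1 - ((x - a) / a) ** 2, 0.0)), 2 * a)
        res = geometric_prolate(profile_metrics(img, px))
        gt = analytic_morphometry(prolate_spec(a, b))
        assert res.volume == pytest.approx(gt.volume, rel=0.005)
        assert res.surface == pytest.approx(gt.surface, rel=0.005)


def test_geometric_sphere_reproduces_section_bias():
    """Profiles with mean radius (π/4)·R yield (π/4)³ of the true volume."""
    res = geometric_sphere(disc_metrics(math.pi / 4 * 10.0))
    gt = analytic_morphometry(sphere_spec(10.0))
    assert res.volume == pytest.approx((math.pi / 4) ** 3 * gt.volume, rel=1e-12)


def test_geometric_estimators_reject_empty_input():
    empty = ProfileMetrics(0, 0, 0, 0, 0)
    for fn in (geometric_sphere, geometric_cylinder, geometric_capsule, geometric_prolate):
        with pytest.raises(EstimationError):
            fn([empty, empty])


def test_capsule_degenerate_cases():
    # L = 2r reduces exactly to the sphere model
    m = ProfileMetrics(math.pi * 25, 0, 10.0, 10.0, 5.0)
    cap, sph = geometric_capsule(m), geometric_sphere(m)
    assert cap.volume == pytest.approx(sph.volume, rel=1e-12)
    # L < 2r falls back to the sphere model with a metadata flag
    m = ProfileMetrics(math.pi * 25, 0, 8.0, 10.0, 5.0)
    cap = geometric_capsule(m)
    assert cap.sampling.get("sphere_fallback") is True
    assert cap.volume == pytest.approx(4 / 3 * math.pi * 125, rel=1e-12)


def test_prolate_swaps_axes_with_flag():
    m = ProfileMetrics(1.0, 0, 10.0, 40.0, 1.0)  # W > L
    res = geometric_prolate(m)
    assert res.sampling.get("axes_swapped") is True
    assert res.sampling["a_um"] == 20.0 and res.sampling["b_um"] == 5.0


def test_geometric_cylinder_squat_degenerate():
    m = ProfileMetrics(100.0, 0, 10.0, 10.0, 5.64)
    res = geometric_cylinder(m)
    assert np.isfinite(res.volume) and np.isfinite(res.surface)
    assert res.sampling["h_um"] == pytest.approx(2 * res.sampling["r_um"])


def test_projection_estimate_sphere(sphere_fine):
    _, vox, gt = sphere_fine
    res = projection_estimate(project(vox, axis=2))
    assert res.volume == pytest.approx(gt.volume, rel=0.03)
    assert res.surface == pytest.approx(gt.surface, rel=0.05)


def test_projection_estimate_capsule(capsule_fine):
    _, vox, gt = capsule_fine
    res = projection_estimate(project(vox, axis=2))
    assert res.volume == pytest.approx(gt.volume, rel=0.03)


def test_projection_estimate_trilobed_finite():
    from mesoshape import trilobed_spec

    vox = voxelize(trilobed_spec(), 0.5)
    res = projection_estimate(project(vox, axis=2))
    assert np.isfinite(res.volume) and res.volume > 0
    assert np.isfinite(res.surface) and res.surface > 0


def test_cavalieri_identity_full_stack(capsule_fine):
    from mesoshape.sectioning import _foreground_extent

    _, vox, _ = capsule_fine
    i0, i1 = _foreground_extent(vox, 0)
    st = section_stack(vox, i1 - i0 + 1, axis=0, seed=0)
    res = cavalieri_volume(st)
    assert res.volume == pytest.approx(vox.foreground_count * vox.voxel_volume, rel=1e-9)


def test_cavalieri_needs_two_sections(sphere_fine):
    _, vox, _ = sphere_fine
    with pytest.raises(EstimationError):
        cavalieri_volume(section_stack(vox, 1, axis=0, seed=0))


def test_cavalieri_grid_mode_close_to_pixel_mode(sphere_fine):
    _, vox, _ = sphere_fine
    st = section_stack(vox, 20, axis=0, seed=4)
    pix = cavalieri_volume(st)
    grid = cavalieri_volume(st, area_mode="grid", point_spacing=0.5, seed=9)
    assert grid.volume == pytest.approx(pix.volume, rel=0.05)


def test_vsg_requires_vertical_sections(sphere_fine):
    _, vox, _ = sphere_fine
    st = section_stack(vox, 20, axis=0, seed=0)
    with pytest.raises(ValueError, match="vertical"):
        vsg_surface(st)


def test_vsg_zero_intersection_grid_warns(sphere_fine):
    _, vox, _ = sphere_fine
    st = section_stack(vox, 5, axis=2, seed=0)
    res = vsg_surface(st, CycloidGrid(rho=2.0, tile_w=500.0, tile_h=500.0), seed=0)
    assert res.surface == 0.0
    assert res.sampling["zero_intersection_warning"] is True


def test_vsg_scale_equivariance():
    """Doubling every length scales the mean surface estimate ×4."""
    ests = {}
    for R in (5.0, 10.0):
        vox = voxelize(sphere_spec(R), 0.25 * R / 5.0)  # same relative resolution
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(40):
            st = section_stack(vox, 20, axis=2,
                               seed=int(rng.integers(2**31)),
                               azimuth=float(rng.uniform(0, 2 * math.pi)))
            vals.append(vsg_surface(st, CycloidGrid(rho=0.4 * R / 5.0),
                                    seed=int(rng.integers(2**31))).surface)
        ests[R] = np.mean(vals)
    assert ests[10.0] / ests[5.0] == pytest.approx(4.0, rel=0.15)


def test_estimate_all_registry_and_determinism(capsule_fine):
    _, vox, _ = capsule_fine
    cfg = EstimatorConfig(n_sections=20, seed=123)
    results = estimate_all(vox, cfg)
    tags = [r.method for r in results]
    assert len(tags) == len(set(tags)) == 8
    assert set(tags) == {"voxel3d", "cavalieri", "vsg", "geom_sphere",
                         "geom_cylinder", "geom_capsule", "geom_prolate", "projection"}
    again = estimate_all(vox, EstimatorConfig(n_sections=20, seed=123))
    csv_a = results_to_frame(results).to_csv(index=False)
    csv_b = results_to_frame(again).to_csv(index=False)
    assert csv_a == csv_b
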
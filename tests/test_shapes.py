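"""Shape factory: closed forms, voxelization, suite construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesoshape import (
    GroundTruth,
    ResolutionError,
    ShapeSpec,
    SuiteConfig,
    UnsupportedFamilyError,
    analytic_morphometry,
    capsule_spec,
    cylinder_spec,
    make_benchmark_suite,
    prolate_spec,
    protruded_spec,
    read_voxels,
    sphere_spec,
    trilobed_spec,
    voxelize,
    write_voxels,
)


@pytest.mark.parametrize("spec, volume, surface", [
    (sphere_spec(1.0), 4 * math.pi / 3, 4 * math.pi),
    (capsule_spec(1.0, 4.0), 2 * math.pi + 4 * math.pi / 3, 4 * math.pi + 4 * math.pi),
    (cylinder_spec(1.0, 2.0), 2 * math.pi, 4 * math.pi + 2 * math.pi),
    # a = b degenerates to the sphere of radius 2
    (prolate_spec(2.0, 2.0), 4 / 3 * math.pi * 8, 16 * math.pi),
])
def test_closed_forms(spec, volume, surface):
    gt = analytic_morphometry(spec)
    assert gt.volume == pytest.approx(volume, rel=1e-12)
    assert gt.surface == pytest.approx(surface, rel=1e-12)
    assert gt.provenance == "analytic"


def test_capsule_l_equals_2r_is_a_sphere():
    cap = analytic_morphometry(capsule_spec(3.0, 6.0))
    sph = analytic_morphometry(sphere_spec(3.0))
    assert cap.volume == pytest.approx(sph.volume, rel=1e-12)
    assert cap.surface == pytest.approx(sph.surface, rel=1e-12)


@pytest.mark.parametrize("bad", [
    lambda: ShapeSpec("x", "sphere", {"radius": -1.0}),
    lambda: ShapeSpec("x", "capsule", {"radius": 3.0, "length": 4.0}),  # L < 2r
    lambda: ShapeSpec("x", "prolate_spheroid", {"a": 1.0, "b": 2.0}),  # a < b
    lambda: ShapeSpec("x", "lobed", {"core": {"radius": 1.0, "length": 2.0},
                                     "protrusions": [{"radius": 0.5, "length": 2.0,
                                                      "attach": (50, 0, 0),
                                                      "direction": (1, 0, 0)}]}),
])
def test_invalid_specs_rejected(bad):
    with pytest.raises(ValueError):
        bad()


def test_lobed_has_no_closed_form():
    with pytest.raises(UnsupportedFamilyError, match="mesh"):
        analytic_morphometry(trilobed_spec())


def test_tapered_capsule_has_no_closed_form():
    with pytest.raises(UnsupportedFamilyError):
        analytic_morphometry(capsule_spec(5.0, 40.0, taper=0.8))


@given(scale=st.floats(0.5, 5.0), r=st.floats(0.5, 5.0), elong=st.floats(2.0, 10.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_closed_forms_scale_equivariant(scale, r, elong):
    """Volume scales as length³ and surface as length² under rescaling,
    and every (V, S) pair satisfies the isoperimetric inequality."""
    for make in (lambda k: sphere_spec(k * r),
                 lambda k: capsule_spec(k * r, k * r * elong),
                 lambda k: prolate_spec(k * r * elong / 2, k * r)):
        base, scaled = analytic_morphometry(make(1.0)), analytic_morphometry(make(scale))
        assert scaled.volume == pytest.approx(base.volume * scale**3, rel=1e-9)
        assert scaled.surface == pytest.approx(base.surface * scale**2, rel=1e-9)
        assert base.surface**3 >= 36 * math.pi * base.volume**2 * (1 - 1e-9)


def test_isoperimetric_violation_rejected():
    with pytest.raises(ValueError, match="isoperimetric"):
        GroundTruth(volume=100.0, surface=1.0, provenance="analytic")


def test_voxel_volume_converges_to_analytic():
    spec = sphere_spec(10.0)
    gt = analytic_morphometry(spec)
    errs = []
    for spacing in (1.0, 0.5):
        v = voxelize(spec, spacing)
        errs.append(abs(v.foreground_count * v.voxel_volume - gt.volume) / gt.volume)
    assert errs[-1] < 0.01
    assert errs[1] < errs[0]  # monotone refinement on a smooth body


def test_voxelize_pads_and_resolves():
    v = voxelize(sphere_spec(10.0), 0.5)
    assert not v.touches_boundary()
    with pytest.raises(ResolutionError, match="4 voxels"):
        voxelize(sphere_spec(1.0), 1.0)


def test_voxelize_deterministic():
    a = voxelize(trilobed_spec(), 0.5)
    b = voxelize(trilobed_spec(), 0.5)
    assert np.array_equal(a.occupancy, b.occupancy)


def test_trilobed_is_connected():
    from scipy import ndimage

    v = voxelize(trilobed_spec(5.0, 20.0), 0.5)
    _, n = ndimage.label(v.occupancy, structure=np.ones((3, 3, 3), bool))
    assert n == 1


def test_lobed_volume_bounded_by_component_sum():
    """Union volume never exceeds the sum of the component capsules."""
    spec = trilobed_spec(5.0, 20.0)
    v = voxelize(spec, 0.5)
    union = v.foreground_count * v.voxel_volume
    core = analytic_morphometry(capsule_spec(5.0, 10.0)).volume
    arm = analytic_morphometry(capsule_spec(5.0, 20.0)).volume
    assert union <= core + 3 * arm


def test_benchmark_suite_contents():
    suite = make_benchmark_suite(SuiteConfig(seed=42))
    assert len(suite) >= 5
    ids = [spec.shape_id for spec, _, _ in suite]
    assert {"sphere", "capsule", "palisade", "trilobed", "protruded"} <= set(ids)
    for spec, vox, truth in suite:
        assert truth.surface**3 >= 36 * math.pi * truth.volume**2 * (1 - 1e-3)
        assert vox.foreground_count > 0
    # the sphere member's truth is the analytic closed form
    sphere_truth = next(t for s, _, t in suite if s.shape_id == "sphere")
    gt = analytic_morphometry(sphere_spec(10.0))
    assert sphere_truth.volume == gt.volume and sphere_truth.surface == gt.surface


def test_benchmark_suite_deterministic():
    a = make_benchmark_suite(SuiteConfig(seed=42))
    b = make_benchmark_suite(SuiteConfig(seed=42))
    for (_, va, _), (_, vb, _) in zip(a, b):
        assert np.array_equal(va.occupancy, vb.occupancy)


def test_tiff_roundtrip(tmp_path):
    v = voxelize(capsule_spec(5.0, 40.0), 0.5)
    write_voxels(v, tmp_path / "cell.tif")
    back = read_voxels(tmp_path / "cell.tif")
    assert np.array_equal(back.occupancy, v.occupancy)
    assert back.spacing == v.spacing
    assert back.shape_id == v.shape_id
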
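import numpy as np
import pytest

from mesoshape import (
    analytic_morphometry,
    capsule_spec,
    sphere_spec,
    voxelize,
)


@pytest.fixture(scope="session")
def sphere_fine():
    """Digital sphere R=10 µm at 0.25 µm voxels (radius spans 40 voxels)."""
    spec = sphere_spec(10.0)
    return spec, voxelize(spec, 0.25), analytic_morphometry(spec)


@pytest.fixture(scope="session")
def capsule_fine():
    """Digital capsule r=5, L=40 µm at 0.25 µm voxels."""
    spec = capsule_spec(5.0, 40.0)
    return spec, voxelize(spec, 0.25), analytic_morphometry(spec)


@pytest.fixture(scope="session")
def benchmark_records():
    """One shared full-factorial benchmark run (seeded, 20 replicates)."""
    from mesoshape import BenchmarkConfig, run_benchmark

    return run_benchmark(BenchmarkConfig(replicates=20, seed=7))
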
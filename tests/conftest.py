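import dataclasses

import numpy as np
import pytest

from tdtract.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact phantom for unit tests: steeper pennation, short fascicles."""
    return PhantomSpec(
        grid_shape=(30, 20, 24),
        voxel_size=(1.5, 1.5, 3.0),
        pennation_angle=40.0,
        muscle_half_width=15.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noisefree_phantom(small_spec):
    spec = dataclasses.replace(small_spec, snr=1e12, denoising_gain=1.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full two-pass pipeline on the default phantom (the study conditions),
    including the three-method comparison on the right compartment."""
    from tdtract.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    config = RunConfig(out_dir=str(out), phantom={}, compare_muscle=2, seed=0)
    return run_pipeline(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
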
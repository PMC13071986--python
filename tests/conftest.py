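import numpy as np
import pytest

from bonemorph import PhantomSpec, generate_bone_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact long-bone phantom that keeps morphology tests fast."""
    return PhantomSpec(
        length_vox=96,
        outer_radius_vox=36.0,
        cortical_thickness_vox=7.0,
        noise_sigma=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(volume, ground_truth) for the compact phantom."""
    return generate_bone_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_small_phantom(small_spec):
    """Noiseless variant of the compact phantom."""
    from dataclasses import replace

    return generate_bone_phantom(replace(small_spec, noise_sigma=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
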
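import numpy as np
import pytest

from atlasmorph.containers import BinaryMask, LabelVolume
from atlasmorph.phantom import PhantomSpec, SubjectRecord, build_template, generate_subject


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced grid for fast per-test phantom work."""
    return PhantomSpec(grid_shape=(32, 36, 32), voxel_size=4.0)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def hs_subject(small_spec):
    rec = SubjectRecord("HS-000", "HS", "F", 1.5, ("I0",))
    return generate_subject(small_spec, rec)


@pytest.fixture(scope="session")
def small_template(small_spec):
    return build_template(small_spec)


def random_label_volume(rng, shape=(10, 10, 10), n_codes=4, voxel_size=1.0) -> LabelVolume:
    grid = rng.integers(0, n_codes + 1, size=shape).astype(np.int16)
    return LabelVolume(grid, (voxel_size,) * 3)


def random_mask(rng, shape=(10, 10, 10), p=0.5, voxel_size=1.0) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p, (voxel_size,) * 3)
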
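import numpy as np
import pytest

from gpcrswitch import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def toy_catalogue():
    return synthetic.toy_dof_catalogue()


@pytest.fixture(scope="session")
def toy_bw():
    return synthetic.toy_bw_map()


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 50-frame written fixture from the beta-arrestin-ideal preset."""
    out = tmp_path_factory.mktemp("fixture")
    spec = synthetic.preset("beta_arrestin_ideal", n_frames=50, seed=11)
    paths = synthetic.write_fixture(spec, out)
    return spec, paths


def random_feature_vector(rng):
    """Uniform draw from the builder's constructible ranges."""
    return {d: rng.uniform(lo, hi)
            for d, (lo, hi) in synthetic.CONSTRUCTIBLE_RANGES.items()
            if d in synthetic.BASE_DOFS}
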
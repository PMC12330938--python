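import numpy as np
import pytest
from hypothesis import settings

import metconf as mc

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return mc.default_config()


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory, cfg):
    """Canonical synthetic fixture suite written once per session."""
    out = tmp_path_factory.mktemp("suite")
    written = mc.fixture_suite(cfg, str(out), seed=0)
    return out, written


def simple_recipe(name="fix", hd=3.5, ke=9.0, **kw):
    return mc.FixtureRecipe(name=name, targets={"HD": hd, "KE": ke}, **kw)


@pytest.fixture
def inactive_model(cfg):
    return mc.build_fixture(simple_recipe("inactive"), cfg)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
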
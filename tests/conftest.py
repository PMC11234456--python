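import numpy as np
import pytest

from msiox import mc, synth
from msiox.chromophores import load_chromophores


@pytest.fixture(scope="session")
def chromophores():
    return load_chromophores()


@pytest.fixture(scope="session")
def lut_small():
    """Tiny reflectance LUT for cheap functional tests.

    The Monte-Carlo noise in the nodes is shared by every consumer of the
    LUT (synthesis and fitting), so recovery-style tests remain exact even
    at this photon budget.
    """
    spec = mc.LutAxisSpec(
        t_epi=np.geomspace(0.02, 0.35, 4),
        mu_s_prime=np.geomspace(0.9, 17.0, 4),
        mu_a=np.concatenate(([0.0], np.geomspace(1e-4, 50.0, 10))),
    )
    return mc.build_lut(spec, n_photons_per_node=3000, seed=1)


@pytest.fixture(scope="session")
def models_small(lut_small):
    return synth.ForwardModels.default(lut_small)


@pytest.fixture(scope="session")
def study_models():
    """Forward models at the reference-study photon budget (seed 1)."""
    from msiox import study
    return study.build_study_models(1)
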
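import numpy as np
import pytest

from expomix.presets import postnatal_spec, prenatal_spec
from expomix.registry import load_default_registry
from expomix.simulate import simulate_study


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def small_prenatal_study():
    """A modest pregnancy cohort with a known DBP-asthma effect."""
    spec = prenatal_spec(
        n_subjects=600,
        analytes=["DBP", "DEHP"],
        outcomes=["asthma", "wheeze"],
        true_rr={("DBP", "asthma"): 1.30},
        seed=42,
    )
    return simulate_study(spec, seed=42)


@pytest.fixture(scope="session")
def small_postnatal_study():
    """A modest childhood cohort with a known MCPP-wheeze effect."""
    spec = postnatal_spec(
        n_subjects=600,
        analytes=["MCPP", "DEHP"],
        outcomes=["wheeze", "eczema"],
        true_rr={("MCPP", "wheeze"): 1.25},
        seed=7,
    )
    return simulate_study(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
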
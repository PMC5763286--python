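import numpy as np
import pytest

from pbpkcnm import DrugParameterSet, load_packaged_study


@pytest.fixture(scope="session")
def study():
    return load_packaged_study()


@pytest.fixture(scope="session")
def patient1(study):
    return study.patients[0]


@pytest.fixture(scope="session")
def bounds(study):
    return study.bounds


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


def random_params(bounds, rng, n=1):
    """Log-uniform parameter draws within the estimation bounds."""
    lo, hi = np.log(bounds.lower), np.log(bounds.upper)
    draws = np.exp(rng.uniform(lo, hi, size=(n, len(bounds))))
    sets = [DrugParameterSet(d) for d in draws]
    return sets[0] if n == 1 else sets


def distribution_only_params(kp=1.0, eps=1e-12):
    """Kp everywhere, all elimination and transit rates effectively off."""
    v = np.full(105, eps)
    v[:70] = kp
    return DrugParameterSet(v)
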
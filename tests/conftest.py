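import numpy as np
import pytest

from transjs.data import (
    ORIGIN_TRANSLOCATED,
    ORIGIN_WILD,
    CaptureData,
    CaptureHistory,
    StudyDesign,
)
from transjs.likelihood import ParameterSet
from transjs.simulate import scenario, simulate_dataset


def random_parameter_set(rng, T, tau=2, n_super=25.0):
    """A valid random ParameterSet with entry mass from occasion tau."""
    phi = rng.uniform(0.05, 0.95, size=T - 1)
    p = rng.uniform(0.05, 0.95, size=T)
    beta = np.zeros(T)
    raw = rng.uniform(0.1, 1.0, size=T - tau + 1)
    beta[tau - 1:] = raw / raw.sum()
    return ParameterSet(n_super=n_super, phi=phi, p=p, beta=beta)


def random_dataset(rng, T, tau=2, n_wild=6, n_trans=3):
    """A small observable dataset: random valid wild + translocated rows."""
    histories = []
    for i in range(n_wild):
        while True:
            x = (rng.random(T) < 0.5).astype(np.int8)
            if x.sum() and int(np.argmax(x)) + 1 >= tau:
                break
        histories.append(CaptureHistory(f"w{i}", ORIGIN_WILD, x))
    for i in range(n_trans):
        x = (rng.random(T) < 0.5).astype(np.int8)
        x[0] = 1
        histories.append(CaptureHistory(f"t{i}", ORIGIN_TRANSLOCATED, x))
    design = StudyDesign(
        n_occasions=T, occasion_times=np.arange(T, dtype=float), tau=tau
    )
    return CaptureData(design, histories)


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)


@pytest.fixture(scope="session")
def scenario5_replicate():
    """One seeded replicate of the mid-capture, 30-release scenario."""
    data, truth = simulate_dataset(scenario(5), 12345)
    return data, truth
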
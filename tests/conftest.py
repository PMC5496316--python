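import numpy as np
import pytest

from mimicsim import Dataset, ItemBank


@pytest.fixture
def rng():
    return np.random.default_rng(20170620)


def simulate_structural(
    n: int,
    lam: np.ndarray,
    tau: np.ndarray,
    psi: np.ndarray,
    gamma: float,
    beta: float,
    psi_z: float,
    studied_item: int,
    rng: np.random.Generator,
    focal_fraction: float = 0.5,
) -> Dataset:
    """Simulate directly from the linear MIMIC structural equations.

    Used as the correctly-specified oracle for parameter recovery and
    standard-error calibration: continuous normal indicators, binary group.
    """
    k = lam.shape[0]
    n_focal = int(round(n * focal_fraction))
    x = np.zeros(n)
    x[n - n_focal :] = 1.0
    theta = gamma * x + rng.normal(0.0, np.sqrt(psi_z), n)
    y = tau + np.outer(theta, lam)
    y[:, studied_item] += beta * x
    y += rng.normal(0.0, np.sqrt(psi), (n, k))
    bank = ItemBank(np.full(k, 1.75), np.tile([-1.0, 1.0], (k, 1)))
    return Dataset(y, x.astype(np.int64), bank, studied_item)
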
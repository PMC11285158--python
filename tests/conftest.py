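import numpy as np
import pytest

from gmatpipe import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_config(p: int = 2, seed: int = 0, **overrides) -> SimConfig:
    """A quick two-trait single-environment design used across tests."""
    base = dict(
        species="sp",
        n_blocks=4,
        environments=["e1"],
        offspring_per_family_per_env=6,
        trait_names=[f"t{i}" for i in range(p)],
        Sigma_sire=0.05 * np.eye(p),
        Sigma_dam=0.04 * np.eye(p),
        sigma2_block=0.002,
        Sigma_resid=0.4 * np.eye(p),
        rho_GE=1.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_table():
    return simulate_dataset(small_config(seed=7))


def random_psd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((p, p + 2))
    return scale * (A @ A.T) / (p + 2)
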
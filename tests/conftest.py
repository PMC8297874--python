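import logging

import numpy as np
import pytest

from fmmst import experiments
from fmmst.synth import SyntheticTrainSpec, default_spec, generate_train

logging.getLogger("fmmst").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def factorial_records():
    """The scaled factorial study: 100 configurations per stimulus level.

    Shared across the acceptance tests; this is the expensive fixture of
    the suite (it simulates and fits several hundred signals).
    """
    return experiments.run_factorial(100, seed=1)


@pytest.fixture(scope="session")
def analyzed_frame(factorial_records):
    df = experiments.records_to_frame(factorial_records)
    return df[df.fit_ok & (df.s >= 1)]


@pytest.fixture()
def three_spike_spec():
    """A clean 3-spike train with HH-like shapes and mild noise."""
    return default_spec(s=3, sigma=1.0, seed=42)


@pytest.fixture()
def noiseless_signal():
    spec = default_spec(s=3, sigma=0.0)
    theta, y = generate_train(spec)
    return spec, theta, y


def make_spec(s: int, sigma: float, seed: int, rng: np.random.Generator) -> SyntheticTrainSpec:
    """Randomized spike-train spec for recovery studies."""
    base = 2 * np.pi / s
    alpha_a = tuple(
        (0.5 + k * base + rng.uniform(-0.1, 0.1) * base) % (2 * np.pi) for k in range(s)
    )
    alpha_b = tuple((a + rng.uniform(0.25, 0.45) * base) % (2 * np.pi) for a in alpha_a)
    return SyntheticTrainSpec(
        s=s,
        M=float(rng.uniform(60, 120)),
        A_A=tuple(float(rng.uniform(45, 60)) for _ in range(s)),
        A_B=tuple(float(rng.uniform(12, 22)) for _ in range(s)),
        alpha_A=alpha_a,
        alpha_B=alpha_b,
        beta_A=float(rng.uniform(2.3, 2.9)),
        beta_B=float(rng.uniform(4.4, 5.0)),
        omega_A=float(rng.uniform(0.02, 0.05)),
        omega_B=float(rng.uniform(0.06, 0.12)),
        sigma=sigma,
        n=1200,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
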
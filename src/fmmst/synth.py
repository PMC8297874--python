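"""Synthetic spike-train generation from the FMM_ST generative model.

Signals are exact model evaluations (shared-shape A and B wave trains plus
intercept) with i.i.d. Gaussian noise, used both as test fixtures and for
parameter-recovery studies.  Defaults mirror the waveform regime of
simulated HH spike trains: dominant amplitudes near 50 mV, B amplitudes
near 15-20 mV, sharp A waves (omega ~ 0.03) and broader B waves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrain import SpikeTrainModel
from .waves import _TWO_PI

__all__ = ["SyntheticTrainSpec", "generate_train", "default_spec"]


@dataclass(frozen=True)
class SyntheticTrainSpec:
    """Ground truth for one synthetic spike train.

    Locations must interleave cyclically and A waves must dominate their
    spike's B wave; violations raise at construction.
    """

    s: int
    M: float
    A_A: tuple[float, ...]
    A_B: tuple[float, ...]
    alpha_A: tuple[float, ...]
    alpha_B: tuple[float, ...]
    beta_A: float
    beta_B: float
    omega_A: float
    omega_B: float
    sigma: float = 0.0
    n: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be >= 1")
        for name in ("A_A", "A_B", "alpha_A", "alpha_B"):
            if len(getattr(self, name)) != self.s:
                raise ValueError(f"{name} must have length s={self.s}")
        if any(a <= 0 for a in self.A_A + self.A_B):
            raise ValueError("amplitudes must be positive")
        if any(aa < ab for aa, ab in zip(self.A_A, self.A_B)):
            raise ValueError("dominance violated: every A_A must be >= A_B")
        for om in (self.omega_A, self.omega_B):
            if not (0 < om <= 1):
                raise ValueError("omega must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("noise sd sigma must be >= 0")
        # cyclic interleaving alpha_A[0] <= alpha_B[0] <= alpha_A[1] <= ...
        seq = []
        for aa, ab in zip(self.alpha_A, self.alpha_B):
            seq += [aa % _TWO_PI, ab % _TWO_PI]
        rel = [(x - seq[0]) % _TWO_PI for x in seq]
        if any(b < a - 1e-12 for a, b in zip(rel[:-1], rel[1:])):
            raise ValueError("alpha locations must interleave cyclically (A,B,A,B,...)")

    def to_model(self) -> SpikeTrainModel:
        return SpikeTrainModel(
            M=self.M,
            s=self.s,
            A_A=np.asarray(self.A_A, dtype=float),
            alpha_A=np.asarray(self.alpha_A, dtype=float) % _TWO_PI,
            beta_A=self.beta_A % _TWO_PI,
            omega_A=self.omega_A,
            A_B=np.asarray(self.A_B, dtype=float),
            alpha_B=np.asarray(self.alpha_B, dtype=float) % _TWO_PI,
            beta_B=self.beta_B % _TWO_PI,
            omega_B=self.omega_B,
            variant="ST",
            sigma2=self.sigma**2,
            r2=1.0,
        )


def default_spec(s: int = 3, sigma: float = 0.0, n: int = 1200, seed: int = 0) -> SyntheticTrainSpec:
    """A realistic HH-like spike-train spec with ``s`` evenly spaced spikes."""
    alpha_a = tuple((0.8 + k * _TWO_PI / s) % _TWO_PI for k in range(s))
    alpha_b = tuple((a + 0.35 * _TWO_PI / s) % _TWO_PI for a in alpha_a)
    return SyntheticTrainSpec(
        s=s,
        M=90.0,
        A_A=tuple(50.0 + 2.0 * k for k in range(s)),
        A_B=tuple(15.0 + 1.0 * k for k in range(s)),
        alpha_A=alpha_a,
        alpha_B=alpha_b,
        beta_A=2.6,
        beta_B=4.7,
        omega_A=0.03,
        omega_B=0.09,
        sigma=sigma,
        n=n,
        seed=seed,
    )


def generate_train(spec: SyntheticTrainSpec):
    """Evaluate the generative model on a uniform angle grid plus noise.

    Returns ``(theta, signal)`` with ``theta`` uniform on [0, 2*pi).
    Deterministic given ``spec.seed``.
    """
    theta = np.linspace(0.0, _TWO_PI, spec.n, endpoint=False)
    clean = spec.to_model().predict(theta)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.sigma, size=spec.n)
    return theta, clean
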
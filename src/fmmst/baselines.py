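"""Fourier harmonic-regression baselines.

An FD_a model regresses the signal on ``cos(k*theta), sin(k*theta)`` for
harmonics k = 1..a plus an intercept (1 + 2a free parameters), providing a
like-for-like comparison point for FMM spike-train models matched on the
number of free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waves import _TWO_PI, r_squared

__all__ = ["FourierModel", "fit_fourier"]


@dataclass
class FourierModel:
    a: int
    intercept: float
    cos_coef: np.ndarray
    sin_coef: np.ndarray
    r2: float

    @property
    def n_free_params(self) -> int:
        return 1 + 2 * self.a

    def predict(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(1, self.a + 1)
        return (
            self.intercept
            + np.cos(np.outer(theta, k)) @ self.cos_coef
            + np.sin(np.outer(theta, k)) @ self.sin_coef
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "intercept": self.intercept,
            "cos_coef": [float(c) for c in self.cos_coef],
            "sin_coef": [float(c) for c in self.sin_coef],
            "r2": self.r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FourierModel":
        return cls(
            a=int(d["a"]),
            intercept=float(d["intercept"]),
            cos_coef=np.asarray(d["cos_coef"], dtype=float),
            sin_coef=np.asarray(d["sin_coef"], dtype=float),
            r2=float(d["r2"]),
        )


def fit_fourier(signal, a: int, theta=None) -> FourierModel:
    """Ordinary least-squares harmonic regression with ``a`` harmonics."""
    if a <= 0:
        raise ValueError("number of harmonics a must be positive")
    y = np.asarray(signal, dtype=float)
    if 2 * a + 1 >= y.size:
        raise ValueError(f"a={a} requires more than {2 * a + 1} samples, got {y.size}")
    theta = (
        np.linspace(0.0, _TWO_PI, y.size, endpoint=False)
        if theta is None
        else np.asarray(theta, dtype=float)
    )
    k = np.arange(1, a + 1)
    X = np.column_stack(
        [np.ones(y.size), np.cos(np.outer(theta, k)), np.sin(np.outer(theta, k))]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return FourierModel(
        a=a,
        intercept=float(coef[0]),
        cos_coef=coef[1 : 1 + a].copy(),
        sin_coef=coef[1 + a :].copy(),
        r2=r_squared(y, fitted),
    )
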
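"""Frequency-modulated Mobius (FMM) waves and multicomponent model fitting.

An FMM wave is ``W(t; A, alpha, beta, omega) = A * cos(phi(t))`` with a
Mobius-transformed phase

    phi(t) = beta + 2*arctan(omega * tan((t - alpha) / 2)),

where ``t`` lives on the unit circle ``[0, 2*pi)``.  ``A`` is the amplitude,
``alpha`` the location, ``beta`` the skewness and ``omega`` the kurtosis of
the wave: ``omega = 1`` gives a plain sinusoid, small ``omega`` a sharp
spike-like deflection at ``alpha``.

A multicomponent FMM model is a signal-plus-error decomposition

    X(t_i) = M + sum_J W(t_i; v_J) + e(t_i),   e ~ N(0, sigma^2),

fitted by a two-stage scheme: a grid search over the nonlinear pair
``(alpha, omega)`` with the remaining parameters ``(M, A, beta)`` profiled
out by linear least squares, followed by derivative-free local refinement,
and backfitting across waves in the multicomponent case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "TimeGrid",
    "FMMWave",
    "FMMModel",
    "phase",
    "wave_value",
    "model_values",
    "fit_mono",
    "fit_multi",
    "r_squared",
]

_TWO_PI = 2.0 * np.pi

#: smallest admissible kurtosis parameter; below this the wave degenerates
#: into a numerically ill-conditioned delta-like spike
OMEGA_MIN = 0.01


@dataclass(frozen=True)
class TimeGrid:
    """Rescaling of an observed time window onto the circle [0, 2*pi).

    Parameters
    ----------
    t0
        Origin of the analyzed segment (same units as the raw times,
        typically ms).
    period
        Length ``T`` of the segment; times map as
        ``theta = (t - t0) * 2*pi / T``.
    theta
        The rescaled angles, strictly increasing in ``[0, 2*pi)``.
    """

    t0: float
    period: float
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim != 1 or th.size < 2:
            raise ValueError("theta must be a 1-D array with >= 2 points")
        if np.any(np.diff(th) <= 0):
            raise ValueError("theta must be strictly increasing")
        if th[0] < 0 or th[-1] >= _TWO_PI:
            raise ValueError("theta must lie in [0, 2*pi)")
        object.__setattr__(self, "theta", th)

    @classmethod
    def from_times(cls, t: np.ndarray) -> "TimeGrid":
        """Build a grid from raw times, treating the span as one period.

        The half-open period is ``[t[0], t[0] + T)`` with
        ``T = n * median(dt)`` so that the last sample maps strictly below
        ``2*pi``.
        """
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need a 1-D time vector with >= 2 points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time vector must be strictly increasing")
        period = t.size * float(np.median(dt))
        theta = (t - t[0]) * _TWO_PI / period
        return cls(t0=float(t[0]), period=period, theta=theta)


@dataclass(frozen=True)
class FMMWave:
    """Parameters of a single FMM wave."""

    A: float
    alpha: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"amplitude must be positive, got {self.A}")
        if not (0 < self.omega <= 1):
            raise ValueError(f"omega must be in (0, 1], got {self.omega}")
        object.__setattr__(self, "alpha", float(self.alpha) % _TWO_PI)
        object.__setattr__(self, "beta", float(self.beta) % _TWO_PI)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return wave_value(theta, self)


@dataclass
class FMMModel:
    """A fitted multicomponent FMM decomposition.

    Waves are ordered by decreasing amplitude unless the caller imposes a
    train-specific ordering.
    """

    M: float
    waves: list[FMMWave]
    sigma2: float
    r2: float

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return model_values(theta, self.M, self.waves)

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "sigma2": self.sigma2,
            "r2": self.r2,
            "waves": [
                {"A": w.A, "alpha": w.alpha, "beta": w.beta, "omega": w.omega}
                for w in self.waves
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FMMModel":
        return cls(
            M=float(d["M"]),
            waves=[FMMWave(**w) for w in d["waves"]],
            sigma2=float(d["sigma2"]),
            r2=float(d["r2"]),
        )


def phase(theta, alpha: float, beta: float, omega: float):
    """Mobius phase ``beta + 2*arctan(omega*tan((theta - alpha)/2))``.

    Evaluated through ``arctan2`` so the branch is continuous across the
    singularity of ``tan`` at ``theta - alpha = pi``, where the phase takes
    its limit value ``beta + pi``.  Advances monotonically by ``2*pi`` per
    period for any ``omega`` in (0, 1].
    """
    if not (0 < omega <= 1):
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    u = (np.asarray(theta, dtype=float) - alpha) / 2.0
    return beta + 2.0 * np.arctan2(omega * np.sin(u), np.cos(u))


def wave_value(theta, wave: FMMWave):
    """Evaluate ``A*cos(phi)`` for a single wave."""
    return wave.A * np.cos(phase(theta, wave.alpha, wave.beta, wave.omega))


def model_values(theta, M: float, waves) -> np.ndarray:
    out = np.full_like(np.asarray(theta, dtype=float), M)
    for w in waves:
        out = out + wave_value(theta, w)
    return out


def r_squared(observed, fitted) -> float:
    """Proportion of variance explained, ``1 - SSE/SST``.

    Raises for constant ``observed`` (zero total variance).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have the same shape")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined for a constant observed signal")
    sse = float(np.sum((observed - fitted) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# fitting


_HALF_ANGLE_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _half_angles(theta: np.ndarray):
    """Cached (theta, sin(theta/2), cos(theta/2)) keyed by array identity."""
    key = id(theta)
    hit = _HALF_ANGLE_CACHE.get(key)
    if hit is not None and hit[0] is theta:
        return hit[1], hit[2]
    if len(_HALF_ANGLE_CACHE) > 8:
        _HALF_ANGLE_CACHE.clear()
    sh, ch = np.sin(theta / 2.0), np.cos(theta / 2.0)
    _HALF_ANGLE_CACHE[key] = (theta, sh, ch)
    return sh, ch


def _mobius_base(theta: np.ndarray, alpha, omega: float) -> np.ndarray:
    """Phase with beta = 0; ``alpha`` may be an array (broadcast over rows).

    Uses the angle-difference identity on cached half-angle tables so each
    evaluation costs one arctan2 pass instead of three transcendental ones.
    """
    sh, ch = _half_angles(theta)
    a = np.atleast_1d(np.asarray(alpha, dtype=float))[:, None] / 2.0
    ca, sa = np.cos(a), np.sin(a)
    sin_u = sh * ca - ch * sa
    cos_u = ch * ca + sh * sa
    return 2.0 * np.arctan2(omega * sin_u, cos_u)


def _linear_profile(y: np.ndarray, Z: np.ndarray):
    """Profile (M, A, beta) out by least squares for each row of phases Z.

    The model is linear in ``(M, a, b)`` with regressors ``(1, cos Z, sin Z)``
    where ``a = A*cos(beta)`` and ``b = -A*sin(beta)``.  Returns per-row SSE
    and coefficient arrays.
    """
    n = y.size
    c, s = np.cos(Z), np.sin(Z)
    ones = np.ones(n)
    # batched 3x3 normal equations
    G = np.empty(Z.shape[:1] + (3, 3))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = c.sum(axis=1)
    G[:, 0, 2] = G[:, 2, 0] = s.sum(axis=1)
    G[:, 1, 1] = (c * c).sum(axis=1)
    G[:, 1, 2] = G[:, 2, 1] = (c * s).sum(axis=1)
    G[:, 2, 2] = (s * s).sum(axis=1)
    v = np.stack([np.full(Z.shape[0], y.sum()), c @ y, s @ y], axis=1)
    try:
        coef = np.linalg.solve(G, v[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        coef = np.stack([np.linalg.lstsq(
            np.column_stack([ones, c[i], s[i]]), y, rcond=None)[0]
            for i in range(Z.shape[0])])
    fitted = coef[:, 0:1] + coef[:, 1:2] * c + coef[:, 2:3] * s
    sse = ((y - fitted) ** 2).sum(axis=1)
    return sse, coef


def _coef_to_wave(coef: np.ndarray, alpha: float, omega: float):
    M, a, b = float(coef[0]), float(coef[1]), float(coef[2])
    A = float(np.hypot(a, b))
    beta = float(np.arctan2(-b, a)) % _TWO_PI
    return M, A, beta


def default_omega_grid() -> np.ndarray:
    """Kurtosis grid {0.01, 0.02, ..., 1}."""
    return np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


def fit_mono(
    signal,
    theta=None,
    *,
    alpha_grid: int | np.ndarray = 60,
    omega_grid: np.ndarray | None = None,
    refine: bool = True,
):
    """Fit a single FMM wave plus intercept by grid search + refinement.

    Parameters
    ----------
    signal
        Observed values on ``theta`` (defaults to a uniform grid on
        ``[0, 2*pi)``).
    alpha_grid
        Number of equispaced location candidates, or an explicit array.
    omega_grid
        Kurtosis candidates; defaults to ``{0.01, ..., 1}``.
    refine
        Polish ``(alpha, omega)`` with Nelder-Mead around the grid optimum.

    Returns
    -------
    (M, FMMWave, r2)
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("signal must be 1-D with >= 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate fit: signal is constant")
    theta = (
        np.linspace(0.0, _TWO_PI, y.size, endpoint=False)
        if theta is None
        else np.asarray(theta, dtype=float)
    )
    if theta.shape != y.shape:
        raise ValueError("theta and signal must have equal length")
    alphas = (
        np.linspace(0.0, _TWO_PI, int(alpha_grid), endpoint=False)
        if np.isscalar(alpha_grid)
        else np.asarray(alpha_grid, dtype=float)
    )
    omegas = default_omega_grid() if omega_grid is None else np.asarray(omega_grid)

    best = None  # (sse, coef, alpha, omega)
    for om in omegas:
        Z = _mobius_base(theta, alphas, float(om))
        sse, coef = _linear_profile(y, Z)
        i = int(np.argmin(sse))
        if best is None or sse[i] < best[0]:
            best = (float(sse[i]), coef[i], float(alphas[i]), float(om))

    sse0, coef0, alpha0, omega0 = best

    if refine:

        def objective(x):
            al, om = x
            om = float(np.clip(om, OMEGA_MIN, 1.0))
            Z = _mobius_base(theta, al, om)
            sse, _ = _linear_profile(y, Z)
            return float(sse[0])

        res = minimize(
            objective,
            x0=[alpha0, omega0],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 300},
        )
        if res.fun < sse0:
            alpha0 = float(res.x[0]) % _TWO_PI
            omega0 = float(np.clip(res.x[1], OMEGA_MIN, 1.0))
            Z = _mobius_base(theta, alpha0, omega0)
            sse_arr, coef_arr = _linear_profile(y, Z)
            sse0, coef0 = float(sse_arr[0]), coef_arr[0]

    M, A, beta = _coef_to_wave(coef0, alpha0, omega0)
    if A <= 0:  # degenerate flat fit; nudge to the admissible boundary
        A = 1e-12
    wave = FMMWave(A=A, alpha=alpha0, beta=beta, omega=omega0)
    fitted = M + wave(theta)
    return M, wave, r_squared(y, fitted)


def _joint_linear(y: np.ndarray, theta: np.ndarray, shapes):
    """Joint LS over (M, a_J, b_J) given all (alpha_J, omega_J) pairs.

    ``shapes`` is a list of (alpha, omega).  Returns (M, waves, fitted, sse).
    """
    cols = [np.ones_like(theta)]
    for al, om in shapes:
        Z = _mobius_base(theta, al, om)[0]
        cols.append(np.cos(Z))
        cols.append(np.sin(Z))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    M = float(coef[0])
    waves = []
    for j, (al, om) in enumerate(shapes):
        a, b = coef[1 + 2 * j], coef[2 + 2 * j]
        A = float(np.hypot(a, b))
        waves.append(
            FMMWave(A=max(A, 1e-12), alpha=al, beta=float(np.arctan2(-b, a)) % _TWO_PI, omega=om)
        )
    sse = float(np.sum((y - fitted) ** 2))
    return M, waves, fitted, sse


def fit_multi(
    signal,
    m: int,
    theta=None,
    *,
    alpha_grid: int = 60,
    omega_grid: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> FMMModel:
    """Fit an ``m``-wave FMM model by backfitting.

    Waves are added greedily (each new wave mono-fitted to the running
    residual), then cycled: each wave's ``(alpha, omega)`` is refitted
    against the residual of the others, with all linear parameters
    ``(M, A_J, beta_J)`` re-solved jointly after every update, until the
    relative SSE improvement drops below ``tol``.  The returned waves are
    sorted by decreasing amplitude.
    """
    y = np.asarray(signal, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > y.size / 4:
        raise ValueError(f"m={m} too large for n={y.size} samples")
    theta = (
        np.linspace(0.0, _TWO_PI, y.size, endpoint=False)
        if theta is None
        else np.asarray(theta, dtype=float)
    )

    shapes: list[tuple[float, float]] = []
    fitted = np.zeros_like(y)
    M = 0.0
    for _ in range(m):
        resid = y - fitted
        if np.ptp(resid) == 0:
            # nothing left to explain; park a negligible wave
            shapes.append((0.0, 1.0))
        else:
            _, w, _ = fit_mono(resid, theta, alpha_grid=alpha_grid, omega_grid=omega_grid)
            shapes.append((w.alpha, w.omega))
        M, waves, fitted, sse = _joint_linear(y, theta, shapes)

    for _ in range(max_sweeps):
        sse_prev = sse
        for j in range(m):
            others = [s for k, s in enumerate(shapes) if k != j]
            _, _, fit_others, _ = _joint_linear(y, theta, others) if others else (0.0, [], np.zeros_like(y), 0.0)
            resid = y - fit_others
            if np.ptp(resid) == 0:
                continue
            _, w, _ = fit_mono(resid, theta, alpha_grid=alpha_grid, omega_grid=omega_grid)
            cand = list(shapes)
            cand[j] = (w.alpha, w.omega)
            M2, waves2, fitted2, sse2 = _joint_linear(y, theta, cand)
            if sse2 < sse:
                shapes, M, waves, fitted, sse = cand, M2, waves2, fitted2, sse2
        if sse_prev - sse < tol * max(sse_prev, 1e-300):
            break

    order = np.argsort([-w.A for w in waves], kind="stable")
    waves = [waves[i] for i in order]
    sigma2 = sse / y.size
    return FMMModel(M=M, waves=waves, sigma2=sigma2, r2=r_squared(y, fitted))
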
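"""Spike detection and the restricted FMM spike-train (FMM_ST) model family.

A spike train with ``s`` action potentials is modelled as

    X(t_i) = M + sum_S [ W(t_i; A_S^A, alpha_S^A, beta^A, omega^A)
                       + W(t_i; A_S^B, alpha_S^B, beta^B, omega^B) ] + e(t_i)

i.e. each spike carries a dominant A wave (depolarization/repolarization)
and a B wave (hyperpolarization), all spikes share the shape parameters
``(beta, omega)`` of their wave class, the locations interleave cyclically
(alpha_1^A <= alpha_1^B <= alpha_2^A <= ...), and the A wave dominates
(A_S^A >= A_S^B).  Four nested variants are supported:

======  ======================================  ==================
tag     restrictions                            free parameters
======  ======================================  ==================
ST      shared shapes only                      1 + 4s + 4
ST*     + equal amplitudes across spikes        1 + 2s + 6
s*      A waves only (no B), free amplitudes    1 + 2s + 2
s**     A waves only, equal amplitudes          1 + s + 3
======  ======================================  ==================

Estimation alternates (a) a shared-shape search over (beta, omega) with the
intercept and amplitudes profiled out linearly, (b) per-spike location
scans, and (c) joint linear refits, accepting only SSE-improving moves;
larger variants are warm-started from feasible points of smaller ones so
the fitted R^2 respects the restriction lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks

from .waves import (
    _TWO_PI,
    OMEGA_MIN,
    FMMWave,
    _mobius_base,
    r_squared,
)

__all__ = [
    "DetectionConfig",
    "SpikeTrainModel",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "VARIANTS",
    "detect_spikes",
    "free_param_count",
    "fit_st",
    "fit_variants",
    "wave_distances",
    "extract_features",
]

VARIANTS = ("ST", "ST*", "s*", "s**")


@dataclass(frozen=True)
class DetectionConfig:
    """Naive threshold spike detector settings.

    ``k_factor`` scales the sample standard deviation of the (mean-centered)
    signal into the detection threshold; ``refractory`` is the minimum peak
    separation in ms; ``dominance_factor`` is the constant C of the optional
    margin rule ``A^A - A^B >= C * max-iteration-difference``.

    ``min_sigma`` (mV) declares flatter signals AP-free before thresholding.
    An action potential is a ~100 mV excursion, which even at one spike per
    60 ms record forces a signal SD above ~12 mV, while subthreshold
    responses and solver-level ripple stay below a few mV — the k*sigma rule
    alone is degenerate there because sigma shrinks with the excursion.
    """

    k_factor: float = 2.5
    refractory: float = 2.0
    dominance_factor: float = 0.70
    enforce_dominance_margin: bool = False
    min_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


def detect_spikes(signal, t=None, config: DetectionConfig | None = None, baseline=None):
    """Count APs as local maxima exceeding ``k*sigma`` above a baseline.

    ``sigma`` is the sample standard deviation of the signal.  The height
    reference defaults to the signal mean; for membrane-potential records
    pass the resting level as ``baseline`` so the threshold reads as an
    absolute voltage excursion from rest.  Signals with ``sigma`` below
    ``config.min_sigma`` are treated as flat (no spikes) — the threshold
    rule is degenerate at solver-noise level on noiseless simulations.

    Returns ``(s, peak_indices)``.  With ``t`` given, the refractory
    separation is interpreted in ms; otherwise in samples.
    """
    config = config or DetectionConfig()
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("signal must be 1-D with >= 10 samples")
    yc = y - (y.mean() if baseline is None else float(baseline))
    sigma = float(y.std(ddof=1))
    if sigma < config.min_sigma:
        return 0, np.array([], dtype=int)
    if t is not None:
        dt = float(np.median(np.diff(np.asarray(t, dtype=float))))
        distance = max(1, int(round(config.refractory / dt)))
    else:
        distance = max(1, int(round(config.refractory)))
    peaks, _ = find_peaks(yc, height=config.k_factor * sigma, distance=distance)
    return int(peaks.size), peaks


def free_param_count(variant: str, s: int) -> int:
    """Free parameters of each model variant for an ``s``-spike signal."""
    if s < 1:
        raise ValueError("s must be >= 1")
    if variant == "ST":
        return 1 + 4 * s + 4
    if variant == "ST*":
        return 1 + 2 * s + 6
    if variant == "s*":
        return 1 + 2 * s + 2
    if variant == "s**":
        return 1 + s + 3
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass
class SpikeTrainModel:
    """A fitted restricted FMM spike-train model."""

    M: float
    s: int
    A_A: np.ndarray
    alpha_A: np.ndarray
    beta_A: float
    omega_A: float
    A_B: np.ndarray | None
    alpha_B: np.ndarray | None
    beta_B: float | None
    omega_B: float | None
    variant: str
    sigma2: float
    r2: float
    dominance_ok: bool = True

    @property
    def has_b_waves(self) -> bool:
        return self.A_B is not None

    @property
    def n_free_params(self) -> int:
        return free_param_count(self.variant, self.s)

    def waves_a(self) -> list[FMMWave]:
        return [
            FMMWave(A=max(float(a), 1e-12), alpha=al, beta=self.beta_A, omega=self.omega_A)
            for a, al in zip(self.A_A, self.alpha_A)
        ]

    def waves_b(self) -> list[FMMWave]:
        if not self.has_b_waves:
            return []
        return [
            FMMWave(A=max(float(a), 1e-12), alpha=al, beta=self.beta_B, omega=self.omega_B)
            for a, al in zip(self.A_B, self.alpha_B)
        ]

    def predict(self, theta: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(theta, dtype=float), self.M)
        for w in self.waves_a() + self.waves_b():
            out = out + w(theta)
        return out

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "M": self.M,
            "s": self.s,
            "A_A": [float(a) for a in self.A_A],
            "alpha_A": [float(a) for a in self.alpha_A],
            "beta_A": self.beta_A,
            "omega_A": self.omega_A,
            "sigma2": self.sigma2,
            "r2": self.r2,
            "n_free_params": self.n_free_params,
            "dominance_ok": self.dominance_ok,
        }
        if self.has_b_waves:
            d.update(
                A_B=[float(a) for a in self.A_B],
                alpha_B=[float(a) for a in self.alpha_B],
                beta_B=self.beta_B,
                omega_B=self.omega_B,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpikeTrainModel":
        has_b = "A_B" in d
        return cls(
            M=float(d["M"]),
            s=int(d["s"]),
            A_A=np.asarray(d["A_A"], dtype=float),
            alpha_A=np.asarray(d["alpha_A"], dtype=float),
            beta_A=float(d["beta_A"]),
            omega_A=float(d["omega_A"]),
            A_B=np.asarray(d["A_B"], dtype=float) if has_b else None,
            alpha_B=np.asarray(d["alpha_B"], dtype=float) if has_b else None,
            beta_B=float(d["beta_B"]) if has_b else None,
            omega_B=float(d["omega_B"]) if has_b else None,
            variant=d["variant"],
            sigma2=float(d["sigma2"]),
            r2=float(d["r2"]),
            dominance_ok=bool(d.get("dominance_ok", True)),
        )


# ---------------------------------------------------------------------------
# distances and features


def wave_distances(model: SpikeTrainModel):
    """Circular 1 - cos distances: per-spike A-to-B and consecutive-AP.

    ``d_AP[S] = 1 - cos(alpha_S^A - alpha_{S+1}^A)`` for S = 1..s-1 and
    ``d_AB[S] = 1 - cos(alpha_S^A - alpha_S^B)``; both lie in [0, 2].
    """
    aA = np.asarray(model.alpha_A, dtype=float)
    d_ap = 1.0 - np.cos(aA[:-1] - aA[1:]) if model.s > 1 else np.array([])
    if model.has_b_waves:
        d_ab = 1.0 - np.cos(aA - np.asarray(model.alpha_B, dtype=float))
    else:
        d_ab = np.array([])
    return d_ab, d_ap


FEATURE_COLUMNS = (
    "M",
    "AmA",
    "betaA",
    "omegaA",
    "dmAP",
    "s",
    "AmB",
    "cosBetaB",
    "sinBetaB",
    "omegaB",
    "dmAB",
)

#: predictors of the dominant-wave feature set tau^A
TAU_A = ("M", "AmA", "betaA", "omegaA", "dmAP", "s")
#: additional predictors contributed by the B waves (tau^B)
TAU_B = ("AmB", "cosBetaB", "sinBetaB", "omegaB", "dmAB")


@dataclass(frozen=True)
class FeatureVector:
    """Waveform descriptors of a fitted spike-train model.

    Medians are taken over spikes; ``dmAP`` is NaN for single-spike signals
    (no consecutive pair) and is imputed downstream.  ``betaB`` enters
    linear/kernel methods through its cosine and sine.
    """

    M: float
    AmA: float
    betaA: float
    omegaA: float
    dmAP: float
    s: int
    AmB: float
    cosBetaB: float
    sinBetaB: float
    omegaB: float
    dmAB: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def extract_features(model: SpikeTrainModel) -> FeatureVector:
    d_ab, d_ap = wave_distances(model)
    has_b = model.has_b_waves
    beta_b = model.beta_B if has_b else math.nan
    return FeatureVector(
        M=float(model.M),
        AmA=float(np.median(model.A_A)),
        betaA=float(model.beta_A),
        omegaA=float(model.omega_A),
        dmAP=float(np.median(d_ap)) if d_ap.size else math.nan,
        s=int(model.s),
        AmB=float(np.median(model.A_B)) if has_b else math.nan,
        cosBetaB=float(np.cos(beta_b)),
        sinBetaB=float(np.sin(beta_b)),
        omegaB=float(model.omega_B) if has_b else math.nan,
        dmAB=float(np.median(d_ab)) if d_ab.size else math.nan,
    )


# ---------------------------------------------------------------------------
# fitting machinery


@dataclass
class _Train:
    """Mutable state of one wave train during fitting."""

    alphas: np.ndarray
    amps: np.ndarray
    beta: float
    omega: float
    equal_amp: bool

    def copy(self) -> "_Train":
        return _Train(self.alphas.copy(), self.amps.copy(), self.beta, self.omega, self.equal_amp)

    def regressors(self, theta: np.ndarray) -> np.ndarray:
        Z = _mobius_base(theta, self.alphas, self.omega)
        return np.cos(self.beta + Z)

    def values(self, theta: np.ndarray) -> np.ndarray:
        return self.amps @ self.regressors(theta)


def _lsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via normal equations (few columns), lstsq fallback."""
    G = X.T @ X
    try:
        return np.linalg.solve(G, X.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, y, rcond=None)[0]


def _solve_amplitudes(y: np.ndarray, R: np.ndarray, equal_amp: bool, with_intercept: bool):
    """LS amplitudes (and intercept) for fixed shapes; amplitudes >= 0.

    ``R`` holds one regressor row per spike.  Negative solutions are pinned
    to ~0 and the rest re-solved.
    """
    s = R.shape[0]
    if equal_amp:
        cols = [R.sum(axis=0)]
    else:
        cols = list(R)
    if with_intercept:
        X = np.column_stack([np.ones(y.size)] + cols)
    else:
        X = np.column_stack(cols)
    coef = _lsq(X, y)
    off = 1 if with_intercept else 0
    amps = coef[off:]
    if np.any(amps < 0):
        free = amps >= 0
        amps = np.maximum(amps, 1e-9)
        if free.any():
            Xf = X[:, [True] * off + list(free)] if off else X[:, free]
            cf = _lsq(Xf, y)
            out = np.full(amps.size, 1e-9)
            out[free] = np.maximum(cf[off:], 1e-9)
            amps = out
            coef = np.concatenate([cf[:off], amps]) if off else amps
        M = float(cf[0]) if (off and free.any()) else (float(coef[0]) if off else 0.0)
    else:
        M = float(coef[0]) if off else 0.0
    if equal_amp:
        amp_vec = np.full(s, float(amps[0]))
        fitted = (M if off else 0.0) + float(amps[0]) * cols[0]
    else:
        amp_vec = np.asarray(amps, dtype=float)
        fitted = (M if off else 0.0) + amp_vec @ R
    sse = float(np.sum((y - fitted) ** 2))
    return M, amp_vec, fitted, sse


_BETA_GRID = np.linspace(0.0, _TWO_PI, 16, endpoint=False)
_OMEGA_GRID = np.array([0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.2, 0.35])


def _fit_train(
    y: np.ndarray,
    theta: np.ndarray,
    train: _Train,
    *,
    with_intercept: bool,
    search_shape: bool = True,
    sweeps: int = 2,
    alpha_span: float | None = None,
):
    """Fit one shared-shape wave train to ``y`` by alternating updates.

    Only SSE-improving moves are accepted, so the SSE of the incoming
    ``train`` state is an upper bound for the result.
    """
    s = train.alphas.size
    # cyclic gaps bound each alpha's scan window so the ordering is kept
    order = np.argsort(train.alphas)
    train.alphas = train.alphas[order]
    train.amps = train.amps[order]

    def joint(tr: _Train):
        R = tr.regressors(theta)
        return _solve_amplitudes(y, R, tr.equal_amp, with_intercept)

    if search_shape and s > 0:
        best = None
        for om in _OMEGA_GRID:
            for be in _BETA_GRID:
                cand = train.copy()
                cand.beta, cand.omega = float(be), float(om)
                M, amps, fitted, sse = joint(cand)
                if best is None or sse < best[0]:
                    best = (sse, float(be), float(om))
        _, train.beta, train.omega = best

    M, train.amps, fitted, sse = joint(train)

    def shape_refine():
        nonlocal M, fitted, sse

        def objective(x):
            cand = train.copy()
            cand.beta = float(x[0])
            cand.omega = float(np.clip(x[1], OMEGA_MIN, 1.0))
            return joint(cand)[3]

        res = minimize(
            objective,
            x0=[train.beta, train.omega],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8 * max(sse, 1.0), "maxiter": 150},
        )
        if res.fun < sse:
            train.beta = float(res.x[0]) % _TWO_PI
            train.omega = float(np.clip(res.x[1], OMEGA_MIN, 1.0))
            M_, amps_, fitted_, sse_ = joint(train)
            M, train.amps, fitted, sse = M_, amps_, fitted_, sse_

    def alpha_scan(span: float, n_cand: int = 15):
        nonlocal M, fitted, sse
        for j in range(s):
            lo = hi = span
            if s > 1:
                gap_prev = (train.alphas[j] - train.alphas[j - 1]) % _TWO_PI
                gap_next = (train.alphas[(j + 1) % s] - train.alphas[j]) % _TWO_PI
                lo = min(span, 0.45 * gap_prev)
                hi = min(span, 0.45 * gap_next)
            cands = train.alphas[j] + np.linspace(-lo, hi, n_cand)
            improved = False
            for al in cands:
                if abs(al - train.alphas[j]) < 1e-12:
                    continue
                cand = train.copy()
                cand.alphas = train.alphas.copy()
                cand.alphas[j] = al % _TWO_PI
                M2, amps2, fitted2, sse2 = joint(cand)
                if sse2 < sse:
                    train.alphas = cand.alphas
                    M, train.amps, fitted, sse = M2, amps2, fitted2, sse2
                    improved = True
            if improved:
                order = np.argsort(train.alphas)
                train.alphas = train.alphas[order]
                train.amps = train.amps[order]

    span0 = alpha_span if alpha_span is not None else (0.3 if s == 1 else 0.25)
    for sweep in range(sweeps):
        alpha_scan(span0 / (3.0**sweep))
        shape_refine()
    M, train.amps, fitted, sse = joint(train)
    return M, fitted, sse, train


def _initial_alphas(y: np.ndarray, theta: np.ndarray, s: int, config: DetectionConfig):
    """Initial A-wave locations from the s most prominent maxima.

    A Mobius wave with small omega carries its sharp extremum near
    ``alpha + pi`` (the phase transits fastest half a period away from
    alpha), so detected peak angles are shifted by pi.
    """
    n = y.size
    distance = max(1, n // (4 * max(s, 1)))
    yc = y - y.mean()
    peaks, props = find_peaks(yc, distance=distance, height=-np.inf)
    if peaks.size >= s:
        top = peaks[np.argsort(props["peak_heights"])[::-1][:s]]
    else:
        extra = np.linspace(0, n - 1, s - peaks.size + 2, dtype=int)[1:-1]
        top = np.concatenate([peaks, extra])[:s]
    return np.sort((theta[np.sort(top)] + math.pi) % _TWO_PI)


def _init_b_alphas(
    resid: np.ndarray, theta: np.ndarray, alpha_a: np.ndarray, omega_a: float = 0.04
):
    """Place B waves at the residual minimum within each inter-spike arc.

    Works in feature space (angles shifted by -pi from the alphas, where
    the waves' sharp extrema live) and shifts back by +pi.  An exclusion
    zone scaled to the A wave's transit width keeps the search away from
    the sharp fit mismatch right at the spike, so the minimum found is the
    hyperpolarization trough rather than a repolarization artefact.
    """
    s = alpha_a.size
    feat_a = (alpha_a - math.pi) % _TWO_PI
    ang = theta % _TWO_PI
    excl = max(0.12, 4.0 * omega_a)
    out = np.empty(s)
    for j in range(s):
        gap = (feat_a[(j + 1) % s] - feat_a[j]) % _TWO_PI
        if gap <= 0:
            gap = _TWO_PI
        rel = (ang - feat_a[j]) % _TWO_PI
        mask = (rel >= min(excl, 0.4 * gap)) & (rel <= 0.85 * gap)
        if not mask.any():
            trough = feat_a[j] + 0.3 * gap
        else:
            idx = np.flatnonzero(mask)
            trough = ang[idx[np.argmin(resid[idx])]]
        out[j] = (trough + math.pi) % _TWO_PI
    return out


def _assemble(
    y,
    theta,
    M,
    trainA: _Train,
    trainB: _Train | None,
    variant: str,
    config: DetectionConfig,
) -> SpikeTrainModel:
    dominance_ok = True
    if trainB is not None:
        # pair each spike's B wave with the A wave it follows cyclically
        # (sorting both arrays independently would mis-pair across the wrap)
        order = np.empty(trainA.alphas.size, dtype=int)
        taken = np.zeros(trainB.alphas.size, dtype=bool)
        for j, a in enumerate(trainA.alphas):
            gaps = (trainB.alphas - a) % _TWO_PI
            gaps[taken] = np.inf
            order[j] = int(np.argmin(gaps))
            taken[order[j]] = True
        trainB.alphas = trainB.alphas[order]
        trainB.amps = trainB.amps[order]
        dominance_ok = bool(np.all(trainA.amps >= trainB.amps - 1e-9))
    model = SpikeTrainModel(
        M=M,
        s=trainA.alphas.size,
        A_A=trainA.amps.copy(),
        alpha_A=trainA.alphas.copy(),
        beta_A=trainA.beta,
        omega_A=trainA.omega,
        A_B=trainB.amps.copy() if trainB is not None else None,
        alpha_B=trainB.alphas.copy() if trainB is not None else None,
        beta_B=trainB.beta if trainB is not None else None,
        omega_B=trainB.omega if trainB is not None else None,
        variant=variant,
        sigma2=0.0,
        r2=0.0,
        dominance_ok=dominance_ok,
    )
    fitted = model.predict(theta)
    model.sigma2 = float(np.mean((y - fitted) ** 2))
    model.r2 = r_squared(y, fitted)
    return model


def _joint_amplitude_refit(y, theta, trainA: _Train, trainB: _Train, with_intercept=True):
    """Re-solve M and all amplitudes of both trains jointly (linear)."""
    RA = trainA.regressors(theta)
    RB = trainB.regressors(theta)
    colsA = [RA.sum(axis=0)] if trainA.equal_amp else list(RA)
    colsB = [RB.sum(axis=0)] if trainB.equal_amp else list(RB)
    X = np.column_stack([np.ones(y.size)] + colsA + colsB)
    coef = _lsq(X, y)
    nA = len(colsA)
    ampsA = np.maximum(coef[1 : 1 + nA], 1e-9)
    ampsB = np.maximum(coef[1 + nA :], 1e-9)
    M = float(coef[0])
    sA = trainA.alphas.size
    sB = trainB.alphas.size
    newA = np.full(sA, float(ampsA[0])) if trainA.equal_amp else np.asarray(ampsA)
    newB = np.full(sB, float(ampsB[0])) if trainB.equal_amp else np.asarray(ampsB)
    fitted = M + newA @ RA + newB @ RB
    sse = float(np.sum((y - fitted) ** 2))
    return M, newA, newB, fitted, sse


def _polish(
    y: np.ndarray,
    theta: np.ndarray,
    trainA: _Train,
    trainB: _Train | None,
    *,
    maxiter: int | None = None,
):
    """Joint Nelder-Mead over all nonlinear parameters (shared shapes and
    per-spike locations) with intercept and amplitudes profiled out by
    least squares.  Returns the polished state only if the SSE improved."""
    s = trainA.alphas.size

    def split(x):
        tA = trainA.copy()
        tA.beta = float(x[0]) % _TWO_PI
        tA.omega = float(np.clip(x[1], OMEGA_MIN, 1.0))
        tA.alphas = np.sort(np.asarray(x[2 : 2 + s]) % _TWO_PI)
        if trainB is None:
            return tA, None
        tB = trainB.copy()
        tB.beta = float(x[2 + s]) % _TWO_PI
        tB.omega = float(np.clip(x[3 + s], OMEGA_MIN, 1.0))
        tB.alphas = np.sort(np.asarray(x[4 + s :]) % _TWO_PI)
        return tA, tB

    def objective(x):
        tA, tB = split(x)
        if tB is None:
            R = tA.regressors(theta)
            return _solve_amplitudes(y, R, tA.equal_amp, True)[3]
        return _joint_amplitude_refit(y, theta, tA, tB)[4]

    x0 = np.concatenate(
        [[trainA.beta, trainA.omega], trainA.alphas]
        + ([[trainB.beta, trainB.omega], trainB.alphas] if trainB is not None else [])
    )
    sse0 = objective(x0)
    if maxiter is None:
        maxiter = min(150 * x0.size, 1200)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7 * max(sse0, 1.0)},
    )
    # one cheap restart: a fresh simplex around the optimum escapes the
    # collapsed-simplex stalls NM is prone to in >8 dimensions
    res2 = minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter // 2, "xatol": 1e-4, "fatol": 1e-8 * max(sse0, 1.0)},
    )
    if res2.fun < res.fun:
        res = res2
    if res.fun >= sse0:
        return trainA, trainB, None
    tA, tB = split(res.x)
    if tB is None:
        R = tA.regressors(theta)
        M, tA.amps, _, _ = _solve_amplitudes(y, R, tA.equal_amp, True)
    else:
        M, tA.amps, tB.amps, _, _ = _joint_amplitude_refit(y, theta, tA, tB)
    return tA, tB, M


def _fit_variant(
    y: np.ndarray,
    theta: np.ndarray,
    variant: str,
    alphas0: np.ndarray,
    config: DetectionConfig,
    warm: SpikeTrainModel | None = None,
    full: tuple[np.ndarray, np.ndarray] | None = None,
    polish: bool = True,
) -> SpikeTrainModel:
    """Fit one variant; the nonlinear search runs on (y, theta), which may
    be a decimated view, while the final linear solve and the reported R^2
    use the ``full`` grid when given."""
    s = alphas0.size
    equal_amp = variant in ("ST*", "s**")
    has_b = variant in ("ST", "ST*")

    if warm is not None:
        trainA = _Train(
            alphas=np.asarray(warm.alpha_A, dtype=float).copy(),
            amps=(np.full(s, float(np.mean(warm.A_A))) if equal_amp else np.asarray(warm.A_A, dtype=float).copy()),
            beta=warm.beta_A,
            omega=warm.omega_A,
            equal_amp=equal_amp,
        )
        search_shape = False
    else:
        amp0 = np.ptp(y) / 2.0
        trainA = _Train(
            alphas=alphas0.copy(),
            amps=np.full(s, amp0),
            beta=0.85 * math.pi,
            omega=0.05,
            equal_amp=equal_amp,
        )
        search_shape = True

    trainB: _Train | None = None
    if has_b and warm is not None and warm.has_b_waves:
        trainB = _Train(
            alphas=np.asarray(warm.alpha_B, dtype=float).copy(),
            amps=(np.full(s, float(np.mean(warm.A_B))) if equal_amp else np.asarray(warm.A_B, dtype=float).copy()),
            beta=warm.beta_B,
            omega=warm.omega_B,
            equal_amp=equal_amp,
        )

    targetA = y if trainB is None else y - trainB.values(theta)
    M, fittedA, sse, trainA = _fit_train(
        targetA, theta, trainA, with_intercept=True, search_shape=search_shape
    )

    if not has_b:
        if polish:
            tA, _, M2 = _polish(y, theta, trainA, None)
            if M2 is not None:
                trainA, M = tA, M2
        if full is not None:
            y_f, theta_f = full
            R = trainA.regressors(theta_f)
            M, trainA.amps, _, _ = _solve_amplitudes(y_f, R, trainA.equal_amp, True)
            return _assemble(y_f, theta_f, M, trainA, None, variant, config)
        return _assemble(y, theta, M, trainA, None, variant, config)
    best = None
    warm_b = trainB is not None
    for outer in range(1 if warm_b else 2):
        resid = y - M - trainA.values(theta)
        if trainB is None:
            alphas_b = _init_b_alphas(resid, theta, trainA.alphas, trainA.omega)
            trainB = _Train(
                alphas=alphas_b,
                amps=np.full(s, max(np.ptp(resid) / 4.0, 1e-6)),
                beta=1.5 * math.pi,
                omega=0.1,
                equal_amp=equal_amp,
            )
            _, _, _, trainB = _fit_train(
                resid, theta, trainB, with_intercept=False, search_shape=True, sweeps=2
            )
        else:
            _, _, _, trainB = _fit_train(
                resid, theta, trainB, with_intercept=False, search_shape=False,
                sweeps=1 if warm_b else 2,
            )
        # refit A against the B residual, then joint amplitude polish
        residA = y - trainB.values(theta)
        M, _, _, trainA = _fit_train(
            residA, theta, trainA, with_intercept=True, search_shape=False, sweeps=1
        )
        M, trainA.amps, trainB.amps, fitted, sse = _joint_amplitude_refit(
            y, theta, trainA, trainB
        )
        if best is None or sse < best[0]:
            best = (sse, M, trainA.copy(), trainB.copy())
    _, M, trainA, trainB = best

    if polish:
        tA, tB, M2 = _polish(y, theta, trainA, trainB)
        if M2 is not None:
            trainA, trainB, M = tA, tB, M2

    # dominance: cap B amplitudes at their spike's A amplitude
    if np.any(trainB.amps > trainA.amps):
        trainB.amps = np.minimum(trainB.amps, trainA.amps)
        M, trainA.amps, trainB.amps, _, _ = _joint_amplitude_refit(y, theta, trainA, trainB)
        trainB.amps = np.minimum(trainB.amps, trainA.amps)
    if config.enforce_dominance_margin:
        margin = config.dominance_factor * float(np.max(trainA.amps - trainB.amps))
        trainB.amps = np.minimum(trainB.amps, trainA.amps - margin).clip(min=1e-9)

    if full is not None:
        y_f, theta_f = full
        M, trainA.amps, trainB.amps, _, _ = _joint_amplitude_refit(y_f, theta_f, trainA, trainB)
        trainB.amps = np.minimum(trainB.amps, trainA.amps)
        return _assemble(y_f, theta_f, M, trainA, trainB, variant, config)
    return _assemble(y, theta, M, trainA, trainB, variant, config)


def _refit_as(
    parent: SpikeTrainModel,
    child_variant: str,
    y: np.ndarray,
    theta: np.ndarray,
    config: DetectionConfig,
) -> SpikeTrainModel:
    """Embed a fitted model into a less-restricted variant and refit the
    linear parameters.  The parent's solution is feasible in the child
    class, so the child's R^2 is (up to amplitude clipping) at least the
    parent's — used to restore the restriction-lattice ordering when the
    decimated nonlinear searches land in slightly different optima."""
    s = parent.s
    equal_amp = child_variant in ("ST*", "s**")
    has_b = child_variant in ("ST", "ST*")
    trainA = _Train(
        alphas=np.asarray(parent.alpha_A, dtype=float).copy(),
        amps=np.asarray(parent.A_A, dtype=float).copy(),
        beta=parent.beta_A,
        omega=parent.omega_A,
        equal_amp=equal_amp,
    )
    if not has_b:
        R = trainA.regressors(theta)
        M, trainA.amps, _, _ = _solve_amplitudes(y, R, equal_amp, True)
        return _assemble(y, theta, M, trainA, None, child_variant, config)
    if parent.has_b_waves:
        trainB = _Train(
            alphas=np.asarray(parent.alpha_B, dtype=float).copy(),
            amps=np.asarray(parent.A_B, dtype=float).copy(),
            beta=parent.beta_B,
            omega=parent.omega_B,
            equal_amp=equal_amp,
        )
    else:
        resid = y - parent.predict(theta)
        trainB = _Train(
            alphas=_init_b_alphas(resid, theta, trainA.alphas, trainA.omega),
            amps=np.full(s, 1e-6),
            beta=1.5 * math.pi,
            omega=0.1,
            equal_amp=equal_amp,
        )
        _, _, _, trainB = _fit_train(
            resid, theta, trainB, with_intercept=False, search_shape=True, sweeps=1
        )
    M, trainA.amps, trainB.amps, _, _ = _joint_amplitude_refit(y, theta, trainA, trainB)
    trainB.amps = np.minimum(trainB.amps, trainA.amps)
    return _assemble(y, theta, M, trainA, trainB, child_variant, config)


def fit_variants(
    signal,
    s: int | None = None,
    variants=VARIANTS,
    theta=None,
    config: DetectionConfig | None = None,
) -> dict[str, SpikeTrainModel]:
    """Fit several restricted variants, sharing warm starts along the
    restriction lattice (s** -> s*, s** -> ST* -> ST)."""
    config = config or DetectionConfig()
    y = np.asarray(signal, dtype=float)
    theta = (
        np.linspace(0.0, _TWO_PI, y.size, endpoint=False)
        if theta is None
        else np.asarray(theta, dtype=float)
    )
    if s is None:
        # without a time axis, enforce a refractory of 1/60 of the period
        # (1 ms on a 60 ms record) and reference heights to the baseline
        auto_cfg = replace(config, refractory=max(config.refractory, y.size / 60.0))
        s, _ = detect_spikes(y, config=auto_cfg, baseline=float(np.median(y)))
        if s == 0:
            raise ValueError("no spikes detected; pass s explicitly")
    if y.size < free_param_count("ST", s) * 3:
        raise ValueError(f"too few samples ({y.size}) for s={s} spikes")
    alphas0 = _initial_alphas(y, theta, s, config)

    # nonlinear searches run on a decimated grid for speed; final linear
    # solves and reported R^2 always use the full grid
    k = max(1, y.size // 700)
    if k > 1:
        y_d, theta_d, full = y[::k], theta[::k], (y, theta)
    else:
        y_d, theta_d, full = y, theta, None

    out: dict[str, SpikeTrainModel] = {}
    base = _fit_variant(y_d, theta_d, "s**", alphas0, config, full=full, polish=False)
    out["s**"] = base

    if "s*" in variants or "ST" in variants:
        cand = _fit_variant(y_d, theta_d, "s*", alphas0, config, warm=base, full=full)
        if cand.r2 < base.r2:
            alt = _refit_as(base, "s*", y, theta, config)
            cand = cand if cand.r2 >= alt.r2 else alt
        out["s*"] = cand
    if "ST*" in variants or "ST" in variants:
        # when ST* is only a warm start for ST, its own joint polish is
        # redundant (ST polishes the same parameters with freer amplitudes)
        cand = _fit_variant(
            y_d, theta_d, "ST*", alphas0, config, warm=base, full=full,
            polish="ST*" in variants,
        )
        if cand.r2 < base.r2:
            alt = _refit_as(base, "ST*", y, theta, config)
            cand = cand if cand.r2 >= alt.r2 else alt
        out["ST*"] = cand
    if "ST" in variants:
        cand = _fit_variant(y_d, theta_d, "ST", alphas0, config, warm=out["ST*"], full=full)
        if cand.r2 < out["s*"].r2:
            alt = _fit_variant(y_d, theta_d, "ST", alphas0, config, warm=out["s*"], full=full)
            cand = cand if cand.r2 >= alt.r2 else alt
        for parent in (out["ST*"], out["s*"]):
            if cand.r2 < parent.r2:
                alt = _refit_as(parent, "ST", y, theta, config)
                cand = cand if cand.r2 >= alt.r2 else alt
        out["ST"] = cand
    return {v: out[v] for v in variants if v in out}


def fit_st(
    signal,
    s: int | None = None,
    variant: str = "ST",
    theta=None,
    config: DetectionConfig | None = None,
) -> SpikeTrainModel:
    """Fit one restricted spike-train variant (see module docstring)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return fit_variants(signal, s=s, variants=(variant,), theta=theta, config=config)[variant]
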
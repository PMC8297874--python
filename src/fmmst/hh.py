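"""Hodgkin-Huxley membrane-potential simulation and the factorial design.

The HH model couples the membrane potential ``X`` (mV) to three gating
probabilities ``m, n, h`` through the ODE system

    C dX/dt = -gK n^4 (X - VK) - gNa m^3 h (X - VNa) - gL (X - VL) + I(t)
    dg/dt   = (1 - g) * a_g(X) - g * b_g(X),   g in {m, n, h}

with the canonical voltage-dependent transition rates of the modern
convention (rest near -65 mV, VK = -77, VNa = 50).  The kinetic factors
``aM, bM, aN, bN, aH, bH`` scale those rates multiplicatively, so a factor
of 1 recovers the textbook squid-axon dynamics while values away from 1
speed up or slow down individual gates.

Two dimensionless summaries compress the parameter space:

    S = gNa / (gNa + gK)              (structural, conductance balance)
    K = (aN + bM) / (aN + bN + aM + bM)   (kinetic, gate-rate balance)

The factorial design draws each varied parameter uniformly from a set of
experimentally observed values, crossed with five square-pulse stimulus
amplitudes; signals span 60 ms with a 1 ms pulse at t = 10 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "HHParameters",
    "StimulusProtocol",
    "HHTrajectory",
    "SKPair",
    "DESIGN_VALUE_SETS",
    "STIMULUS_AMPLITUDES",
    "simulate",
    "compute_sk",
    "sample_design",
    "preprocess",
    "classify_dynamics",
]


@dataclass(frozen=True)
class HHParameters:
    """Biophysical constants of one HH neuron.

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2;
    the kinetic factors are dimensionless multipliers on the canonical
    rate functions.
    """

    C: float = 1.0
    gNa: float = 120.0
    gK: float = 36.0
    gL: float = 0.31
    VNa: float = 50.0
    VK: float = -77.0
    VL: float = -54.0
    aM: float = 1.0
    aN: float = 1.0
    aH: float = 1.0
    bM: float = 1.0
    bN: float = 1.0
    bH: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        for name in ("gNa", "gK", "gL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"conductance {name} must be positive")
        for name in ("aM", "aN", "aH", "bM", "bN", "bH"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic factor {name} must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """A square current pulse: ``amplitude`` uA/cm^2 during
    ``[onset, onset + duration)`` within a record of ``total_time`` ms."""

    amplitude: float = 12.0
    onset: float = 10.0
    duration: float = 1.0
    total_time: float = 60.0
    shape: str = "square"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset + self.duration > self.total_time:
            raise ValueError("stimulus must end within total_time")
        if self.shape != "square":
            raise ValueError(f"unsupported stimulus shape: {self.shape!r}")

    def current(self, t: float) -> float:
        return self.amplitude if self.onset <= t < self.onset + self.duration else 0.0


@dataclass
class HHTrajectory:
    """Simulated state paths on a uniform time grid (ms, mV)."""

    t: np.ndarray
    X: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    resting_value: float

    def __post_init__(self) -> None:
        lengths = {len(self.t), len(self.X), len(self.m), len(self.n), len(self.h)}
        if len(lengths) != 1:
            raise ValueError("t, X, m, n, h must have equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class SKPair:
    S: float
    K: float


# canonical modern-convention rate functions ------------------------------


def _vtrap(x: float) -> float:
    """x / (1 - exp(-x)) with the analytic limit 1 at x = 0."""
    if abs(x) < 1e-7:
        return 1.0 + x / 2.0
    return x / (1.0 - math.exp(-x))


def _rates(X: float) -> tuple[float, float, float, float, float, float]:
    am = _vtrap((X + 40.0) / 10.0)          # 0.1*(X+40)/(1-exp(-(X+40)/10))
    bm = 4.0 * math.exp(-(X + 65.0) / 18.0)
    an = 0.1 * _vtrap((X + 55.0) / 10.0)    # 0.01*(X+55)/(1-exp(-(X+55)/10))
    bn = 0.125 * math.exp(-(X + 65.0) / 80.0)
    ah = 0.07 * math.exp(-(X + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(X + 35.0) / 10.0))
    return am, bm, an, bn, ah, bh


def _gate_steady(params: HHParameters, X: float) -> tuple[float, float, float]:
    am, bm, an, bn, ah, bh = _rates(X)
    am, bm = params.aM * am, params.bM * bm
    an, bn = params.aN * an, params.bN * bn
    ah, bh = params.aH * ah, params.bH * bh
    return am / (am + bm), an / (an + bn), ah / (ah + bh)


def _membrane_current(params: HHParameters, X: float, m: float, n: float, h: float) -> float:
    return (
        -params.gK * n**4 * (X - params.VK)
        - params.gNa * m**3 * h * (X - params.VNa)
        - params.gL * (X - params.VL)
    )


def resting_state(params: HHParameters) -> tuple[float, float, float, float]:
    """Resting equilibrium: X with zero net current at steady-state gates.

    Root-found on [-90, -35] mV; if several equilibria exist the most
    hyperpolarized one (the physiological rest) is returned.
    """

    def f(X: float) -> float:
        m, n, h = _gate_steady(params, X)
        return _membrane_current(params, X, m, n, h)

    grid = np.linspace(-90.0, -35.0, 221)
    vals = [f(x) for x in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            X0 = float(lo)
            break
        if flo * fhi < 0:
            X0 = float(brentq(f, lo, hi, xtol=1e-10))
            break
    else:
        raise RuntimeError(
            "no resting equilibrium found in [-90, -35] mV; "
            f"current at -90: {vals[0]:.3g}, at -35: {vals[-1]:.3g}"
        )
    m, n, h = _gate_steady(params, X0)
    return X0, m, n, h


_NOMINAL_REST_CACHE: dict[None, float] = {}


def nominal_rest_voltage() -> float:
    """Resting potential of the canonical configuration (~ -64.81 mV).

    This is the zero of the original squid-axon voltage convention; all
    simulated experiments start from it regardless of their own parameters,
    so configurations whose equilibrium differs relax (or fire) from t = 0.
    """
    if None not in _NOMINAL_REST_CACHE:
        _NOMINAL_REST_CACHE[None] = resting_state(HHParameters())[0]
    return _NOMINAL_REST_CACHE[None]


def _rhs(t, y, params: HHParameters, current: float):
    X, m, n, h = y
    am, bm, an, bn, ah, bh = _rates(X)
    dX = (_membrane_current(params, X, m, n, h) + current) / params.C
    dm = (1.0 - m) * params.aM * am - m * params.bM * bm
    dn = (1.0 - n) * params.aN * an - n * params.bN * bn
    dh = (1.0 - h) * params.aH * ah - h * params.bH * bh
    return (dX, dm, dn, dh)


def simulate(
    params: HHParameters,
    stim: StimulusProtocol,
    dt: float = 0.05,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    init: str = "nominal",
) -> HHTrajectory:
    """Integrate the HH system from rest and sample on a uniform grid.

    ``init="nominal"`` (default) starts every experiment at the canonical
    resting voltage with the gates at this configuration's own steady state
    for that voltage — configurations whose equilibrium differs relax or
    fire from t = 0, which is how pre-stimulus APs arise.
    ``init="equilibrium"`` starts at the configuration's exact resting
    equilibrium instead.

    The stimulus discontinuities split the integration into segments so the
    adaptive (LSODA) solver never steps across a jump in the current.
    Gating values are clipped to [0, 1] only when numerically outside by
    less than 1e-9; larger violations raise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init == "nominal":
        X0 = nominal_rest_voltage()
        y0 = (X0, *_gate_steady(params, X0))
    elif init == "equilibrium":
        y0 = resting_state(params)
    else:
        raise ValueError(f"unknown init mode {init!r}")
    edges = sorted({0.0, stim.onset, stim.onset + stim.duration, stim.total_time})
    edges = [e for e in edges if 0.0 <= e <= stim.total_time]
    t_full = np.arange(0.0, stim.total_time + dt / 2, dt)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        current = stim.current((a + b) / 2.0)
        t_eval = t_full[(t_full >= a - 1e-12) & (t_full <= b + 1e-12)]
        sol = solve_ivp(
            _rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            args=(params, current),
            rtol=rtol,
            atol=atol,
            max_step=max(b - a, 1e-3),
        )
        if not sol.success:
            raise RuntimeError(
                f"HH integration failed on [{a}, {b}] ms: {sol.message}"
            )
        # drop the duplicated segment edge
        keep = slice(1, None) if ts and sol.t.size and abs(sol.t[0] - ts[-1][-1]) < 1e-9 else slice(None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    X, gates = Y[0], Y[1:]
    if gates.min() < -1e-9 or gates.max() > 1 + 1e-9:
        raise RuntimeError(
            f"gating variables escaped [0,1]: min={gates.min():.3e}, max={gates.max():.3e}"
        )
    gates = np.clip(gates, 0.0, 1.0)
    return HHTrajectory(
        t=t, X=X, m=gates[0], n=gates[1], h=gates[2], resting_value=float(y0[0])
    )


def compute_sk(params: HHParameters) -> SKPair:
    """The (S, K) structural/kinetic summary of an HH configuration."""
    denom_s = params.gNa + params.gK
    denom_k = params.aN + params.bN + params.aM + params.bM
    if denom_s <= 0 or denom_k <= 0:
        raise ValueError("S and K require positive denominators")
    return SKPair(
        S=params.gNa / denom_s,
        K=(params.aN + params.bM) / denom_k,
    )


# factorial design ---------------------------------------------------------

#: value sets for the varied parameters (experimentally observed ranges)
DESIGN_VALUE_SETS: dict[str, tuple[float, ...]] = {
    "gNa": (64, 92, 120, 148, 176, 204, 232, 260),
    "gK": (27, 30, 33, 36, 39, 42, 45, 48),
    "gL": (0.12, 0.215, 0.31, 0.405, 0.5),
    "aN": (0.85, 0.95, 1.05, 1.15),
    "bN": (0.7, 0.85, 1.0, 1.15, 1.3),
    "aM": (0.8, 0.9, 1.0, 1.1, 1.2, 1.3),
    "bM": (0.7, 0.85, 1.0, 1.15, 1.3),
}

#: square-pulse amplitudes crossed with the sampled parameters (uA/cm^2)
STIMULUS_AMPLITUDES: tuple[float, ...] = (0.0, 4.5, 7.0, 9.5, 12.0)


def sample_design(
    n_per_stimulus: int,
    rng_seed: int,
    *,
    amplitudes: tuple[float, ...] = STIMULUS_AMPLITUDES,
) -> list[tuple[HHParameters, StimulusProtocol]]:
    """Draw the factorial design: ``n_per_stimulus`` random configurations
    for each stimulus amplitude, parameters uniform over their value sets."""
    if n_per_stimulus < 0:
        raise ValueError("n_per_stimulus must be >= 0")
    rng = np.random.default_rng(rng_seed)
    design: list[tuple[HHParameters, StimulusProtocol]] = []
    for amp in amplitudes:
        stim = StimulusProtocol(amplitude=float(amp))
        for _ in range(n_per_stimulus):
            draws = {
                name: float(rng.choice(values))
                for name, values in DESIGN_VALUE_SETS.items()
            }
            design.append((HHParameters(**draws), stim))
    return design


def classify_dynamics(spike_count: int) -> str:
    """Dynamic regime from the AP count: none, one, or repetitive."""
    if spike_count < 0:
        raise ValueError("spike_count must be >= 0")
    if spike_count == 0:
        return "non-excitable"
    if spike_count == 1:
        return "excitable"
    return "oscillatory"


#: half-width (ms) of the window replaced when an AP is discarded
PEAK_HALF_WIDTH_MS = 3.0

#: APs peaking within this many ms of the record end are discarded
LATE_WINDOW_MS = 6.0


def preprocess(
    traj: HHTrajectory,
    stim: StimulusProtocol,
    spike_times,
    *,
    peak_lead: float = PEAK_HALF_WIDTH_MS,
    rest_tol: float = 2.0,
) -> HHTrajectory:
    """Blank incomplete APs so only whole spikes enter the fit.

    An AP peaking before the stimulus onset, or within the final 6 ms, is
    replaced by the resting value.  The blanked window spans the AP's full
    extent: from ``peak_lead`` ms before the peak until the potential first
    returns within ``rest_tol`` mV of rest (after the hyperpolarization),
    capped at the rise of the next AP or the record end.  If the only AP
    precedes the stimulus the signal is returned unchanged.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size == 0:
        return traj
    to_blank: list[int] = []  # indices into spike_times
    if spike_times[0] < stim.onset:
        if spike_times.size == 1:
            return traj
        to_blank.append(0)
    if spike_times[-1] > traj.t[-1] - LATE_WINDOW_MS:
        if not (spike_times.size == 1 and spike_times[-1] < stim.onset):
            to_blank.append(spike_times.size - 1)
    if not to_blank:
        return traj
    X = traj.X.copy()
    t = traj.t
    for k in set(to_blank):
        peak = spike_times[k]
        start = peak - peak_lead
        # forward extent: first return to rest after the peak
        cap = spike_times[k + 1] - peak_lead if k + 1 < spike_times.size else t[-1]
        after = (t > peak + 1.0) & (t <= cap)
        settled = after & (np.abs(X - traj.resting_value) < rest_tol)
        stop = t[settled][0] if settled.any() else cap
        X[(t >= start) & (t <= stop)] = traj.resting_value
    return replace(traj, X=X)
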
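"""Readers and writers for signals, fitted models and configuration.

Signals travel as two-column CSV (``t_ms,X_mV``, or ``theta,value`` for
data already on the circle); fitted models as JSON; configuration as YAML
or JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import FourierModel
from .spiketrain import SpikeTrainModel
from .waves import _TWO_PI, FMMModel, TimeGrid

__all__ = [
    "read_signal",
    "write_signal",
    "read_model",
    "write_model",
    "read_config",
    "write_trajectory",
]


def read_signal(path) -> tuple[TimeGrid, np.ndarray]:
    """Read a two-column signal CSV into a (TimeGrid, values) pair.

    Accepts headers ``t_ms,X_mV`` (times rescaled to [0, 2*pi) treating the
    record as one period) or ``theta,value`` (used as-is).  Malformed rows
    are rejected with their line numbers; non-monotone time is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected a signal CSV") from None
    cols = list(df.columns)
    if cols[:2] not in (["t_ms", "X_mV"], ["theta", "value"]):
        raise ValueError(
            f"{path}: expected columns t_ms,X_mV or theta,value; got {cols}"
        )
    bad = df[df.iloc[:, :2].isna().any(axis=1) |
             ~df.iloc[:, :2].map(np.isreal).all(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad.index[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{path}: time/angle column must be strictly increasing")
    if cols[0] == "theta":
        grid = TimeGrid(t0=0.0, period=_TWO_PI, theta=x)
    else:
        grid = TimeGrid.from_times(x)
    _warn_if_open_loop(y)
    return grid, y


def _warn_if_open_loop(y: np.ndarray) -> None:
    """The periodic model assumes X(t1) ~= X(tn); warn when the endpoint gap
    exceeds 3x the local noise scale estimated from first differences."""
    if y.size < 20:
        return
    noise = float(np.median(np.abs(np.diff(y[:10])))) + float(
        np.median(np.abs(np.diff(y[-10:])))
    )
    if abs(y[0] - y[-1]) > 3.0 * max(noise, 1e-12):
        warnings.warn(
            "signal endpoints differ by more than 3x the endpoint noise; "
            "the periodic model assumes X(t1) ~= X(tn)",
            stacklevel=3,
        )


def write_signal(path, t, values, *, angle: bool = False) -> None:
    header = ("theta", "value") if angle else ("t_ms", "X_mV")
    pd.DataFrame({header[0]: t, header[1]: values}).to_csv(path, index=False)


def write_trajectory(path, traj) -> None:
    """Trajectory CSV with header ``t_ms,X_mV,m,n,h``."""
    pd.DataFrame(
        {"t_ms": traj.t, "X_mV": traj.X, "m": traj.m, "n": traj.n, "h": traj.h}
    ).to_csv(path, index=False)


_MODEL_KINDS = {
    "fmm": FMMModel,
    "spiketrain": SpikeTrainModel,
    "fourier": FourierModel,
}


def write_model(model, path) -> None:
    for kind, cls in _MODEL_KINDS.items():
        if isinstance(model, cls):
            break
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    payload = {"kind": kind, **model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("kind")
    d.pop("n_free_params", None)
    return _MODEL_KINDS[kind].from_dict(d)


def read_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty configuration file")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
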
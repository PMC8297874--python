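"""Factorial simulation study and HH-parameter prediction.

Pipeline per configuration: simulate the HH signal, detect APs, blank
incomplete edge APs, re-detect, classify the dynamic regime and — for
signals with at least one AP — fit the restricted FMM spike-train variants
and extract waveform features.  The aggregated records feed (i) summary
tables of fit quality and parameter estimates by spike count and (ii)
supervised prediction of HH parameters (S, K, gNa, aM, bM) from the
waveform features with 10-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .hh import (
    HHParameters,
    StimulusProtocol,
    classify_dynamics,
    compute_sk,
    preprocess,
    sample_design,
    simulate,
)
from .spiketrain import (
    TAU_A,
    TAU_B,
    DetectionConfig,
    FeatureVector,
    SpikeTrainModel,
    detect_spikes,
    extract_features,
    fit_variants,
)
from .waves import TimeGrid, r_squared

__all__ = [
    "ExperimentRecord",
    "PredictionReport",
    "run_factorial",
    "records_to_frame",
    "summarize",
    "predict_hh",
    "PREDICTION_TARGETS",
]

log = logging.getLogger(__name__)

PREDICTION_TARGETS = ("S", "K", "gNa", "aM", "bM")


@dataclass
class ExperimentRecord:
    """Everything retained from one simulated configuration."""

    index: int
    params: HHParameters
    stimulus: float
    S: float
    K: float
    s: int
    dynamics: str
    r2: dict[str, float] = field(default_factory=dict)
    features: FeatureVector | None = None
    fit: SpikeTrainModel | None = None
    fit_ok: bool = True
    fit_error: str | None = None

    @property
    def analyzed(self) -> bool:
        return self.s >= 1 and self.fit_ok


@dataclass(frozen=True)
class PredictionReport:
    """Cross-validated prediction of one HH parameter."""

    target: str
    predictor_set: str
    method: str
    r2: float
    fold_r2: tuple[float, ...]
    cv_seed: int
    n_records: int


def run_factorial(
    n_per_stimulus: int,
    seed: int,
    fit_variant=("s*", "ST"),
    *,
    dt: float = 0.05,
    config: DetectionConfig | None = None,
    keep_fits: bool = False,
    progress: bool = False,
) -> list[ExperimentRecord]:
    """Run the full factorial design and fit every signal with >= 1 AP.

    Deterministic given ``seed``.  Individual fit failures are logged and
    flagged on the record, not fatal.
    """
    if n_per_stimulus < 0:
        raise ValueError("n_per_stimulus must be >= 0")
    config = config or DetectionConfig()
    if isinstance(fit_variant, str):
        fit_variant = (fit_variant,)
    design = sample_design(n_per_stimulus, seed)
    records: list[ExperimentRecord] = []
    for idx, (params, stim) in enumerate(design):
        sk = compute_sk(params)
        traj = simulate(params, stim, dt)
        _, peaks = detect_spikes(
            traj.X, t=traj.t, config=config, baseline=traj.resting_value
        )
        traj = preprocess(traj, stim, traj.t[peaks])
        s, _ = detect_spikes(
            traj.X, t=traj.t, config=config, baseline=traj.resting_value
        )
        rec = ExperimentRecord(
            index=idx,
            params=params,
            stimulus=stim.amplitude,
            S=sk.S,
            K=sk.K,
            s=s,
            dynamics=classify_dynamics(s),
        )
        if s >= 1:
            grid = TimeGrid.from_times(traj.t)
            try:
                fits = fit_variants(
                    traj.X, s=s, variants=fit_variant, theta=grid.theta, config=config
                )
                rec.r2 = {v: m.r2 for v, m in fits.items()}
                feature_model = fits.get("ST") or next(iter(fits.values()))
                rec.features = extract_features(feature_model)
                if keep_fits:
                    rec.fit = feature_model
            except Exception as exc:  # noqa: BLE001 - isolate per-signal failures
                rec.fit_ok = False
                rec.fit_error = str(exc)
                log.warning("fit failed for record %d (s=%d): %s", idx, s, exc)
        records.append(rec)
        if progress and (idx + 1) % 50 == 0:
            log.info("processed %d/%d configurations", idx + 1, len(design))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per configuration)."""
    rows = []
    for r in records:
        row = {
            "index": r.index,
            "I": r.stimulus,
            "gNa": r.params.gNa,
            "gK": r.params.gK,
            "gL": r.params.gL,
            "aN": r.params.aN,
            "bN": r.params.bN,
            "aM": r.params.aM,
            "bM": r.params.bM,
            "S": r.S,
            "K": r.K,
            "s": r.s,
            "dynamics": r.dynamics,
            "fit_ok": r.fit_ok,
        }
        for v, val in r.r2.items():
            row[f"r2_{v}"] = val
        if r.features is not None:
            row.update({f"feat_{k}": v for k, v in r.features.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


_SUMMARY_STATS = [
    ("r2_s*", "r2_s*"),
    ("r2_ST", "r2_ST"),
    ("M", "feat_M"),
    ("AmA", "feat_AmA"),
    ("AmB", "feat_AmB"),
    ("betaA", "feat_betaA"),
    ("cosBetaB", "feat_cosBetaB"),
    ("sinBetaB", "feat_sinBetaB"),
    ("omegaA", "feat_omegaA"),
    ("omegaB", "feat_omegaB"),
    ("dmAP", "feat_dmAP"),
    ("dmAB", "feat_dmAB"),
]


def summarize(records) -> pd.DataFrame:
    """Means and SDs of fit statistics and parameter estimates, grouped by
    the number of APs, plus an ALL column."""
    df = records_to_frame([r for r in records if r.analyzed])
    if df.empty:
        raise ValueError("no analyzed records to summarize")
    out: dict[str, dict[str, float]] = {}
    groups = [(str(s), sub) for s, sub in df.groupby("s")] + [("ALL", df)]
    for label, sub in groups:
        col: dict[str, float] = {"n": float(len(sub))}
        for name, src in _SUMMARY_STATS:
            if src not in sub.columns:
                continue
            vals = sub[src].dropna()
            col[f"{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
            col[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[label] = col
    return pd.DataFrame(out)


def _target_values(records, target: str) -> np.ndarray:
    if target not in PREDICTION_TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {PREDICTION_TARGETS}")
    if target in ("S", "K"):
        return np.array([getattr(r, target) for r in records])
    return np.array([getattr(r.params, target) for r in records])


def _make_estimator(method: str, seed: int):
    num = Pipeline(
        [("impute", SimpleImputer(strategy="median")), ("scale", StandardScaler())]
    )
    if method == "lr":
        return Pipeline([("pre", num), ("model", LinearRegression())])
    if method == "rf":
        return Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("model", RandomForestRegressor(n_estimators=300, random_state=seed)),
            ]
        )
    if method == "gbm":
        return Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("model", GradientBoostingRegressor(random_state=seed)),
            ]
        )
    if method == "svm":
        base = Pipeline([("pre", num), ("model", SVR(kernel="rbf"))])
        grid = {
            "regressor__model__C": [1.0, 10.0, 100.0],
            "regressor__model__gamma": [0.01, 0.03, 0.1, 0.3],
            "regressor__model__epsilon": [0.05, 0.1],
        }
        ttr = TransformedTargetRegressor(regressor=base, transformer=StandardScaler())
        return GridSearchCV(ttr, grid, cv=5, scoring="r2", n_jobs=1)
    raise ValueError(f"unknown method {method!r}; expected lr, rf, svm or gbm")


def predict_hh(
    records,
    target: str,
    predictor_set: str = "tauA+tauB",
    method: str = "svm",
    cv_seed: int = 0,
) -> PredictionReport:
    """Predict one HH parameter from waveform features with 10-fold CV.

    ``predictor_set`` is ``"tauA"`` (dominant-wave features) or
    ``"tauA+tauB"``.  The reported R^2 pools all out-of-fold predictions.
    """
    analyzed = [r for r in records if r.analyzed and r.features is not None]
    if len(analyzed) < 100:
        raise ValueError(f"need >= 100 analyzed records, got {len(analyzed)}")
    if predictor_set == "tauA":
        cols = list(TAU_A)
    elif predictor_set in ("tauA+tauB", "tauB+tauA"):
        cols = list(TAU_A) + list(TAU_B)
    else:
        raise ValueError(f"unknown predictor_set {predictor_set!r}")
    feats = pd.DataFrame([r.features.to_dict() for r in analyzed])
    X = feats[cols].to_numpy(dtype=float)
    y = _target_values(analyzed, target)
    if np.ptp(y) == 0:
        raise ValueError(f"target {target} is constant over the records")

    cv = KFold(n_splits=10, shuffle=True, random_state=cv_seed)
    oof = np.full(y.size, np.nan)
    fold_r2: list[float] = []
    for train_idx, test_idx in cv.split(X):
        est = _make_estimator(method, cv_seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        oof[test_idx] = pred
        if np.ptp(y[test_idx]) > 0:
            fold_r2.append(r_squared(y[test_idx], pred))
    return PredictionReport(
        target=target,
        predictor_set=predictor_set,
        method=method,
        r2=r_squared(y, oof),
        fold_r2=tuple(fold_r2),
        cv_seed=cv_seed,
        n_records=len(analyzed),
    )
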
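# fmmst — Möbius-wave models for action-potential trains

`fmmst` models neuronal membrane-potential recordings as sums of
frequency-modulated Möbius (FMM) waves and uses the fitted waveform
parameters to recover the biophysics that generated them. It is aimed at
computational neuroscientists and biostatisticians who want a *parametric,
interpretable* description of spike waveforms — an alternative to both
mechanistic ODE fitting and black-box feature extraction.

The core signal model on a record rescaled to the circle `θ ∈ [0, 2π)` is

    X(θᵢ) = M + Σ_S [ W(θᵢ; A_S^A, α_S^A, β^A, ω^A) + W(θᵢ; A_S^B, α_S^B, β^B, ω^B) ] + eᵢ

with `W(θ; A, α, β, ω) = A·cos(β + 2·arctan(ω·tan((θ − α)/2)))`. Each of
the `s` action potentials contributes a dominant **A wave**
(depolarization/repolarization) and a **B wave** (hyperpolarization); all
spikes share the shape parameters `(β, ω)` of their wave class, locations
interleave cyclically, and `A_S^A ≥ A_S^B`. Restricted variants (`ST`,
`ST*`, `s*`, `s**`) trade flexibility for parsimony; Fourier models with
matched free-parameter counts serve as baselines.

The package also contains:

- a Hodgkin–Huxley simulator (modern-convention rates, multiplicative
  kinetic scale factors) with the factorial experiment design over
  conductances and gate kinetics, and the `(S, K)` structural/kinetic
  summary `S = g_Na/(g_Na+g_K)`, `K = (ã_n+b̃_m)/(ã_n+b̃_n+ã_m+b̃_m)`;
- threshold spike detection, AP-train preprocessing, and feature
  extraction (`τ^A`, `τ^B` sets);
- cross-validated prediction of HH parameters from waveform features
  (linear regression, random forest, RBF-SVM, gradient boosting);
- a synthetic spike-train generator for parameter-recovery studies;
- a CLI: `fmmst simulate | design | fit | features | experiment | synth`.

See `docs/methods.md` for the estimation algorithm and all numerical
choices.

## Worked example

Simulate an oscillatory neuron, detect its spikes and fit the spike-train
model:

```python
import numpy as np
from fmmst import (HHParameters, StimulusProtocol, simulate,
                   detect_spikes, fit_st, extract_features, TimeGrid)

params = HHParameters(gNa=232, gK=27, gL=0.12)     # sodium-rich, leaky
traj = simulate(params, StimulusProtocol(amplitude=12.0))
s, _ = detect_spikes(traj.X, t=traj.t, baseline=traj.resting_value)
model = fit_st(traj.X, s=s, variant="ST",
               theta=TimeGrid.from_times(traj.t).theta)
f = extract_features(model)
print(f"s={s}  R2={model.r2:.4f}")
print(f"A^A={np.round(model.A_A,1)}  beta^A={model.beta_A:.2f}  omega^A={model.omega_A:.3f}")
print(f"AmB={f.AmB:.1f}  dmAP={f.dmAP:.3f}  dmAB={f.dmAB:.3f}")
```

prints

```
s=3  R2=0.9920
A^A=[50.3 48.1 49.7]  beta^A=2.15  omega^A=0.020
AmB=37.4  dmAP=1.386  dmAB=0.021
```

Three spikes are found; the full model explains 99.2 % of the signal
variance. The dominant waves are ~50 mV and sharp (`ω^A ≈ 0.02`); the
consecutive-spike circular distance `d_m^AP ≈ 1.39` corresponds to an
inter-spike interval of roughly 20 ms on the 60 ms record, and the small
`d_m^AB` says each hyperpolarization hugs its spike.

Run the factorial study end to end (records, summary table, optional
SVM prediction of S and K) from the shell:

```bash
fmmst experiment --n-per-stimulus 20 --seed 1 --out-dir out/ --predict
```

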
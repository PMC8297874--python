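# Methods

## The signal model

A membrane-potential record on a window `[t0, t0 + T)` is rescaled to the
circle, `θ = (t − t0)·2π/T`, and modelled as a sum of frequency-modulated
Möbius (FMM) waves plus Gaussian error:

    X(θ_i) = M + Σ_J A_J cos(φ_J(θ_i)) + e_i,
    φ_J(θ) = β_J + 2·arctan(ω_J · tan((θ − α_J)/2)),   e_i ~ N(0, σ²).

Each wave has an amplitude `A > 0`, a location `α`, a skewness `β` and a
kurtosis `ω ∈ (0, 1]`. At `ω = 1` the wave is a plain sinusoid; as `ω → 0`
it concentrates its variation into a sharp transit. Two geometric facts
matter in practice:

- the phase passes through `β` exactly at `θ = α` and through `β ± π` at
  `θ = α ± π`;
- for small `ω` the phase lingers near `β` over most of the circle and
  transits rapidly near `θ = α + π`, so the *visible extremum* of a
  spiky wave sits half a period away from its `α`. Detected spike peaks
  are therefore shifted by `π` before they seed the location estimates.

### The spike-train family

A train of `s` action potentials is a restricted 2s-wave model: each spike
carries a dominant A wave (depolarization/repolarization) and a B wave
(hyperpolarization); all A waves share `(β^A, ω^A)` and all B waves share
`(β^B, ω^B)`; locations interleave cyclically
(`α_1^A ≤ α_1^B ≤ α_2^A ≤ …`); and each spike's A wave dominates its B
wave (`A_S^A ≥ A_S^B`). Four nested variants are fitted:

| tag  | restriction                                   | free parameters |
|------|-----------------------------------------------|-----------------|
| ST   | shared shapes only                            | 1 + 4s + 4      |
| ST*  | + equal amplitudes across spikes              | 1 + 2s + 6      |
| s*   | A waves only, free amplitudes                 | 1 + 2s + 2      |
| s**  | A waves only, equal amplitudes                | 1 + s + 3       |

Derived descriptors: inter-spike distances `d_S^AP = 1 − cos(α_S^A −
α_{S+1}^A)` and within-spike distances `d_S^AB = 1 − cos(α_S^A − α_S^B)`,
both in `[0, 2]`; medians of amplitudes and distances over spikes form the
feature sets `τ^A` (dominant-wave descriptors plus the spike count) and
`τ^B` (B-wave descriptors, with `β^B` expanded to cosine and sine for
linear and kernel methods). Goodness of fit is `R² = 1 − SSE/SST`.

Note the distance convention: both `d^AP` and `d^AB` use `1 − cos(·)`.
A same-spike A–B pair a few tenths of a radian apart then has `d^AB` of a
few hundredths, which is the scale on which these values are reported.

## Estimation

Monocomponent fits use the standard two-stage scheme: a grid over the
nonlinear pair `(α, ω)` — `α` on equispaced angles, `ω` on
`{0.01, …, 1}` — with `(M, A·cosβ, −A·sinβ)` profiled out by linear least
squares, followed by Nelder–Mead refinement of `(α, ω)`. Multicomponent
fits backfit waves against the running residual with a joint linear
re-solve of all amplitude-phase coefficients after every update, which
makes `R²` provably non-decreasing in the number of waves.

Spike-train fits alternate three updates, accepting only SSE-improving
moves:

1. a shared-shape search for `(β, ω)` of a train, with the intercept and
   all amplitudes profiled out linearly (coarse grid, then Nelder–Mead);
2. per-spike location scans inside windows bounded by the neighbouring
   spikes (preserving the cyclic ordering);
3. a B-train fit to the residual of the A-train, then a joint linear
   refit of the intercept and every amplitude.

A final joint Nelder–Mead polish over *all* nonlinear parameters (shared
shapes and every location, amplitudes profiled) closes most of the
remaining optimality gap; on oscillatory HH signals it typically lifts the
full-model `R²` from ~0.96 to ~0.99.

Variants are fitted along the restriction lattice: `s**` first, then
`s*` and `ST*` warm-started from it, then `ST` warm-started from `ST*`
(falling back to `s*` if that start is better). Because every larger model
starts from a feasible point of a smaller one and accepts only
improvements, the fitted `R²` respects `s** ≤ s*`, `s** ≤ ST* ≤ ST` and
`s* ≤ ST` by construction. `s* ≤ ST*` is not a set inclusion (free
amplitudes versus equal amplitudes plus B waves) and is asserted
empirically; a linear re-embedding fallback restores the ordering if the
independent searches ever invert it.

For speed, the nonlinear searches run on a grid decimated to ≤ 700
points; final amplitude solves and all reported `R²` values use the full
grid. Kurtosis is bounded below at 0.01 to avoid numerically degenerate
spikes; angles are stored in `[0, 2π)` and compared circularly.

## Spike detection

Spikes are local maxima exceeding `k·σ_X` (default `k = 2.5`, `σ_X` the
sample SD of the record) above a height reference, with a refractory
separation (default 2 ms). The reference defaults to the signal mean; the
simulation pipeline passes the resting level instead, which reads the
threshold as an absolute voltage excursion from rest. Records whose
overall SD is below `min_sigma` (default 5 mV) are declared spike-free:
an action potential is a ~100 mV excursion and forces the record SD above
~12 mV even at one spike per 60 ms, while subthreshold responses and
solver-level ripple stay below a few mV — a relative threshold alone is
degenerate there because `σ_X` shrinks with the excursion. On noiseless
simulations peak excursions are strictly bimodal (< 15 mV or > 80 mV), so
the classification is insensitive to the exact floor.

## The Hodgkin–Huxley simulator

The classical four-state system (potential `X`; gates `m, n, h`) with the
modern-convention rate functions (rest near −65 mV, `V_Na = 50`,
`V_K = −77`, `V_L = −54` mV; conductances in mS/cm²). The kinetic factors
`ã_j, b̃_j` scale the voltage-dependent rates multiplicatively — a factor
of 1 recovers the textbook squid axon; literal replacement of the rate
functions by constants would abolish voltage-dependent gating and with it
all spiking, so the multiplicative reading is the only one consistent
with excitable dynamics. Two scalar summaries compress a configuration:
`S = g_Na/(g_Na + g_K)` (structure) and
`K = (ã_n + b̃_m)/(ã_n + b̃_n + ã_m + b̃_m)` (kinetics).

Integration uses LSODA with `rtol 1e-6 / atol 1e-8`, split at the
stimulus edges so the solver never steps across a current discontinuity,
sampled on a uniform grid (default `dt = 0.05` ms, 1200 points over
60 ms — fine enough that a transit of width `ω ≈ 0.02` still spans ~8
samples). Gates are clipped to `[0, 1]` only for violations below 1e-9;
anything larger raises.

Every experiment starts at the *canonical* resting voltage (≈ −64.81 mV,
the zero of the original squid-axon convention) with the gates at the
configuration's own steady state for that voltage. Configurations whose
equilibrium differs relax — or fire — from `t = 0`, which is why
pre-stimulus action potentials exist and why the preprocessing rules
below are needed. An exact-equilibrium start (`init="equilibrium"`,
root-finding on the full system at `I = 0`) is available; under it no
pre-stimulus AP can ever occur and oscillatory configurations sampled at
their unstable equilibrium never leave it, which contradicts the observed
phenomenology of this experiment class.

### Factorial design and preprocessing

Each varied parameter draws uniformly from its value set
(`g_Na ∈ {64…260}`, `g_K ∈ {27…48}`, `g_L ∈ {0.12…0.5}`,
`ã_n ∈ {0.85…1.15}`, `b̃_n, b̃_m ∈ {0.7…1.3}`, `ã_m ∈ {0.8…1.3}`), crossed
with square-pulse amplitudes `I ∈ {0, 4.5, 7, 9.5, 12}` µA/cm² (1 ms at
`t = 10` ms; 60 ms records). A first AP peaking before the stimulus, or a
last AP peaking in the final 6 ms, is blanked to the resting value over
its full extent — from 3 ms before the peak until the potential first
returns within 2 mV of rest, capped at the next spike's rise. If the only
AP precedes the stimulus the record is analyzed as is. Spike counts and
the excitable / oscillatory / non-excitable labels are taken after
preprocessing.

## Parameter prediction

`S`, `K`, `g_Na`, `ã_m` and `b̃_m` are predicted from the fitted features
(`τ^A` or `τ^A + τ^B`) with off-the-shelf learners: linear regression,
random forest, RBF-kernel SVR (within-pipeline standardization of
features and target, `(C, γ, ε)` tuned by an inner 5-fold grid search)
and gradient boosting. Validation is 10-fold cross-validation with the
reported `R²` computed once on the pooled out-of-fold predictions (the
natural reading of the variance-explained statistic; fold-averaged values
are also retained on the report). `d_m^AP` is undefined for single-spike
records and is median-imputed inside each training fold.

## Synthetic data generator

`SyntheticTrainSpec`/`generate_train` evaluate the spike-train model
exactly and add i.i.d. Gaussian noise. Defaults mirror the waveform
regime of simulated HH trains: dominant amplitudes ~50 mV, B amplitudes
~15–20 mV, `β^A ≈ 2.6`, `β^B ≈ 4.7`, `ω^A ≈ 0.03`, `ω^B ≈ 0.09`, evenly
spaced spikes. What the generator does *not* emulate: solver transients,
blanking scars from discarded edge APs, spike-to-spike shape drift, and
non-Gaussian or correlated noise. Recovery tests on this generator
therefore certify the estimator under its own model assumptions; the HH
pipeline tests cover model misspecification of the kind real simulations
produce.

## Problem sizes and reported numbers

The package's own study runs at desk scale: the test suite uses 100
configurations per stimulus level (500 experiments) and the acceptance
script 200 per level (1000 experiments), one-tenth and one-fifth of the
full-scale design. Fraction-type and mean-type summaries are
scale-invariant up to sampling noise; the cross-validated prediction
accuracy is not — its learning curve is still steep in this range
(explained variance for `S` rises by roughly ten points between 120 and
300 analyzed records), so prediction numbers move by a few points with
the scale and seed. The full-extent AP blanking also caps the analyzed
spike count at about 4 per record.

## Known limitations

- Excitability calibration: with the printed stimulus amplitudes taken as
  current densities, ~59 % of experiments fire at least one AP;
  reconciling the reported ~72 % would require an effective stimulus
  scale factor (~1.75×) for which no printed basis exists. Waveform
  statistics of the firing experiments are unaffected.
- The dominant-wave-only fit (`s*`) is reported at the optimum our joint
  optimizer finds; restriction schemes that average unrestricted
  estimates and refit (a common practical shortcut) yield systematically
  lower `R²` for multi-spike records.
- Overlapping spikes, multi-channel records, non-square stimuli and the
  equal-distance restricted variants are out of scope.
- `ST` fits with one spike are a reparameterized two-wave FMM model; the
  two optimizers may land in slightly different local optima on noisy
  records.
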
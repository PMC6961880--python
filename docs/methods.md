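# Methods

## Model

A single diffusing species `u(x, t)` (dermal histamine, dimensionless
concentration) on the unit square with zero-flux boundaries:

```
du/dt = D_u ∇²u + f_act(u) − g_inh(u) + μ − α₀ u
f_act = γ u χ(U),   χ = 1 while ∫₀ᵗ γ u dt ≤ U_tot, 0 afterwards (one-way)
g_inh = α₂ u / (α₁ + u²)
```

The activation term models cascaded histamine release from mast cells whose
granule stores are finite; once a cell's cumulative release `U` exceeds
`U_tot` it never releases again (histamine resynthesis is neglected).  The
inhibition term is a bell-shaped, concentration-dependent brake, strongest
at `u = √α₁` with ceiling `α₂`.  Defaults (the "Set I" reference):
`γ = 4.0, α₀ = 0.7, α₁ = 0.4, α₂ = 4.5, μ = 1.5, U_tot = 150,
D_u = 4.7×10⁻⁶`, all per dimensionless time/length.  Physically the domain
is 27.4 cm × 27.4 cm and one time unit is 250 s; only length, time and
speed are converted between the two columns, because the published
dimensional rate constants are not mutually consistent with any single
time/concentration scaling (their implied ratios differ by factors of
2–20 across rows).  Speed conversion: `mm/hr = c_nd × 274 mm × 3600 /
250 s`.

At Set I the space-free kinetics have a stable resting state
`u0* ≈ 0.224` and an unstable ignition threshold `ul* ≈ 0.623`
(`χ = 1`).  Above `ul*` the rate is positive and `u` grows at the
asymptotic rate `γ − α₀` until store depletion flips `χ`, after which the
cell relaxes to the depleted equilibrium (`≈ 0.13`).  The wheal readout
`H(u) = 1/(1 + exp(−β(u − u_r)))` is diagnostic only (no feedback on `u`);
`β = 30` while `u` is rising and `150` while falling (defaults; only the
inequality rise < fall is physically constrained — the skin recovers with
a sharper effective threshold than it wheals), `u_r = 0.5` by default,
chosen between the resting state and the concentrations reached by
ignited tissue.  Masks are binarized at `H ≥ 0.5`.

## Numerics

Explicit Euler with a 5-point Laplacian and mirrored ghost cells (2-D), or
a finite-volume cylindrical Laplacian on cell-centred radii (radial mode;
the r = 0 face carries zero flux geometrically).  Stability guards,
enforced at every step: `dt ≤ h²/(4 D_u)` and `dt × max|dR/du| ≤ 0.1`,
where the kinetic bound is `γ + α₀ + α₂/α₁`.  Automatic `dt` takes 0.8 of
the tighter limit.  Cumulative release uses the rectangle rule with the
pre-step concentration.  Per-cell rising/falling direction is the sign of
the last nonzero increment, initialized to rising.  NaN or negative
concentrations abort with an error naming the offending `dt`.

Grid choices.  Pattern runs default to 512² (the published figures'
structures are resolved well below this).  Front-speed work uses the
radial mode: the front width is `√(D_u/|R'|) ≈ 1.1×10⁻³` domain lengths,
so the default front measurement uses 2048 cells over a 0.25-length
radial window (~8 cells across the front).  Test-suite and acceptance
runs use these or smaller problem sizes (16²–256² grids, radial windows
of 0.125–0.25) — sizes at which every measured quantity reported here is
resolution-converged (halving the front grid changes the speed by < 2%;
front speed is also stable to within ~30% down to 64-cell radial grids).

## Initial stimulus and P_min

`u(x,0) = u0* + r (φ + s ψ)/(1 + s)` with `φ` i.i.d. uniform[0,1) per
cell (seeded; the field is resolution-dependent, so seed and grid size
are recorded with outputs) and `ψ = (cos(nπx/L) cos(mπy/L) + 1)/2`.
Stimulus strength is reported as `P_r = 100 r / c_max`; the reference
concentration `c_max` defaults to 1.0 (configurable — no operational
definition of the "maximal concentration" is available, so percentages
are relative to this documented convention).  `P_min` is located by
bisection on `r` (1% relative tolerance) at a fixed seed, with
"develops" = the spatial maximum of `u` exceeds `u_r` at any time after a
burn-in of 1 time unit (the raw perturbation may exceed `u_r`
transiently).  When the kinetics admit no positive equilibrium (no
inhibition, `α₂ = 0`, with `γ > α₀`) the base state itself grows and
`P_min = 0`; when `γ − α₀ < 0` no stimulus can ignite release and the
search reports "never develops".

## Pattern classification

The clinical taxonomy is visual; the classifier makes it reproducible
with explicit thresholds (all configurable).  Components are 8-connected;
equivalent diameter `2√(area/π)` in mm; a component is a *ring* if its
filled area exceeds its area by ≥ 20%, an *arc* if solidity < 0.5 without
a hole, a *disk* if solidity ≥ 0.9 without a hole.  Decision order:
empty → none; coverage ≥ 0.9 → uniform; median diameter < 3 mm → fine
dots; ≥ 20 components with median < 8 mm → dots; among components ≥ 5 mm,
ring majority → annular (large/small split at 20 mm median outer
diameter), arcs outnumbering rings → broken annular, disk majority →
circular; otherwise dots.  The size cutoffs (3 mm fine dots) follow the
published description; the solidity/coverage values are this package's
own operational choices.  Classification is invariant under rotations and
reflections and stable under one-cell dilation for features ≥ 10 cells
wide (tested).

## Injection analytics and D estimation

The intradermal bolus is pure diffusion: `u(r,t) = u0/(4πD t)
exp(−r²/4Dt)` with `u0 = u_nd × dose`, `u_nd = 0.03 ml/µg`.  The wheal
edge is the threshold radius `r*(t) = √(4Dt log(u0/(4πD u_r t)))`, which
peaks at `t* = u0/(4πD u_r e)` with value `2√(D t*)`; the measured radius
adds the initial bleb radius `r0`.  With the published 10 µg/ml fit
(`D = 0.08474977 mm²/min`, `u_r = 0.003748`, `u0 = 0.3`,
`r0 = 3.20875 mm`), `t* ≈ 27.6 min` and the mean expansion velocity over
the first 15 minutes is 0.191 mm/min.

Estimation pipeline (three doses, 3/10/30 µg/ml): fit each radius time
course with `Y = Y0 + (P − Y0)(1 − e^{−αt})`; the stopping time is where
the fitted speed falls to `ε = 0.005 mm/min` (closed form
`t* = log(α(P−Y0)/ε)/α`), clamped into the observation window; `r*max` is
the observed curve at `t*` (fitted value corrected by the locally
averaged data-minus-fit residual, ±2.5 min — this tracks the data while
averaging noise); the known `r0` is subtracted; and for each dose pair
the equality of threshold concentrations
`u(r*ᵢ, t*ᵢ; D) = u(r*ⱼ, t*ⱼ; D)` is solved for `D` by bracketed
root-finding on [10⁻⁴, 10] mm²/min.  `D̂` is the mean over pairs.

Two properties of this estimator drove the design and are worth knowing:

1. *Exactness on the threshold curve.*  If both extracted points lie
   exactly on their doses' true threshold curves, every pair returns the
   true `D` identically — hence `r*max` is read from the observed series,
   not extrapolated from the surrogate fit (whose model error beyond the
   window biases `D` by tens of percent).
2. *Degeneracy at the maximizer.*  If both points sit exactly at their
   theoretical maximizers, `r*²/t* = 4D` and `u0 ∝ t*` make the pairwise
   equation independent of `D` (0/0).  Identifiability comes from the
   stopping points straddling the maximizers, which the window clamp
   provides naturally.  Pairs detected as degenerate (identical doses or
   stopping points) are flagged unidentifiable and skipped.

The literal shared-radius form of the pairwise equations (one `r` in both
exponentials) is preserved behind `shared_r=True`; it often fails to
bracket a root and is not the default.

*Fixture generator.*  Clinical series are emulated as radii on the
threshold-radius law up to each dose's own `t*`, held at the maximum
thereafter (wheals persist once formed — skin recovery is far slower than
histamine clearance, the same asymmetry the hysteretic `H` encodes), with
Gaussian noise on every point except the `t = 0` bleb radius (set by
injected volume, treated as known).  Sampling is minutes 0–20, the
clinical observation window.  What this generator does *not* emulate:
inter-subject variability in `u_r` and `r0`, the dose-independent ~15-min
clinical plateau (the printed parameters put the 30 µg/ml stopping time
near 83 min — a tension internal to the published fit), pixel-quantized
radii, and irregular sampling.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to every clinical artifact.  Performance
under the stated conditions: noise-free recovery within 1%; at 0.1 mm
noise the median absolute error over 50 seeds is ~9%.

## Front speed

A central suprathreshold Gaussian stimulus (amplitude 1.0, width 0.005)
in radial mode ignites an annular trigger wave: the rim spikes to
`u ~ O(100)`, depletes, and collapses while diffusion ignites the next
annulus.  The outermost `u = u_r` crossing expands at constant speed
(residuals of a linear fit < 5% of the radius range over > 90% of the
trace) until either the domain edge or global background depletion
(`U_tot/(γ u0*) ≈ 167` time units at Set I) ends the propagation.

The measured speed at Set I is `7.1–7.2×10⁻³` domain lengths per time
unit, resolution-converged (n = 1024–4096 radial cells agree to < 2%;
coarse grids are slightly *faster*, never slower) and consistent in scale
with the analytic linearized bound `2√(D_u R'(ul*)) = 7.8×10⁻³`.  With
the stated physical scales this is ≈ 28 mm/hr — two orders of magnitude
above the clinically observed sub-mm/hr CSU wheal expansion, and *faster*
than the injection-model expansion (0.19 mm/min ≈ 11.5 mm/hr mean over
15 min), not ≥ 7× slower.  Because an ignition wave bounds any expansion
from below once any site fires, no stimulus shape or marginality can slow
the resolved front of this model below the trigger-wave speed; matching
the clinical scale would require different parameters or scales than the
stated ones.  The package reports the computed value; the acceptance
checks that compare it against the clinical-scale figure are expected to
fail and say so in their assertion messages.

Front tracking: outermost threshold crossing, linearly interpolated; in
2-D, the angular mean over 32 rays (bilinear sampling at half-cell
steps) with the across-ray standard deviation reported.  The constant
phase is the longest window (≥ 5 snapshots) on which the linear fit's
maximum residual stays below 5% of the within-window radius range; ties
prefer later windows.

## Known limitations

- Explicit Euler is first-order in time; the growth phase of ignited
  cells carries O(λ² t dt/2) relative error (documented in tests; the
  convergence check halves dt in the smooth regime).
- The wheal readout does not feed back on `u`; duration asymmetries enter
  only through the hysteretic `β`.
- No histamine resynthesis: late-time behaviour (hours) is dominated by
  irreversible store depletion; the model cannot recur.
- The pattern classes are operational surrogates for visual categories;
  boundary cases between "dots" and "broken annular" depend on the
  configured solidity thresholds.
- `P_min` maps are single-seed by design (the noise field is part of the
  condition); ensemble averaging is out of scope.
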
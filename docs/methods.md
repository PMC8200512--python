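# Methods

This note documents the models, defaults and numerical choices behind
`beamtune`, and what the synthetic engine does and does not emulate.

## The synthetic dose engine

The engine replaces both the linac (role `measured`) and the TPS (role
`calculated`) with the simplest closed-form laws that reproduce the
qualitative behaviour a commissioning physicist relies on. It is not a
transport calculation; its purpose is to give every tuning stage a ground
truth to recover.

**Profiles.** A square MLC-defined field of side `f` scanned along axis
`x` yields

    reading(x) = (1 − T) · ½ [erf((w − x)/(√2 σ_eff)) + erf((w + x)/(√2 σ_eff))] + T

with half-width `w = f/2 + DLG/2` on the crossline axis (the MLC edges
along leaf travel are widened by the dosimetric leaf gap) and `w = f/2`
inline. `σ_eff² = σ_axis² + detector_sigma²` for measured profiles (finite
detector size blurs the measurement in quadrature) and `σ_eff = σ_axis`
for calculated ones. Profiles are normalized to 100% at the central axis
— deliberately not at the maximum, which matters for unflattened (FFF)
beams. The 20–80% penumbra of a pure erf edge is `2√2·erfinv(0.6)·σ_eff ≈
1.683·σ_eff` mm, which is the closed form the penumbra tests pin.

**Sweeping gaps.** A uniform gap `g` sweeping over length `L` with
adjacent leaf pairs staggered by `s = τ·g` (tongue-and-groove fraction τ)
deposits

    D = C (g + DLG − λ s) / L + T (1 − g/L)

where `λ` is the TG fluence-loss coefficient — `tg_loss_measured` for the
linac, `tg_loss_calculated` for the TPS stand-in. Synchronous sweeps
(τ = 0) cannot distinguish the two; asynchronous ones can, and a TPS that
overestimates TG losses (λ_calc > λ_meas) pushes the aOSG-optimal DLG
above the physical one by `(λ_calc − λ_meas)·s̄` on average. This
asymmetry is the engine's mechanism for the clinically observed gap
between aOSG-tuned and sweeping-gap DLG values.

**Output factors.** `OF = (1 − T)·E(f/2 + DLG/2, σX)·E(f/2, σY) + T`
with `E(w, σ) = erf(w/(√2 σ))` (1 when σ = 0): a product of one
source-occlusion edge per axis. OF increases strictly in DLG and T and
decreases in σX, σY while the field partially occludes the source, and
tends to 1 for large fields.

**Dose planes.** Weighted sums of erf-edged rectangular apertures (x edges
DLG-widened and σX-blurred, y edges σY-blurred) on a transmission floor,
normalized by total weight. `ModulationPattern.random(seed)` draws a
reproducible pseudo-clinical overlap of apertures; all randomness enters
through that seed.

**Noise.** Measured signals optionally carry multiplicative Gaussian noise
with coefficient of variation `noise_cv`, seeded per (quantity, geometry)
so regenerated fixtures are bit-identical for the same seed. Defaults:
`detector_sigma = 0.3 mm`, `noise_cv = 0.003` (measurement reproducibility
below 1%), `C` such that the open reading is 1.000, `L = 100 mm`.

**What the engine does not emulate.** Off-axis FFF cone shape (irrelevant
once profiles are normalized at the central axis for the small fields
studied), scatter and spectral changes with field size, leaf-end
synchronization details, gantry-angle effects, film response. Passing
tests therefore demonstrate that the *estimators* recover the parameters
of a model with the right qualitative structure — not that any specific
TPS is accurate.

## Tuning stages

**Spot size.** Default grid 0–2 mm in 0.2 mm steps (11 points), one axis
per call. The objective is the signed mean over {5 field sizes × left,
right} of (calculated − measured) penumbra; the optimum is the linearly
interpolated zero crossing. When the deviation never changes sign (a
measured penumbra narrower than the sharpest calculation), the grid argmin
of |deviation| is reported with `method="argmin"` — typically σ = 0.
Multiple crossings are all reported and flagged ambiguous. Level crossings
use linear interpolation between bracketing samples: at the 0.1 mm scan
step of the fixtures, higher-order schemes change nothing at the reported
precision. Cross-independence holds in the engine: DLG shifts edge
*position*, not width; transmission moves the 20/80 levels by ≤ 0.1 mm at
clinical T values, and the orthogonal σ does not enter at all.

**Transmission** is measured (closed/open ratio), never co-fitted. The
pipeline evaluates it first because calculated profiles and sweeping doses
need a transmission value, and reports it in the conventional order
(spot → transmission → DLG).

**DLG.** Default grid 0–3.4 mm in 0.1 mm steps (grid step chosen to match
the 0.1 mm precision commissioning reports use). Differences are relative
to the measured dose of each plan; the cost is their mean absolute value.
The cost of the affine engine is piecewise linear and unimodal, so the
argmin is well defined; ties return the smallest DLG and are flagged. An
optional three-point parabolic refinement exists but is off by default.
With a 0.1 mm grid the argmin can sit half a step (0.05 mm) from a truth
that falls between grid points. The per-plan standard deviation of the
differences is reported alongside the cost; its minimum in `d` need not
coincide exactly with the cost minimum (both are quadratic-like but not
identical functionals), so the documented guarantee is only that the
optimum's spread does not exceed the worse grid endpoint's.

**Sweeping-gap DLG.** Readings are corrected for the transmission
accumulated while the point is shielded, `R'(g) = R(g) − T·R_open·(1 −
g/L)`, then fitted by least squares; DLG = intercept/slope. For the
engine's exactly affine law this is exact to machine precision; the fit
refuses non-positive slopes and fewer than two gaps.

**DOE.** The L27(3¹³) array is generated from its GF(3) representation:
runs are the triples (a, b, c) ∈ {0,1,2}³, column k with coefficient
vector (u, v, w) holds `1 + (ua + vb + wc) mod 3`. Factors occupy columns
1, 2, 5, 10 — four columns whose diagonal runs are level-consistent, so
trials 1, 14, 27 set every factor to level 1, 2, 3 respectively. A
requested interaction occupies the two columns algebraically confounded
with its factor pair (for the defaults: DLG×σX → columns 6, 7; DLG×σY →
columns 8, 11). The remaining columns (3, 4, 9, 12, 13; 10 df) pool into
the error term — the design has no replication, so unassigned-column
pooling is the only error estimate available, with the standard Taguchi
assumption that unassigned interactions are negligible. Per field size:
main-effect SS = 9·Σ(level mean − grand mean)² with 2 df, interaction SS =
the sum over its two columns with 4 df, F against the pooled error,
significance at α = 1%. The decomposition is exact (source SS + error SS =
total SS) because all 13 column SS partition the total in an orthogonal
array. Deterministic (noise-free) responses make the error SS vanish; the
table is then flagged degenerate and ranked by SS instead of p — no F test
is fabricated. Responses are signed (calculated − measured, percent), one
independent analysis per field size; amplitudes are max − min of the level
(or 3×3 cell) means.

**Gamma.** Global normalization: the dose-difference denominator is
`dose_pct`% of the reference-plane maximum; reference points below
`threshold_pct`% of that maximum are excluded from the map and the
pass-rate denominator. The evaluated plane is bilinearly interpolated on a
search lattice of step ≤ dta/10 within radius 3·dta; offsets are visited
nearest-first so the search can stop once the pure distance term exceeds
every current minimum. The brute-force exhaustive search over the same
lattice is kept as an independent test oracle. The discrete lattice makes
the map accurate to the lattice resolution; role-swapped gamma agrees only
within that discretization on smooth planes. Verdicts: ≥ 95% pass, 90–95%
investigate, < 90% fail.

## Pipeline and fixtures

`run_commission` executes transmission → spot (both axes) → DLG (aOSG +
sweeping) → DOE → gamma, validates grids before any computation, skips
missing input families with a logged warning, and emits a JSON report that
is byte-identical for identical (config, inputs, seed). Calculated-side
quantities inside the pipeline always come from the engine configured by
the same config (tg-loss coefficients, measured transmission, currently
tuned spot sizes).

`generate_fixtures` writes every input family from a single
`SyntheticTruth`: 10 profiles (5 sizes × 2 axes), the 15-plan aOSG battery,
a 6-gap sweeping series with open/closed references, a two-detector
output-factor table whose raw ratios are divided by synthetic small-field
correction factors (so that correction × raw = true OF), a
measured/evaluated dose-plane pair, and a ready-to-run config. Parameter-
recovery tests use `detector_sigma = 0` and `noise_cv = 0`: with detector
blurring the tuned effective spot is by construction
`√(σ² + detector_sigma²)` — the effective width the measurement actually
has — so exact recovery of σ itself is only meaningful without blur.

## Problem sizes

Tests and the acceptance script use the workflow's native sizes: 11-point
σ grids over 5 field sizes × 2 sides, 35-point DLG grids over 15 plans,
27-trial designs over 6 field sizes, and 21×21 / 15×15 dose planes at 2 mm
spacing (441-point gamma maps with ~2800-offset searches). The full suite
runs in seconds.

## Known limitations

* The engine's laws are separable and noise is purely multiplicative;
  real profile tails, interleaf leakage patterns and detector spectral
  effects are richer.
* Transmission is a single scalar: no interleaf/intraleaf distinction, no
  field-size dependence.
* The aOSG abstraction collapses arc delivery to one dose law per plan;
  MU, dose rate and gantry effects are out of scope.
* Detector correction factors are taken as given inputs; their derivation
  is out of scope.
* Gamma is 2D single-plane; no 3D dose comparison and no film-processing
  chain.
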
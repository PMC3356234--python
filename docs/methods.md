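# Methods

## Model

`chondrosim` simulates the injury response of articular cartilage on a
radially symmetric disc.  Chondrocytes are fixed in the extracellular
matrix, so all spatial coupling runs through four diffusing chemical
species; cells change *state* in place.  Writing `sat(x, λ) = x/(λ+x)`
and `H(s) = 1 for s < 0, 0 for s ≥ 0`, the fields evolve as

    ∂t R = ∇·(D_R ∇R) − δ_R R + σ_R S_T
    ∂t M = ∇·(D_M ∇M) − δ_M M + σ_M D_N + δ_U U sat(F, λ_F)
    ∂t F = ∇·(D_F ∇F) − δ_F F + σ_F S_T
    ∂t P = ∇·(D_P ∇P) − δ_P P + σ_P C sat(R(t−τ₂), λ_R) Λ/(Λ+F)
    ∂t U = −δ_U U sat(F, λ_F)
    ∂t C  = α S_A sat(P, λ_P) − [β₁ sat(M, λ_M) + β₂ sat(F, λ_F)] C H(P−P_c)
    ∂t S_T = [β₁ sat(M, λ_M) + β₂ sat(F, λ_F)] C H(P−P_c)
             − γ S_T(t−τ₁) sat(F(t−τ₁), λ_F) − ν S_T sat(F, λ_F) sat(M, λ_M)
    ∂t S_A = γ S_T(t−τ₁) sat(F(t−τ₁), λ_F) − α S_A sat(P, λ_P)
             − μ_SA S_A sat(F, λ_F)
    ∂t D_N = −μ_DN D_N

with R = reactive oxygen species, M = DAMPs/alarmins, F = TNF-α,
P = EPO, U = matrix density, C = healthy, S_T = catabolic,
S_A = EPOR-active and D_N = necrotic chondrocytes.  An optional ledger
D_A accumulates both apoptosis fluxes (the ν and μ_SA terms); it never
feeds back, but it closes the cell balance: pointwise,
d(C + S_T + S_A + D_A)/dt ≡ 0.

Key structural features, as the equations are printed:

* **EPO production uses the current healthy population and the delayed
  ROS level.**  A healthy cell starts secreting EPO τ₂ = 24 h after
  ROS signalling; production is damped by TNF-α through Λ/(Λ+F).
* **EPOR activation is delayed**: the S_T → S_A flux at time t is
  driven by the catabolic density and TNF level at t − τ₁ (12 h).
  Because this drain is not proportional to the *current* S_T, it can
  transiently overshoot zero when γ·τ₁ is large; the reference value
  keeps γ·τ₁·sat(F) well below the oscillation threshold 1/e and the
  reference runs stay nonnegative to solver precision.
* **Catabolic apoptosis requires TNF-α and DAMPs together** (product of
  the two saturations).
* **The threshold gate** H(P−P_c) *permits* the healthy → catabolic
  switch only while the local EPO level is below the critical level
  P_c.  Taking H ≡ 1 instead (exposed as
  `h_identically_one_mode`, internally P_c = +∞) removes the only
  negative control on the pro-inflammatory loop; the loop is then
  self-amplifying and consumes the healthy field — the package's
  "infinite feedback" diagnostic.  A logistic smoothing of the gate
  (`h_width > 0`) is available as a purely numerical device for
  solvers that dislike discontinuous right-hand sides; it is off by
  default, and runs converge to the hard-switch solution as the width
  shrinks.

Units: hours, millimetres, cells/mm² for densities; concentrations are
in arbitrary units normalised so that the half-saturation constants
are order one.

## Parameters

The two delays carry physiological provenance: τ₁ = 12 h (upper end of
the reported 8–12 h range for EPOR expression) and τ₂ = 24 h (reported
20–24 h for EPO synthesis onset, fixed at the upper end).  **Every
other constant is a calibration**, chosen once so that the two
reference scenarios reproduce the qualitative injury-response regimes,
and marked `calibrated` in the config metadata.  The interesting
choices:

| symbol | value | why |
|---|---|---|
| D_R, D_M, D_F | 0.02, 0.002, 0.002 mm²/h | ROS is small and fast; the protein signals are slow, keeping the inflammatory front sharp (decay length √(D/δ) ≈ 0.06–0.3 mm) |
| D_P, δ_P | 0.08 mm²/h, 0.005/h | EPO acts as a long-range, long-lived field: range √(D_P/δ_P) ≈ 4 mm, so the anti-inflammatory signal blankets the whole 5-mm domain (see *Abatement mechanism*) |
| β₁, β₂ | 0.3, 0.02 /h | the DAMP channel dominates the healthy → catabolic switch; the direct TNF channel is a small correction (and is reported robust under perturbation) |
| δ_U, δ_M, λ_M | 0.06, 0.25, 0.7 | matrix degradation sustains the DAMP signal behind the front long enough to convert ≳95% of the cells the front passes (the matrix is a finite DAMP budget: ∫M dt ≤ U₀/δ_M per unit area) |
| γ | 0.02 /h | S_T → S_A on a ~2-day timescale; γ·τ₁·sat(F) ≈ 0.2 < 1/e keeps the delayed drain monotone |
| α, λ_P | 0.015 /h, 0.3 | EPO rescue over days, so the penumbra persists through day 10 while the healthy population visibly recovers |
| Λ | 150 | far above the TNF scale (F ≲ 4): the suppression factor is a mild modulation, consistent with its reported robustness under ±perturbation |
| λ_R, σ_P, P_c | 8, 0.02, 0.4 | the EPO trigger stays unsaturated at ring ROS levels (R ≈ 2–3), so halving/doubling ROS or EPO production visibly shifts the gate-closure time, while 0.05× abolishes closure |
| C₀, U₀ | 100 cells/mm², 1 | background healthy density and matrix density; injury necrotic density defaults to C₀ (all cells in the disc die at once) |

## Spatial discretisation

The disc (default radius 5 mm, 200 cells) is partitioned into uniform
annuli; values live at annulus centroids.  The diffusion operator
∇·(D∇u) = D r⁻¹ ∂r(r ∂r u) is discretised conservatively: the flux
through the edge at radius e is 2πe·D·Δu/Δr, the innermost edge (r = 0)
and the outer wall carry none.  The scheme is second-order, exactly
conservative (the area-weighted sum of the operator telescopes to
zero) and self-adjoint in the area inner product; pure diffusion–decay
of a Gaussian bump converges to the closed-form radial heat kernel at
second order under grid halving.  The outer wall is zero-flux; a
run-time warning fires when a chemical's boundary value exceeds 1% of
its spatial maximum (in the EPO-free reference the front genuinely
reaches the wall, and the warning fires by design).

## Time integration

The semi-discrete system is a large delay-differential system,
integrated by the method of steps with an explicit embedded
Bogacki–Shampine 2(3) pair and a cubic-Hermite continuous extension
(third-order interpolant, C¹ across steps because the pair is FSAL).
The step size is capped at min(τ₁, τ₂), so delayed arguments always
fall in already-accepted history; before t = 0 they are served by the
scenario's constant pre-injury history.  Error control is standard
(mixed tolerance `atol + rtol·|y|`, RMS norm, PI-free controller with
safety 0.9 and growth clamp).  No event location is attempted at the
gate discontinuity; the error controller resolves the crossing, and
the smoothed-gate option exists for cross-checks.

Numerical choices worth flagging:

* **Tolerances.**  rtol = 1e-6 and atol = 1e-12 in the reference
  scenarios.  The small atol is not about accuracy: wherever the gate
  is open, the healthy field is *linearly unstable* (any trace of
  TNF/DAMPs self-amplifies at ≈0.2–0.3 /h), so absolute-tolerance-level
  noise acts as a seed bank that detonates after roughly ln(1/atol)/0.3
  hours.  At atol = 1e-12 spurious seeds cannot reach visible amplitude
  within the 10-day horizon, while the *physical* precursor tails of
  the front (≈e⁻³⁰ at millimetre distances) remain smaller still.
* **Positivity.**  Snapshot values in (−1e-6, 0) are clipped to zero
  and larger violations raise.  The threshold is deliberately
  decoupled from atol (clipping at 100·atol = 1e-10 would false-alarm
  on benign roundoff in fields of magnitude 100).  Sensitivity sweeps
  disable the contract, because extreme γ values can legitimately
  overdrain the delayed catabolic pool below zero.
* **Determinism.**  The package contains no random number generation;
  identical inputs give bit-identical trajectories on one platform.
* **Checkpointing.**  With `keep_dense=True` the full Hermite knot
  sequence is retained; a checkpoint at an interior time carries the
  interpolated state plus the knots covering the preceding delay
  window, and a restarted run matches the uninterrupted one to a small
  multiple of the integration tolerance (bit-exactly when restarted at
  t = 0).

## Scenarios

The canonical initial condition is a necrotic disc of radius 0.25 mm:
inside it D_N = C₀ and C = 0 (the annulus cell straddling the edge is
split by area-overlap fraction, so the integrated necrotic mass equals
C₀·π·0.25² exactly); outside it C = C₀; U = U₀ and all chemicals are
zero everywhere.  The pre-initial history is the *pre-injury*
equilibrium — C = C₀ everywhere, including inside the disc, and no
necrotic pool — since the injury happens at t = 0.  No delayed term
references the healthy field, so the alternative convention (history
with the hole already present) produces identical dynamics; the choice
is recorded for reproducibility.  The disc edge is sharp by default;
`injury_density` and the grid settings are configurable.

The two reference regimes differ **only** in σ_P (0 versus 0.02) and
run through the identical code path.  Because the EPO source is gated
by R(t−τ₂) and the chemical history is zero, the two trajectories are
*bit-identical* until τ₂ = 24 h — the delays, not a code branch,
produce the shared first day.

## Abatement mechanism, and what the reference calibration emulates

Without EPO the front is a classical pulled wave: TNF/DAMP precursor
tails seed every annulus ahead, each seed grows exponentially, and the
lesion consumes the domain (the healthy population falls below 5% of
its initial value by day 10).

With EPO, a *spatially local* rescue cannot produce a truly fixed
penumbra radius in this model: EPO production lags the front by τ₂
wherever it relies on locally generated ROS, so a locally pinned front
either creeps or re-detonates from precursor seeds ("echo" outbreaks)
— we verified both failure modes numerically.  The shipped reference
set therefore realises abatement as a **global EPO blanket**: EPO is
long-range and long-lived (√(D_P/δ_P) ≈ 4 mm, half-life ≈ 6 days), so
the production ring near the lesion raises P above P_c across the
entire domain by about day 4, the gate closes everywhere at once, the
penumbra freezes at the radius the front had reached (≈3.4 mm), and
EPOR-active cells slowly revert.  This is the package's operational
reading of a "fixed radius beyond which the penumbra cannot expand";
it is a property of this calibrated regime, not of every parameter
set.

For the gate-forced-open diagnostic, "healthy cells exhausted" is
operationalised as the integrated healthy population falling below a
quarter of its initial value; the integrated penumbra is required to
grow strictly monotonically up to that point (it does, and the healthy
field indeed collapses to ≈20%).

## Metrics

The model defines no scalar lesion observable, so the reductions use
documented thresholds: the **lesion radius** is the outermost
(linearly interpolated) radius where C < θ_C·C₀ with θ_C = 0.5; the
**penumbra** is the support of S_T + S_A > θ_S·C₀ with θ_S = 0.05; a
run is **expanding** when the lesion radius still grows faster than
ε_slope = 0.01 mm/day over the final three days, **abated** when it
has stalled but a detectable penumbra persists, **resolved**
otherwise.  The **abatement day** is the first time from which the
radius never again rises by more than max(5%, 0.05 mm), with at least
one further day of record demonstrating the stall.  All reductions are
pure functions of the trajectory.

## Sensitivity study

Each parameter z of the one-at-a-time protocol is swept over [0, 2z]
(floor 0.05 z for the strictly positive constants λ_R, λ_M, λ_F, λ_P,
Λ, α), nine points by default, five in the reduced-resolution
acceptance configuration.  Direction labels compare each sweep extreme
against the base and EPO-free runs; the thresholds (module constants
in `sensitivity.py`) are: a one-day shift in abatement day, a 10%
(floor 1 mm) change in day-10 lesion radius, a ±10–25% change in
day-10 penumbra outer radius, a 15-point change in the recovered
fraction of lost healthy cells, and 90% of the EPO-free day-10 radius
for the approaches-no-EPO diagnosis.  Degradation labels are tested
before improvement labels.

One known deviation from the expected response table: decreasing α or
γ should make the penumbra "more vigorous but smaller in radius".
The slower-recovery half reproduces strongly (recovered fraction
0.00–0.04 versus 0.43 at base), but the smaller-radius half cannot:
EPO production is ∝ C·sat(R) with R ∝ local S_T = C₀ − C, so the
production integral is nearly invariant to the cell-cycling rates α
and γ (gate closure shifts < 0.2 day across their whole range), and
the day-10 penumbra of a low-α/low-γ run is the *un-eroded* formation
radius — always slightly larger than base, never smaller.  These two
sweep directions therefore label `less-efficient-abatement`.

## Limitations

* All quantitative parameter values except the two delays are
  calibrations, not measurements; conclusions are qualitative.
* The healthy state is linearly unstable wherever the gate is open, so
  very long horizons (≫10 days) eventually show outbreaks seeded at
  solver precision regardless of tolerance.
* No IL-1β pathway, no cell motility, no mechanics, no exogenous EPO
  dosing schedules; one spatial dimension (radial symmetry).
* The explicit pair makes the diffusion CFL limit the step size; the
  reference run takes ~45k steps. A stiff/IMEX integrator is future
  work.
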
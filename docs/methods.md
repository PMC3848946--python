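# Methods

## Model and assumptions

The package analyses a theta neuron (phase `θ_E ∈ [−π, π)`, spike at
`θ_E = π`) receiving a constant drive `I_E`, a sinusoidal theta-phase drive
`λ(1 + cos Θ)` with `Θ` advancing at rate `ε_Θ·ω`, and self-inhibition
`−g_IE·s_I` through a synapse that decays at rate `ε_I` and receives a unit
kick at every spike.  The inhibitory interneuron of the underlying PING
loop is treated as instantaneously enslaved: every excitatory spike
triggers an immediate inhibitory spike, so only the synaptic variable is
dynamical.  Coupling is feedforward only (no gamma-to-theta feedback), and
there is no noise.

Three time scales are assumed well separated: the gamma-cell membrane
(order 1), synaptic decay (`1/ε_I`), and the theta rhythm (`1/(ε_Θ·ω)`),
with the modelling convention `ε_Θ ≈ ε_I²`.  The two parameters are kept
independent throughout the code — the asymptotic ISI and count formulas use
`ε ≡ ε_I` while phase updates use `ε_Θ` — and constructing a parameter set
that violates `|ε_Θ − ε_I²|/ε_I² ≤ 0.5` emits a warning rather than an
error, since only the count-formula rescaling relies on the convention
quantitatively.

`I_E = 0` is rejected as degenerate rather than assigned a regime: both
analytic branches are singular there (`π/√I_E` and the SNIC expansion
coefficient `1/sqrt(−I_E)` diverge).

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `IE` | constant drive | — | sign selects the regime |
| `lam` | theta-gamma coupling λ ≥ 0 | 0 | excitable needs `2λ + IE > 0` |
| `gIE` | inhibitory strength | 0 | recursion needs `gIE > IE + 2λ` |
| `epsI` | synaptic decay rate ε | 0.1 | the `ε` of all ISI formulas |
| `epsTheta` | slow scale ε_Θ | 0.01 | theta frequency is `epsTheta·omega` |
| `omega` | theta frequency factor | 4 | `ε_Θ·ω = 0.04` ⇒ theta period ≈ 157 |

The defaults are the reference conditions used across the validation suite
(`ε = 0.1`, `ε_Θ = ε² = 0.01`, `ω = 4`, `g_IE = 6` where inhibition is on);
with a membrane time constant of a few milliseconds these place the fast
cell in the gamma band and the slow drive in the delta/theta band.

## Numerical choices

**Simulator.**  Integration is performed in θ-coordinates (compact, no
blow-up at spikes) with `scipy.solve_ivp`/LSODA, `rtol = 1e−9`,
`atol = 1e−11`; the stiffness-switching stepper matters near the SNIC where
`dθ_E/dt ≈ 0`.  Spikes are located by event detection on `θ_E − π`
(upward crossings); at each spike the state is restarted with `θ_E = −π`
and `s_I` incremented by one.  The δ-kick amplitude is fixed at 1 and `s_I`
does not saturate; `g_IE` absorbs any scale.  State is never reset across
theta cycles, so multi-cycle runs carry residual inhibition into the next
cycle.  Default initial conditions are the theta trough with no residual
inhibition: `θ_E(0) = −π` (a just-reset oscillator, `V = −∞`) in the
oscillator regime, `θ_E(0) = θ₀` (the rest state) in the excitable regime,
`Θ(0) = −π`, `s_I(0) = 0`.

**QIF cross-check.**  The voltage-coordinate first-spike simulator
integrates `dV/dt = V² + F(Θ(t))` from `V = −10³` with blow-up detection at
`+10³` and adds the analytic tail `2/V_cap` for the time a pure `V²` flow
spends beyond the caps.  It exists so that the Mathieu branch can be
validated against an independent coordinate system.

**Mathieu branch.**  General-`(a, q)` Mathieu functions are not assumed
available as library special functions; only the first zero of the
specific initial-value solution is needed, so `u″ = −(a − 2q cos 2z)u` is
integrated directly (DOP853, `rtol = 1e−11`) from `u(0) = 0, u′(0) = 1` —
the initial condition encoding `V(0) = −∞` through `V = −u′/u`; any
positive `u′(0)` has the same zeros.  The sign convention
`cos(ε_Θωt − π) = −cos 2z` is absorbed into the sign of the `q` term, not
into a shift of `z`.  The first zero is detected as the first downward
crossing of `u` (which automatically excludes the root at `z = 0`) and
refined by bisection on the dense output.

**Slow-passage constant.**  `Ω₀` is computed as minus the smallest positive
root of `J_{−1/3}(2y^{3/2}/3) + J_{1/3}(2y^{3/2}/3)` (bracketed Brent,
`xtol = 1e−14`) and cross-checked against the first zero of `Ai(−y)` — the
two representations describe the same function up to a positive factor —
with an internal consistency guard at `1e−8`.  The sign is stored negative
so that every downstream passage correction comes out positive.

**Count estimator.**  The phase integrals `∫ ln(g_IE/F)` and
`∫ (−Ω₀)F^{−1/3}` use adaptive quadrature (`epsabs = 1e−10`); in the
excitable case both integrands have integrable singularities at the window
edges where `F → 0`, which the adaptive scheme handles.  The averaged
recursion bounds the number of complete interspike intervals `k` (largest
integer with `k·⟨ΔT⟩` strictly inside the available active time; exact ties
broken downward).  A window holding `k` complete intervals contains
`k + 1` spikes — each interval ends in a spike and the chain is opened by
the first spike, which is paid for by the first-spike drift and passage
rather than by an interval — so the reported count is `M = k + 1`.  This
spikes-vs-intervals distinction is within the ±1 resolution of the
averaging argument itself; the chosen convention reproduces the simulated
count exactly on three of the four reference sets (see Limitations).  In
the excitable regime, if the predicted first spike falls beyond the closing
SNIC crossing (`2λ + I_E → 0⁺`: the window closes faster than the
slow-passage delay), `M = 0`.

**ISI extrema.**  The quadratic expansions of `ΔT(Θ)` about the trough and
peak are re-derived from the recursion itself:
`dΔT/dF = −1/(εF) + Ω₀/(3ε^{1/3}F^{4/3})` with
`F ≈ I_E + (λ/2)(Θ+π)²` (trough) and `F ≈ I_E + 2λ − (λ/2)Θ²` (peak).  Both
quadratic coefficients are negative at the trough and positive at the peak
(`Ω₀ < 0`), so the two expansions bracket every mid-cycle ISI; a property
test verifies fourth-order agreement with the unexpanded recursion at both
points.

**Second spike (excitable).**  The first spike leaves the phase just past
the SNIC where the drive is marginal, so the second spike waits for
inhibition to decay almost completely: gap `≈ −ln(ε)/ε` to leading order,
refined to `(−ln ε − ln(−ln ε) + A)/ε` with
`A = ln(g_IE/(−λω·sin Θ₀))` (well defined: `sin Θ₀ < 0`).

## Design choices where the design was open

* The regime boundary `I_E = −2λ` is classified silent (the net drive never
  becomes positive, only touches zero at the theta peak).
* `Θ₀` is always stored as the negative-branch solution in `(−π, 0)`; the
  symmetric exit crossing is `−Θ₀`.
* The excitable count estimator defines the active window intrinsically as
  `W = {Θ : F(Θ) > 0}`, of phase length `2|Θ₀|`; this reduces exactly to
  the full-cycle form when `W = [−π, π]`.
* The derivatives certifying the absent logarithmic correction
  (`φ_x`, `φ_xxx`, `ψ_x` at the singular point `(0, Θ₀)`) are evaluated
  from their exact trigonometric forms, not finite differences, so the
  assertion tolerance can sit at machine scale.
* Sequence assembly stops an excitable burst when the next predicted phase
  exits the active window or the next ISI is undefined; an oscillator
  sequence stops after one theta period.

## What the validation does and does not show

All validation inputs are generated by the package's own simulator at the
reference conditions above; there is no external data.  Agreement
demonstrates the internal consistency of the asymptotics with the exact
dynamics of this idealised model — it says nothing about conductance-based
neurons, networks with an explicit interneuron population or synaptic
delays, bidirectional theta-gamma coupling, or noisy drive, none of which
are modelled.

Problem sizes: validation grids are 9–15 parameter points with one
theta cycle (≈ 157 time units) simulated per point, and the scaling studies
run three `ε_Θ`-halvings (up to ≈ 630 time units per run).  The entire
suite and the acceptance script each complete in seconds.

## Known limitations

* **Asymptotic, not exact.**  The excitable first-spike error scales as
  `ε_Θ^{1/3}` relative; it is ≈ 0.3% at `I_E = −0.5` but grows to ≈ 12% at
  `I_E = −0.02` (`ε_Θ = 0.01`), where the saddle-node flattens.
* **Frozen-phase ISIs.**  The recursion evaluates the drive at the phase of
  the previous spike.  Near the theta trough, where ISIs are long, the
  phase advances substantially within one interval and the recursion
  overestimates it; predicted spike times are accurate mid-cycle and
  degrade toward the cycle edges.  The count estimate inherits a ±1
  ambiguity: on the four reference sets it is exact on three and
  undercounts by one on the shallow excitable set (`I_E = −0.1, λ = 1`,
  predicted 5 vs simulated 6).
* **Second-spike refinement at moderate ε.**  At `ε = 0.1` the refined
  estimate is *not* closer to simulation than the leading one: the omitted
  slow-passage delay after the drive re-crosses zero (≈ +4.7 time units at
  the reference set) happens to nearly cancel the `−ln(−ln ε) + A`
  correction (≈ −2.8), making the leading estimate accidentally near-exact.
  The ordering asserted by the asymptotics holds once `ε ≲ 0.02`, which the
  test suite verifies by simulation.
* **Count validity region.**  Outside inhibition dominance the recursion
  does not apply and the package raises/flags rather than extrapolating;
  near the dominance boundary and at very small λ the estimate drifts from
  simulation in the directions expected from the neglected higher-order
  terms.
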
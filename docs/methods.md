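# Methods

## Models

Three two-species circuits with constant input u > 0, controller x and
output y; all rate constants α, β, γ, δ strictly positive, K ≥ 0:

| motif | controller | output |
|-------|------------|--------|
| IFFL1 | x' = αu − δx | y' = βu − γxy |
| IFFL2 | x' = αu − δx | y' = βu/(K+x) − γy |
| IFB   | x' = x(αy − δ) | y' = βu/(K+x) − γy |

With K = 0 each motif adapts perfectly: the output converges to
βδ/(γα) (IFFLs) or δ/α (IFB) regardless of u.  Default initial outputs
are these adapted values — the monotonicity statements for IFFL1 and IFB
assume them — and can be overridden.  IFFL2 with K > 0 has the steady
output βuδ/(γ(δK + αu)); IFB with K > 0 additionally has the boundary
fixed point (0, βu/(γK)).  The interior IFB fixed point
(αβu/(γδ) − K, δ/α) exists iff K < αβu/(γδ).

Normalizations remove all parameters: IFFL1 scales time by δ, x by γ/δ
and y by γα/(δβ), giving x' = −x + û, y' = −xy + û with y(0) = 1 and
û = (γα/δ²)u.  (The y-scale is fixed by requiring ŷ(0) = 1 at the adapted
initial output and by consistency of the normalized output equation.)
IFB with K = 0 scales time by γ and y by α/γ, giving x' = x(y − p),
y' = û/x − y with p = δ/γ, û = (αβ/γ²)u.

## Numerical integration

All simulations use `scipy.integrate.solve_ivp` with DOP853 at
rtol 1e-9 / atol 1e-12.  These defaults are deliberately tight: the
Hamiltonian event detection and the monotonicity verdicts downstream
resolve effects as small as 1e-3 against curve values of order 10.  The
cumulative output z(t) = ∫₀ᵗ y is carried as an extra quadrature state
(ż = y, with small negative y excursions clipped at zero), so cDR values
inherit solver accuracy and do not depend on the output grid.  A state
excursion below −1e-9 aborts with an integration-quality error; the
models are positivity-preserving analytically.

Forward sensitivities ∂x/∂u, ∂y/∂u solve the variational ODE
s' = J(x, y)s + ∂f/∂u jointly with the state from zero initial
sensitivity, with hand-written Jacobians per motif; ∂z/∂u is a further
quadrature state.  Central finite differences of two simulations serve
only as a test oracle.

Monotonicity of a response curve is judged pairwise on the dose grid: a
decrease counts only if it exceeds rel_tol (default 1e-6) of the curve's
range plus an optional absolute floor.  The floor matters for fully
adapted, near-flat curves whose range itself sits at integration-noise
level; the genuine IFB decreases are orders of magnitude larger.

## Closed forms for normalized IFFL1

The controller solves exactly to x(t) = u − (u − x0)e^{−t}; variation of
parameters gives y(t), and changing the order of integration yields

    cDR(u, T) = T + ∫₀ᵀ e^{−us}/(1−e^{−s}) · (e^{κ(1−e^{−s})} −
                e^{κ(e^{s−T}−e^{−T})}) ds,    κ = u − x0,

and an analogous integral for d(cDR)/du.  Numerical care:

* The bracketed difference is written as e^{a₂}·expm1(κρ(s)) with
  ρ(s) = (1−e^{−s})(1−e^{s−T}), which makes the removable singularity at
  s = 0 benign (limit κ(1−e^{−T})); when κρ exceeds 1 the code switches
  to the direct difference of exponentials, whose exponents are ≤ 0 and
  cannot overflow.
* The derivative integral is split at T/2, where its integrand changes
  character (the single-sign-change function f_κ crosses there in the
  worst case); adaptive quadrature at abs/rel tolerance 1e-10.
* The boundary function I(s, T) = Ei(κ(1−e^{−s})) − Ei(κ(e^{s−T}−e^{−T}))
  is evaluated by `scipy.special.expi` except when both arguments are
  below 0.1 in magnitude, where the difference of the entire parts of Ei
  is summed as Σ (a₁ⁿ − a₂ⁿ)/(n·n!) and the log difference is supplied
  exactly as T − s.  The degenerate dose u = x0 short-circuits to exact
  answers (y ≡ 1, cDR = T, I = T − s).
* G(u) = ∫₀^∞ (e^{−u w(s)} − e^{−us})/(1−e^{−s}) ds with
  w(s) = s + e^{−s} − 1 also equals Σ_{n≥0} Lₙ(u)/(n+1),
  Lₙ(u) = Π_{j=1..n} u/(u+j).  Since Lₙ(u) = uⁿΓ(u+1)/Γ(u+n+1), the terms
  decay factorially once n > u; plain truncation with a geometric tail
  bound reaches below 1e-12 within a few hundred terms for u ≤ 100.  The
  two representations cross-validate each other in the tests.

## IFB error system and the score

The error system integrates (z, ỹ, β, β', w) jointly: ż = −zỹ,
ỹ' = z − p − ỹ, the β-oscillator β'' + β' + zβ = 0 from β(0) = 1,
β'(0) = 0, and w = ∫ỹ as a quadrature state (which also provides the
exact identity check z = (u/x0)e^{−w}).  Hamiltonians H and H_β are
derived pointwise with ω = √z; the square root is forced by the
oscillator form and the frequency equation ω' = ż/(2ω).

T_u = inf{t : H(t) ≤ 4 and H_β(t) ≤ 1} is found on the solver's dense
output: a pre-scan at step 0.01 locates the first admissible grid point
(the admissible set need not be an interval), then bisection refines the
entry time to 1e-8.  T_u = 0 whenever H(0) = (u − p·x0)²/(u·x0) ≤ 4,
since H_β(0) = 1 always.  The search horizon defaults to
50·max(1, 1/p) normalized time units — T_u is finite because both
Hamiltonians decay to zero, and for x0 = p = 1 the largest scanned doses
give T_u ≈ 28 — and exhausting it raises an error rather than returning
a guess.

S(u) integrates (β − 1)₊ on [0, T_u] by the trapezoid rule at step 0.01,
which resolves the β oscillation period 2π/√u up to u ~ 4·10⁵.  The
onset scan uses the grid 100..400 in steps of 5 (for x0 = p = 1) and
refines the smallest positive-score dose by bisection to ±0.5; scores
below 1e-10 count as zero.  The onset is a numerical observation — no
analytical characterization exists — so agreement is expected at the
≈220 level, not to a digit.

The error analysis is restricted to K = 0: the generic simulator accepts
K > 0 IFB, but the error system, T_u and S are defined for the
normalized K = 0 form only.  (Non-monotonicity found at K = 0 persists
for small K > 0 by parametric continuity of the flow.)

Stability diagnostics for IFB use the energy Lyapunov function
V(x̃, ỹ₂) = ∫_{x̄}^{x̃} f(r)dr + ỹ₂²/2 in the coordinates (ln x, αy − δ)
with the nonlinear spring f(x) = γδ − αβu/(K + eˣ); the f-integral has a
closed form for K = 0 and is quadratured for K > 0.  Along trajectories
dV/dt = −γy² ≤ 0; the check tolerates increases up to 1e-8 for solver
noise.

## Rate estimation from cumulative tables

Cumulative tables are long-format records (dose, time, replicate,
cumulative).  A (t = 0, z = 0) origin is prepended when absent — the
convention that no output has accumulated before stimulation.  Rates are
first differences y(t_i) = (z_i − z_{i−1})/(t_i − t_{i−1}) assigned to
the right endpoint (the measurement time; midpoint assignment is an
option), with y(0) = 0.  Negative estimates are retained and flagged
rather than clipped — in real assays they reflect noise or a baseline —
and an optional per-series baseline subtraction removes the minimum
rate.  First differences followed by re-summation reproduce the input
table exactly; against a noiseless generating simulation the estimates
converge at first order in the sampling step.  Adaptation is summarized
by the per-dose mean rate over the final fraction of time points
(default 25%) and the maximal cross-dose spread of those tail means,
reported both raw and relative to the peak response.

## Synthetic assay generator

The generator emulates the *structure* of a cytokine-secretion time
course: 8 log-spaced doses spanning 0.1–100 (three decades, as dose
panels in such assays typically span several decades), hourly sampling
at t = 1..8, and 3 replicates, matching the replicate count of the
motivating experiments.  The noiseless signal is the simulated z(t) at
the sampling times.  Noise is multiplicative lognormal with
CV 0.1 by default — assay readouts are positive with roughly
dose-proportional error, and 10% is a realistic plate-assay figure —
mean-corrected so the expected measurement equals the noiseless value,
plus an optional additive baseline.  A running-maximum pass keeps each
series non-decreasing (secreted totals cannot shrink); this is a
generator artifact applied after the noise, not part of the noise model.
Tables are exactly reproducible from the integer seed.

What the generator does *not* emulate: the absolute magnitudes and units
(ng/well) of real TNF-α data, detection floors/saturation, missing
wells, or temporally correlated errors.  Tests passing on synthetic
tables therefore establish correctness of the estimation pipeline, not
fidelity of any noise model to a particular instrument.

## Problem sizes and test design

The randomized monotonicity sweeps run 200 parameter draws per IFFL
family with 8-dose log grids at rtol 1e-8 — the decreases the theory
excludes would be orders of magnitude above that tolerance — while
closed-form/ODE comparisons run at rtol 1e-10.  The acceptance script
integrates the IFB toy model to t = 200 (its convergence is oscillatory
and slow at small doses), scans 61 doses for the onset, and checks six
qualifying triples to t = 100.  All quantities it reports are
deterministic; `--seed` exists so stochastic extensions keep a stable
interface.

## Known limitations

* The closed-form IFFL1 functions operate in normalized coordinates
  only; callers normalize first.  Extremely large normalized doses
  (û ≫ 10³) can overflow the Ei-based boundary function I(s, T) for
  mid-range s — the weighted integrals that matter avoid this region.
* No time-varying inputs, no stochastic (chemical-master-equation)
  variants, no motifs beyond the three above, no bifurcation analysis.
* `check_monotone` is a grid verdict; a decrease entirely between grid
  points goes unseen.  Default dose grids are log-spaced with enough
  points that the documented effects are resolved.
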
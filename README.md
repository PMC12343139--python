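# cdrmotifs

Cumulative dose-response analysis for the paradigmatic perfect-adaptation
motifs of systems biology: two incoherent feedforward loops (IFFL1, IFFL2)
and the nonlinear integral-feedback circuit (IFB).

## The problem

Many biological readouts are *cumulative*: a cytokine-secretion assay
measures the total TNF-α accumulated in the medium by hour *t*, a
pharmacokinetic study measures the area under a concentration-time curve,
an HbA1c test integrates blood glucose over weeks.  For a circuit with
constant input (dose) *u* and output *y_u(t)*, the familiar dose response
at horizon *T* is DR(u, T) = y_u(T), while the **cumulative dose
response** is

    cDR(u, T) = ∫₀ᵀ y_u(t) dt.

Experimental cumulative curves from T-cell stimulation are strikingly
*non-monotonic* in the dose.  Which adaptation motifs can produce that?
This package provides the machinery to answer the question numerically
and to exercise the supporting closed-form theory:

* **IFFL1** (degradation enhancement): x' = αu − δx, y' = βu − γxy.
  Its DR can be non-monotonic, but its cDR is *always* increasing in u —
  for every parameter set, initial controller level, and horizon.
* **IFFL2** (production inhibition): x' = αu − δx, y' = βu/(K+x) − γy.
  Both DR and cDR are always increasing in u.
* **IFB** (integral feedback): x' = x(αy − δ), y' = βu/(K+x) − γy.
  The cDR *can* be non-monotonic — the only one of the three motifs
  consistent with the experimental observations.

For the normalized IFB system (set-point p, error ỹ = y − p,
z = u/x), the error obeys a damped oscillator ỹ'' + ỹ' + zỹ = 0 with
Hamiltonian H = ỹ² + (ỹ'/ω)², ω = √z.  If (u − p·x0)² ≤ 4·u·x0 the cDR
is provably monotone; otherwise a **non-monotonicity score**

    S(u) = ∫₀^{T_u} (β(t) − 1)₊ dt,   β(t) = 1 − u ∫₀ᵗ ∂_u ỹ ds,

computed up to the first time T_u at which H ≤ 4 and H_β ≤ 1, certifies
non-monotonicity whenever S(u) > 0.  For x0 = p = 1 the score first turns
positive near u ≈ 220.

## Worked example

```python
import numpy as np
from cdrmotifs import (MotifSpec, response_curve, check_monotone,
                       score_S, scan_scores)

# IFFL1 toy model x' = -x + u, y' = -10xy + u from x(0)=0, y(0)=1/10
spec = MotifSpec("IFFL1", gamma=10.0, x0=0.0, y0=0.1)
grid = np.logspace(-1, 3, 25)
dr = response_curve(spec, grid, horizon=1.5, kind="DR")
cdr = response_curve(spec, grid, horizon=1.5, kind="cDR")
print(check_monotone(dr).is_monotone)    # False  (DR dips then flattens)
print(check_monotone(cdr).is_monotone)   # True   (cDR always increases)

# Normalized IFB, set-point p = 1, x0 = 1, dose above the onset
r = score_S(300.0, p=1.0, x0=1.0)
print(f"Tu={r.Tu:.3f}  S={r.S:.4f}")     # Tu=24.711  S=0.1426

# locate the onset of non-monotonicity
results, onset = scan_scores(np.arange(200.0, 245.0, 5.0), p=1.0, x0=1.0)
print(round(onset, 1))                   # 218.0
```

The DR values for the toy IFFL1 at T = 1.5 fall from 0.1461 (u = 0.1)
through 0.1292 (u ≈ 10) to 0.1287 (u = 1000) — non-monotone — while the
cDR rises from 0.2065 to 0.6496 across the same doses.  The positive
score S(300) = 0.14 certifies that the IFB cumulative response decreases
somewhere in dose for some horizon below T_u ≈ 24.7.

A command-line interface mirrors the library
(`cdrmotifs simulate | curve | fig4 | fig5 | fig8 | fig9 | fig10 | scan |
synth | estimate`); run `cdrmotifs --help`.  The `synth` and `estimate`
commands generate synthetic cumulative assay tables (log-spaced doses,
hourly sampling, lognormal noise) and recover response rates by first
differences, emulating how adaptation is assessed from real secretion
data.

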
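# Methods

## Model class

`pkbound` works with linear compartmental pharmacokinetic models

    dx/dt = A x + b u(t),        y = cᵀ x,

where the state `x` collects instantaneous drug *amounts* (mg) per
compartment, `A` (1/h) is a Metzler matrix (all off-diagonal entries ≥ 0)
with non-positive diagonal, and `y` is the amount in the single compartment
from which samples can be drawn.  Such systems are *positive*: nonnegative
initial amounts and inputs keep every state nonnegative for all time, which
is the structural property all of the bounding machinery rests on.

Two concrete structures are built in:

- **Two-compartment oral absorption** — GIT (`x1`, absorption rate `ka`,
  local elimination `ke1`) feeding the central/blood compartment (`x2`,
  elimination `ke2`); the measured output is `x2`.
- **Three-compartment cascade** — GIT → central (`k23` transfer) → tissue
  (`ke3` elimination); blood samples are typically drawn from the tissue
  compartment, so the observation defaults to `x3`.  Observing `x1` in this
  triangular structure leaves `x2`, `x3` unobservable; the builder still
  allows it because the observation compartment is an explicit argument.

The oral bolus dose `M0` (default 50 mg) is encoded as `x1(0) = M0`; the
`b` vector is retained in the data model for future infusion inputs but is
unused by the bolus workflows.  All times are hours, amounts mg,
concentrations mg/mL, and unit tags on sample series are mandatory.

## Interval models and guaranteed envelopes

Parametric uncertainty is expressed as a fraction `Δ ∈ [0, 1)`: every
nonzero entry `q` of `A` (and of `c`, and optionally of `x0` via a separate
`x0_delta`) is relaxed to the interval `[q − Δ|q|, q + Δ|q|]`; structural
zeros stay zero.  The lumped diagonal `−(ka + ke1)` is perturbed as a single
quantity, not per rate constant (per-entry overrides are available for the
finer-grained case).  The entrywise maximum `A_hi` (diagonals shrunk in
magnitude, off-diagonals grown) and minimum `A_lo` are then both Metzler for
`Δ < 1`, and the elementwise order `A_lo ≤ A ≤ A_hi` holds for every
admissible system.

For Metzler matrices, elementwise matrix ordering implies trajectory
ordering from ordered initial states (the Kamke–Müller comparison
principle).  Simulating the pair `(A_lo, x0_lo)` and `(A_hi, x0_hi)`
therefore yields curves `x_L(t) ≤ x(t) ≤ x_U(t)` bounding every in-interval
system — the *guaranteed envelope*.  This is verified empirically by a
seeded Monte-Carlo draw of random in-interval systems (uniform per nonzero
entry), each of which must stay inside the envelope at every grid point.

## Numerical integration

Trajectories are propagated on a uniform grid by per-step matrix
exponentials (`expm(A·h)`), which is exact for LTI dynamics up to
round-off; the default grid is 0.01 h steps over 12 h, covering the 0–6 h
sampling window with ample margin.  An independent analytic oracle,
`closed_form_cascade`, evaluates the sum-of-exponentials solution of
lower-triangular systems with pairwise distinct diagonal rates by forward
substitution of modal coefficients; the two paths are required to agree to
1e−8 relative.  The confluent (repeated-rate) case is deliberately not
implemented in the oracle and raises, directing users to the numeric path.

Peak statistics (`cmax`, `tmax`) are refined by a quadratic fit through the
three grid points around the discrete maximum, so circa-level peak values
do not require a pathologically fine grid.  Settling time uses a 2 %-of-own-
peak band (a declared convention — the underlying study states none), with
linear interpolation of the band crossing.  AUC is the trapezoid rule.

## State-bounding observers

Given interval bounds and a measured output `y(t) ≥ 0`, the twin observers

    dx_U/dt = (A_hi − L c_loᵀ) x_U + L y
    dx_L/dt = (A_lo − L c_hiᵀ) x_L + L y

bracket the true state of any in-interval system from bracketing initial
bounds, provided `L ≥ 0` and both observer matrices are Metzler (the error
dynamics `e = x_U − x` then have Metzler drift plus nonnegative forcing, so
`e ≥ 0` is forward-invariant) and Hurwitz (bounds stay bounded).  Both
properties are checked explicitly and shipped as certificates on the
`ObserverGain`; `run_observers` refuses uncertified gains, since the
guarantee would be void.

Gain synthesis offers two strategies:

- `zero` — `L = 0`, always certified for the cascade structures (their
  bound matrices are triangular with negative diagonals).  The observers
  then collapse to open-loop envelope prediction; this is the default
  because it introduces no design freedom beyond the interval bounds
  themselves.
- `max_feedback` — a linear program maximizing `ΣL` subject to `L ≥ 0`, the
  (linear) Metzler constraints on both observer matrices, and a row-sum
  stability margin `M·1 ≤ −ε` (ε = 1e−6).  The row-sum bound is a linear
  surrogate for the Hurwitz condition (valid for Metzler matrices by
  Gershgorin-type dominance); when it is infeasible the LP is re-solved on
  the Metzler constraints alone and stability is verified a posteriori on
  the eigenvalues.  Because along the observed column larger `L` only
  strengthens both conditions, the objective is unbounded without a box
  constraint; `l_max` (default 10 per hour per unit output) closes the box
  and is an explicit, documented parameter.  In the triangular structures
  the Metzler constraints force `L_i = 0` for every compartment `i` whose
  row has a structural zero in the observed column, so feedback effectively
  enters only the measured compartment.

Measured signals are piecewise-linear (or zero-order-hold) interpolations
of the sample series, clamped at zero, holding the last value beyond the
final sample.  The driven observers are discretized exactly for
piecewise-linear inputs via a Van Loan augmented matrix exponential, so
integration error reduces to the interpolation error of `y` between grid
points — O(h²), and zero when the signal really is piecewise linear on the
grid.  For verification, `run_observers_with_model` wires the observers to
a simulated plant's output and propagates plant + observers as one coupled
LTI system, which is exact to round-off; the Monte-Carlo containment check
(100 random in-interval plants, tolerance 1e−6) uses this path.  The
sampled-signal containment test instead samples the plant densely
(0.01 h) and uses a 1e−4 tolerance reflecting the reconstruction error
carried through the gain.

## Rate-constant identification

`fit_rates` minimizes the unweighted sum of squared residuals on amounts
(the workflow converts concentrations first; a log-residual flag offers
relative weighting) over nonnegative rate constants, using multi-start
bounded Levenberg–Marquardt/TRF (`scipy.optimize.least_squares`) from 32
log-uniform starting points in [1e−3, 10] 1/h, seeded for bitwise
reproducibility.  The small sample counts make the problem poorly
conditioned, so a single local fit is indefensible; per-start traces and a
dispersion diagnostic are part of the result.

**Observational equivalence.** Observing a triangular cascade from its
terminal compartment determines the *set* of exponential rates
{`ka+ke1`, `k23`, `ke3`} and the amplitude prefactor `ka·k23`, but not the
assignment of rates to roles: several parameter vectors reproduce the
output exactly (the two-compartment oral model has the classic "flip-flop"
twin `ke2 ↔ ka+ke1`).  `fit_rates` therefore clusters all objective-tied
optima, reports every distinct mode in `equivalent_modes`, and returns a
canonical representative — the lexicographically smallest parameter tuple
in declared order (absorption rate first).  Users with prior knowledge of
which rate is which should select among the reported modes themselves.

On noiseless self-generated data the canonical representative recovers the
generating three-compartment no-tenside parameters to well under 1 % with
SSE below 1e−12.  Under multiplicative noise the median parameter error
grows quickly with the noise level (mode-hopping between equivalent
branches contributes), which is the quantitative face of the
ill-conditioning noted above.

The blood volume used to convert concentrations to amounts defaults to
12.78 mL, the constant amount/concentration ratio of the shipped reference
samples; body-weight-based computation is out of scope and the value is a
plain configuration parameter.  One shipped concentration/amount pair
(t = 4 h) does not share that ratio (12.95 mL); both printed values are
shipped verbatim and the discrepancy is flagged in the fixture manifest.

## Synthetic data

`sample_model` emulates the in vivo design: the observed output sampled at
a handful of times (default experiments use t = 0…6 h), corrupted by
multiplicative lognormal noise with unit mean and a chosen coefficient of
variation (default 0.1 — assay errors in PK scale with the signal, and
positivity needs no truncation).  An additive truncated-Gaussian
alternative is provided.  Exact zeros (the pre-dose sample) stay zero under
both models.  `sample_interval_system` draws the "true animal" for
containment experiments uniformly per nonzero entry within the interval
bounds.  What the generator does *not* emulate: assay quantification
limits/censoring, inter-animal variability, and time-varying kinetics —
tests passing on synthetic data say nothing about those effects.

## Therapeutic-range assessment

Given an envelope and a range `[lo, hi]` for one compartment, the guard
`g(t) = min(x_lo(t) − lo, hi − x_hi(t))` is evaluated on the grid and its
zero crossings located by linear interpolation; `g ≥ 0` defines the
*guaranteed-in-range* time set (effectiveness certified by the lower bound,
safety by the upper).  Complementary intervals are annotated with which
bound breaches.  With `Δ = 0` this degenerates to range-checking the
nominal trajectory; widening the range can only grow the guaranteed set.

## Numerical conventions and edge cases

- Sign/Metzler checks use a 1e−12 tolerance (1e−9 for certified observer
  matrices, which pass through an LP solver).
- Validation is reporting-style (`validate` returns a list of violations);
  constructors of invalid objects do not throw, so diagnostics can be
  inspected, but every simulation/synthesis entry point rejects invalid
  inputs.
- Agreement with values printed to four decimals is asserted with an
  absolute tolerance of 5.05e−5, which admits exact half-way roundings
  present in the reference matrices (e.g. 1.2725 × 1.1 = 1.39975).
- A printed lower-bound matrix entry with an obviously shifted decimal
  point is shipped corrected, with the original noted in the manifest: only
  the corrected value is consistent with the ±10 % rule and with the
  published envelope peak range.
- Degenerate inputs: zero dose gives identically zero trajectories and
  all-zero PK metrics; an all-zero sample series yields a fit flagged
  `degenerate` with the absorption rate at the zero boundary.

## Problem sizes

Default experiments use a 1201-point grid (12 h at 0.01 h), 100–200
Monte-Carlo draws for containment checks, 32 fit starts for headline
identification runs and 6–16 starts in repeated-fit studies.  These sizes
were chosen so every documented property is exercised at full fidelity
while a complete run of the test suite stays comfortably interactive.
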
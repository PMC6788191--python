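# Methods

## Model

Two infinite populations — schools, and student/guardian households —
repeatedly face the possibility of a sports-injury accident.  Each
population mixes two pure strategies, *appropriate caution* (invest in
prevention: cost `cc` for a school, `cs` for a household) and *no
caution*.  Accidents are deterministic in the stylized sense of the model:
mutual caution prevents the accident entirely; any carelessness produces
an accident of total loss `p` (personal injury, property damage and
enforcement costs aggregated into one monetary figure).  A court then
allocates the burden:

* proportional rule — the school bears the share `a ∈ [0, 1]` of the loss
  when neither side was cautious, and the share `b ∈ [0, 1]` of the
  students' prevention cost when only the students were cautious;
* strict rule — full school liability.  This is representable either as
  the `a = b = 1` corner of the proportional family or as a literal
  override table in which the school additionally bears the loss even when
  only the students were careless and the students never pay anything
  beyond their own prevention cost.  The two encodings differ in exactly
  one cell — (careless students, cautious school): `(−p, −cc)` parametric
  versus `(0, −cc−p)` override — and both are exposed because legal
  narratives of strict liability genuinely support either reading.
  Neither is asserted as the correct one; `GameParams.strict()` selects
  the override.

All payoffs are non-positive (costs).  The model narrative assumes
`cs < cc`; two of the preset study cases violate it deliberately, so the
constructor warns instead of rejecting.

## Dynamics and stability

Strategy frequencies follow two-population replicator dynamics: each
strategy's frequency grows at a rate proportional to its payoff advantage
over its population's average.  For the parametric payoff table this has
the closed form given in the README; a generic-bimatrix replicator flow
computed directly from the payoff cells is kept alongside as an
independent oracle and is also what `strict_override` trajectories
integrate, since the closed forms encode the parametric table only.

Rest points are the four corners and, when it lies strictly inside the
square, the interior point `(α*, β*)`.  Stability is decided by the
determinant/trace criterion at the linearization: ESS iff `Det > 0` and
`Tr < 0`; saddle iff `Det < 0`; unstable iff both positive; within a
tolerance of zero (1e−12 × max(cc, cs, p)) the point is reported
*non-hyperbolic* rather than guessed.  The Jacobian's off-diagonal entry
`∂(dβ/dt)/∂α` is implemented as the true derivative `β(1−β)(a·p − b·cs)`;
a structurally similar but incorrect form — repeating the α-independent
bracket `β(1−β)((1−a)p − (1−b)cs)` — circulates in write-ups of this
system and is *not* used: corner results are unaffected (off-diagonals
vanish there) but interior classification requires the true derivative.

Two structural facts shape the reporting:

* the interior point, when valid, has zero trace (both diagonal brackets
  vanish at it), so it is a saddle (`Det < 0`) or a linear center
  (`Det > 0`); it is never an ESS.  Interior validity occurs in exactly
  two sign regimes of `(π1..π4)`: the bistable pattern
  `(−, +, +, −)` (interior saddle, both `(0,0)` and `(1,1)` stable) and
  the cycling pattern `(−, +, −, +)` (center, no stable corner);
* the corner ESS conditions are *not* mutually exclusive — the bistable
  pattern has two stable corners, and which one the population reaches
  depends on the initial state.  Stability reports always list every
  stable corner next to the single tabulated prediction.

The ten-scenario sign classification follows the published numbering;
scenarios 1–8 are full sign patterns, 9 and 10 partial conditions matched
afterwards.  Two strict-sign patterns reachable from valid parameters —
`(+,+,+,+)` and `(+,+,−,−)` — fit no listed scenario and are labelled
`"unlisted"`; their corners are still classified correctly by the Det/Tr
rule.  Patterns with `π1 > 0 > π2` are rejected as infeasible
(`π2 − π1 = (1−a)p + b·cs ≥ 0` for every valid parameter set).  Any zero
component yields the label `"boundary"`.

## Numerical integration

Trajectories are integrated with scipy's LSODA at `rtol = 1e−10`,
`atol = 1e−12`, default horizon `t_max = 500` (time units are arbitrary —
scaling all monetary parameters by `k` just rescales the clock by `1/k`).
LSODA rather than a pure explicit Runge–Kutta scheme because the system,
though polynomial and smooth, becomes numerically stiff once the faster
strategy has settled on an edge while the slower one still drifts: the
settled direction contributes a decay rate of the order of the monetary
scale, which for the large-loss study case (p = 1000) stability-limits
explicit steps to ~10⁻³ time units.  LSODA switches to a stiff method in
that regime at no accuracy cost.

The tolerance choice is driven by forward invariance: the exact field is
tangent to the unit square's boundary, so any excursion outside is purely
numerical, of the order of the solver's error floor `rtol · |state|`.  At
`rtol = 1e−10` the worst measured excursion across all study-case sweeps
is ~2e−10; states are clipped to the square after integration and the
pre-clip maximum is reported on every trajectory.

A trajectory's verdict is `corner (i,j)` when its final state lies within
`corner_tol = 1e−3` of a corner *and* the flow norm there is below
`flow_tol = 1e−8`; `interior` when it ends within `corner_tol` of a valid
interior equilibrium; `cycling/undecided` otherwise.  Because the solver's
error floor can leave a converged state a residual `~rtol` offset from the
corner — keeping the flow norm just above threshold although the exact
solution settled long ago — a short restarted pass at `rtol = 1e−12`,
`atol = 1e−14` over `0.2 · t_max` is appended whenever a trajectory ends
near a corner with an unsettled flow norm; restarting resets the
accumulated error and the offset decays to rounding level.  All
thresholds are configurable.

Degenerate parameter sets (some `πi = 0`, e.g. `cs = p`) create continua
of rest points on edges; trajectories then stall at edge points that are
neither corners nor the interior equilibrium and are honestly reported
`cycling/undecided`, never force-assigned a corner.

## Study cases and sweeps

Five preset cases fix the cost triple `(p, cc, cs)` and sweep the shares
`(a, b)` over printed ranges (unit square, except case 5's `a ∈ [0.5, 1]`;
case 5 states no `b` range and the full unit interval is used), all from
the common initial state `(0.5, 0.5)`.  Default grid 21×21; the test
suite and the sweep examples use 11×11 for speed — results are
grid-resolution-insensitive because each cell is an independent ODE run.
Strict-rule summaries run both strict encodings; the proportional summary
is the modal verdict over interior cells `0.1 ≤ a, b ≤ 0.9` (a sweep
yields a distribution of outcomes, and a single representative convention
has to be explicit).  Every cell's verdict and sign-scenario label are
retained, and cells whose simulated verdict contradicts the case's claimed
outcome are recorded individually, never averaged away.  Known
discrepancies the package reports rather than resolves:

* case 3 (p=12, cc=8, cs=4), proportional rule: `π2 = 4 + 4b > 0` and
  `π3 = 8 > 0` for *all* shares, so mutual caution `(1,1)` is the stable
  corner everywhere, not the claimed (no caution, caution);
* case 4 (p=12, cc=16, cs=4), strict reading: near `a = 1, b = 0`,
  `π4 < 0` hands the basin to `(0,0)`, so the claimed (no caution,
  caution) holds only on part of the share range;
* case 5 (p=1000, cc=400, cs=1000): `cs = p` makes `π3 = 0` — every cell
  is a sign boundary, the `α = 1` edge is a rest continuum, and no
  outcome is asserted.  The case description carries an undefined
  constant λ = 1/100 which is kept as metadata and ignored in computation;
* cases whose strict cells stall on a rest edge (case 1 at `a = b = 1`
  has `π4 = 0`) likewise yield `cycling/undecided` instead of the claimed
  corner and appear as recorded disagreements.

Phase portraits sample the flow on a lattice; basin rectangles delimited
by `(α*, β*)` — upper-left → `(0,1)`, upper-right → `(1,1)`, lower-left →
`(0,0)`, lower-right → `(1,0)` — are assigned only in the interior-saddle
regime.  In the center regime the portrait is field-only, flagged
"cycling expected", but still reports the interior point.

## Determinism and I/O

The pipeline is deterministic: no randomness enters any computation except
user-requested sampled starts (seeded, logged).  Floats are serialized at
12 significant digits — below integrator tolerance, above representation
noise — so repeated runs are byte-identical.  Configs are YAML or JSON
with strict schema validation (unknown keys rejected, domains checked,
offending key named) and the fully resolved config is echoed into every
output.  CLI exit codes: 0 success, 2 validation error, 3 numerical
failure.

## What the tests do and do not show

The test suite verifies the algebraic skeleton exactly (closed forms vs
independent symbolic and brute-force oracles), the stability
classification against its sign conditions both symbolically and on
random draws, and the qualitative convergence claims on the preset cases.
The model itself remains a stylized instrument: accidents are certain
under any carelessness, losses are scalar and known, both populations are
homogeneous imitators, and no third parties (co-students, contractors,
insurers) exist.  Passing tests validate the mathematics and its
implementation, not the calibration of any parameter to real litigation
data — monetary units are arbitrary throughout.

The scenario-parameter search used by the convergence suite scans a fixed
coarse grid over `(p, cc, cs, a, b)` and returns the first match of each
sign pattern, so the suite's parameter sets are reproducible constants of
the grid, not tuned values.  Problem sizes (1000 random draws per oracle
comparison, 3×3 start grids, 11×11 sweep grids) keep the full suite under
half a minute on one CPU while exercising every code path; enlarging them
changes nothing qualitatively.
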
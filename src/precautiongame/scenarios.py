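"""Parameter-sweep reproduction of the five study cases and phase portraits.

Each case fixes the cost triple (p, cc, cs), sweeps the liability shares
(a, b) over printed ranges, integrates every cell from the common initial
state (0.5, 0.5) and compares the simulated convergence verdicts against
the case's claimed outcome per liability rule:

===== ==================== ======================= ========================
case  (p, cc, cs)          strict-rule claim       proportional-rule claim
===== ==================== ======================= ========================
1     (5, 10, 6)           (no caution, no caution) same
2     (12, 8, 10)          (caution, caution)       same
3     (12, 8, 4)           (caution, caution)       (no caution, caution)
4     (12, 16, 4)          (no caution, caution)    same
5     (1000, 400, 1000)    (caution, no caution)    same
===== ==================== ======================= ========================

Outcome pairs are ordered (school, students); "caution" abbreviates
"appropriate caution".  The "strict" interpretation is run both as the
a = b = 1 parametric corner and as the literal strict-override table; the
"proportional" interpretation is summarized by the modal verdict over the
interior share cells 0.1 <= a, b <= 0.9.  Disagreements between simulation
and claim are recorded per cell and never suppressed: case 3's
proportional claim contradicts the sign analysis (pi2 = 4 + 4b > 0 and
pi3 = 8 > 0 for all shares, making (1,1) the stable corner), case 4's
strict claim fails near a = 1, b = 0 where pi4 < 0, and case 5 has
cs = p (pi3 = 0), a non-hyperbolic boundary case for which no outcome is
asserted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dynamics import _corner_verdict, flow, integrate, interior_equilibrium
from .errors import DegenerateEquilibriumError, NumericalError
from .model import GameParams, LiabilityRule, classify_scenario, net_gains
from .stability import classify_equilibria

__all__ = [
    "CaseSpec",
    "CASES",
    "SweepResult",
    "PhasePortrait",
    "run_case",
    "phase_portrait",
    "corner_outcome_label",
]

logger = logging.getLogger(__name__)

_STRATEGY_NAME = {0: "no caution", 1: "appropriate caution"}


def corner_outcome_label(corner: tuple[float, float]) -> str:
    """Human-readable (school, students) outcome for a corner."""
    return f"(school: {_STRATEGY_NAME[int(corner[0])]}, students: {_STRATEGY_NAME[int(corner[1])]})"


@dataclass(frozen=True)
class CaseSpec:
    """One study case: fixed costs, share sweep ranges and claimed outcomes.

    ``expected`` maps rule interpretation ("strict" / "proportional") to
    the claimed attractor corner, or None when the claim is not asserted
    (degenerate case 5).  ``metadata`` carries printed-but-unused values.
    """

    case_id: int
    p: float
    cc: float
    cs: float
    a_range: tuple[float, float] = (0.0, 1.0)
    b_range: tuple[float, float] = (0.0, 1.0)
    initial: tuple[float, float] = (0.5, 0.5)
    expected: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def params(self, a: float, b: float, rule: LiabilityRule = LiabilityRule.PARAMETRIC) -> GameParams:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GameParams(cc=self.cc, cs=self.cs, p=self.p, a=a, b=b, rule=rule)


#: The five study cases.  Case 5's "lambda" is printed in the source
#: scenario description without a definition; it is carried as metadata and
#: ignored in computation.  Case 5 gives no b range; the full unit interval
#: is used.
CASES: dict[int, CaseSpec] = {
    1: CaseSpec(case_id=1, p=5.0, cc=10.0, cs=6.0,
                expected={"strict": (0.0, 0.0), "proportional": (0.0, 0.0)},
                metadata={"description": "both prevention costs high"}),
    2: CaseSpec(case_id=2, p=12.0, cc=8.0, cs=10.0,
                expected={"strict": (1.0, 1.0), "proportional": (1.0, 1.0)},
                metadata={"description": "school bears a high share of student prevention cost"}),
    3: CaseSpec(case_id=3, p=12.0, cc=8.0, cs=4.0,
                expected={"strict": (1.0, 1.0), "proportional": (0.0, 1.0)},
                metadata={"description": "high accident loss"}),
    4: CaseSpec(case_id=4, p=12.0, cc=16.0, cs=4.0,
                expected={"strict": (0.0, 1.0), "proportional": (0.0, 1.0)},
                metadata={"description": "low student prevention cost, high school cost"}),
    5: CaseSpec(case_id=5, p=1000.0, cc=400.0, cs=1000.0, a_range=(0.5, 1.0),
                expected={"strict": None, "proportional": None},
                metadata={"description": "low school prevention cost, cs = p (non-hyperbolic)",
                          "lambda": 0.01,
                          "claimed_outcome_not_asserted": [1.0, 0.0]}),
}


@dataclass(frozen=True)
class SweepResult:
    """Verdicts of a (a, b) sweep with per-rule summaries and disagreements.

    ``verdicts[i, j]`` (as nested lists) is the convergence verdict for
    ``a_values[i], b_values[j]``; ``scenarios`` the matching gain-sign
    scenario labels.  ``disagreements`` lists every interior proportional
    cell whose verdict differs from the claimed corner, plus summary-level
    entries for the strict interpretations; nothing is averaged away.
    """

    case_id: int
    a_values: np.ndarray
    b_values: np.ndarray
    verdicts: list
    scenarios: list
    strict_parametric_verdict: str
    strict_override_verdict: str
    proportional_modal_verdict: str
    expected: dict
    disagreements: list
    max_boundary_violation: float
    metadata: dict

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "a_values": [float(a) for a in self.a_values],
            "b_values": [float(b) for b in self.b_values],
            "verdicts": self.verdicts,
            "scenarios": self.scenarios,
            "strict_parametric_verdict": self.strict_parametric_verdict,
            "strict_override_verdict": self.strict_override_verdict,
            "proportional_modal_verdict": self.proportional_modal_verdict,
            "expected": {
                rule: (list(corner) if corner is not None else None)
                for rule, corner in self.expected.items()
            },
            "disagreements": self.disagreements,
            "max_boundary_violation": self.max_boundary_violation,
            "metadata": self.metadata,
        }


def run_case(
    spec: CaseSpec,
    grid_resolution: int = 21,
    t_max: float = 500.0,
    **integrate_kwargs,
) -> SweepResult:
    """Integrate every (a, b) grid cell of a case from its initial state.

    Any cell whose integration fails numerically is recorded with the
    verdict ``"error: ..."`` and logged; the sweep continues.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be at least 2")
    a_values = np.linspace(spec.a_range[0], spec.a_range[1], grid_resolution)
    b_values = np.linspace(spec.b_range[0], spec.b_range[1], grid_resolution)
    verdicts: list[list[str]] = []
    scenarios: list[list] = []
    max_violation = 0.0
    for a in a_values:
        row_v, row_s = [], []
        for b in b_values:
            params = spec.params(a, b)
            row_s.append(classify_scenario(net_gains(params), zero_tol=1e-12 * params.scale))
            try:
                traj = integrate(params, spec.initial, t_max=t_max, **integrate_kwargs)
            except NumericalError as exc:
                logger.warning("case %d cell (a=%.3g, b=%.3g) aborted: %s", spec.case_id, a, b, exc)
                row_v.append(f"error: {exc}")
                continue
            max_violation = max(max_violation, traj.max_boundary_violation)
            row_v.append(traj.verdict)
        verdicts.append(row_v)
        scenarios.append(row_s)

    strict_param = integrate(spec.params(1.0, 1.0), spec.initial, t_max=t_max, **integrate_kwargs)
    strict_override = integrate(
        spec.params(1.0, 1.0, rule=LiabilityRule.STRICT_OVERRIDE),
        spec.initial, t_max=t_max, **integrate_kwargs,
    )
    max_violation = max(max_violation, strict_param.max_boundary_violation,
                        strict_override.max_boundary_violation)

    interior_mask = [
        (i, j)
        for i, a in enumerate(a_values)
        for j, b in enumerate(b_values)
        if 0.1 <= a <= 0.9 and 0.1 <= b <= 0.9
    ]
    interior_verdicts = [verdicts[i][j] for i, j in interior_mask]
    modal = Counter(interior_verdicts).most_common(1)[0][0] if interior_verdicts else "n/a"

    disagreements: list[dict] = []
    expected_prop = spec.expected.get("proportional")
    if expected_prop is not None:
        expected_verdict = _corner_verdict(expected_prop)
        for i, j in interior_mask:
            if verdicts[i][j] != expected_verdict:
                disagreements.append({
                    "rule": "proportional",
                    "a": float(a_values[i]), "b": float(b_values[j]),
                    "expected": expected_verdict, "observed": verdicts[i][j],
                })
    expected_strict = spec.expected.get("strict")
    if expected_strict is not None:
        expected_verdict = _corner_verdict(expected_strict)
        for label, verdict in (("strict (parametric a=b=1)", strict_param.verdict),
                               ("strict (override table)", strict_override.verdict)):
            if verdict != expected_verdict:
                disagreements.append({
                    "rule": label, "a": 1.0, "b": 1.0,
                    "expected": expected_verdict, "observed": verdict,
                })

    return SweepResult(
        case_id=spec.case_id,
        a_values=a_values,
        b_values=b_values,
        verdicts=verdicts,
        scenarios=scenarios,
        strict_parametric_verdict=strict_param.verdict,
        strict_override_verdict=strict_override.verdict,
        proportional_modal_verdict=modal,
        expected=dict(spec.expected),
        disagreements=disagreements,
        max_boundary_violation=max_violation,
        metadata=dict(spec.metadata),
    )


#: Rectangle regions delimited by the interior point and their predicted
#: attractor corner: trajectories starting above-left of (alpha*, beta*)
#: drift to (0,1), above-right to (1,1), below-left to (0,0), below-right
#: to (1,0).
REGION_ATTRACTORS = {
    "I": (0.0, 1.0),    # alpha < alpha*, beta > beta*
    "II": (1.0, 1.0),   # alpha > alpha*, beta > beta*
    "III": (0.0, 0.0),  # alpha < alpha*, beta < beta*
    "IV": (1.0, 0.0),   # alpha > alpha*, beta < beta*
}


@dataclass(frozen=True)
class PhasePortrait:
    """Sampled flow field, with rectangle-region basin predictions when defined.

    ``regions`` is None in field-only mode (degenerate interior point, or
    no stable corner — the cycling pattern); the reason is in ``flag``.
    """

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    dalpha: np.ndarray
    dbeta: np.ndarray
    interior: "tuple[float, float] | None"
    regions: "dict | None"
    flag: str = ""


def phase_portrait(params: GameParams, resolution: int = 21) -> PhasePortrait:
    """Sample the replicator field on a lattice and assign basin regions.

    Region assignment requires a valid interior equilibrium and at least
    one ESS corner; otherwise the portrait is field-only with an
    explanatory flag (e.g. "cycling expected" for the center pattern).
    """
    alpha_grid = np.linspace(0.0, 1.0, resolution)
    beta_grid = np.linspace(0.0, 1.0, resolution)
    dalpha = np.empty((resolution, resolution))
    dbeta = np.empty((resolution, resolution))
    for i, alpha in enumerate(alpha_grid):
        for j, beta in enumerate(beta_grid):
            dalpha[i, j], dbeta[i, j] = flow(params, (alpha, beta))

    try:
        eq = interior_equilibrium(params)
    except DegenerateEquilibriumError as exc:
        return PhasePortrait(alpha_grid, beta_grid, dalpha, dbeta, None, None,
                             flag=f"field-only: {exc}")
    if not eq.valid:
        return PhasePortrait(alpha_grid, beta_grid, dalpha, dbeta, None, None,
                             flag="field-only: interior equilibrium outside the open unit square")
    report = classify_equilibria(params)
    if not report.ess:
        flag = "field-only: no stable corner"
        if report.scenario == 10:
            flag += "; cycling expected"
        return PhasePortrait(alpha_grid, beta_grid, dalpha, dbeta, eq.as_tuple(), None, flag=flag)
    regions = {
        name: {"attractor": list(corner)} for name, corner in REGION_ATTRACTORS.items()
    }
    regions["boundaries"] = {"alpha_star": eq.alpha, "beta_star": eq.beta}
    return PhasePortrait(alpha_grid, beta_grid, dalpha, dbeta, eq.as_tuple(), regions)
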
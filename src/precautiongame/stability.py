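"""Linearized stability of the replicator rest points and the ten-scenario table.

A rest point is an evolutionarily stable strategy (ESS) of the replicator
system when the Jacobian there has Det > 0 and Tr < 0 (Friedman's
criterion); Det < 0 marks a saddle, Det > 0 with Tr > 0 an unstable node,
and Det = 0 or Tr = 0 (with Det > 0) a non-hyperbolic point where the
linearization is inconclusive.

In terms of the corner net gains pi1..pi4 the corner classifications are

    (0,0) ESS  <=>  pi1 < 0 and pi4 < 0
    (1,1) ESS  <=>  pi2 > 0 and pi3 > 0
    (0,1) ESS  <=>  pi2 < 0 and pi4 > 0
    (1,0) ESS  <=>  pi1 > 0 and pi3 < 0

Note these conditions are not mutually exclusive: the sign pattern
pi1 < 0, pi2 > 0, pi3 > 0, pi4 < 0 (scenario 3) makes *both* (0,0) and
(1,1) stable, so the system is bistable with basins split by the stable
manifold of an interior or boundary saddle.

The off-diagonal Jacobian entry dG/dalpha is implemented as the true
partial derivative beta (1-beta)(a p - b cs).  (A form sometimes quoted
for this entry, beta (1-beta)((1-a)p - (1-b)cs), is not the alpha
derivative of the student flow; corner results are unaffected because the
off-diagonals vanish at corners, but interior classification requires the
true derivative.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CORNERS, InteriorEquilibrium, _alpha_beta, interior_equilibrium
from .errors import DegenerateEquilibriumError
from .model import GameParams, NetGains, TABLE_ESS_CORNER, classify_scenario, net_gains

__all__ = [
    "ESS",
    "UNSTABLE",
    "SADDLE",
    "NON_HYPERBOLIC",
    "EquilibriumReport",
    "StabilityReport",
    "jacobian",
    "corner_det_trace",
    "classify_point",
    "classify_equilibria",
    "ess_corners",
    "find_scenario_params",
]

ESS = "ESS"
UNSTABLE = "unstable"
SADDLE = "saddle"
NON_HYPERBOLIC = "non-hyperbolic"


def jacobian(params: GameParams, state) -> np.ndarray:
    """Jacobian of (school_flow, student_flow) at a state.

    J11 = (1-2 alpha)[beta ((1-a)p + b cs) + (a p - cc)]
    J12 = alpha (1-alpha)((1-a)p + b cs)
    J21 = beta (1-beta)(a p - b cs)
    J22 = (1-2 beta)[((1-a)p - (1-b)cs) - (b cs - a p) alpha]
    """
    alpha, beta = _alpha_beta(state)
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    j11 = (1 - 2 * alpha) * (beta * ((1 - a) * p + b * cs) + (a * p - cc))
    j12 = alpha * (1 - alpha) * ((1 - a) * p + b * cs)
    j21 = beta * (1 - beta) * (a * p - b * cs)
    j22 = (1 - 2 * beta) * (((1 - a) * p - (1 - b) * cs) - (b * cs - a * p) * alpha)
    return np.array([[j11, j12], [j21, j22]])


def corner_det_trace(params: GameParams) -> dict[tuple[float, float], tuple[float, float]]:
    """Closed-form (Det, Tr) of the Jacobian at the four corners.

    The off-diagonals vanish at every corner, so Det and Tr are the product
    and sum of the diagonal, giving (with pi1..pi4 the corner net gains)::

        (0,0): ( (ap-cc)((1-a)p-(1-b)cs),      p - cc - (1-b)cs )
        (0,1): ( -(p+bcs-cc)((1-a)p-(1-b)cs),  ap + cs - cc )
        (1,0): ( -(ap-cc)(p-cs),               (1-a)p + cc - cs )
        (1,1): ( (p+bcs-cc)(p-cs),             -2p + (1-b)cs + cc )
    """
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    g = net_gains(params)
    return {
        (0.0, 0.0): (g.pi1 * g.pi4, p - cc - (1 - b) * cs),
        (0.0, 1.0): (-g.pi2 * g.pi4, a * p + cs - cc),
        (1.0, 0.0): (-g.pi1 * g.pi3, (1 - a) * p + cc - cs),
        (1.0, 1.0): (g.pi2 * g.pi3, -2 * p + (1 - b) * cs + cc),
    }


def classify_point(det: float, tr: float, zero_tol: float) -> str:
    """Friedman Det/Tr classification with an explicit non-hyperbolic band.

    Values of Det (or, when Det > 0, of Tr) within ``zero_tol`` of zero are
    treated as zero and reported non-hyperbolic rather than guessed.
    """
    if abs(det) <= zero_tol:
        return NON_HYPERBOLIC
    if det < 0:
        return SADDLE
    if abs(tr) <= zero_tol:
        return NON_HYPERBOLIC
    return ESS if tr < 0 else UNSTABLE


@dataclass(frozen=True)
class EquilibriumReport:
    """Det/Tr classification of a single rest point."""

    coords: tuple[float, float]
    det: float
    tr: float
    classification: str
    kind: str  # "corner" or "interior"

    def as_dict(self) -> dict:
        return {
            "coords": list(self.coords),
            "det": self.det,
            "tr": self.tr,
            "classification": self.classification,
            "kind": self.kind,
        }


@dataclass(frozen=True)
class StabilityReport:
    """Full stability account: gains, scenario label and per-point verdicts.

    ``predicted_ess`` is the single corner the ten-scenario table
    associates with the scenario (None for scenario 10 and for boundary /
    unlisted patterns); ``ess`` lists every corner that actually satisfies
    Det > 0, Tr < 0 — the two differ exactly in the bistable scenario-3
    pattern, where (1,1) is stable alongside the tabulated (0,0).
    """

    params: GameParams
    gains: NetGains
    scenario: "int | str"
    equilibria: tuple[EquilibriumReport, ...]
    predicted_ess: "tuple[float, float] | None"
    interior: "InteriorEquilibrium | None"
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ess(self) -> list[tuple[float, float]]:
        """Corners classified as ESS by the Det/Tr rule."""
        return [e.coords for e in self.equilibria if e.kind == "corner" and e.classification == ESS]

    def as_dict(self) -> dict:
        return {
            "params": {
                "cc": self.params.cc, "cs": self.params.cs, "p": self.params.p,
                "a": self.params.a, "b": self.params.b, "rule": self.params.rule.value,
            },
            "gains": {f"pi{i}": v for i, v in enumerate(self.gains.as_tuple(), start=1)},
            "scenario": self.scenario,
            "predicted_ess": list(self.predicted_ess) if self.predicted_ess else None,
            "ess_corners": [list(c) for c in self.ess],
            "equilibria": [e.as_dict() for e in self.equilibria],
            "notes": list(self.notes),
        }


def classify_equilibria(params: GameParams, zero_tol: "float | None" = None) -> StabilityReport:
    """Classify the four corners and, when valid, the interior rest point.

    ``zero_tol`` defaults to 1e-12 times the monetary scale max(cc, cs, p).
    The interior point of a two-population replicator system has a zero
    trace at the rest point (the diagonal brackets vanish there), so it is
    reported as a saddle or as non-hyperbolic (a linear center) — never as
    an ESS.  Corners are reported by coordinates, never by letters.
    """
    if zero_tol is None:
        zero_tol = 1e-12 * params.scale
    gains = net_gains(params)
    scenario = classify_scenario(gains, zero_tol=zero_tol)
    notes: list[str] = []

    reports = []
    for corner, (det, tr) in corner_det_trace(params).items():
        reports.append(
            EquilibriumReport(coords=corner, det=det, tr=tr,
                              classification=classify_point(det, tr, zero_tol), kind="corner")
        )

    interior: InteriorEquilibrium | None
    try:
        interior = interior_equilibrium(params)
    except DegenerateEquilibriumError as exc:
        interior = None
        notes.append(str(exc))
    if interior is not None and interior.valid:
        J = jacobian(params, interior.as_tuple())
        det = float(np.linalg.det(J))
        tr = float(np.trace(J))
        cls = classify_point(det, tr, zero_tol)
        if cls == NON_HYPERBOLIC and det > zero_tol:
            notes.append("interior point is a linear center (Det > 0, Tr = 0); cycling expected")
        reports.append(
            EquilibriumReport(coords=interior.as_tuple(), det=det, tr=tr,
                              classification=cls, kind="interior")
        )

    predicted = TABLE_ESS_CORNER.get(scenario) if isinstance(scenario, int) else None
    if scenario == 3:
        notes.append(
            "bistable pattern: pi2 > 0 and pi3 > 0 make (1,1) an ESS alongside (0,0); "
            "the attained corner depends on the initial state"
        )
    return StabilityReport(
        params=params, gains=gains, scenario=scenario,
        equilibria=tuple(reports), predicted_ess=predicted,
        interior=interior, notes=tuple(notes),
    )


def ess_corners(params: GameParams, zero_tol: "float | None" = None) -> list[tuple[float, float]]:
    """Corners satisfying Det > 0 and Tr < 0 for these parameters."""
    return classify_equilibria(params, zero_tol=zero_tol).ess


# Coarse deterministic search grids for realizing sign patterns.  Every
# tabulated scenario is reachable on this grid; the first lexicographic
# match is returned so the choice is reproducible.
_P_GRID = (2.0, 5.0, 8.0, 12.0, 15.0)
_COST_GRID = (1.0, 3.0, 6.0, 10.0, 14.0, 18.0)
_SHARE_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


def find_scenario_params(scenario: int) -> GameParams:
    """Grid-search parameters whose gain sign pattern realizes a scenario.

    Searches a fixed coarse grid over (p, cc, cs, a, b) and returns the
    first parameter set whose strict sign pattern classifies as the
    requested scenario (1-10).

    Raises
    ------
    ValueError
        If the scenario is not realized anywhere on the grid.
    """
    import warnings

    for p in _P_GRID:
        for cc in _COST_GRID:
            for cs in _COST_GRID:
                for a in _SHARE_GRID:
                    for b in _SHARE_GRID:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            params = GameParams(cc=cc, cs=cs, p=p, a=a, b=b)
                        if classify_scenario(net_gains(params)) == scenario:
                            return params
    raise ValueError(f"scenario {scenario!r} not realized on the search grid")
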
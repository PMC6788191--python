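"""Replicator dynamics of the liability game on the unit square.

State is the pair (alpha, beta): the fraction of schools, respectively of
student/guardian households, playing "appropriate caution".  Each fraction
grows in proportion to the payoff advantage of caution over the population
average, giving the two-population replicator system

    dalpha/dt = alpha (1 - alpha) [ beta ((1-a)p + b cs) - (cc - a p) ]
    dbeta/dt  = beta (1 - beta) [ ((1-a)p - (1-b)cs) - (b cs - a p) alpha ]

whose rest points are the four corners of [0, 1]^2 plus, when it lies in
the open square, the interior point

    alpha* = ((1-a)p - (1-b)cs) / (b cs - a p)
    beta*  = (cc - a p) / ((1-a)p + b cs).

A generic-bimatrix replicator flow built directly from the payoff cells is
provided as an independent oracle for the closed forms, and is also what
trajectories under the ``strict_override`` payoff table integrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateEquilibriumError, NumericalError, ParameterError
from .model import GameParams, LiabilityRule, PayoffBimatrix, build_payoff_matrix

__all__ = [
    "StateProfile",
    "ExpectedGains",
    "Trajectory",
    "InteriorEquilibrium",
    "expected_gains",
    "school_flow",
    "student_flow",
    "flow",
    "generic_bimatrix_flow",
    "interior_equilibrium",
    "rest_points",
    "integrate",
    "CORNERS",
]

#: The four pure-strategy rest points, as (alpha, beta).
CORNERS: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))


@dataclass(frozen=True)
class StateProfile:
    """Population state: caution frequencies of school (alpha) and students (beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {getattr(self, name)!r}")
            object.__setattr__(self, name, value)

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def _alpha_beta(state) -> tuple[float, float]:
    if isinstance(state, StateProfile):
        return state.alpha, state.beta
    alpha, beta = state
    return float(alpha), float(beta)


@dataclass(frozen=True)
class ExpectedGains:
    """Expected payoffs of each pure strategy and the population averages.

    ``ea``/``en`` are the school's expected payoffs under caution / no
    caution; ``ec`` the school population average.  ``sa``/``sn``/``sc``
    are the students' analogues.
    """

    ea: float
    en: float
    ec: float
    sa: float
    sn: float
    sc: float


def expected_gains(params: GameParams, state) -> ExpectedGains:
    """Expected payoffs at a state, from the parametric payoff structure.

    ea = -cc;  en = -beta (p + b cs) - (1 - beta) a p;
    sa = -alpha cs - (1 - alpha)(1 - b) cs;
    sn = -alpha p - (1 - alpha)(1 - a) p;
    and the averages ec = alpha*ea + (1-alpha)*en, sc = beta*sa + (1-beta)*sn.
    """
    alpha, beta = _alpha_beta(state)
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    ea = -cc
    en = -beta * (p + b * cs) - (1 - beta) * a * p
    sa = -alpha * cs - (1 - alpha) * (1 - b) * cs
    sn = -alpha * p - (1 - alpha) * (1 - a) * p
    return ExpectedGains(
        ea=ea, en=en, ec=alpha * ea + (1 - alpha) * en,
        sa=sa, sn=sn, sc=beta * sa + (1 - beta) * sn,
    )


def school_flow(params: GameParams, state) -> float:
    """dalpha/dt = alpha (1-alpha) [beta ((1-a)p + b cs) - (cc - a p)]."""
    alpha, beta = _alpha_beta(state)
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    return alpha * (1 - alpha) * (beta * ((1 - a) * p + b * cs) - (cc - a * p))


def student_flow(params: GameParams, state) -> float:
    """dbeta/dt = beta (1-beta) [((1-a)p - (1-b)cs) - (b cs - a p) alpha]."""
    alpha, beta = _alpha_beta(state)
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    return beta * (1 - beta) * (((1 - a) * p - (1 - b) * cs) - (b * cs - a * p) * alpha)


def flow(params: GameParams, state) -> tuple[float, float]:
    """(dalpha/dt, dbeta/dt), honouring the liability-rule tag.

    Parametric parameters use the closed forms; ``strict_override``
    parameters use the generic bimatrix flow on the override table (the
    closed forms encode the parametric table only).
    """
    if params.rule is LiabilityRule.STRICT_OVERRIDE:
        return generic_bimatrix_flow(build_payoff_matrix(params), state)
    return school_flow(params, state), student_flow(params, state)


def generic_bimatrix_flow(matrix: PayoffBimatrix, state) -> tuple[float, float]:
    """Two-population replicator flow built directly from payoff cells.

    Computes each pure strategy's fitness against the opponent mix and
    multiplies the fitness advantage by own frequency — never touching the
    closed forms, so this serves as their independent oracle.
    """
    alpha, beta = _alpha_beta(state)
    student_mix = np.array([beta, 1 - beta])     # over student strategies (rows)
    school_mix = np.array([alpha, 1 - alpha])    # over school strategies (cols)
    school_fitness = student_mix @ matrix.school     # fitness of school's AC, NC
    student_fitness = matrix.student @ school_mix    # fitness of students' AC, NC
    dalpha = alpha * (1 - alpha) * (school_fitness[0] - school_fitness[1])
    dbeta = beta * (1 - beta) * (student_fitness[0] - student_fitness[1])
    return float(dalpha), float(dbeta)


@dataclass(frozen=True)
class InteriorEquilibrium:
    """Interior rest point candidate; ``valid`` iff it lies strictly inside (0,1)^2."""

    alpha: float
    beta: float
    valid: bool

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def interior_equilibrium(params: GameParams) -> InteriorEquilibrium:
    """Solve the interior rest point of the replicator system.

    alpha* = ((1-a)p - (1-b)cs) / (b cs - a p);
    beta*  = (cc - a p) / ((1-a)p + b cs).

    Raises
    ------
    DegenerateEquilibriumError
        If either denominator vanishes (named in the message); the interior
        point is then undefined and rest points may form continua.
    """
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    denom_alpha = b * cs - a * p
    denom_beta = (1 - a) * p + b * cs
    if denom_alpha == 0.0:
        raise DegenerateEquilibriumError(
            "denominator b*cs - a*p of alpha* vanishes; interior equilibrium undefined"
        )
    if denom_beta == 0.0:
        raise DegenerateEquilibriumError(
            "denominator (1-a)*p + b*cs of beta* vanishes; interior equilibrium undefined"
        )
    alpha = ((1 - a) * p - (1 - b) * cs) / denom_alpha
    beta = (cc - a * p) / denom_beta
    valid = 0.0 < alpha < 1.0 and 0.0 < beta < 1.0
    return InteriorEquilibrium(alpha=alpha, beta=beta, valid=valid)


def rest_points(params: GameParams) -> list[tuple[float, float]]:
    """All isolated rest points of the system in [0, 1]^2.

    The four corners always; the interior point when it is valid.  For
    degenerate parameter sets (a vanishing flow bracket on an edge, e.g.
    pi3 = 0 making the whole alpha = 1 edge stationary) rest points form
    continua which are not enumerated here.
    """
    points: list[tuple[float, float]] = list(CORNERS)
    try:
        eq = interior_equilibrium(params)
    except DegenerateEquilibriumError:
        return points
    if eq.valid:
        points.append(eq.as_tuple())
    return points


@dataclass(frozen=True)
class Trajectory:
    """Numerically integrated path of the replicator system.

    ``verdict`` is ``"corner (i,j)"`` when the path settled on a corner
    (within ``corner_tol`` with flow norm below ``flow_tol``),
    ``"interior"`` when it settled near a valid interior equilibrium, and
    ``"cycling/undecided"`` otherwise.  ``max_boundary_violation`` is the
    largest excursion outside the unit square before clipping — a purely
    floating-point effect, since the exact field is tangent at boundaries.
    """

    t: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    verdict: str
    final_state: tuple[float, float]
    final_flow_norm: float
    max_boundary_violation: float

    @property
    def states(self) -> np.ndarray:
        """(n, 2) array of (alpha, beta) samples."""
        return np.column_stack([self.alpha, self.beta])


def _corner_verdict(corner: tuple[float, float]) -> str:
    return f"corner ({corner[0]:g},{corner[1]:g})"


def integrate(
    params: GameParams,
    initial,
    *,
    t_max: float = 500.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    corner_tol: float = 1e-3,
    flow_tol: float = 1e-8,
) -> Trajectory:
    """Integrate the replicator flow with adaptive Runge-Kutta (RK45).

    The field is a smooth polynomial and is integrated with an adaptive
    scheme at tight tolerances (defaults rtol=1e-10, atol=1e-12, chosen so
    the numerical drift outside the unit square stays below 1e-9).  States
    are clipped to the unit square after integration; the largest pre-clip
    excursion is recorded on the trajectory.

    Raises
    ------
    NumericalError
        If the integrator fails or produces a non-finite state (the
        offending state is named in the message).
    """
    alpha0, beta0 = _alpha_beta(initial)
    if not (0.0 <= alpha0 <= 1.0 and 0.0 <= beta0 <= 1.0):
        raise ParameterError(f"initial state ({alpha0}, {beta0}) must lie in [0, 1]^2")
    if t_max <= 0:
        raise ParameterError(f"t_max must be > 0, got {t_max}")

    if params.rule is LiabilityRule.STRICT_OVERRIDE:
        matrix = build_payoff_matrix(params)

        def rhs(_t, y):
            return generic_bimatrix_flow(matrix, y)
    else:
        # dalpha = alpha(1-alpha)(k1 beta - k2); dbeta = beta(1-beta)(k3 - k4 alpha)
        cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
        k1 = (1 - a) * p + b * cs
        k2 = cc - a * p
        k3 = (1 - a) * p - (1 - b) * cs
        k4 = b * cs - a * p

        def rhs(_t, y):
            alpha, beta = y
            return (alpha * (1 - alpha) * (k1 * beta - k2),
                    beta * (1 - beta) * (k3 - k4 * alpha))

    # LSODA rather than a pure explicit Runge-Kutta: the field is smooth,
    # but once a fast strategy (decay rate ~ monetary scale) has settled on
    # an edge while the other still drifts, the system is numerically stiff
    # and an explicit scheme becomes stability-limited; LSODA switches to a
    # stiff method automatically in that regime.
    sol = solve_ivp(rhs, (0.0, float(t_max)), [alpha0, beta0], method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise NumericalError(f"integration failed: {sol.message}")
    t, y = sol.t, sol.y
    if not np.isfinite(y).all():
        k = int(np.argmax(~np.isfinite(y).all(axis=0)))
        raise NumericalError(
            f"non-finite state at t={t[k]:.6g}: (alpha, beta)=({y[0, k]!r}, {y[1, k]!r})"
        )

    def _near_corner(state) -> bool:
        return min(np.hypot(state[0] - c[0], state[1] - c[1]) for c in CORNERS) < corner_tol

    final_raw = (float(y[0, -1]), float(y[1, -1]))
    if _near_corner(final_raw) and np.hypot(*rhs(t[-1], final_raw)) >= flow_tol:
        # The adaptive solver's error floor (~rtol * state) can leave the
        # state a residual offset from an attracting corner, keeping the
        # flow norm above threshold even though the exact solution has long
        # since settled.  A short restarted pass at tight tolerance resets
        # the accumulated error and lets the offset decay to rounding level.
        refine = solve_ivp(rhs, (0.0, 0.2 * float(t_max)), list(final_raw),
                           method="LSODA", rtol=1e-12, atol=1e-14)
        if refine.success and np.isfinite(refine.y).all():
            t = np.concatenate([t, t[-1] + refine.t[1:]])
            y = np.concatenate([y, refine.y[:, 1:]], axis=1)

    violation = float(max(0.0, np.max(y - 1.0, initial=0.0), np.max(-y, initial=0.0)))
    y = np.clip(y, 0.0, 1.0)
    final = (float(y[0, -1]), float(y[1, -1]))
    f_final = rhs(t[-1], final)
    flow_norm = float(np.hypot(*f_final))

    verdict = "cycling/undecided"
    distances = [np.hypot(final[0] - c[0], final[1] - c[1]) for c in CORNERS]
    nearest = int(np.argmin(distances))
    if distances[nearest] < corner_tol and flow_norm < flow_tol:
        verdict = _corner_verdict(CORNERS[nearest])
    elif params.rule is not LiabilityRule.STRICT_OVERRIDE:
        try:
            eq = interior_equilibrium(params)
        except DegenerateEquilibriumError:
            eq = None
        if eq is not None and eq.valid and np.hypot(final[0] - eq.alpha, final[1] - eq.beta) < corner_tol:
            verdict = "interior"

    return Trajectory(
        t=t,
        alpha=y[0],
        beta=y[1],
        verdict=verdict,
        final_state=final,
        final_flow_norm=flow_norm,
        max_boundary_violation=violation,
    )
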
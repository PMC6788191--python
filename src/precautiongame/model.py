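"""Parameters, payoff bimatrix and corner net gains of the liability game.

The game has two populations: a *school* choosing whether to invest in
accident prevention ("appropriate caution", cost ``cc``) and *students and
their guardians* choosing likewise ("appropriate caution", cost ``cs``).
If either side is careless an accident of total loss ``p`` occurs; a court
splits the loss and, in one asymmetric cell, part of the students'
prevention cost, according to the liability shares ``a`` and ``b``.

Two liability-rule encodings are provided:

* ``parametric`` — the proportional rule: the school bears the share ``a``
  of the loss when neither side was cautious, and the share ``b`` of the
  students' prevention cost when only the students were cautious.  Strict
  liability is the ``a = b = 1`` corner of this family.
* ``strict_override`` — a literal strict-liability table in which the
  school bears the *full* loss whenever an accident occurs, including the
  cell where only the students were careless, and the students never pay
  anything unless they invest in their own prevention.

The two encodings agree at ``a = b = 1`` in every cell except
(student careless, school cautious), where the override charges the school
``-cc - p`` instead of ``-cc`` and the students ``0`` instead of ``-p``.
Both are exposed; neither is asserted as the "correct" strict rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from math import isfinite

import numpy as np

from .errors import InfeasibleGainsError, ParameterError

__all__ = [
    "LiabilityRule",
    "GameParams",
    "PayoffBimatrix",
    "NetGains",
    "APPROPRIATE_CAUTION",
    "NO_CAUTION",
    "STRATEGIES",
    "build_payoff_matrix",
    "net_gains",
    "classify_scenario",
    "SCENARIO_PATTERNS",
    "TABLE_ESS_CORNER",
]

APPROPRIATE_CAUTION = "appropriate_caution"
NO_CAUTION = "no_caution"
#: Strategy order used on both axes of the bimatrix (index 0, index 1).
STRATEGIES = (APPROPRIATE_CAUTION, NO_CAUTION)


class LiabilityRule(str, Enum):
    """How court liability shapes the payoff table."""

    PARAMETRIC = "parametric"
    STRICT_OVERRIDE = "strict_override"


def _as_rule(rule: "LiabilityRule | str") -> LiabilityRule:
    if isinstance(rule, LiabilityRule):
        return rule
    try:
        return LiabilityRule(rule)
    except ValueError:
        valid = ", ".join(r.value for r in LiabilityRule)
        raise ParameterError(f"unknown liability rule {rule!r}; expected one of: {valid}") from None


@dataclass(frozen=True)
class GameParams:
    """Scalar parameters of the liability game.

    Parameters
    ----------
    cc : float
        School prevention cost (currency units, > 0).
    cs : float
        Student/guardian prevention cost (currency units, > 0).
    p : float
        Total accident loss (currency units, > 0).
    a : float
        School's share of the loss when neither side is cautious, in [0, 1].
    b : float
        Share of the students' prevention cost borne by the school when only
        the students are cautious, in [0, 1].
    rule : LiabilityRule or str
        Payoff-table encoding; see module docstring.

    Notes
    -----
    The model narrative assumes ``cs < cc`` (student prevention is cheaper
    than institutional prevention), but this ordering is *not* enforced —
    several study cases deliberately violate it.  A warning is emitted when
    ``cs >= cc``.
    """

    cc: float
    cs: float
    p: float
    a: float
    b: float
    rule: LiabilityRule = LiabilityRule.PARAMETRIC

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", _as_rule(self.rule))
        for name in ("cc", "cs", "p", "a", "b"):
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ParameterError(f"parameter {name!r} must be a real number, got {value!r}") from None
            if not isfinite(value):
                raise ParameterError(f"parameter {name!r} must be finite, got {value!r}")
            object.__setattr__(self, name, value)
        for name in ("cc", "cs", "p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"parameter {name!r} must be > 0, got {getattr(self, name)}")
        for name in ("a", "b"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"parameter {name!r} must lie in [0, 1], got {value}")
        if self.cs >= self.cc:
            warnings.warn(
                f"cs ({self.cs}) >= cc ({self.cc}): the usual cost ordering cs < cc is violated "
                "(allowed, but note the model narrative assumes cheaper student prevention)",
                stacklevel=3,
            )

    @classmethod
    def strict(cls, cc: float, cs: float, p: float) -> "GameParams":
        """Strict-liability parameters: literal override table, a = b = 1."""
        return cls(cc=cc, cs=cs, p=p, a=1.0, b=1.0, rule=LiabilityRule.STRICT_OVERRIDE)

    def with_shares(self, a: float, b: float) -> "GameParams":
        """Copy with new liability shares (keeps costs and rule)."""
        return replace(self, a=a, b=b)

    @property
    def scale(self) -> float:
        """Characteristic monetary scale, used for relative zero tolerances."""
        return max(self.cc, self.cs, self.p)


@dataclass(frozen=True)
class PayoffBimatrix:
    """2x2 payoff table; rows index the student strategy, columns the school's.

    ``student[i, j]`` / ``school[i, j]`` are the payoffs (non-positive in
    this model) when the students play ``STRATEGIES[i]`` and the school
    plays ``STRATEGIES[j]``.
    """

    student: np.ndarray
    school: np.ndarray

    def __post_init__(self) -> None:
        student = np.asarray(self.student, dtype=float)
        school = np.asarray(self.school, dtype=float)
        if student.shape != (2, 2) or school.shape != (2, 2):
            raise ParameterError("payoff bimatrix must consist of two 2x2 tables")
        if not (np.isfinite(student).all() and np.isfinite(school).all()):
            raise ParameterError("payoff bimatrix entries must be finite")
        object.__setattr__(self, "student", student)
        object.__setattr__(self, "school", school)

    def cell(self, student_strategy: str, school_strategy: str) -> tuple[float, float]:
        """(student payoff, school payoff) for a pure-strategy combination."""
        i = STRATEGIES.index(student_strategy)
        j = STRATEGIES.index(school_strategy)
        return float(self.student[i, j]), float(self.school[i, j])


def build_payoff_matrix(params: GameParams) -> PayoffBimatrix:
    """Construct the payoff bimatrix for the given parameters and rule.

    Under the ``parametric`` rule the four (student, school) cells are::

        (AC, AC) = (-cs,        -cc)
        (AC, NC) = (-(1-b)cs,   -p - b*cs)
        (NC, AC) = (-p,         -cc)
        (NC, NC) = (-(1-a)p,    -a*p)

    Under ``strict_override`` the school bears the full loss whenever an
    accident occurs (plus the students' prevention cost when only they were
    cautious) and the students only ever pay their own prevention cost::

        (AC, AC) = (-cs,  -cc)
        (AC, NC) = (0,    -p - cs)
        (NC, AC) = (0,    -cc - p)
        (NC, NC) = (0,    -p)
    """
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    if params.rule is LiabilityRule.STRICT_OVERRIDE:
        student = np.array([[-cs, 0.0], [0.0, 0.0]])
        school = np.array([[-cc, -p - cs], [-cc - p, -p]])
    else:
        student = np.array([[-cs, -(1 - b) * cs], [-p, -(1 - a) * p]])
        school = np.array([[-cc, -p - b * cs], [-cc, -a * p]])
    return PayoffBimatrix(student=student, school=school)


@dataclass(frozen=True)
class NetGains:
    """Corner net gains from switching to "appropriate caution".

    pi1
        School's gain from caution when the students are careless:
        ``a*p - cc``.
    pi2
        School's gain from caution when the students are cautious:
        ``p + b*cs - cc``.
    pi3
        Students' gain from caution when the school is cautious:
        ``p - cs``.
    pi4
        Students' gain from caution when the school is careless:
        ``(1-a)*p - (1-b)*cs``.

    ``pi2 - pi1 = (1-a)*p + b*cs >= 0`` for every valid parameter set.
    """

    pi1: float
    pi2: float
    pi3: float
    pi4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pi1, self.pi2, self.pi3, self.pi4)

    def signs(self, zero_tol: float = 0.0) -> tuple[int, int, int, int]:
        """Sign pattern with values in {-1, 0, +1}; |x| <= zero_tol counts as 0."""
        return tuple(0 if abs(x) <= zero_tol else (1 if x > 0 else -1) for x in self.as_tuple())


def net_gains(params: GameParams) -> NetGains:
    """The four corner net-income differentials.

    These are defined on the parametric (proportional-rule) payoff table
    and are independent of the ``rule`` tag.
    """
    cc, cs, p, a, b = params.cc, params.cs, params.p, params.a, params.b
    return NetGains(
        pi1=a * p - cc,
        pi2=p + b * cs - cc,
        pi3=p - cs,
        pi4=(1 - a) * p - (1 - b) * cs,
    )


#: Full strict-sign patterns (sgn pi1, sgn pi2, sgn pi3, sgn pi4) of the
#: first eight tabulated scenarios.  Scenarios 9 and 10 are matched by
#: partial conditions after these (see :func:`classify_scenario`).
SCENARIO_PATTERNS: dict[int, tuple[int, int, int, int]] = {
    1: (-1, -1, -1, -1),
    2: (-1, 1, -1, -1),
    3: (-1, 1, 1, -1),
    4: (-1, -1, 1, -1),
    5: (-1, 1, 1, 1),
    6: (1, 1, 1, -1),
    7: (-1, -1, 1, 1),
    8: (-1, -1, -1, 1),
}

#: Corner the stability table marks as the ESS for each scenario (None for
#: scenario 10, which has no stable corner).  Scenario 3 additionally has
#: (1, 1) as an ESS by the Det/Tr rule — the pattern pi2 > 0, pi3 > 0 makes
#: (1, 1) stable regardless — so the system is bistable there; see
#: :func:`precautiongame.stability.classify_equilibria`.
TABLE_ESS_CORNER: dict[int, "tuple[float, float] | None"] = {
    1: (0.0, 0.0),
    2: (0.0, 0.0),
    3: (0.0, 0.0),
    4: (0.0, 0.0),
    5: (1.0, 1.0),
    6: (1.0, 1.0),
    7: (0.0, 1.0),
    8: (0.0, 1.0),
    9: (1.0, 0.0),
    10: None,
}


def classify_scenario(gains: NetGains, zero_tol: float = 0.0) -> "int | str":
    """Map the sign pattern of (pi1..pi4) to the ten-scenario numbering.

    Scenarios 1-8 are matched by their full strict-sign patterns; then
    scenario 9 by ``pi1 > 0, pi3 < 0, pi4 > 0`` and scenario 10 by
    ``pi1*pi2 < 0, pi3*pi4 < 0, pi1*pi3 > 0``.  Any zero sign (within
    ``zero_tol``) returns ``"boundary"`` — a non-hyperbolic case that must
    not silently receive a stability verdict.  Two strict patterns,
    (+,+,+,+) and (+,+,-,-), are reachable from valid parameters but appear
    in no tabulated scenario; they return ``"unlisted"`` (their corners are
    still classified correctly by the Det/Tr rule).

    Raises
    ------
    InfeasibleGainsError
        For the pattern pi1 > 0, pi2 < 0, which no valid parameter set can
        produce (pi2 - pi1 >= 0 always).
    """
    s = gains.signs(zero_tol)
    if 0 in s:
        return "boundary"
    if s[0] > 0 and s[1] < 0:
        raise InfeasibleGainsError(
            f"sign pattern {s} has pi1 > 0 and pi2 < 0, but pi2 - pi1 = (1-a)p + b*cs >= 0 "
            "for every valid parameter set; these gains were not produced by net_gains()"
        )
    for scenario, pattern in SCENARIO_PATTERNS.items():
        if s == pattern:
            return scenario
    if s[0] > 0 and s[2] < 0 and s[3] > 0:
        return 9
    g = gains
    if g.pi1 * g.pi2 < 0 and g.pi3 * g.pi4 < 0 and g.pi1 * g.pi3 > 0:
        return 10
    return "unlisted"
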
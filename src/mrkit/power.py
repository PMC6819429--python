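"""Statistical power for MR with a binary outcome.

Implements the published summary-level power formulas for a two-stage MR
analysis of a binary outcome. With case fraction K = n_cases/n_total, the
attenuated causal effect on the observed (linear-probability) scale is

    b = K * (OR / (1 + K*(OR - 1)) - 1),

its sampling variance under an instrument explaining a fraction R² of the
exposure variance is

    v = (K*(1 - K) - b²) / (n_total * R²),

and the two-sided Wald test has non-centrality b²/v, so power is the upper
tail of a non-central chi-square(1) beyond the alpha-level critical value —
equivalently the normal tail beyond z_{1−alpha/2} shifted by sqrt(b²/v).
Note the formula is *not* exactly symmetric in OR ↔ 1/OR (the attenuation is
asymmetric around the null), which is why the detectable risk-increasing and
protective ORs are solved separately rather than taken as reciprocals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

from scipy import stats
from scipy.optimize import brentq

from .errors import NoSolutionError, ValidationError

#: Upper end of the odds-ratio bracket searched by :func:`detectable_or`.
OR_BRACKET_HIGH = 10.0
#: Convergence tolerance (on power) for the detectable-OR root solve.
POWER_TOL = 1e-6


@dataclass(frozen=True)
class PowerQuery:
    """Inputs to the binary-outcome MR power computation.

    ``r_squared`` is the fraction of exposure variance explained by the
    instrument set; ``odds_ratio`` the causal OR per exposure SD to detect;
    ``alpha`` the two-sided significance level of the Wald test.
    """

    n_total: int
    n_cases: int
    r_squared: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0 or self.n_cases <= 0:
            raise ValidationError("sample and case counts must be positive")
        if self.n_cases >= self.n_total:
            raise ValidationError("n_cases must be smaller than n_total")
        if not (0.0 < self.r_squared < 1.0):
            raise ValidationError(f"r_squared must lie in (0, 1), got {self.r_squared!r}")
        if self.odds_ratio <= 0:
            raise ValidationError(f"odds_ratio must be positive, got {self.odds_ratio!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha!r}")


class DetectableOr(NamedTuple):
    """Detectable effect sizes at a target power: risk-increasing and protective."""

    or_risk: float
    or_protective: float


def mr_power_binary(query: PowerQuery) -> float:
    """Power of the two-sided MR Wald test to detect ``query.odds_ratio``.

    Returns a fraction in (0, 1); at OR = 1 it equals the significance level
    exactly (the test rejects at rate alpha under the null).
    """
    k = query.n_cases / query.n_total
    b = k * (query.odds_ratio / (1.0 + k * (query.odds_ratio - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (query.n_total * query.r_squared)
    if v <= 0:
        # the attenuated effect has swallowed the whole outcome variance: the
        # non-centrality diverges as v -> 0+, so power saturates at 1
        return 1.0
    ncp = b * b / v
    critical = stats.chi2.isf(query.alpha, 1)
    return float(stats.ncx2.sf(critical, 1, ncp))


def detectable_or(
    n_total: int,
    n_cases: int,
    r_squared: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> DetectableOr:
    """Smallest odds ratios detectable at ``target_power``.

    Root-solves the power function over OR in (1, 10] for the risk-increasing
    bound and over OR in (0.1, 1) for the protective bound. Because the power
    formula is not reciprocal-symmetric the two bounds are solved independently.
    """
    if not (0.0 < target_power < 1.0):
        raise ValidationError(f"target_power must lie in (0, 1), got {target_power!r}")
    base = PowerQuery(n_total=n_total, n_cases=n_cases, r_squared=r_squared,
                      odds_ratio=2.0, alpha=alpha)

    def gap(or_value: float) -> float:
        return mr_power_binary(replace(base, odds_ratio=or_value)) - target_power

    # power(1) = alpha exactly, so a target at or below alpha is met in the
    # limit of a null effect on both sides
    if target_power <= alpha:
        return DetectableOr(or_risk=1.0, or_protective=1.0)

    def solve(near_null: float, extreme: float) -> float:
        if gap(extreme) < 0:
            raise NoSolutionError(
                f"power {target_power} unreachable for any OR between {near_null} and "
                f"{extreme} (max attainable {gap(extreme) + target_power:.4f})"
            )
        low, high = sorted((near_null, extreme))
        return float(brentq(gap, low, high, xtol=POWER_TOL))

    or_risk = solve(1.0, OR_BRACKET_HIGH)
    or_protective = solve(1.0, 1.0 / OR_BRACKET_HIGH)
    return DetectableOr(or_risk=or_risk, or_protective=or_protective)
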
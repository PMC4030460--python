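"""Interaction detection: observed versus multiplicatively-expected accuracy.

For a set of conditions x_1..x_k and an outcome class, the *observed*
accuracy is P(outcome | all conditions) estimated from the table.  The
*expected* accuracy under independent, multiplicative effects is

    expected = min(1, P(outcome) * prod_i P(outcome | x_i) / P(outcome))

i.e. the class prevalence scaled by each condition's individual
relative effect.  A genuine interaction shows up as observed accuracy
exceeding this expectation.

The effect size is the relative risk from the 2x2 table of the full
condition set against its complement (exposed = all conditions hold):

    RR = [a / (a + b)] / [c / (c + d)]

with the usual log-normal 95% confidence interval
``exp(ln RR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``.  Zero
cells propagate to 0 or infinite bounds, rendered ``*`` in the text
output.

The *expected* RR is the multiplicative expectation mapped onto the
same exposed/complement scale as the observed RR: with prevalence
``pi``, exposed fraction ``p_S`` and expected exposed risk
``r = expected accuracy``, the expected unexposed risk is
``(pi - r * p_S) / (1 - p_S)`` and the expected RR their ratio.  Under
an exactly multiplicative null this equals the true RR, which makes
the test calibrated.  (The naive alternative — multiplying the k
single-condition RRs, each taken against its own complement — lives on
a different scale than the joint RR and rejects a true multiplicative
null far above the nominal level.)

The interaction is flagged significant when the expected RR falls
outside the observed RR's confidence interval *and* the observed
accuracy exceeds the expected one — a one-directional test for effects
greater than the independence prediction.  Any arity >= 2 is
supported, so three-way (and higher) hypotheses can be tested the
same way.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .network import RuleNetwork
from .rules import Condition, DecisionTable

__all__ = [
    "Margins",
    "RelativeRisk",
    "InteractionTest",
    "RankedTest",
    "observed_accuracy",
    "expected_accuracy",
    "relative_risk",
    "test_interaction",
    "rank_and_test",
    "format_bound",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class Margins(NamedTuple):
    """2x2 margins: exposed = all conditions hold, case = outcome class."""

    a: int  # exposed, case
    b: int  # exposed, non-case
    c: int  # unexposed, case
    d: int  # unexposed, non-case


@dataclass(frozen=True)
class RelativeRisk:
    rr: float  # may be inf
    ci_low: float
    ci_high: float
    margins: Margins


@dataclass(frozen=True)
class InteractionTest:
    """Observed vs expected accuracy and relative risks for a condition set."""

    conditions: tuple[Condition, ...]
    outcome: str
    n_joint: int
    n_joint_outcome: int
    observed_accuracy: float
    expected_accuracy: float
    rr_observed: float
    rr_expected: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass(frozen=True)
class RankedTest:
    """One row of :func:`rank_and_test`: a connection with its test or error."""

    conditions: tuple[Condition, ...]
    score: float
    test: InteractionTest | None
    error: str | None = None


def _margins(table: DecisionTable, conditions: Sequence[Condition], outcome: str) -> Margins:
    joint = table.mask(conditions)
    out = table.df[table.decision].to_numpy() == outcome
    a = int((joint & out).sum())
    b = int((joint & ~out).sum())
    c = int((~joint & out).sum())
    d = int((~joint & ~out).sum())
    return Margins(a, b, c, d)


def observed_accuracy(
    table: DecisionTable, conditions: Sequence[Condition], outcome: str
) -> tuple[float, Margins]:
    """P(outcome | all conditions) with the 2x2 margins."""
    if not conditions:
        raise ValueError("at least one condition is required")
    m = _margins(table, conditions, outcome)
    if m.a + m.b == 0:
        raise ValueError(
            f"no supporting objects for {' AND '.join(map(str, conditions))}"
        )
    return m.a / (m.a + m.b), m


def expected_accuracy(
    table: DecisionTable, conditions: Sequence[Condition], outcome: str
) -> float:
    """Accuracy expected under independent multiplicative condition effects."""
    if not conditions:
        raise ValueError("at least one condition is required")
    out = table.mask([Condition(table.decision, outcome)])
    prevalence = out.mean()
    if prevalence == 0:
        raise ValueError(f"outcome {outcome!r} does not occur in the table")
    product = prevalence
    for cond in conditions:
        m = table.mask([cond])
        if not m.any():
            raise ValueError(f"condition {cond} has no supporting objects")
        product *= (out[m].mean()) / prevalence
    return min(1.0, float(product))


def relative_risk(
    table: DecisionTable, conditions: Sequence[Condition], outcome: str
) -> RelativeRisk:
    """Relative risk of the outcome for exposed (all conditions) vs the rest.

    Zero cells yield RR of 0 or infinity with a (0, inf) interval; the
    degenerate bounds are rendered ``*`` by :func:`format_bound`.
    """
    _, m = observed_accuracy(table, conditions, outcome)
    risk_exposed = m.a / (m.a + m.b)
    if m.c + m.d == 0:
        raise ValueError("no unexposed objects; relative risk is undefined")
    risk_unexposed = m.c / (m.c + m.d)
    if m.a == 0:
        return RelativeRisk(0.0, 0.0, math.inf, m)
    if m.c == 0:
        return RelativeRisk(math.inf, 0.0, math.inf, m)
    rr = risk_exposed / risk_unexposed
    se = math.sqrt(1 / m.a - 1 / (m.a + m.b) + 1 / m.c - 1 / (m.c + m.d))
    return RelativeRisk(
        rr,
        rr * math.exp(-Z_95 * se),
        rr * math.exp(Z_95 * se),
        m,
    )


def test_interaction(
    table: DecisionTable, conditions: Sequence[Condition], outcome: str
) -> InteractionTest:
    """Full interaction test of a condition set against one outcome.

    The expected RR combines the k single-condition effects
    multiplicatively and expresses the result on the observed RR's
    exposed-versus-complement scale (see the module docstring); under
    independent multiplicative effects it coincides with the true RR.
    """
    conditions = tuple(conditions)
    if len(conditions) < 2:
        raise ValueError("an interaction test needs at least two conditions")
    obs_acc, m = observed_accuracy(table, conditions, outcome)
    exp_acc = expected_accuracy(table, conditions, outcome)
    rr = relative_risk(table, conditions, outcome)
    n = m.a + m.b + m.c + m.d
    prevalence = (m.a + m.c) / n
    p_exposed = (m.a + m.b) / n
    if p_exposed >= 1.0:
        raise ValueError("conditions cover every object; no complement to compare")
    q_expected = (prevalence - exp_acc * p_exposed) / (1.0 - p_exposed)
    rr_expected = math.inf if q_expected <= 0 else exp_acc / q_expected
    significant = bool(
        obs_acc > exp_acc
        and (rr_expected < rr.ci_low or rr_expected > rr.ci_high)
    )
    return InteractionTest(
        conditions=conditions,
        outcome=outcome,
        n_joint=m.a + m.b,
        n_joint_outcome=m.a,
        observed_accuracy=obs_acc,
        expected_accuracy=exp_acc,
        rr_observed=rr.rr,
        rr_expected=rr_expected,
        ci_low=rr.ci_low,
        ci_high=rr.ci_high,
        significant=significant,
    )


def rank_and_test(
    network: RuleNetwork, table: DecisionTable, top_n: int = 10
) -> list[RankedTest]:
    """Interaction-test the strongest connections of a network.

    Takes the ``top_n`` highest-scored edges (the network's edges are
    already score-ordered) and tests each condition pair; a per-edge
    failure (e.g. the two conditions never co-occur in the table) is
    recorded on its row while the remaining edges proceed.
    """
    results: list[RankedTest] = []
    for e in network.edges[:top_n]:
        conds = (e.x, e.y)
        try:
            t = test_interaction(table, conds, network.outcome)
            results.append(RankedTest(conds, e.score, t))
        except ValueError as exc:
            results.append(RankedTest(conds, e.score, None, error=str(exc)))
    return results


def format_bound(x: float) -> str:
    """Render a CI bound; ``*`` denotes an infinite bound (0 is -inf on the log scale)."""
    if math.isinf(x) or x == 0.0:
        return "*"
    return f"{x:.3g}"
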
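"""Rule post-processing: deduplication, hypergeometric significance and
superset-rule removal.

The significance of a rule is the upper-tail (enrichment) probability
of drawing at least ``k`` objects of the rule's class when ``n`` of
``N`` objects are sampled without replacement and ``K`` of the ``N``
belong to the class — i.e. ``P(X >= k)`` for
``X ~ Hypergeometric(N, K, n)`` with ``n`` the rule support and ``k``
the number of supporting objects in the class.  Smaller is more
significant.

The superset filter implements a parsimony preference: a rule is
dropped when a strictly shorter rule with the same outcome, whose
conditions it contains, is at least as significant.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .rules import DecisionTable, Rule, RuleSet

__all__ = ["RulePValue", "dedupe_rules", "rule_pvalue", "superset_filter"]


@dataclass(frozen=True)
class RulePValue:
    """Hypergeometric enrichment test of one rule.

    N = table size, K = objects in the rule's class, n = rule support,
    k = objects matching both LHS and outcome, p = P(X >= k).
    """

    rule_id: str
    N: int
    K: int
    n: int
    k: int
    p: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError(
                f"inconsistent counts for rule {self.rule_id!r}: "
                f"k={self.k} exceeds min(n={self.n}, K={self.K})"
            )


def dedupe_rules(rs: RuleSet) -> RuleSet:
    """Collapse rules with identical (LHS, outcome) to the first occurrence.

    Rules with the same LHS but different outcomes are distinct and all
    kept.  Statistics are taken from the first occurrence (identical by
    construction when duplicates come from merged cross-validation
    folds over near-identical training data).
    """
    seen: set = set()
    out: list[Rule] = []
    for r in rs:
        if r.key in seen:
            continue
        seen.add(r.key)
        out.append(r)
    return RuleSet(out, rs.decision_feature)


def rule_pvalue(
    rule: Rule,
    table: DecisionTable | None = None,
    N: int | None = None,
    K: int | None = None,
) -> RulePValue:
    """Exact upper-tail hypergeometric p-value of a rule.

    With a table, the counts are recomputed from it; otherwise ``N``
    and ``K`` must be given and ``k`` is reconstructed as
    ``round(support * accuracy)``.  A rule with zero support gets
    ``p = 1`` and is flagged degenerate.
    """
    if table is not None:
        N = table.n_objects
        K = int(table.mask([rule.outcome]).sum())
        m = table.mask(rule.lhs)
        n = int(m.sum())
        k = int((m & table.mask([rule.outcome])).sum())
    else:
        if N is None or K is None:
            raise ValueError("either a table or both N and K are required")
        n = rule.support
        k = 0 if rule.accuracy is None else round(rule.support * rule.accuracy)
    if n == 0:
        return RulePValue(rule.id, N, K, 0, 0, 1.0, degenerate=True)
    if k > min(n, K):
        raise ValueError(
            f"inconsistent counts for rule {rule.id!r}: k={k} > min(n={n}, K={K})"
        )
    p = float(hypergeom.sf(k - 1, N, K, n))
    return RulePValue(rule.id, N, K, n, k, min(p, 1.0))


def superset_filter(
    rs: RuleSet,
    table: DecisionTable | None = None,
    N: int | None = None,
    K_by_class: dict[str, int] | None = None,
    return_log: bool = False,
) -> RuleSet | tuple[RuleSet, list[tuple[Rule, Rule, float, float]]]:
    """Remove superset rules that are not more significant than a sub-rule.

    Rule ``r`` is removed iff some rule ``s`` in the set has the same
    outcome, ``LHS(s)`` a proper subset of ``LHS(r)``, and
    ``p(s) <= p(r)`` — shorter rules are preferred when at least
    equally significant.  The operation is idempotent and independent
    of rule order.

    With ``return_log=True`` also returns ``(removed, kept_sub, p_removed,
    p_sub)`` tuples.
    """
    pvals: list[float] = []
    for r in rs:
        if table is not None:
            pv = rule_pvalue(r, table)
        elif r.pvalue is not None:
            pv = None
            pvals.append(r.pvalue)
            continue
        else:
            if N is None or K_by_class is None:
                raise ValueError(
                    "p-values unavailable: supply a table, rule pvalues, or N and K_by_class"
                )
            pv = rule_pvalue(r, N=N, K=K_by_class[r.outcome.value])
        pvals.append(pv.p)
    keep: list[Rule] = []
    log: list[tuple[Rule, Rule, float, float]] = []
    for i, r in enumerate(rs):
        removed_by = None
        for j, s in enumerate(rs):
            if i == j or s.outcome != r.outcome:
                continue
            if s.lhs < r.lhs and pvals[j] <= pvals[i]:
                removed_by = (s, pvals[j])
                break
        if removed_by is None:
            keep.append(r)
        else:
            log.append((r, removed_by[0], pvals[i], removed_by[1]))
    filtered = RuleSet(keep, rs.decision_feature)
    return (filtered, log) if return_log else filtered
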
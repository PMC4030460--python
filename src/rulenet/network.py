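"""Rule networks: condition co-occurrence scoring and graph assembly.

Two conditions *x* and *y* are connected when they co-occur in at least
one rule; the connection score is

    connection(x, y) = sum over rules r containing both x and y
                       of support(r) * accuracy(r)

so a rule with m >= 2 conditions contributes its ``support*accuracy``
to all C(m, 2) of its condition pairs, and single-condition rules
contribute nothing.  One network is built per outcome class; a
*combined* network aggregates rules of every outcome and records a
per-outcome score breakdown on each edge.

Nodes are the conditions with at least one connection, ordered with
features alphabetical and values increasing within a feature (numeric
value order where all of a feature's values are numeric).  A node's
weight is the sum of the scores of its incident edges, so the node
weights total twice the edge score total.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .rules import Condition, Rule, RuleSet
from . import io as _io

__all__ = [
    "Connection",
    "RuleNetwork",
    "connection_scores",
    "build_network",
    "outcome_network",
    "combined_network",
    "connection_share",
    "edge_rule_lookup",
    "network_to_json",
    "network_from_json",
]

COMBINED = "combined"


def _canonical(x: Condition, y: Condition) -> tuple[Condition, Condition]:
    return (x, y) if x <= y else (y, x)


@dataclass
class Connection:
    """A scored, unordered pair of co-occurring conditions."""

    x: Condition
    y: Condition
    outcome: str
    score: float
    rule_ids: list[str] = field(default_factory=list)
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("a connection needs two distinct conditions")
        self.x, self.y = _canonical(self.x, self.y)

    @property
    def pair(self) -> tuple[Condition, Condition]:
        return (self.x, self.y)

    @property
    def sort_key(self) -> tuple:
        return (-self.score, self.x.feature, self.x.value, self.y.feature, self.y.value)

    def __str__(self) -> str:
        return f"{self.x} -- {self.y} [{self.outcome}] score={self.score:g}"


@dataclass
class RuleNetwork:
    """A per-outcome (or combined) graph of conditions and connections."""

    outcome: str
    nodes: list[tuple[Condition, float]]
    edges: list[Connection]
    total_score: float
    rules_by_id: dict[str, Rule] = field(default_factory=dict)
    decision_feature: str = "decision"

    @property
    def node_conditions(self) -> list[Condition]:
        return [c for c, _ in self.nodes]

    def find_edge(self, x: Condition, y: Condition) -> Connection:
        x, y = _canonical(x, y)
        for e in self.edges:
            if e.x == x and e.y == y:
                return e
        raise KeyError(f"no edge between {x} and {y} in the {self.outcome!r} network")

    def __len__(self) -> int:
        return len(self.edges)


def connection_scores(rs: RuleSet, outcome: str) -> list[Connection]:
    """Score every unordered condition pair co-occurring in rules of ``outcome``.

    Pairs whose total score is zero (only zero-accuracy rules) are
    omitted.  The result is sorted by descending score, ties broken by
    the pair's (feature, value) labels.
    """
    if outcome not in rs.outcome_classes:
        raise ValueError(
            f"unknown outcome {outcome!r}; available: {', '.join(rs.outcome_classes)}"
        )
    return _score_rules([r for r in rs if r.outcome.value == outcome], outcome)


def _score_rules(rules: list[Rule], outcome: str) -> list[Connection]:
    acc: dict[tuple[Condition, Condition], Connection] = {}
    for r in rules:
        if r.accuracy is None or len(r.lhs) < 2:
            continue
        weight = r.support * r.accuracy
        conds = r.sorted_lhs
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                key = (conds[i], conds[j])
                conn = acc.get(key)
                if conn is None:
                    conn = acc[key] = Connection(conds[i], conds[j], outcome, 0.0)
                if weight > 0:
                    conn.score += weight
                    conn.rule_ids.append(r.id)
                    conn.breakdown[r.outcome.value] = (
                        conn.breakdown.get(r.outcome.value, 0.0) + weight
                    )
    out = [c for c in acc.values() if c.score > 0]
    out.sort(key=lambda c: c.sort_key)
    return out


def _value_sort_key(values: list[str]):
    try:
        as_num = {v: float(v) for v in values}
        return lambda v: as_num[v]
    except ValueError:
        return lambda v: v


def build_network(
    conns: list[Connection],
    outcome: str | None = None,
    min_score: float | None = None,
    top_n: int | None = None,
    ruleset: RuleSet | None = None,
) -> RuleNetwork:
    """Assemble a network from scored connections, applying edge filters.

    ``min_score`` keeps edges scoring at least that value; ``top_n``
    keeps the n strongest (ties broken deterministically by the pair
    labels).  Conditions left without any edge are dropped.  When a
    ``ruleset`` is supplied, the contributing rules are attached so
    edges can be resolved back to rules.
    """
    outcomes = {c.outcome for c in conns}
    if outcome is None:
        if len(outcomes) > 1:
            raise ValueError(f"connections span several outcomes: {sorted(outcomes)}")
        outcome = next(iter(outcomes)) if outcomes else ""
    elif outcomes - {outcome}:
        raise ValueError(f"connections for {sorted(outcomes - {outcome})} in {outcome!r} network")
    edges = sorted(conns, key=lambda c: c.sort_key)
    if min_score is not None:
        edges = [e for e in edges if e.score >= min_score]
    if top_n is not None:
        edges = edges[:top_n]
    if not edges and conns:
        warnings.warn("all connections were filtered out; the network is empty")

    weights: dict[Condition, float] = {}
    for e in edges:
        weights[e.x] = weights.get(e.x, 0.0) + e.score
        weights[e.y] = weights.get(e.y, 0.0) + e.score
    by_feature: dict[str, list[str]] = {}
    for c in weights:
        by_feature.setdefault(c.feature, []).append(c.value)
    nodes: list[tuple[Condition, float]] = []
    for feat in sorted(by_feature):
        vals = sorted(set(by_feature[feat]), key=_value_sort_key(by_feature[feat]))
        for v in vals:
            cond = Condition(feat, v)
            nodes.append((cond, weights[cond]))

    rules_by_id: dict[str, Rule] = {}
    decision = ruleset.decision_feature if ruleset is not None else "decision"
    if ruleset is not None:
        wanted = {rid for e in edges for rid in e.rule_ids}
        rules_by_id = {rid: r for rid, r in ruleset.by_id.items() if rid in wanted}
    return RuleNetwork(
        outcome=outcome,
        nodes=nodes,
        edges=edges,
        total_score=sum(e.score for e in edges),
        rules_by_id=rules_by_id,
        decision_feature=decision,
    )


def outcome_network(
    rs: RuleSet,
    outcome: str,
    min_score: float | None = None,
    top_n: int | None = None,
) -> RuleNetwork:
    """Connection scoring and network assembly for one outcome class."""
    return build_network(
        connection_scores(rs, outcome),
        outcome=outcome,
        min_score=min_score,
        top_n=top_n,
        ruleset=rs,
    )


def combined_network(
    rs: RuleSet, min_score: float | None = None, top_n: int | None = None
) -> RuleNetwork:
    """Network over rules of every outcome; edges carry a per-outcome
    score breakdown."""
    conns = _score_rules(list(rs), COMBINED)
    return build_network(
        conns, outcome=COMBINED, min_score=min_score, top_n=top_n, ruleset=rs
    )


def connection_share(conn: Connection, network: RuleNetwork) -> float:
    """Fraction of the network's total score carried by one connection."""
    found = network.find_edge(conn.x, conn.y)
    if network.total_score <= 0:
        raise ValueError("network total score is zero; share is undefined")
    return found.score / network.total_score


def edge_rule_lookup(
    network: RuleNetwork,
    edges: Connection | tuple[Condition, Condition] | list,
) -> list[Rule]:
    """Resolve an edge (or several) to the contributing rules.

    A single edge yields all rules containing both of its conditions;
    several edges yield the intersection of their rule sets — the
    multi-select semantics of an interactive viewer.
    """
    if isinstance(edges, (Connection, tuple)):
        edges = [edges]
    if not edges:
        return []
    if not network.rules_by_id:
        raise ValueError("network carries no rules; build it with a ruleset attached")
    id_sets = []
    first_order: list[str] = []
    for e in edges:
        conn = e if isinstance(e, Connection) else None
        if conn is None:
            conn = network.find_edge(*e)
        else:
            conn = network.find_edge(conn.x, conn.y)
        id_sets.append(set(conn.rule_ids))
        if not first_order:
            first_order = list(conn.rule_ids)
    common = set.intersection(*id_sets)
    return [network.rules_by_id[rid] for rid in first_order if rid in common]


def network_to_json(network: RuleNetwork) -> dict:
    """JSON-serializable document of a network (nodes, edges, rule lookup)."""
    total = network.total_score
    return {
        "outcome": network.outcome,
        "decision_feature": network.decision_feature,
        "total_score": total,
        "nodes": [
            {"feature": c.feature, "value": c.value, "weight": w}
            for c, w in network.nodes
        ],
        "edges": [
            {
                "x": {"feature": e.x.feature, "value": e.x.value},
                "y": {"feature": e.y.feature, "value": e.y.value},
                "score": e.score,
                "share": (e.score / total) if total > 0 else 0.0,
                "rule_ids": list(e.rule_ids),
                "breakdown": dict(e.breakdown),
            }
            for e in network.edges
        ],
        "rules": {rid: str(r) for rid, r in sorted(network.rules_by_id.items())},
    }


def network_from_json(doc: dict) -> RuleNetwork:
    """Rebuild a :class:`RuleNetwork` from :func:`network_to_json` output."""
    import dataclasses

    edges = [
        Connection(
            Condition(e["x"]["feature"], e["x"]["value"]),
            Condition(e["y"]["feature"], e["y"]["value"]),
            doc["outcome"],
            e["score"],
            rule_ids=list(e["rule_ids"]),
            breakdown=dict(e.get("breakdown", {})),
        )
        for e in doc["edges"]
    ]
    nodes = [
        (Condition(n["feature"], n["value"]), n["weight"]) for n in doc["nodes"]
    ]
    rules_by_id = {}
    for rid, text in doc.get("rules", {}).items():
        rule = _io.parse_rule_line(text)
        rules_by_id[rid] = dataclasses.replace(rule, id=rid)
    return RuleNetwork(
        outcome=doc["outcome"],
        nodes=nodes,
        edges=edges,
        total_score=doc["total_score"],
        rules_by_id=rules_by_id,
        decision_feature=doc.get("decision_feature", "decision"),
    )
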
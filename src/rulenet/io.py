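"""Readers and writers for rule files and decision tables.

Two rule dialects are accepted:

* line-by-line::

      IF f=v AND g=w THEN dec=c ; support=12 ; accuracy=0.75

* a ROSETTA-style export::

      f(v) AND g(w) => dec(c)  supp=12  acc=0.75

  where the trailing statistics may be ``supp``/``acc`` (or
  ``support``/``accuracy``) key-value tokens or bare whitespace-separated
  numbers (first = support, second = accuracy).  Unrecognized trailing
  tokens are ignored with a warning, since real exports vary between
  versions.

Rules are always written in the line-by-line dialect.  ``#`` starts a
comment line; blank lines are skipped.
"""
from __future__ import annotations

import re
import warnings
from os import PathLike
from typing import IO

import pandas as pd

from .rules import Condition, DecisionTable, Rule, RuleSet, annotate_rule_stats

__all__ = [
    "RuleParseError",
    "parse_line_rules",
    "parse_rosetta_rules",
    "parse_rule_line",
    "write_rules",
    "read_table",
    "write_table",
]


class RuleParseError(ValueError):
    """A rule file line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_STAT_KEYS = {
    "support": "support",
    "supp": "support",
    "accuracy": "accuracy",
    "acc": "accuracy",
    "pvalue": "pvalue",
    "p": "pvalue",
}


def _parse_stats(parts: list[str], lineno: int) -> dict[str, float]:
    stats: dict[str, float] = {}
    for part in parts:
        part = part.strip()
        if not part:
            continue
        key, sep, val = part.partition("=")
        if not sep or key.strip().lower() not in _STAT_KEYS:
            raise RuleParseError(lineno, f"unrecognized statistics field {part!r}")
        name = _STAT_KEYS[key.strip().lower()]
        try:
            stats[name] = float(val)
        except ValueError:
            raise RuleParseError(lineno, f"non-numeric value for {name}: {val!r}") from None
    return stats


def _build_rule(
    conditions: list[Condition],
    outcome: Condition,
    stats: dict[str, float],
    lineno: int,
    table: DecisionTable | None,
) -> Rule:
    has_stats = "support" in stats and "accuracy" in stats
    if not has_stats and table is None:
        raise RuleParseError(
            lineno, "missing support/accuracy and no decision table supplied for annotation"
        )
    support = int(stats.get("support", 0))
    accuracy = stats.get("accuracy") if has_stats else (None if support == 0 else 0.0)
    try:
        return Rule(
            lhs=frozenset(conditions),
            outcome=outcome,
            support=support,
            accuracy=accuracy if has_stats else None,
            pvalue=stats.get("pvalue"),
        )
    except ValueError as exc:
        raise RuleParseError(lineno, str(exc)) from None


def parse_rule_line(line: str, lineno: int = 1) -> Rule:
    """Parse a single line-by-line dialect rule (no comment handling)."""
    m = re.match(r"^\s*IF\s+(.*?)\s+THEN\s+(.*)$", line)
    if not m:
        raise RuleParseError(lineno, f"expected 'IF ... THEN ...', got {line.strip()!r}")
    lhs_text, rest = m.group(1), m.group(2)
    rest_parts = rest.split(";")
    outcome_text = rest_parts[0].strip()
    try:
        conditions = [Condition.parse(t.strip()) for t in re.split(r"\s+AND\s+", lhs_text)]
        outcome = Condition.parse(outcome_text)
    except ValueError as exc:
        raise RuleParseError(lineno, str(exc)) from None
    stats = _parse_stats(rest_parts[1:], lineno)
    return _build_rule(conditions, outcome, stats, lineno, table=None)


def _iter_content_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_line_rules(text: str, table: DecisionTable | None = None) -> RuleSet:
    """Parse the line-by-line rule dialect into a :class:`RuleSet`.

    Order is preserved and duplicate lines yield duplicate rules
    (deduplication is a separate step, see :mod:`rulenet.filtering`).
    If support/accuracy fields are missing, a ``table`` must be supplied
    and the statistics are recomputed from it.
    """
    rules: list[Rule] = []
    missing_stats = False
    for lineno, line in _iter_content_lines(text):
        m = re.match(r"^\s*IF\s+(.*?)\s+THEN\s+(.*)$", line)
        if not m:
            raise RuleParseError(lineno, f"expected 'IF ... THEN ...', got {line!r}")
        rest_parts = m.group(2).split(";")
        try:
            conditions = [Condition.parse(t.strip()) for t in re.split(r"\s+AND\s+", m.group(1))]
            outcome = Condition.parse(rest_parts[0].strip())
        except ValueError as exc:
            raise RuleParseError(lineno, str(exc)) from None
        stats = _parse_stats(rest_parts[1:], lineno)
        if not ("support" in stats and "accuracy" in stats):
            missing_stats = True
        rules.append(_build_rule(conditions, outcome, stats, lineno, table))
    return _finish_ruleset(rules, table, missing_stats)


_ROSETTA_COND = re.compile(r"^\s*([^()]+)\(([^()]*)\)\s*$")


def parse_rosetta_rules(text: str, table: DecisionTable | None = None) -> RuleSet:
    """Parse a ROSETTA-style rule export into a :class:`RuleSet`.

    Conditions have the form ``feature(value)`` joined by ``AND``, the
    LHS and RHS are separated by ``=>``, and trailing statistics follow
    the RHS (see module docstring for the accepted forms).
    """
    rules: list[Rule] = []
    missing_stats = False
    for lineno, line in _iter_content_lines(text):
        if "=>" not in line:
            raise RuleParseError(lineno, f"missing '=>' separator in {line!r}")
        lhs_text, rhs_text = line.split("=>", 1)
        conditions = []
        for tok in re.split(r"\s+AND\s+", lhs_text.strip()):
            m = _ROSETTA_COND.match(tok)
            if not m or not m.group(2):
                raise RuleParseError(lineno, f"not a feature(value) condition: {tok.strip()!r}")
            conditions.append(Condition(m.group(1).strip(), m.group(2).strip()))
        m = re.match(r"^\s*([^()]+)\(([^()]*)\)\s*(.*)$", rhs_text.strip())
        if not m or not m.group(2):
            raise RuleParseError(lineno, f"outcome is not feature(value): {rhs_text.strip()!r}")
        outcome = Condition(m.group(1).strip(), m.group(2).strip())
        stats: dict[str, float] = {}
        numeric: list[float] = []
        for tok in re.split(r"[,;\s]+", m.group(3).strip()):
            if not tok:
                continue
            key, sep, val = tok.partition("=")
            if sep and key.strip().lower() in _STAT_KEYS:
                try:
                    stats[_STAT_KEYS[key.strip().lower()]] = float(val)
                except ValueError:
                    raise RuleParseError(
                        lineno, f"non-numeric value for {key.strip()}: {val!r}"
                    ) from None
            else:
                try:
                    numeric.append(float(tok))
                except ValueError:
                    warnings.warn(
                        f"line {lineno}: ignoring unrecognized trailing token {tok!r}",
                        stacklevel=2,
                    )
        if "support" not in stats and numeric:
            stats["support"] = numeric.pop(0)
        if "accuracy" not in stats and numeric:
            stats["accuracy"] = numeric.pop(0)
        if not ("support" in stats and "accuracy" in stats):
            missing_stats = True
        rules.append(_build_rule(conditions, outcome, stats, lineno, table))
    return _finish_ruleset(rules, table, missing_stats)


def _finish_ruleset(
    rules: list[Rule], table: DecisionTable | None, missing_stats: bool
) -> RuleSet:
    if rules:
        decision = rules[0].outcome.feature
    elif table is not None:
        decision = table.decision
    else:
        decision = "decision"
    import dataclasses

    rules = [dataclasses.replace(r, id=f"r{i}") for i, r in enumerate(rules, start=1)]
    rs = RuleSet(rules, decision)
    if missing_stats:
        assert table is not None
        rs = annotate_rule_stats(rs, table)
    return rs


def write_rules(rs: RuleSet) -> str:
    """Serialize a rule set in the line-by-line dialect (round-trip stable)."""
    lines = [str(r) for r in rs]
    return "\n".join(lines) + ("\n" if lines else "")


def read_table(
    source: str | PathLike | IO[str],
    decision: str | None = None,
    sep: str | None = None,
) -> DecisionTable:
    """Read a CSV/TSV decision table (header row mandatory).

    The delimiter is sniffed when ``sep`` is None.  The decision column
    defaults to the last column.  All cells are read as discrete string
    labels; ragged or incomplete rows raise an error naming the row.
    """
    try:
        df = pd.read_csv(
            source, sep=sep, engine="python", dtype=str, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table: {exc}") from None
    df = df.replace("", pd.NA)
    return DecisionTable(df, decision=decision)


def write_table(table: DecisionTable, path: str | PathLike | None = None, sep: str = ",") -> str:
    """Write a decision table as CSV (or TSV); returns the text."""
    text = table.df.to_csv(index=False, sep=sep)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
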
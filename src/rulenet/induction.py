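"""Rule induction by bounded conjunction enumeration, plus discretization,
rule voting classification and cross-validation.

The learner enumerates every conjunction of up to ``max_len`` conditions
that occurs in the data and emits one rule per outcome class that meets
the support and accuracy thresholds.  Pruning keeps the rule list
minimal; the default mode requires a rule to be statistically
significant (upper-tail hypergeometric test of its class enrichment)
and, for every proper sub-conjunction, *conditionally* enriched within
that generalization's own support (again an exact hypergeometric tail,
drawn from the sub-rule's objects instead of the whole table).  The
conditional test is what makes the minimality real: a chance marginal
association cannot propagate into a cascade of specialized near-copies
of itself, because conditioning on an uninformative extra feature does
not enrich beyond the generalization.  An accuracy-dominance mode (the
longer rule must beat every generalization's accuracy) and no pruning
are also available.

At 15 binary features and conjunction length <= 3 the enumeration is
exact and fast; it is not intended for high-dimensional data without
prior feature selection.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .rules import Condition, DecisionTable, Rule, RuleSet

__all__ = [
    "InductionConfig",
    "CVResult",
    "equal_frequency_binning",
    "discretize_decision",
    "discretize_table",
    "induce_rules",
    "classify",
    "classify_table",
    "cross_validate",
]

UNCLASSIFIED_FALLBACK = "unclassified-fallback"


@dataclass(frozen=True)
class InductionConfig:
    """Rule learner settings.

    prune
        ``"significance"`` (default): keep a rule iff its global
        hypergeometric p-value is below ``alpha`` and it is
        conditionally enriched (below ``alpha``) within every proper
        sub-conjunction's support; ``"accuracy"``: keep a rule iff its
        accuracy exceeds that of every proper sub-conjunction (including
        the empty conjunction, i.e. the class prevalence); ``None``:
        keep everything passing the support/accuracy thresholds.
    """

    max_len: int = 3
    min_support: int = 2
    min_accuracy: float = 0.5
    prune: str | None = "significance"
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if not 0.0 <= self.min_accuracy <= 1.0:
            raise ValueError("min_accuracy must be in [0, 1]")
        if self.prune not in (None, "significance", "accuracy"):
            raise ValueError(f"unknown prune mode {self.prune!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


def _format_bound(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def equal_frequency_binning(
    values: Sequence[float] | np.ndarray, k: int
) -> tuple[list[float], np.ndarray]:
    """Discretize a numeric column into ``k`` equal-frequency intervals.

    Cut points sit at the empirical quantiles of the sorted column;
    intervals are left-closed/right-open and labeled ``[lo,hi)`` with
    the outermost bounds rendered ``*``.  Duplicate quantiles collapse
    (fewer bins, with a warning).

    Returns ``(cuts, labels)`` where ``labels`` is the per-value label
    array.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError("values contain non-numeric entries")
    srt = np.sort(arr)
    n = arr.size
    cuts: list[float] = []
    for j in range(1, k):
        c = float(srt[int(n * j / k)])
        # a cut must actually split: above the minimum and novel
        if c > float(srt[0]) and (not cuts or c > cuts[-1]):
            cuts.append(c)
    if len(cuts) < k - 1:
        warnings.warn(
            f"only {len(cuts) + 1} distinct bin(s) available for k={k}", stacklevel=2
        )
    return cuts, discretize_decision(arr, cuts, labels=_interval_labels(cuts))


def _interval_labels(cuts: Sequence[float]) -> list[str]:
    bounds = ["*"] + [_format_bound(c) for c in cuts] + ["*"]
    return [f"[{bounds[i]},{bounds[i + 1]})" for i in range(len(bounds) - 1)]


def discretize_decision(
    values: Sequence[float] | np.ndarray,
    cuts: Sequence[float],
    labels: Sequence[str] | None = None,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map numeric values to interval labels given explicit cut points.

    ``cuts`` must be strictly increasing; the intervals are half-open,
    so a value equal to a cut goes to the upper interval.  With no cuts
    every value gets the single label.  Labels default to ``"0"``,
    ``"1"``, ... in interval order.  If ``bounds`` is given, values
    outside ``[lo, hi)`` raise an error.
    """
    cuts = list(cuts)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be strictly increasing")
    arr = np.asarray(values, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(cuts) + 1)]
    if len(labels) != len(cuts) + 1:
        raise ValueError(f"need {len(cuts) + 1} labels, got {len(labels)}")
    if bounds is not None:
        lo, hi = bounds
        bad = (arr < lo) | (arr >= hi)
        if bad.any():
            raise ValueError(f"value(s) outside [{lo}, {hi}): {arr[bad][:5].tolist()}")
    idx = np.searchsorted(cuts, arr, side="right")
    return np.asarray(labels, dtype=object)[idx]


def discretize_table(
    df: pd.DataFrame,
    decision: str,
    k: int = 4,
    decision_cuts: Sequence[float] | None = None,
    decision_labels: Sequence[str] | None = None,
) -> DecisionTable:
    """Equal-frequency-bin every numeric feature column of ``df``.

    The decision column is binned with explicit ``decision_cuts`` if
    given, otherwise kept as-is (assumed already discrete).
    """
    out = {}
    for col in df.columns:
        if col == decision:
            if decision_cuts is not None:
                out[col] = discretize_decision(
                    df[col].to_numpy(dtype=float), decision_cuts, decision_labels
                )
            else:
                out[col] = df[col].astype(str)
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        if series.notna().all():
            _, out[col] = equal_frequency_binning(series.to_numpy(), k)
        else:
            out[col] = df[col].astype(str)
    return DecisionTable(pd.DataFrame(out, index=df.index), decision)


def _factorize_sorted(col: pd.Series) -> tuple[np.ndarray, list[str]]:
    uniques = sorted(col.unique())
    lookup = {v: i for i, v in enumerate(uniques)}
    return col.map(lookup).to_numpy(dtype=np.int64), uniques


def induce_rules(table: DecisionTable, cfg: InductionConfig | None = None) -> RuleSet:
    """Learn rules from a discrete decision table by exhaustive bounded
    conjunction enumeration.

    Output order is deterministic: conjunction length, then features
    alphabetically, then value combinations in sorted value order, then
    outcome classes in sorted order.  Every emitted rule carries its
    hypergeometric enrichment p-value.
    """
    cfg = cfg or InductionConfig()
    n = table.n_objects
    feats = sorted(table.features)
    codes: dict[str, np.ndarray] = {}
    values: dict[str, list[str]] = {}
    for f in feats:
        codes[f], values[f] = _factorize_sorted(table.df[f])
        if len(values[f]) > max(20, int(np.sqrt(n))):
            try:
                [float(v) for v in values[f]]
            except ValueError:
                continue  # many labels, but not numeric: accept as discrete
            raise ValueError(
                f"column {f!r} has {len(values[f])} distinct numeric values and looks "
                "continuous; discretize it first (see equal_frequency_binning)"
            )
    dec_codes, classes = _factorize_sorted(table.df[table.decision])
    n_classes = len(classes)
    K = np.bincount(dec_codes, minlength=n_classes)

    # (frozenset of Condition, class index) -> (accuracy, pvalue, support, k)
    stats: dict[tuple[frozenset, int], tuple[float, float, int, int]] = {}
    candidates: list[tuple[frozenset, int, int, float, float]] = []

    for length in range(1, cfg.max_len + 1):
        for fs in itertools.combinations(feats, length):
            radices = [len(values[f]) for f in fs]
            n_cells = int(np.prod(radices))
            cell = np.zeros(n, dtype=np.int64)
            for f, radix in zip(fs, radices):
                cell = cell * radix + codes[f]
            counts = np.bincount(
                cell * n_classes + dec_codes, minlength=n_cells * n_classes
            ).reshape(n_cells, n_classes)
            supports = counts.sum(axis=1)
            occupied = np.flatnonzero(supports)
            if occupied.size == 0:
                continue
            # vectorized upper-tail hypergeometric p-values per outcome
            pvals = np.empty((occupied.size, n_classes))
            for oi in range(n_classes):
                pvals[:, oi] = hypergeom.sf(
                    counts[occupied, oi] - 1, n, int(K[oi]), supports[occupied]
                )
            for row, ci in enumerate(occupied):
                # decode the cell index into per-feature values
                vals = []
                rem = int(ci)
                for radix in reversed(radices):
                    vals.append(rem % radix)
                    rem //= radix
                vals.reverse()
                conds = frozenset(
                    Condition(f, values[f][v]) for f, v in zip(fs, vals)
                )
                supp = int(supports[ci])
                for oi in range(n_classes):
                    k = int(counts[ci, oi])
                    acc = k / supp
                    p = float(pvals[row, oi])
                    stats[(conds, oi)] = (acc, p, supp, k)
                    if supp >= cfg.min_support and acc >= cfg.min_accuracy:
                        candidates.append((conds, oi, supp, float(acc), p))

    prevalence = K / n
    rules: list[Rule] = []
    for conds, oi, supp, acc, p in candidates:
        if cfg.prune == "accuracy":
            if acc <= prevalence[oi] or not _beats_subs_accuracy(conds, oi, acc, stats):
                continue
        elif cfg.prune == "significance":
            k = stats[(conds, oi)][3]
            if p >= cfg.alpha or not _enriched_within_subs(
                conds, oi, supp, k, stats, cfg.alpha
            ):
                continue
        rules.append(
            Rule(
                lhs=conds,
                outcome=Condition(table.decision, classes[oi]),
                support=supp,
                accuracy=acc,
                id=f"r{len(rules) + 1}",
                pvalue=p,
            )
        )
    return RuleSet(rules, table.decision)


def _beats_subs_accuracy(
    conds: frozenset,
    oi: int,
    acc: float,
    stats: Mapping[tuple[frozenset, int], tuple[float, float, int, int]],
) -> bool:
    """True iff accuracy strictly exceeds every proper sub-conjunction's."""
    for r in range(1, len(conds)):
        for sub in itertools.combinations(conds, r):
            entry = stats.get((frozenset(sub), oi))
            if entry is not None and acc <= entry[0]:
                return False
    return True


def _enriched_within_subs(
    conds: frozenset,
    oi: int,
    supp: int,
    k: int,
    stats: Mapping[tuple[frozenset, int], tuple[float, float, int, int]],
    alpha: float,
) -> bool:
    """True iff the rule is conditionally enriched inside every proper
    sub-conjunction's support.

    For sub-rule s the null is that the extra conditions are independent
    of the class among s's objects: P(X >= k) with
    X ~ Hypergeometric(N=supp_s, K=k_s, n=supp_rule) must fall below
    ``alpha``.  This blocks cascades of specializations that merely
    re-express a generalization's (possibly chance) signal.
    """
    for r in range(1, len(conds)):
        for sub in itertools.combinations(conds, r):
            entry = stats.get((frozenset(sub), oi))
            if entry is None:
                continue
            _, _, supp_s, k_s = entry
            p_cond = float(hypergeom.sf(k - 1, supp_s, k_s, supp))
            if p_cond >= alpha:
                return False
    return True


def _rule_priors(rs: RuleSet) -> dict[str, float]:
    # proxy for the training class priors when no table is supplied:
    # total support*accuracy mass per class
    mass: dict[str, float] = {c: 0.0 for c in rs.outcome_classes}
    for r in rs:
        if r.accuracy is not None:
            mass[r.outcome.value] += r.support * r.accuracy
    total = sum(mass.values())
    if total > 0:
        mass = {c: v / total for c, v in mass.items()}
    return mass


def classify(
    rs: RuleSet, obj: Mapping[str, str], priors: Mapping[str, float] | None = None
) -> tuple[str, dict[str, float], str | None]:
    """Classify a single object by rule voting.

    Every rule whose LHS the object satisfies casts ``support*accuracy``
    votes for its outcome; the predicted class is the argmax of the
    summed votes.  Ties go to the class with the larger training prior,
    then lexicographically.  If no rule fires, the majority-prior class
    is returned with the flag ``"unclassified-fallback"``.

    Returns ``(predicted_class, votes, flag)``.
    """
    if not len(rs):
        raise ValueError("cannot classify with an empty rule set")
    priors = dict(priors) if priors is not None else _rule_priors(rs)
    votes: dict[str, float] = {c: 0.0 for c in rs.outcome_classes}
    fired = False
    for r in rs:
        if r.accuracy is not None and r.matches(obj):
            votes[r.outcome.value] += r.support * r.accuracy
            fired = True
    if not fired:
        fallback = max(priors or votes, key=lambda c: (priors.get(c, 0.0), c))
        return fallback, votes, UNCLASSIFIED_FALLBACK
    best = max(votes, key=lambda c: (votes[c], priors.get(c, 0.0), c))
    return best, votes, None


def classify_table(
    rs: RuleSet,
    table: DecisionTable,
    priors: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame, list[str | None]]:
    """Vectorized rule voting over all rows of a table.

    Returns ``(predictions, votes, flags)`` where ``votes`` is an
    objects x classes DataFrame of summed ``support*accuracy`` votes.
    """
    if not len(rs):
        raise ValueError("cannot classify with an empty rule set")
    priors = dict(priors) if priors is not None else _rule_priors(rs)
    class_list = sorted(set(rs.outcome_classes) | set(priors))
    cidx = {c: i for i, c in enumerate(class_list)}
    votes = np.zeros((table.n_objects, len(class_list)))
    fired = np.zeros(table.n_objects, dtype=bool)
    for r in rs:
        if r.accuracy is None:
            continue
        m = table.mask(r.lhs)
        votes[m, cidx[r.outcome.value]] += r.support * r.accuracy
        fired |= m
    # argmax with (vote, prior, label) tie-breaking, vectorized over rows
    prior_arr = np.array([priors.get(c, 0.0) for c in class_list])
    order = sorted(range(len(class_list)), key=lambda i: (prior_arr[i], class_list[i]))
    rank = np.empty(len(class_list))
    rank[order] = np.arange(len(class_list))
    best = np.argmax(votes + rank[None, :] * 1e-12, axis=1)
    preds = np.array(class_list, dtype=object)[best]
    fallback = max(class_list, key=lambda c: (priors.get(c, 0.0), c))
    preds[~fired] = fallback
    flags: list[str | None] = [
        None if f else UNCLASSIFIED_FALLBACK for f in fired
    ]
    votes_df = pd.DataFrame(votes, columns=class_list)
    return preds, votes_df, flags


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold accuracies and pooled predictions."""

    fold_count: int
    fold_accuracies: list[float]
    mean_accuracy: float
    predictions: pd.Series
    flags: list[str | None] = field(default_factory=list)


def cross_validate(
    table: DecisionTable,
    cfg: InductionConfig | None = None,
    folds: int | str = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold (or leave-one-out) cross-validation.

    ``folds`` is an integer k or ``"loo"``.  Folds are stratified by
    class and seeded; each fold's rules are induced on the training
    part and the held-out objects are classified by voting with the
    training-part class priors.
    """
    cfg = cfg or InductionConfig()
    n = table.n_objects
    if folds == "loo":
        k = n
        assignment = np.arange(n)
    else:
        k = int(folds)
        if k < 2 or k > n:
            raise ValueError(f"folds must be in [2, {n}], got {k}")
        rng = np.random.default_rng(seed)
        assignment = np.empty(n, dtype=int)
        pos = 0
        dec = table.df[table.decision].to_numpy()
        for cls in sorted(np.unique(dec)):
            idx = np.flatnonzero(dec == cls)
            rng.shuffle(idx)
            assignment[idx] = (np.arange(idx.size) + pos) % k
            pos += idx.size
    preds = pd.Series(index=range(n), dtype=object)
    all_flags: list[str | None] = [None] * n
    fold_accuracies: list[float] = []
    truth = table.df[table.decision].to_numpy()
    for fold in range(k):
        test_mask = assignment == fold
        train = DecisionTable(table.df.loc[~test_mask], table.decision)
        test = DecisionTable(table.df.loc[test_mask], table.decision)
        if len(set(train.df[train.decision])) < len(set(truth)):
            warnings.warn(f"fold {fold}: a class is absent from the training part")
        rules = induce_rules(train, cfg)
        counts = train.class_counts()
        total = sum(counts.values())
        priors = {c: v / total for c, v in counts.items()}
        if len(rules):
            p, _, flags = classify_table(rules, test, priors=priors)
        else:
            fallback = max(priors, key=lambda c: (priors[c], c))
            p = np.array([fallback] * test.n_objects, dtype=object)
            flags = [UNCLASSIFIED_FALLBACK] * test.n_objects
        where = np.flatnonzero(test_mask)
        for j, i in enumerate(where):
            preds.iloc[i] = p[j]
            all_flags[i] = flags[j]
        fold_accuracies.append(float(np.mean(p == truth[test_mask])))
    return CVResult(
        fold_count=k,
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        predictions=preds,
        flags=all_flags,
    )
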
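# Methods

This note documents the models and procedures implemented in `rulenet`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Rules, decision tables and the connection score

A *decision table* is an objects × features matrix of discrete string
labels with one designated decision column.  A *rule* is a conjunction
of `feature=value` conditions (its LHS) implying one value of the
decision feature; its *support* is the number of objects satisfying the
LHS and its *accuracy* is P(RHS | LHS) estimated on the table.
Continuous data must be discretized first (see below); the rule
machinery is deliberately restricted to discrete labels so that a
condition is an exact, countable event.

The network layer scores every unordered pair of conditions x, y by

    connection(x, y) = Σ_{r ∈ R(x,y)} support(r) · accuracy(r),

R(x, y) being the rules that contain both conditions (for the
per-outcome network, restricted to rules of that outcome).  A rule with
m conditions contributes its support·accuracy to all C(m, 2) pairs;
single-condition rules contribute nothing.  The score is additive over
rule sets and symmetric in x and y; both properties are enforced by
tests against an independent brute-force reference.  One network is
built per outcome class, plus a *combined* network over all rules in
which each edge also records a per-outcome score breakdown.

Node order on the circle: features alphabetically, values within a
feature in increasing order (numeric order when all of a feature's
values parse as numbers, otherwise lexicographic).  This single rule
keeps categorical labels and binned intervals such as `2` vs `10`
ordered sensibly.  Edge filters (`top_n`, `min_score`) break score ties
by the pair's (feature, value) labels so filtered networks are
deterministic.

## Discretization

`equal_frequency_binning(values, k)` places the k−1 cut points at the
empirical quantiles of the sorted column (`sorted[n·j/k]`), yielding
left-closed/right-open intervals labeled `[lo,hi)` with the outermost
bounds rendered `*`.  A cut that does not split the data (ties at the
quantile, constant columns) is dropped with a warning, so fewer bins
may be produced.  `discretize_decision` applies explicit cuts; a value
equal to a cut goes to the upper interval (half-open convention), and
by default labels are `"0", "1", ...` in interval order.

## Rule induction

The learner enumerates every condition conjunction up to `max_len`
(default 3) that occurs in the data, counts its support and per-class
accuracy with vectorized bincounts, and emits one rule per outcome
class passing `min_support` (default 2) and `min_accuracy` (default
0.5).  At the intended scale — tens of discrete features, conjunction
length ≤ 3 — the enumeration is exact; it is not meant for
high-dimensional data without prior feature selection.

Unpruned, this emits one rule per occupied cell and majority class:
hundreds of chance-level rules on a noisy binary table.  The default
pruning therefore imposes *significance-based minimality*: a rule is
kept only if

1. its upper-tail hypergeometric p-value (the probability of drawing at
   least k class members when support objects are sampled from the
   table) is below `alpha` (default 0.01), and
2. for every proper sub-conjunction s, the rule is *conditionally*
   enriched within s's own support: P(X ≥ k) with
   X ~ Hypergeom(N = support(s), K = k(s), n = support(rule)) below
   `alpha` — specializing a rule must sharpen the class signal beyond
   the generalization itself, otherwise the shorter rule stands.

The conditional form of the second requirement matters.  Comparing two
*global* p-values (rule vs sub-rule, both against the whole-table null)
looks equivalent but is not: when a feature has a chance marginal
association, conditioning it on an independent extra feature halves the
support and, about half the time, sharpens the global p by luck — one
spurious marginal then propagates into a cascade of specialized
near-copies that all vote the same way.  The conditional test measures
exactly the added information of the specialization and blocks such
cascades.  The same parsimony principle drives the superset filter
after induction, and it approximates the behaviour of
minimal-feature-set (reduct-based) rule generators: uninformative
specializations of an already-sufficient rule are not emitted.  The
default `alpha` = 0.01 is deliberately stricter than the conventional
0.05 because a 15-feature binary table at length ≤ 2 already offers
~10³ candidate (cell, outcome) rules, so a 5% per-rule level would
admit dozens of spurious rules into the voting pool.  Two alternative
modes are available: `prune="accuracy"` keeps a rule only if its
accuracy strictly exceeds every proper sub-conjunction's (including the
empty conjunction, i.e. the class prevalence), and `prune=None`
disables pruning; both are useful for inspecting the raw rule space.

### Classification and cross-validation

Each rule whose LHS an object satisfies casts `support · accuracy`
votes for its outcome; the predicted class is the argmax of summed
votes, with ties going to the larger training prior and then
lexicographically.  If no rule fires the majority-prior class is
returned, flagged `unclassified-fallback`.  Cross-validation is
stratified k-fold (or leave-one-out), seeded, inducing rules on each
training part and classifying the held-out objects with the training
priors.

## Rule filtering

Duplicate rules (identical LHS and outcome) collapse to their first
occurrence — the case that arises when rules from leave-one-out folds
over near-identical training sets are merged.  Rule significance is the
exact hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n); when
only (support, accuracy) are available k is reconstructed as
round(support·accuracy), and exact counts are used whenever a table is
supplied.  The *superset filter* removes rule r when some rule s with
the same outcome satisfies LHS(s) ⊊ LHS(r) and p(s) ≤ p(r): shorter
rules are preferred when at least equally significant.  Removal is
evaluated against the full input set; because the remover relation is
transitive along subset chains with non-increasing p-values, the result
is idempotent and independent of rule order (property-tested).

## Interaction detection

For conditions x₁..x_k and an outcome class with prevalence π, the
observed accuracy is P(out | x₁..x_k) and the expected accuracy under
independent multiplicative effects is

    expected = min(1, π · Π_i P(out | x_i) / π).

Effect sizes are relative risks from the 2×2 table of the full
condition set against its complement (exposed = all conditions hold),
with the standard log-normal 95% CI
`exp(ln RR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`; zero cells
propagate to 0/∞ and are rendered `*`.

The *expected RR* must live on the same exposed-vs-complement scale as
the observed RR to be comparable.  Multiplying the k single-condition
RRs (each taken against its own single-condition complement) does not:
on data constructed to satisfy the multiplicative model exactly, that
product differs systematically from the joint RR and a test based on it
rejects a true null at ~50%.  Instead the expected exposed risk r =
expected accuracy is converted to an expected unexposed risk
q = (π − r·p_S)/(1 − p_S) (p_S the exposed fraction), and expected RR
= r/q.  Under an exactly multiplicative null this equals the true RR,
so the comparison is calibrated.

A condition set is flagged *significant* when the expected RR falls
outside the observed RR's 95% CI **and** the observed accuracy exceeds
the expected accuracy — one-directional, since only effects greater
than the independence prediction indicate an interaction.  Because the
expected RR is a plug-in estimate from the same sample, the test is
conservative under the null (measured false-positive rate ≪ 5% at
n = 1000) while retaining >90% power for simulated pairs with
interaction probability ≥ 0.5 at n = 1000.  Any arity ≥ 2 is supported;
three-way hypotheses combine the three single-condition effects the
same way.  No multiple-testing correction is applied to the per-edge
tests; the ranked table is an exploratory screen.

## The simulator

Each dataset has a fair binary decision DEC and, by default, five
*correlated* features and five *interacting pairs* over n = 1000
objects.  Feature C_i (i = 0..4) copies DEC with probability
c = X·i/4 and is otherwise a fair coin, giving expected phi correlation
exactly c (since P(C=DEC) = c + (1−c)/2).  Pair (R_i, S_i) draws R as
a fair coin and, with probability p = Y·i/4, sets S = R when DEC = 1
and S = 1−R when DEC = 0 (otherwise S is a fair coin): equal pair
values predict DEC = 1, opposite values DEC = 0, and each member alone
is uncorrelated with DEC.  Names carry the level as a rounded (half-up)
integer percent: at X = 0.15 the correlated features are C0_0, C1_4,
C2_8, C3_11, C4_15.  Grid generation covers an X × Y lattice with
replicates; replicate r of cell (xi, yi) is seeded with the sequence
(base_seed, xi, yi, r) so every dataset is independently reproducible.

What the simulator emulates: the trade-off between marginal
(correlated) signal and purely epistatic (pair) signal in a small
binary feature panel, including the *masking* phenomenon — rule
learners preferentially pick up correlated features, suppressing rules
that carry the pairs.  What it does not emulate: linkage between
features, non-binary or continuous measurements, class imbalance, and
measurement noise structure of real assays; passing the simulation
tests therefore demonstrates correctness of the machinery and
qualitative behaviour, not performance on any particular biological
dataset.

### Study conditions used by the automated experiments

All experiment sizes are chosen to keep each check well-resolved yet
quick: 50 replicates at n = 1000 for simulator moments and for the
weak-interaction recovery (the recovery network pools rules from the 50
replicate classifiers, mirroring how replicate rule sets are merged to
form an average picture before network construction); 25 replicates for
the masking experiment (X = 0.10, Y = 0.15; shares of the strongest
pair measured on the full table, after removing the two strongest
correlated features, and after removing all four informative ones);
1000 Monte-Carlo replicates for null calibration; and 10 replicates for
the headline classification count recomputed by
`scripts/acceptance.py`.

## Rendering

Nodes occupy arcs clockwise from 12 o'clock in network node order, arc
width proportional to node weight scaled so that the arcs plus a
configurable inter-node gap (default 2°) cover the full circle.  Each
node's incident edges subdivide its arc proportionally to their score,
packed in partner order; the inner ring repeats those sub-arcs in the
partner node's color.  Edge stroke width interpolates linearly over a
configured range (default 1–12 px) and edge color linearly in RGB from
yellow `#FFFF00` (minimum displayed score) to red `#FF0000` (maximum);
a degenerate single-score range maps to the red/thick endpoint.  Node
colors come from a categorical palette keyed by feature so both value
nodes of one feature share a hue.  The SVG is assembled with the
stdlib XML tools, formats coordinates to fixed precision, and is
byte-deterministic for a given network; element ids encode the
condition pair and outcome, which the static interactive HTML export
uses to bind click (and Ctrl-multi-select intersection) rule lookups
from an embedded JSON sidecar — no server required.

## Known limitations

- The learner's exhaustive enumeration is exponential in `max_len`;
  it is intended for small, pre-selected feature panels.
- Voting weights equal support·accuracy; on tables where a few
  high-support chance rules survive pruning they can still tilt
  borderline objects.
- The interaction test conditions on the observed margins and uses a
  plug-in expectation; it is conservative rather than exact, and the
  ranked screen applies no multiple-testing correction.
- The circular layout is a faithful-topology rendering, not a pixel
  clone of any particular chord-diagram tool.
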
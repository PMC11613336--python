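# Methods

## Scope and data model

`fcmkit` analyses fuzzy cognitive maps: directed graphs of causal beliefs
elicited from stakeholder groups. The package covers the computational
analysis only — map elicitation, member checking and facilitation are social
procedures outside its scope, as are FCM state-space simulation with
activation functions (a different FCM tradition) and learning/Bayesian
extensions.

Weights arrive on a signed 1–5 elicitation scale and are scaled linearly to
magnitudes |w|/5 ∈ [0, 1]; the linear rule preserves the equal spacing of
the elicitation scale. An unreported link is exactly 0. Storage is bipolar
— per ordered pair a positive magnitude w⁺ and a negative magnitude w⁻ —
because (a) the closure produces separate TC⁺/TC⁻ matrices anyway and (b)
maps merged across sources can legitimately carry both signs on one pair.
Factor identity is the exact label after Unicode NFC normalization and
whitespace trimming; all semantic matching is delegated to an explicit
lexicon, which may qualify entries by knowledge source (the same phrase can
code differently in different communities). Self-links are rejected at
factor level and permitted at category level, where they summarise a
category's internal dynamics.

Weights are serialized with 6 decimals; comparisons use absolute tolerance
1e−9; display rounding (one decimal in correspondence and disagreement
reports) happens only at rendering, never inside computation.

## Fuzzy closure

TC⁺(i, j) is the maximum over all positive-sign walks i→j (even number of
negative links) of the minimum traversed magnitude; TC⁻ is the odd-parity
analogue. Both are computed on the parity-doubled auxiliary graph — two
copies of every node, positive links preserving parity, negative links
flipping it — by a max–min Floyd–Warshall pass, O(k³) on 2k nodes. This
handles mixed-sign walks and cycles without walk enumeration: revisiting a
node can never raise a walk's minimum, so the recursion converges.

Witness walks are recovered after the pass rather than by predecessor
tracking: a walk achieves bottleneck value b from i iff it stays on links of
weight ≥ b, so a breadth-first search on that threshold subgraph returns the
*shortest* walk attaining the maximum, deterministically for a fixed factor
order (adjacency is scanned in factor order). `strongest_walks` ranks
witnesses by weight, then length, then lexicographic node order.

## Probabilistic closure

Magnitudes are read as independent transmission probabilities. The
definition of a walk's weight (product of its link weights) does not by
itself fix how multiple walks combine; two combination rules are provided
and results carry the rule that produced them:

* **reliability** (default) — TC±(i, j) is the probability that at least
  one transmitting path of the required sign parity exists. This is
  two-terminal network reliability on the parity-doubled graph; it reduces
  to the plain product on a single chain. Exact values are computed by
  recursive factoring (condition on one undecided link; prune when the
  present links already realise the path or when even all undecided links
  cannot), restricted per ordered pair to the links on some path between
  the pair; pairs with more than 25 relevant links are refused with a
  pointer to Monte Carlo. Monte Carlo sampling (seed mandatory — no silent
  default; 100 000 samples by default) evaluates reachability per
  realisation by batched boolean matrix squaring and reports the binomial
  standard error per pair.
* **max_product** — the single strongest path product, a max-product
  semiring closure, for users who want a per-pair "best pathway" value
  rather than a union probability.

## Disagreement

d̄ = Σ|d|/N with |d| the absolute difference of net-TC weights of the same
link in two sources. N is defined as the number of links with nonzero net
weight in at least one of the two sources: absence of a link is weight 0 and
participates in |d|, but links absent from both sources carry no
information and are not counted. On the bundled postpartum columns this
convention reproduces the published one-decimal triple exactly (5.6/20,
5.6/14, 8.0/18). Outcome scope compares the influence columns into a
designated outcome; whole-map scope compares full net matrices over the
union factor set and additionally reports Σ|d|/k². d̄ ∈ [0, 2];
normalisation divides by 2, the value attained when one source puts +1 and
the other −1 on every link. Harris (morpheme-frequency) weighting counts
link presence across a group's maps per sign slot, giving
operator-independent weights; `compare_weighting` applies the same d̄
machinery to participant- vs frequency-weighted maps.

## Reduction

Categorization assigns each factor to exactly one theme (strict by default;
a catch-all bucket is available) and keeps the factor-level map for
drill-down. Condensation sums all member-pair weights between categories
per sign slot — totals are conserved, the diagonal holds self-loops, and
results are flagged `category-sum` because values can exceed 1; they are
never fed back into closure without explicit renormalization. Aggregation
averages instead over *all possible* ordered member pairs (|A|·|B|
denominator, |A|² for self-loops, consistent with the whole-map k²
convention; absent links count as 0), staying in [0, 1]; a switch excludes
the |A| diagonal cells from self-loop denominators since the convention for
the diagonal is genuinely open, and singleton categories then report 0.
Relevance-weighted aggregation multiplies each term by r(origin)·r(landing)
and divides by the summed products. Restriction keeps the top-k strongest
links (ties at the cut retained together) or those above a threshold,
whole-map or per landing factor, and always emits a full audit table so no
relationship disappears silently. Category-level outputs carry a level tag;
category-level relationships must not be read like factor-level ones.

## Centralities

Computed on the closure re-read as a map (a raw map triggers a warning:
before closure the "network" is only a pile of individual associations).
A bipolar pair counts as two arrows in degree measures — each sign is a
distinct stated influence; weighted centrality sums |w|. Betweenness uses
unweighted directed hop-count shortest paths by default (Brandes via
networkx, endpoints excluded, self-loops dropped); a weighted variant with
distance 1 − |w| is available since the hop-count convention is not the
only defensible one. All measures are scaled by their maximum to [0, 1];
an all-zero vector stays zero. Scaled values map linearly onto node sizes
for GraphML export.

## Synthetic data

The generators emulate elicitation conditions: links appear independently
with a density probability, raw magnitudes uniform on {1..5}, signs negative
with probability `neg_prob`; groups default to 12 maps (map collection
typically saturates at 12–15 per stakeholder group) and member maps drop
links, jitter magnitudes by ±`jitter_levels` (clipped to 1..5) and replace
labels with synonyms recorded in a returned ground-truth lexicon.
`generate_pair_with_disagreement` builds star maps whose d̄ equals a target
exactly, for calibration tests. All generators are pure functions of their
parameters and a mandatory seed (numpy `default_rng`).

What the generators do *not* model: correlated link reporting, facilitator
and session effects, systematic sign disagreement between groups, and the
heavy-tailed factor counts of real maps. Passing tests on synthetic maps
therefore demonstrate algorithmic correctness (closures match enumeration
oracles, statistics match their definitions), not robustness to real-world
elicitation artefacts.

## Test problem sizes

Oracle sweeps use maps of 3–6 factors (fuzzy closure vs length-bounded walk
enumeration, 200 seeded maps; betweenness vs exhaustive path enumeration),
probabilistic exact mode is checked against full link-subset enumeration on
maps of ≤ 13 links, and Monte Carlo (20 000 samples) against exact values
within 4 standard errors. The pipeline monotonicity check (d̄ non-decreasing
in magnitude jitter) averages 20 seeds over jitter levels 0–3 with two
4-map groups of 6 factors. These sizes make every oracle exact while keeping
the whole suite fast; the algorithms themselves are polynomial (fuzzy
closure O(k³)) and handle realistic maps of tens of factors directly.

## Known limitations

* Exact reliability is exponential in the worst case; the 25-relevant-link
  cap is conservative and dense maps need Monte Carlo.
* The reliability rule assumes independent link transmission; correlated
  links are out of scope.
* One witness walk is recorded per (pair, sign); enumerating all maximal
  walks is not supported.
* The bundled midwife tables encode 22 coded factors that the source
  analysis summarised as 20 unique factors in 12 themes; the full coded
  rows are kept and the theme count (12) is what the reduction operators
  consume.
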
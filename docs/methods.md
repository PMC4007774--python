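# Methods

## Setting and model

An icon is a partial assignment of primitives to five slots (components):
central color, shape, central pictogram, top-right color, top-right
pictogram. Central color and shape are mandatory; only the top-right
pictogram slot is multi-valued by default (component arity is configuration,
not a constant). All primitives hang under one *virtual root*, each inside
its own component subtree, at most six levels deep. The single shared root
is what makes cross-component similarity exactly zero: two primitives from
different components share no ancestor but the root, whose probability is 1
and log-probability 0.

Ancestor closures are self-inclusive (a primitive is its own ancestor).
This convention makes sim(x, x) = 1 fall out of the Lin formula without a
special case, and makes "shared ancestors contain x iff x is an
ancestor-or-self of the other" hold exactly.

## Corpus probabilities and Lin similarity

`p(Pr)` is estimated from a corpus of icon alignments by **cumulative
(descendant-inclusive) counting**: every occurrence of a primitive also
counts toward all of its ancestors. This is the only counting scheme under
which p(root) = 1 exactly, and hence Lin similarity is 0 precisely when the
root is the only common ancestor. Two estimator choices are configurable:

* **occurrence weighting** (`per_relation`, default): each alignment record
  is one occurrence, so an icon aligned to k concepts counts k times;
  `per_icon` counts each distinct icon once. The relation-level reading
  matches a corpus defined as "the entire set of alignments".
* **add-one smoothing** (default on): one pseudo-count per primitive's
  direct count, so no primitive has p = 0 and log p is always finite.
  Deterministic and minimal; it matters only for primitives never used in
  the corpus.

Lin similarity is computed with natural logs; the value is a ratio of logs
and therefore base-invariant (the test oracle uses base 10). Degenerate
case: if two *different* primitives both have p = 1 the ratio is 0/0 and is
defined as 0, continuous with the root case.

`dsc_semantic` takes the pairwise similarity source as a parameter. That is
what allows the packaged worked example to inject its two tabulated
similarities (0.85, 0.35) — those numbers came from a corpus that cannot be
reconstructed, so they are inputs, never outputs, of this package.

## Icon inheritance

A concept with no manual alignment inherits the icon set of its *closest*
manually aligned ancestor(s): breadth-first search upward through all
parents, distance = number of parent edges (node counting and edge counting
give the same argmin on unit steps). Two open points were settled as
package policy:

* **ties**: ancestors tied at the minimal distance contribute the union of
  their icon sets, deduplicated — deterministic and information-preserving;
* **sources**: only manual records seed inheritance; automatic records are
  never chained through. This makes the operation idempotent and keeps the
  provenance semantics clean (an automatic record always traces to a manual
  one).

## Evaluation pipeline

Concept pairs are formed per shared cross identifier (cartesian per id,
deduplicated — a pair sharing two ids still appears once). Pairs where
either side carries more than one icon are excluded, because three-way icon
comparison is not defined here; the retained fraction is reported. Each
retained pair is scored with the three metrics and stratified by the
provenance of the poly-hierarchic side's record.

Statistics: Wald (normal-approximation) 95% CI for the concordance
proportion — this is the interval form that reproduces the published
[70.5–78.0] for 392/528 exactly, identifying the method used in the field —
and a normal-approximation CI for Dice means (a seeded percentile bootstrap
is available behind `ci_method="bootstrap"`; whether the original interval
was normal or bootstrap is not documented, and at n of a few hundred the
two agree to ~0.01). Between-stratum comparisons: Fisher's exact test on
the 2×2 concordance table (binary outcome) and two-sided Wilcoxon rank-sum
on each Dice metric (continuous outcome). Printed counts behind published
percentages are recovered as round(p̂·n).

The worst-case sensitivity analysis scores all excluded pairs 0 on every
metric: concordance becomes c/(n+e), Dice means scale by n/(n+e). It is
monotone non-increasing in the number of excluded pairs.

Rounding: human-readable rendering uses one decimal for percentages and two
for Dice values; the JSON report keeps full precision and round-trips
exactly.

## Synthetic worlds

The generator emulates the structure of the real setting: ~221 primitives
over five components on ≤6 levels; a poly-hierarchic terminology (up to 11
levels, second parents with probability 0.3) of 1000 concepts; a
mono-hierarchic terminology of 700; cross-links on 80% of the smaller side
(560 pairs — enough for stable summary statistics); one third of the
cross-linked poly-side concepts aligned manually, mirroring the 528/1,606
manual share of the published evaluation. Background manual alignments
(probability 0.2 per backbone concept) give the information-content corpus
realistic mass beyond the cross-linked pairs.

Every cross-linked pair starts from one "true" icon: a leaf-biased sample
of a central color and a shape, plus optional slots (central pictogram with
probability 0.9, top-right color 0.4, top-right pictogram 0.5, occasionally
two of them). The mono side's copy, and the source icon of the poly side's
automatic branch, are each perturbed independently with probability δ by
replacing one primitive with a random sibling (`sibling-swap`) or its
parent (`parent-generalization`); the replacement stays in the same
component, so arity is never violated. Manual poly-side alignments are not
perturbed — they play the validated-reference role. A concept in the
automatic branch hangs under a dedicated manually aligned parent carrying
the copy, and its optional second parent is drawn only from unaligned
backbone nodes, so closest-ancestor inheritance reconstructs exactly the
intended icon (this is what makes δ = 0 recover concordance 1.0 *exactly*
through the full pipeline, inheritance included). In the vanishingly rare
case that an icon offers no valid substitution target, the perturbation
falls back to swapping the central color for another color primitive.

Randomness: one `SeedSequence` per run, spawned into independent per-stage
streams, so adding a stage never shifts downstream draws; a sweep derives
one child seed per rate from the base seed, making sweep tables
reproducible but leaving independent Monte-Carlo noise between rates
(monotonicity checks therefore carry a small tolerance).

What the generator does **not** emulate: real label text or code syntax,
the grammar/consistency rules that forbid some primitive combinations in
the real iconic language, human error structure (real discordances cluster
on specificity differences, not uniform random substitutions), multi-icon
alignments, and cross-link noise (every synthetic CUI link is correct).
Passing the synthetic suites therefore shows that the *machinery* —
metrics, inheritance, pairing, stratification, tests — is correct and
well-calibrated, not that real alignments reach any particular agreement
level.

## Known limitations

* The primitive hierarchy is a strict tree per component; multi-parent
  primitives are not supported (poly-hierarchy is a terminology feature
  here).
* Pairs with multiple icons on a side are excluded rather than scored; the
  sensitivity analysis bounds, but does not estimate, their effect.
* Wald intervals degenerate at p̂ ∈ {0, 1}; they are used because they are
  the identified published method, not because they are optimal (a
  Wilson or bootstrap interval would behave better near the boundary).
* The semantic Dice depends on the corpus through p(Pr); two corpora give
  two different similarity scales, so semantic values are only comparable
  within one corpus.
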
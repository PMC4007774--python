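"""Icon-to-icon similarity metrics.

Three metrics compare two icons built from hierarchical primitives:

* **concordance** — are the icons identical, component by component?
* **crude Dice** — ``2 |Pr(I1) ∩ Pr(I2)| / (|Pr(I1)| + |Pr(I2)|)`` on the
  flattened primitive sets;
* **semantic Dice** — each primitive of each icon contributes the *best*
  pairwise similarity against the other icon's primitives, summed over
  both directions and divided by the same denominator. With any
  similarity source satisfying sim(x, x) = 1 and sim ≥ 0, the semantic
  coefficient dominates the crude one.

The default pairwise similarity is Lin's information-content measure over
the primitive hierarchy: ``sim(x, y) = 2 log p(a*) / (log p(x) + log p(y))``
where ``a*`` is the most informative (lowest-probability) common ancestor
and ``p`` is the probability of meeting a primitive — or any of its
descendants — in a reference corpus of icon alignments. It is 1 for
identical primitives and 0 when the only shared ancestor is the root.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping

from .icon_model import ROOT, Icon, PrimitiveHierarchy, icons_identical
from .terminology import Terminology

#: A pairwise primitive similarity source.
SimilaritySource = Callable[[str, str], float]


class CorpusError(ValueError):
    """Raised when corpus probabilities cannot be built."""


class CorpusProbabilities:
    """Occurrence-derived probability p(Pr) for every primitive.

    Counting is cumulative (descendant-inclusive): an occurrence of a
    primitive also counts toward all of its ancestors, so p is monotone
    non-decreasing toward the root and p(root) = 1 exactly. With add-one
    smoothing every primitive has a strictly positive direct count, so
    log p is always defined.

    Parameters
    ----------
    direct_counts:
        Raw (pre-smoothing) occurrence count per primitive id. Missing
        primitives count 0.
    hierarchy:
        The primitive hierarchy the counts refer to.
    smoothing:
        If true (default), add one to every primitive's direct count.
    """

    def __init__(
        self,
        direct_counts: Mapping[str, float],
        hierarchy: PrimitiveHierarchy,
        *,
        smoothing: bool = True,
    ):
        self.hierarchy = hierarchy
        add = 1.0 if smoothing else 0.0
        self.direct_counts: dict[str, float] = {}
        for pid in hierarchy.ids():
            self.direct_counts[pid] = float(direct_counts.get(pid, 0.0)) + add
        for pid in direct_counts:
            if pid not in hierarchy or pid == ROOT:
                raise CorpusError(f"count for unknown primitive {pid!r}")

        self.total = sum(self.direct_counts.values())
        if self.total <= 0:
            raise CorpusError("corpus has no primitive occurrences")

        # cumulative count: sum of direct counts over descendants-or-self
        cumulative: dict[str, float] = {pid: 0.0 for pid in hierarchy.ids()}
        cumulative[ROOT] = 0.0
        for pid, count in self.direct_counts.items():
            for anc in hierarchy.ancestors(pid):
                cumulative[anc] += count
        self.counts = cumulative

        self._p: dict[str, float] = {
            pid: c / self.total for pid, c in cumulative.items()
        }
        self._log_p: dict[str, float] = {
            pid: (math.log(v) if v > 0.0 else float("-inf"))
            for pid, v in self._p.items()
        }

    def p(self, pid: str) -> float:
        """Probability of meeting ``pid`` or any of its descendants."""
        try:
            return self._p[pid]
        except KeyError:
            raise CorpusError(f"unknown primitive: {pid!r}") from None

    def log_p(self, pid: str) -> float:
        try:
            return self._log_p[pid]
        except KeyError:
            raise CorpusError(f"unknown primitive: {pid!r}") from None


def build_corpus_probabilities(
    terminologies: Iterable[Terminology],
    icons: Mapping[str, Icon],
    hierarchy: PrimitiveHierarchy,
    *,
    smoothing: bool = True,
    weighting: str = "per_relation",
) -> CorpusProbabilities:
    """Derive primitive probabilities from a corpus of icon alignments.

    With ``weighting="per_relation"`` (default) every alignment record
    contributes one occurrence of each primitive of its icon, so an icon
    aligned to k concepts counts k times; ``"per_icon"`` counts each
    distinct referenced icon once.
    """
    if weighting not in ("per_relation", "per_icon"):
        raise CorpusError(f"unknown weighting {weighting!r}")

    occurrences: list[str] = []
    if weighting == "per_relation":
        for t in terminologies:
            occurrences.extend(rec.icon for rec in t.alignments)
    else:
        seen: set[str] = set()
        for t in terminologies:
            seen.update(rec.icon for rec in t.alignments)
        occurrences = sorted(seen)

    if not occurrences:
        raise CorpusError("empty corpus: no alignment records")

    direct: dict[str, float] = {}
    for icon_id in occurrences:
        try:
            icon = icons[icon_id]
        except KeyError:
            raise CorpusError(f"alignment references unknown icon {icon_id!r}") from None
        for pid in icon.primitives():
            direct[pid] = direct.get(pid, 0.0) + 1.0

    return CorpusProbabilities(direct, hierarchy, smoothing=smoothing)


def lin_similarity(
    p: str,
    q: str,
    probs: CorpusProbabilities,
    hierarchy: PrimitiveHierarchy,
) -> float:
    """Lin information-content similarity between two primitives, in [0, 1].

    ``2 log p(a*) / (log p(p) + log p(q))`` with ``a*`` the shared ancestor
    of lowest probability. Identical primitives score 1 (by the formula,
    or by convention when both probabilities are 1 and the ratio is 0/0);
    primitives whose only shared ancestor is the root score 0 because
    p(root) = 1. The value is invariant to the logarithm base.
    """
    if p not in hierarchy or p == ROOT:
        raise CorpusError(f"unknown primitive: {p!r}")
    if q not in hierarchy or q == ROOT:
        raise CorpusError(f"unknown primitive: {q!r}")
    if p == q:
        return 1.0
    den = probs.log_p(p) + probs.log_p(q)
    if den == 0.0:
        # both probabilities are 1 and the primitives differ: 0/0 -> 0
        return 0.0
    log_mica = min(probs.log_p(a) for a in hierarchy.shared_ancestors(p, q))
    value = 2.0 * log_mica / den
    return min(1.0, max(0.0, value))


class LinSimilarity:
    """Callable Lin-similarity source with memoization over primitive pairs."""

    def __init__(self, probs: CorpusProbabilities, hierarchy: PrimitiveHierarchy):
        self.probs = probs
        self.hierarchy = hierarchy
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, p: str, q: str) -> float:
        key = (p, q) if p <= q else (q, p)
        try:
            return self._cache[key]
        except KeyError:
            value = lin_similarity(key[0], key[1], self.probs, self.hierarchy)
            self._cache[key] = value
            return value


class FixtureSimilarity:
    """Pairwise similarity backed by an explicit table.

    Identical primitives score 1 unless overridden; listed pairs score
    their tabulated value (symmetric closure is applied); any other pair
    scores ``default``, or raises ``KeyError`` when ``default`` is None
    (strict mode).
    """

    def __init__(
        self,
        table: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
        *,
        default: float | None = 0.0,
    ):
        self._table: dict[tuple[str, str], float] = {}
        if isinstance(table, Mapping):
            entries = [(a, b, s) for (a, b), s in table.items()]
        else:
            entries = [(a, b, s) for a, b, s in table]
        for a, b, s in entries:
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"similarity out of [0,1] for ({a!r}, {b!r}): {s}")
            self._table[(a, b)] = s
            self._table[(b, a)] = s
        self.default = default

    def __call__(self, p: str, q: str) -> float:
        if (p, q) in self._table:
            return self._table[(p, q)]
        if p == q:
            return 1.0
        if self.default is None:
            raise KeyError(f"no similarity defined for pair ({p!r}, {q!r})")
        return self.default


def dsc_crude(a: Icon, b: Icon) -> float:
    """Crude Dice coefficient on the flattened primitive sets."""
    pa, pb = a.primitives(), b.primitives()
    if not pa and not pb:
        raise ValueError("both icons have empty primitive sets")
    return 2.0 * len(pa & pb) / (len(pa) + len(pb))


def dsc_semantic(a: Icon, b: Icon, sim: SimilaritySource) -> float:
    """Best-match semantic Dice coefficient.

    Each primitive of each icon contributes its best similarity against
    the other icon's primitive set; the two directed sums share the crude
    Dice denominator. Symmetric for any symmetric ``sim``.
    """
    pa, pb = a.primitives(), b.primitives()
    if not pa or not pb:
        raise ValueError("semantic Dice requires non-empty primitive sets on both sides")
    forward = sum(max(sim(x, y) for y in pb) for x in pa)
    backward = sum(max(sim(x, y) for x in pa) for y in pb)
    return (forward + backward) / (len(pa) + len(pb))


def concordant(a: Icon, b: Icon) -> bool:
    """True iff the two icons are identical (exact per-component equality)."""
    return icons_identical(a, b)
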
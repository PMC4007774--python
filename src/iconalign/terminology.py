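"""Terminologies, icon-alignment records and icon inheritance.

Two kinds of hierarchical terminology are modeled: poly-hierarchic
thesauri (MeSH-like, where a concept may have several parents) and
mono-hierarchic classifications (ICD10-like, a strict tree). Concepts
carry cross-terminology identifiers (CUI-like) used to pair concepts of
two terminologies that share a meaning, and alignment records linking a
concept to one or more icons, flagged as hand-made (``manual``) or
machine-derived (``automatic``).

The inheritance procedure mirrors common practice for propagating
annotations down a poly-hierarchy: a concept with no manual alignment
receives the icons of its *closest* manually aligned ancestor(s), closest
meaning minimal number of parent edges, searching upward through all
parents breadth-first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

log = logging.getLogger(__name__)

MANUAL = "manual"
AUTOMATIC = "automatic"
PROVENANCES = (MANUAL, AUTOMATIC)


class LoadError(ValueError):
    """Raised when a terminology fails referential-integrity checks."""


@dataclass(frozen=True)
class Concept:
    """A coded term of a terminology."""

    code: str
    terminology: str
    label: str = ""
    parents: frozenset[str] = frozenset()
    cross_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AlignmentRecord:
    """A concept-to-icon relation with provenance."""

    concept: str
    icon: str
    provenance: str  # MANUAL or AUTOMATIC

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise LoadError(
                f"bad provenance {self.provenance!r} for concept {self.concept!r} "
                f"(expected one of {PROVENANCES})"
            )


class Terminology:
    """A set of concepts with a hierarchy and their icon alignments.

    ``hierarchy_kind`` is ``"mono"`` (each non-root concept has exactly one
    parent) or ``"poly"`` (at least one). Construction validates parent
    resolution, acyclicity and the mono/poly constraint, and that every
    alignment's concept resolves.
    """

    def __init__(
        self,
        id: str,
        hierarchy_kind: str,
        concepts: Iterable[Concept],
        alignments: Iterable[AlignmentRecord] = (),
    ):
        if hierarchy_kind not in ("mono", "poly"):
            raise LoadError(f"hierarchy_kind must be 'mono' or 'poly', got {hierarchy_kind!r}")
        self.id = id
        self.hierarchy_kind = hierarchy_kind
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.code in self.concepts:
                raise LoadError(f"duplicate concept code {c.code!r} in terminology {id!r}")
            self.concepts[c.code] = c

        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            if hierarchy_kind == "mono" and len(c.parents) > 1:
                raise LoadError(
                    f"concept {c.code!r} has {len(c.parents)} parents in "
                    f"mono-hierarchic terminology {id!r}"
                )
            for p in c.parents:
                if p not in self.concepts:
                    raise LoadError(f"concept {c.code!r} references unknown parent {p!r}")
                g.add_edge(c.code, p)  # edge points child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise LoadError(f"cyclic hierarchy in terminology {id!r}: {cycle}")
        self._graph = g

        self.alignments: list[AlignmentRecord] = []
        self._by_concept: dict[str, list[AlignmentRecord]] = {}
        for rec in alignments:
            if rec.concept not in self.concepts:
                raise LoadError(
                    f"alignment references unknown concept {rec.concept!r} "
                    f"in terminology {id!r}"
                )
            self.alignments.append(rec)
            self._by_concept.setdefault(rec.concept, []).append(rec)

    # -- accessors -------------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def concept(self, code: str) -> Concept:
        try:
            return self.concepts[code]
        except KeyError:
            raise LoadError(f"unknown concept {code!r} in terminology {self.id!r}") from None

    def records_for(self, code: str) -> tuple[AlignmentRecord, ...]:
        return tuple(self._by_concept.get(code, ()))

    def icons_for(self, code: str, provenance: str | None = None) -> tuple[str, ...]:
        """Distinct icon ids aligned to ``code``, sorted; optionally by provenance."""
        recs = self._by_concept.get(code, ())
        icons = {r.icon for r in recs if provenance is None or r.provenance == provenance}
        return tuple(sorted(icons))

    def graph(self) -> nx.DiGraph:
        """The child->parent digraph (copy)."""
        return self._graph.copy()

    def replace_alignments(self, alignments: Iterable[AlignmentRecord]) -> "Terminology":
        return Terminology(self.id, self.hierarchy_kind, self.concepts.values(), alignments)


def inherit_icons(t: Terminology) -> Terminology:
    """Propagate icons to unaligned concepts from the closest manual ancestor.

    For every concept with no ``manual`` record, search upward through all
    parents breadth-first (unit edge weights) and stop at the first depth
    at which at least one manually aligned ancestor is found. The concept
    receives ``automatic`` records for the union of those ancestors' icon
    sets (ties at equal distance are merged, deduplicated). Concepts with
    no manually aligned ancestor are left untouched; manual records are
    never modified. Only manual records act as sources, so the procedure
    is idempotent: re-running adds nothing.
    """
    manual_icons: dict[str, tuple[str, ...]] = {}
    for code in t.concepts:
        icons = t.icons_for(code, MANUAL)
        if icons:
            manual_icons[code] = icons

    new_records: list[AlignmentRecord] = []
    n_inherited = 0
    for code, concept in t.concepts.items():
        if code in manual_icons:
            continue
        existing_auto = set(t.icons_for(code, AUTOMATIC))
        # breadth-first search upward over all parents
        frontier = {code}
        visited = {code}
        found: set[str] = set()
        while frontier and not found:
            nxt: set[str] = set()
            for node in frontier:
                for parent in t.concepts[node].parents:
                    if parent not in visited:
                        nxt.add(parent)
            visited |= nxt
            frontier = nxt
            for anc in frontier:
                if anc in manual_icons:
                    found.add(anc)
        if not found:
            continue
        inherited = sorted({icon for anc in sorted(found) for icon in manual_icons[anc]})
        added = [i for i in inherited if i not in existing_auto]
        if added:
            n_inherited += 1
            new_records.extend(AlignmentRecord(code, i, AUTOMATIC) for i in added)

    log.info(
        "inherit_icons: %d concepts received automatic records (%d added)",
        n_inherited, len(new_records),
    )
    return t.replace_alignments(list(t.alignments) + new_records)


def pair_by_cross_id(a: Terminology, b: Terminology) -> list[tuple[str, str]]:
    """All (concept in ``a``, concept in ``b``) pairs sharing a cross id.

    Cartesian per shared identifier, deduplicated, sorted by the pair of
    codes for determinism. Symmetric up to pair orientation.
    """
    index_b: dict[str, list[str]] = {}
    for c in b.concepts.values():
        for cid in c.cross_ids:
            index_b.setdefault(cid, []).append(c.code)

    pairs: set[tuple[str, str]] = set()
    for c in a.concepts.values():
        for cid in c.cross_ids:
            for code_b in index_b.get(cid, ()):
                pairs.add((c.code, code_b))
    return sorted(pairs)


def build_terminology(
    terminology_id: str,
    hierarchy_kind: str,
    concept_rows: Iterable[Mapping],
    alignment_rows: Iterable[Mapping] = (),
) -> Terminology:
    """Assemble a Terminology from row mappings (as read from the TSVs).

    Rows may carry a ``__line__`` key; load errors name the offending line.
    Rows whose ``terminology_id`` differs from ``terminology_id`` are
    skipped, so one file can hold several terminologies.
    """
    concepts = []
    for row in concept_rows:
        if row.get("terminology_id", terminology_id) != terminology_id:
            continue
        parents = frozenset(x for x in str(row.get("parents", "")).split("|") if x)
        cross = frozenset(x for x in str(row.get("cross_ids", "")).split("|") if x)
        concepts.append(
            Concept(
                code=row["code"],
                terminology=terminology_id,
                label=row.get("label", ""),
                parents=parents,
                cross_ids=cross,
            )
        )
    alignments = []
    for row in alignment_rows:
        if row.get("terminology_id", terminology_id) != terminology_id:
            continue
        try:
            alignments.append(
                AlignmentRecord(row["code"], row["icon_id"], row["provenance"])
            )
        except LoadError as exc:
            line = row.get("__line__")
            raise LoadError(f"line {line}: {exc}" if line else str(exc)) from None
    return Terminology(terminology_id, hierarchy_kind, concepts, alignments)


def load_terminology(
    concepts_path,
    alignments_path,
    terminology_id: str,
    hierarchy_kind: str,
) -> Terminology:
    """Load one terminology from ``concepts.tsv`` / ``alignments.tsv`` files."""
    from . import io as _io

    concept_rows = _io.read_concept_rows(concepts_path)
    alignment_rows = _io.read_alignment_rows(alignments_path) if alignments_path else []
    return build_terminology(terminology_id, hierarchy_kind, concept_rows, alignment_rows)
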
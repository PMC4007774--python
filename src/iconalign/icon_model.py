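"""Core model of a compositional iconic language.

An icon (in the style of VCM, *Visualization of Concepts in Medicine*) is
assembled from graphical *primitives* — colors, shapes and pictograms —
each filling one of five *components* (slots): the central color, the
shape, the central pictogram, the top-right color and the top-right
pictogram. The central color and shape are mandatory; the other slots may
be empty, and some slots admit several primitives at once.

Primitives are organised in a shallow rooted hierarchy (by default at most
six levels below a single virtual root), with every primitive's ancestor
chain staying inside its own component. The virtual root is the only node
shared across components, so two primitives from different components have
no common ancestor besides the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

#: Reserved identifier of the virtual root spanning all components.
ROOT = "ROOT"


class HierarchyError(ValueError):
    """Raised for a structurally invalid primitive hierarchy."""


class IconError(ValueError):
    """Raised for structural errors while inspecting an icon (e.g. an
    assignment naming a component that does not exist)."""


@dataclass(frozen=True)
class Component:
    """One of the icon's slots.

    ``required`` components must carry at least one primitive in a valid
    icon; ``multi_valued`` components may carry more than one.
    """

    id: str
    name: str
    required: bool = False
    multi_valued: bool = False


def default_components() -> dict[str, Component]:
    """The five modeled icon slots, keyed by id.

    Central color and shape are mandatory and single-valued; the top-right
    pictogram slot is the one allowed to hold several primitives.
    """
    comps = (
        Component("central-color", "Central color", required=True),
        Component("shape", "Shape", required=True),
        Component("central-pictogram", "Central pictogram"),
        Component("top-right-color", "Top-right color"),
        Component("top-right-pictogram", "Top-right pictogram", multi_valued=True),
    )
    return {c.id: c for c in comps}


@dataclass(frozen=True)
class Primitive:
    """An atomic icon building block.

    ``parent`` is another primitive id in the same component, or :data:`ROOT`
    for component-top primitives.
    """

    id: str
    label: str
    component: str
    parent: str


class PrimitiveHierarchy:
    """Rooted tree over all primitives of all components.

    Ancestor closures are self-inclusive and always contain :data:`ROOT`;
    they are precomputed at construction time (the hierarchy is small, a
    few hundred nodes).

    Parameters
    ----------
    primitives:
        The full set of primitives. Parents must resolve within the set
        (or be :data:`ROOT`) and stay within the primitive's component.
    max_depth:
        Maximum allowed number of levels below the root (default 6, the
        depth of the iconic language this package models). Pass ``None``
        to disable the check.
    """

    def __init__(self, primitives: Iterable[Primitive], *, max_depth: int | None = 6):
        self._prims: dict[str, Primitive] = {}
        for p in primitives:
            if p.id == ROOT:
                raise HierarchyError(f"primitive id {ROOT!r} is reserved for the virtual root")
            if p.id in self._prims:
                raise HierarchyError(f"duplicate primitive id: {p.id!r}")
            self._prims[p.id] = p
        if not self._prims:
            raise HierarchyError("empty hierarchy")

        self._children: dict[str, list[str]] = {pid: [] for pid in self._prims}
        for p in self._prims.values():
            if p.parent != ROOT:
                if p.parent not in self._prims:
                    raise HierarchyError(f"unknown parent {p.parent!r} of primitive {p.id!r}")
                if self._prims[p.parent].component != p.component:
                    raise HierarchyError(
                        f"primitive {p.id!r} ({p.component}) has parent {p.parent!r} "
                        f"in component {self._prims[p.parent].component!r}"
                    )
                self._children[p.parent].append(p.id)

        self._depth: dict[str, int] = {}
        self._closure: dict[str, frozenset[str]] = {}
        for pid in self._prims:
            chain = self._walk_to_root(pid)
            self._depth[pid] = len(chain)
            if max_depth is not None and len(chain) > max_depth:
                raise HierarchyError(
                    f"primitive {pid!r} at depth {len(chain)} exceeds max depth {max_depth}"
                )
            self._closure[pid] = frozenset(chain) | {ROOT}

        self._members: dict[str, list[str]] = {}
        for p in self._prims.values():
            self._members.setdefault(p.component, []).append(p.id)
        for comp in self._members.values():
            comp.sort()

    def _walk_to_root(self, pid: str) -> list[str]:
        chain = [pid]
        seen = {pid}
        cur = self._prims[pid]
        while cur.parent != ROOT:
            nxt = cur.parent
            if nxt in seen:
                raise HierarchyError(f"cycle involving primitive {pid!r}")
            chain.append(nxt)
            seen.add(nxt)
            cur = self._prims[nxt]
        return chain

    # -- basic accessors -------------------------------------------------
    def __contains__(self, pid: str) -> bool:
        return pid in self._prims or pid == ROOT

    def __len__(self) -> int:
        return len(self._prims)

    def __iter__(self):
        return iter(self._prims)

    def ids(self) -> list[str]:
        return sorted(self._prims)

    def get(self, pid: str) -> Primitive:
        try:
            return self._prims[pid]
        except KeyError:
            raise HierarchyError(f"unknown primitive: {pid!r}") from None

    def primitives(self) -> list[Primitive]:
        return [self._prims[pid] for pid in self.ids()]

    def parent(self, pid: str) -> str:
        """Parent id of ``pid`` (possibly :data:`ROOT`)."""
        return self.get(pid).parent

    def children(self, pid: str) -> tuple[str, ...]:
        if pid == ROOT:
            return tuple(p.id for p in self._prims.values() if p.parent == ROOT)
        self.get(pid)
        return tuple(self._children[pid])

    def siblings(self, pid: str) -> tuple[str, ...]:
        """Other primitives sharing ``pid``'s parent *and* component."""
        p = self.get(pid)
        return tuple(
            s for s in self.children(p.parent)
            if s != pid and self._prims[s].component == p.component
        )

    def depth(self, pid: str) -> int:
        """Number of levels below the virtual root (component tops are 1)."""
        if pid == ROOT:
            return 0
        self.get(pid)
        return self._depth[pid]

    def components(self) -> list[str]:
        return sorted(self._members)

    def members(self, component: str) -> tuple[str, ...]:
        """All primitive ids of one component, sorted."""
        return tuple(self._members.get(component, ()))

    def leaves(self, component: str | None = None) -> tuple[str, ...]:
        pool = self.members(component) if component is not None else self.ids()
        return tuple(pid for pid in pool if not self._children[pid])

    # -- ancestry --------------------------------------------------------
    def ancestors(self, pid: str, *, include_self: bool = True) -> frozenset[str]:
        """Ancestor-or-self closure of ``pid``; always contains the root."""
        if pid == ROOT:
            return frozenset({ROOT})
        self.get(pid)
        clo = self._closure[pid]
        return clo if include_self else clo - {pid}

    def shared_ancestors(self, p: str, q: str) -> frozenset[str]:
        """Common ancestors of ``p`` and ``q`` (self-inclusive closures).

        Always contains the root; contains ``p`` iff ``p`` is an
        ancestor-or-self of ``q``. Symmetric.
        """
        return self.ancestors(p) & self.ancestors(q)


def shared_ancestors(p: str, q: str, hierarchy: PrimitiveHierarchy) -> frozenset[str]:
    """Functional alias for :meth:`PrimitiveHierarchy.shared_ancestors`."""
    return hierarchy.shared_ancestors(p, q)


class Icon:
    """A compositional icon: a mapping from component ids to primitive sets.

    Components with empty sets are dropped on construction, so a missing
    slot and an empty slot are the same thing.
    """

    __slots__ = ("id", "_assignment")

    def __init__(self, id: str, assignment: Mapping[str, Iterable[str]]):
        self.id = id
        self._assignment: dict[str, frozenset[str]] = {
            comp: frozenset(prims)
            for comp, prims in assignment.items()
            if prims
        }

    @property
    def assignment(self) -> dict[str, frozenset[str]]:
        return dict(self._assignment)

    def primitives(self) -> frozenset[str]:
        """The flattened set of all primitives of the icon, Pr(I)."""
        if not self._assignment:
            return frozenset()
        return frozenset().union(*self._assignment.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Icon):
            return NotImplemented
        return self.id == other.id and self._assignment == other._assignment

    def __hash__(self) -> int:
        return hash((self.id, tuple(sorted(self._assignment.items()))))

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{c}={'|'.join(sorted(ps))}" for c, ps in sorted(self._assignment.items())
        )
        return f"Icon({self.id!r}, {parts})"


def primitives_of(icon: Icon) -> frozenset[str]:
    """Flattened primitive set of an icon (union over all components)."""
    return icon.primitives()


def icons_identical(a: Icon, b: Icon) -> bool:
    """True iff the two icons have equal primitive sets in every component."""
    return a.assignment == b.assignment


def validate_icon(
    icon: Icon,
    hierarchy: PrimitiveHierarchy,
    components: Mapping[str, Component] | Iterable[Component],
) -> list[str]:
    """Check an icon's structural well-formedness.

    Returns the (possibly empty) list of violated invariants:
    required-component emptiness, arity of single-valued components,
    referential integrity of primitive ids, and component membership of
    each primitive. An icon naming an unknown *component* is a structural
    error and raises :class:`IconError` instead.
    """
    if isinstance(components, Mapping):
        comp_map = dict(components)
    else:
        comp_map = {c.id: c for c in components}

    for cid in icon.assignment:
        if cid not in comp_map:
            raise IconError(f"icon {icon.id!r} uses unknown component {cid!r}")

    violations: list[str] = []
    for cid, comp in comp_map.items():
        prims = icon.assignment.get(cid, frozenset())
        if comp.required and not prims:
            violations.append(f"required component empty: {cid}")
        if not comp.multi_valued and len(prims) > 1:
            violations.append(f"multiple primitives in single-valued component: {cid}")
        for pid in sorted(prims):
            if pid not in hierarchy or pid == ROOT:
                violations.append(f"unknown primitive: {pid}")
            elif hierarchy.get(pid).component != cid:
                violations.append(
                    f"primitive {pid} belongs to component "
                    f"{hierarchy.get(pid).component}, not {cid}"
                )
    if not icon.primitives():
        violations.append("icon has no primitives")
    return violations
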
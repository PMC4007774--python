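"""Shared generators and independent brute-force oracles for the tests.

The oracles deliberately avoid the package's traversal code: ancestor
sets are found by walking raw parent maps, corpus probabilities by
enumerating descendants, Lin similarity by direct evaluation of the
formula in base-10 logs, and closest-ancestor inheritance via networkx
shortest path lengths.
"""

from __future__ import annotations

import math

import networkx as nx

from iconalign import (
    ROOT,
    AlignmentRecord,
    Concept,
    Icon,
    Primitive,
    PrimitiveHierarchy,
    Terminology,
)

# ---------------------------------------------------------------- generators

def random_hierarchy(rng, n_nodes=25, n_components=3, max_depth=5) -> PrimitiveHierarchy:
    """A random primitive forest under the virtual root."""
    comp_ids = [f"c{k}" for k in range(n_components)]
    prims = []
    by_comp = {c: [] for c in comp_ids}
    depth = {}
    for k, cid in enumerate(comp_ids):
        top = f"{cid}_top"
        prims.append(Primitive(top, top, cid, ROOT))
        by_comp[cid].append(top)
        depth[top] = 1
    for i in range(n_nodes - n_components):
        cid = comp_ids[int(rng.integers(n_components))]
        pool = [p for p in by_comp[cid] if depth[p] < max_depth]
        parent = pool[int(rng.integers(len(pool)))]
        pid = f"{cid}_p{i}"
        prims.append(Primitive(pid, pid, cid, parent))
        by_comp[cid].append(pid)
        depth[pid] = depth[parent] + 1
    return PrimitiveHierarchy(prims, max_depth=max_depth)


def random_counts(rng, hierarchy) -> dict[str, int]:
    return {pid: int(rng.integers(0, 20)) for pid in hierarchy.ids()}


def icon_from_primitives(hierarchy, icon_id, primitive_ids) -> Icon:
    """Group a primitive set by component into an icon."""
    assign: dict[str, set[str]] = {}
    for pid in primitive_ids:
        assign.setdefault(hierarchy.get(pid).component, set()).add(pid)
    return Icon(icon_id, assign)


def random_icon(rng, hierarchy, icon_id) -> Icon:
    ids = hierarchy.ids()
    k = int(rng.integers(1, min(6, len(ids)) + 1))
    chosen = rng.choice(len(ids), size=k, replace=False)
    return icon_from_primitives(hierarchy, icon_id, [ids[i] for i in chosen])


def random_poly_terminology(
    rng, n=100, manual_prob=0.25, n_icons=12, tid="rand"
) -> Terminology:
    """Random poly-hierarchy with manual alignments on a random subset."""
    codes = [f"N{i:03d}" for i in range(n)]
    concepts = []
    for i, code in enumerate(codes):
        if i == 0:
            parents = frozenset()
        else:
            k = int(rng.integers(1, min(i, 3) + 1))
            parents = frozenset(
                codes[j] for j in rng.choice(i, size=k, replace=False)
            )
        concepts.append(Concept(code, tid, parents=parents))
    records = []
    for code in codes:
        if rng.random() < manual_prob:
            for j in rng.choice(n_icons, size=int(rng.integers(1, 3)), replace=False):
                records.append(AlignmentRecord(code, f"ic{j}", "manual"))
    return Terminology(tid, "poly", concepts, records)


# ------------------------------------------------------------------ oracles

def brute_ancestors(primitives: list[Primitive], pid: str) -> set[str]:
    """Ancestor-or-self closure by walking the raw parent map."""
    parent = {p.id: p.parent for p in primitives}
    out = {pid, ROOT}
    cur = pid
    while parent[cur] != ROOT:
        cur = parent[cur]
        out.add(cur)
    return out


def brute_probability(primitives: list[Primitive], direct: dict[str, float], pid: str) -> float:
    """Cumulative probability by enumerating descendants-or-self."""
    total = sum(direct.values())
    mass = sum(
        c for node, c in direct.items() if pid in brute_ancestors(primitives, node)
    )
    return mass / total


def brute_lin(
    primitives: list[Primitive], direct: dict[str, float], p: str, q: str
) -> float:
    """Direct evaluation of the Lin formula with base-10 logs."""
    if p == q:
        return 1.0
    shared = brute_ancestors(primitives, p) & brute_ancestors(primitives, q)
    shared.discard(ROOT)
    best = 0.0  # the root alone contributes log 1 = 0
    for a in shared:
        best = max(best, -math.log10(brute_probability(primitives, direct, a)))
    den = -math.log10(brute_probability(primitives, direct, p)) - math.log10(
        brute_probability(primitives, direct, q)
    )
    if den == 0.0:
        return 0.0
    return 2.0 * best / den


def brute_dsc_crude(a: Icon, b: Icon) -> float:
    pa, pb = a.primitives(), b.primitives()
    return 2 * len(pa & pb) / (len(pa) + len(pb))


def brute_dsc_semantic(a: Icon, b: Icon, sim) -> float:
    pa, pb = sorted(a.primitives()), sorted(b.primitives())
    num = 0.0
    for x in pa:
        num += max(sim(x, y) for y in pb)
    for y in pb:
        num += max(sim(x, y) for x in pa)
    return num / (len(pa) + len(pb))


def brute_inherited_icons(term: Terminology, code: str) -> tuple[str, ...]:
    """Closest manually aligned ancestors via networkx BFS; union of icons."""
    g = nx.DiGraph()
    g.add_nodes_from(term.concepts)
    for c in term.concepts.values():
        for p in c.parents:
            g.add_edge(c.code, p)
    lengths = nx.single_source_shortest_path_length(g, code)
    manual = {
        c: term.icons_for(c, "manual")
        for c in term.concepts
        if term.icons_for(c, "manual")
    }
    dists = {c: d for c, d in lengths.items() if c in manual and d > 0}
    if not dists:
        return ()
    best = min(dists.values())
    icons: set[str] = set()
    for c, d in dists.items():
        if d == best:
            icons.update(manual[c])
    return tuple(sorted(icons))
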
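"""Seedable synthetic worlds for end-to-end pipeline testing.

Real terminology content (MeSH, ICD10, UMLS cross-links, the icon
alignments built on them) is proprietary-licensed and cannot ship with
the package, so every pipeline stage is exercised on generated worlds
that emulate the real data's structure:

* a primitive hierarchy of ~221 nodes over the five icon components,
  at most six levels deep;
* a poly-hierarchic terminology A (MeSH-like, up to 11 levels) and a
  mono-hierarchic terminology B (ICD10-like);
* partial cross-links (shared CUI-like identifiers) between the two;
* one "true" icon per cross-link, from which both sides' aligned icons
  are copied — perturbed independently with a controlled per-pair
  discordance probability δ, by swapping one primitive for a sibling or
  generalising it to its parent (never violating component arity);
* a manual/automatic split on terminology A: a fraction of the linked
  concepts is aligned manually; each of the rest hangs under a dedicated
  manually aligned parent so the closest-ancestor inheritance step
  reconstructs its icon.

With δ = 0 the full pipeline must report concordance 1.0 and both Dice
means 1.0 exactly; generated metric means decrease as δ grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .icon_model import (
    ROOT,
    Component,
    Icon,
    Primitive,
    PrimitiveHierarchy,
    default_components,
)
from .terminology import MANUAL, AlignmentRecord, Concept, Terminology

log = logging.getLogger(__name__)

PERTURBATION_KINDS = ("sibling-swap", "parent-generalization")


class ConfigError(ValueError):
    """Raised for an inconsistent synthetic configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world.

    Scale defaults mirror the modeled setting: ~221 primitives on ≤6
    levels, a deep poly-hierarchy (≤11 levels) versus a shallower
    mono-hierarchy, about a third of the cross-linked poly-side concepts
    manually aligned, and enough cross-links for stable summary
    statistics (~560 pairs).
    """

    seed: int = 0
    n_primitives: int = 221
    max_primitive_depth: int = 6
    n_components: int = 5
    n_concepts_a: int = 1000
    n_concepts_b: int = 700
    poly_parent_prob: float = 0.3
    manual_fraction: float = 0.33
    crosslink_fraction: float = 0.8
    discordance_rate: float = 0.0
    perturbation_kind: str = "sibling-swap"
    max_depth_a: int = 11
    max_depth_b: int = 5
    background_alignment_prob: float = 0.2

    def __post_init__(self):
        if self.n_components != 5:
            raise ConfigError("exactly the five modeled components are supported")
        if self.n_primitives < 3 * self.n_components:
            raise ConfigError("need at least three primitives per component")
        if self.max_primitive_depth < 2:
            raise ConfigError("primitive hierarchy needs at least two levels")
        for name in (
            "poly_parent_prob",
            "manual_fraction",
            "crosslink_fraction",
            "discordance_rate",
            "background_alignment_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.perturbation_kind not in PERTURBATION_KINDS:
            raise ConfigError(
                f"perturbation_kind must be one of {PERTURBATION_KINDS}, "
                f"got {self.perturbation_kind!r}"
            )
        if min(self.n_concepts_a, self.n_concepts_b) < 20:
            raise ConfigError("each terminology needs at least 20 concepts")
        if self.max_depth_a < 3 or self.max_depth_b < 2:
            raise ConfigError("terminology depth limits too small")


@dataclass
class SyntheticWorld:
    """Everything a pipeline run needs, plus the generating truth."""

    config: SyntheticConfig
    components: dict[str, Component]
    hierarchy: PrimitiveHierarchy
    icons: dict[str, Icon]
    terminology_a: Terminology
    terminology_b: Terminology
    true_icons: dict[str, str] = field(default_factory=dict)  # cross id -> icon id


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    # one spawned stream per stage, so adding a stage never shifts others
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_hierarchy(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> tuple[dict[str, Component], PrimitiveHierarchy]:
    comps = default_components()
    comp_ids = list(comps)
    prims: list[Primitive] = []
    nodes_by_comp: dict[str, list[str]] = {}
    depth: dict[str, int] = {}
    for cid in comp_ids:
        top = f"{cid}:top"
        prims.append(Primitive(top, f"{cid} (top)", cid, ROOT))
        nodes_by_comp[cid] = [top]
        depth[top] = 1
    # guarantee a depth-2 node per component so every component has
    # primitives with an in-component parent (perturbation targets)
    remaining = cfg.n_primitives - len(comp_ids)
    for i in range(remaining):
        if i < len(comp_ids):
            cid = comp_ids[i]
        else:
            cid = comp_ids[rng.integers(len(comp_ids))]
        candidates = [
            p for p in nodes_by_comp[cid] if depth[p] < cfg.max_primitive_depth
        ]
        parent = candidates[rng.integers(len(candidates))]
        pid = f"{cid}:{i:03d}"
        prims.append(Primitive(pid, pid, cid, parent))
        depth[pid] = depth[parent] + 1
        nodes_by_comp[cid].append(pid)
    return comps, PrimitiveHierarchy(prims, max_depth=cfg.max_primitive_depth)


def _sample_primitive(
    rng: np.random.Generator,
    hierarchy: PrimitiveHierarchy,
    component: str,
    exclude: frozenset[str] = frozenset(),
    leaf_bias: float = 0.8,
) -> str:
    members = [p for p in hierarchy.members(component) if p not in exclude]
    leaves = [p for p in members if not hierarchy.children(p)]
    pool = leaves if leaves and rng.random() < leaf_bias else members
    return pool[rng.integers(len(pool))]


def _sample_icon(
    rng: np.random.Generator, hierarchy: PrimitiveHierarchy, icon_id: str
) -> Icon:
    # one mandatory central color and shape, Bernoulli-included optional
    # slots, leaf-biased picks (leaves are the more specific annotations)
    assign: dict[str, set[str]] = {
        "central-color": {_sample_primitive(rng, hierarchy, "central-color")},
        "shape": {_sample_primitive(rng, hierarchy, "shape")},
    }
    if rng.random() < 0.9:
        assign["central-pictogram"] = {
            _sample_primitive(rng, hierarchy, "central-pictogram")
        }
    if rng.random() < 0.4:
        assign["top-right-color"] = {
            _sample_primitive(rng, hierarchy, "top-right-color")
        }
    if rng.random() < 0.5:
        first = _sample_primitive(rng, hierarchy, "top-right-pictogram")
        chosen = {first}
        if rng.random() < 0.2:
            chosen.add(
                _sample_primitive(
                    rng, hierarchy, "top-right-pictogram", exclude=frozenset(chosen)
                )
            )
        assign["top-right-pictogram"] = chosen
    return Icon(icon_id, assign)


def perturb_icon(
    rng: np.random.Generator,
    hierarchy: PrimitiveHierarchy,
    icon: Icon,
    kind: str,
    new_id: str,
) -> Icon:
    """Replace one primitive by a sibling or by its parent.

    The replacement stays inside the primitive's component, so arity is
    preserved; candidates are primitives at depth ≥ 2 (they have an
    in-component parent) whose substitute is not already in the icon.
    """
    if kind not in PERTURBATION_KINDS:
        raise ConfigError(f"unknown perturbation kind {kind!r}")
    prim_set = icon.primitives()
    candidates: list[tuple[str, str, tuple[str, ...]]] = []
    for cid, prims in sorted(icon.assignment.items()):
        for pid in sorted(prims):
            if hierarchy.depth(pid) < 2:
                continue
            if kind == "parent-generalization":
                sub = hierarchy.parent(pid)
                if sub not in prim_set:
                    candidates.append((cid, pid, (sub,)))
            else:
                sibs = tuple(
                    s for s in sorted(hierarchy.siblings(pid)) if s not in prim_set
                )
                if sibs:
                    candidates.append((cid, pid, sibs))
    if not candidates:
        # degenerate icon (all primitives at component tops, or no free
        # siblings): swap the central color for any other color primitive
        cid = "central-color"
        pid = next(iter(icon.assignment[cid]))
        others = tuple(
            m for m in hierarchy.members(cid) if m != pid and m not in prim_set
        )
        candidates = [(cid, pid, others)]
    cid, pid, subs = candidates[rng.integers(len(candidates))]
    sub = subs[rng.integers(len(subs))]
    assign = {c: set(ps) for c, ps in icon.assignment.items()}
    assign[cid].discard(pid)
    assign[cid].add(sub)
    return Icon(new_id, assign)


def _build_backbone(
    rng: np.random.Generator,
    tid: str,
    codes: list[str],
    kind: str,
    max_depth: int,
    poly_parent_prob: float,
) -> tuple[dict[str, Concept], dict[str, int]]:
    concepts: dict[str, Concept] = {}
    depth: dict[str, int] = {}
    for i, code in enumerate(codes):
        if i == 0:
            parents: frozenset[str] = frozenset()
            depth[code] = 1
        else:
            shallow = [c for c in codes[:i] if depth[c] < max_depth]
            p1 = shallow[rng.integers(len(shallow))]
            chosen = {p1}
            depth[code] = depth[p1] + 1
            if kind == "poly" and i > 1 and rng.random() < poly_parent_prob:
                p2 = codes[rng.integers(i)]
                if p2 != p1:
                    chosen.add(p2)
            parents = frozenset(chosen)
        concepts[code] = Concept(code, tid, label=code, parents=parents)
    return concepts, depth


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate a complete, loadable, valid world (deterministic per seed)."""
    r_hier, r_a, r_b, r_icons, r_pert, r_bg = _rngs(cfg.seed, 6)

    comps, hierarchy = _build_hierarchy(r_hier, cfg)

    n_links = int(round(cfg.crosslink_fraction * min(cfg.n_concepts_a, cfg.n_concepts_b)))
    if n_links < 1:
        raise ConfigError("crosslink_fraction too low: no cross-linked pairs")
    link_is_manual = np.zeros(n_links, dtype=bool)
    n_manual = int(round(cfg.manual_fraction * n_links))
    link_is_manual[r_a.permutation(n_links)[:n_manual]] = True
    n_auto = n_links - n_manual

    backbone_a_n = cfg.n_concepts_a - n_links - n_auto
    backbone_b_n = cfg.n_concepts_b - n_links
    if backbone_a_n < 2 or backbone_b_n < 2:
        raise ConfigError(
            "n_concepts too small for the requested crosslink/manual fractions"
        )

    # -- terminology A backbone (poly) + background manual alignments ----
    codes_a = [f"A{i:05d}" for i in range(backbone_a_n)]
    concepts_a, depth_a = _build_backbone(
        r_a, "termA", codes_a, "poly", cfg.max_depth_a, cfg.poly_parent_prob
    )
    icons: dict[str, Icon] = {}
    alignments_a: list[AlignmentRecord] = []
    bg_aligned_a: set[str] = set()
    for code in codes_a:
        if r_bg.random() < cfg.background_alignment_prob:
            icon = _sample_icon(r_icons, hierarchy, f"bg_{code}")
            icons[icon.id] = icon
            alignments_a.append(AlignmentRecord(code, icon.id, MANUAL))
            bg_aligned_a.add(code)
    # second parents for inheritance leaves may only come from unaligned
    # backbone nodes, so no tie can inject a second manual source
    plain_a = [c for c in codes_a if c not in bg_aligned_a]

    # -- terminology B backbone (mono) -----------------------------------
    codes_b = [f"B{i:05d}" for i in range(backbone_b_n)]
    concepts_b, depth_b = _build_backbone(
        r_b, "termB", codes_b, "mono", cfg.max_depth_b, 0.0
    )
    alignments_b: list[AlignmentRecord] = []
    for code in codes_b:
        if r_bg.random() < cfg.background_alignment_prob:
            icon = _sample_icon(r_icons, hierarchy, f"bg_{code}")
            icons[icon.id] = icon
            alignments_b.append(AlignmentRecord(code, icon.id, MANUAL))

    # -- cross-linked concepts, true icons and perturbed copies ----------
    true_icons: dict[str, str] = {}

    def _copy(true: Icon, rng: np.random.Generator, tag: str) -> str:
        """True icon, perturbed with probability δ; returns the icon id."""
        if rng.random() < cfg.discordance_rate:
            variant = perturb_icon(
                rng, hierarchy, true, cfg.perturbation_kind, f"{true.id}_{tag}"
            )
            icons[variant.id] = variant
            return variant.id
        return true.id

    for i in range(n_links):
        cui = f"C{i:07d}"
        true = _sample_icon(r_icons, hierarchy, f"icon_true_{i:05d}")
        icons[true.id] = true
        true_icons[cui] = true.id

        leaf_a = f"AL{i:05d}"
        if link_is_manual[i]:
            # manually aligned side: the validated reference, unperturbed
            p1 = codes_a[int(r_a.integers(backbone_a_n))]
            parents = {p1}
            if r_a.random() < cfg.poly_parent_prob:
                p2 = codes_a[int(r_a.integers(backbone_a_n))]
                if p2 != p1:
                    parents.add(p2)
            concepts_a[leaf_a] = Concept(
                leaf_a, "termA", label=leaf_a,
                parents=frozenset(parents), cross_ids=frozenset({cui}),
            )
            alignments_a.append(AlignmentRecord(leaf_a, true.id, MANUAL))
        else:
            # inheritance case: a dedicated manually aligned parent holds
            # the (possibly perturbed) copy; the leaf itself stays
            # unaligned and is filled in by inherit_icons
            helper = f"AH{i:05d}"
            shallow = [c for c in codes_a if depth_a[c] <= cfg.max_depth_a - 2]
            hp = shallow[int(r_a.integers(len(shallow)))]
            concepts_a[helper] = Concept(
                helper, "termA", label=helper, parents=frozenset({hp})
            )
            source_icon = _copy(true, r_pert, "a")
            alignments_a.append(AlignmentRecord(helper, source_icon, MANUAL))
            parents = {helper}
            if plain_a and r_a.random() < cfg.poly_parent_prob:
                parents.add(plain_a[int(r_a.integers(len(plain_a)))])
            concepts_a[leaf_a] = Concept(
                leaf_a, "termA", label=leaf_a,
                parents=frozenset(parents), cross_ids=frozenset({cui}),
            )

        leaf_b = f"BL{i:05d}"
        shallow_b = [c for c in codes_b if depth_b[c] < cfg.max_depth_b]
        pb = shallow_b[int(r_b.integers(len(shallow_b)))]
        concepts_b[leaf_b] = Concept(
            leaf_b, "termB", label=leaf_b,
            parents=frozenset({pb}), cross_ids=frozenset({cui}),
        )
        alignments_b.append(AlignmentRecord(leaf_b, _copy(true, r_pert, "b"), MANUAL))

    term_a = Terminology("termA", "poly", concepts_a.values(), alignments_a)
    term_b = Terminology("termB", "mono", concepts_b.values(), alignments_b)
    log.info(
        "generate_world(seed=%d, delta=%.2f): %d primitives, %d+%d concepts, "
        "%d links (%d manual)",
        cfg.seed, cfg.discordance_rate, len(hierarchy),
        len(term_a), len(term_b), n_links, n_manual,
    )
    return SyntheticWorld(
        config=cfg,
        components=comps,
        hierarchy=hierarchy,
        icons=icons,
        terminology_a=term_a,
        terminology_b=term_b,
        true_icons=true_icons,
    )


def sweep_discordance(cfg: SyntheticConfig, rates: Sequence[float]) -> pd.DataFrame:
    """Run the full pipeline once per discordance rate.

    Each rate gets its own derived seed (stable across runs of the same
    base config), so the table is reproducible; mean metrics decrease
    with the rate up to Monte-Carlo noise.
    """
    from .pipeline import evaluate_world

    rows = []
    for i, delta in enumerate(rates):
        sub_seed = int(
            np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)
        )
        sub_cfg = replace(cfg, seed=sub_seed, discordance_rate=float(delta))
        world = generate_world(sub_cfg)
        report, _ = evaluate_world(world)
        overall = report.strata["all"]
        rows.append(
            {
                "delta": float(delta),
                "n_pairs": overall.n,
                "concordance": overall.concordance,
                "dsc_crude": overall.mean_dsc_crude,
                "dsc_semantic": overall.mean_dsc_semantic,
            }
        )
    return pd.DataFrame(rows)
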
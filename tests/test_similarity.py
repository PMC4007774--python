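import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iconalign import (
    ROOT,
    AlignmentRecord,
    Concept,
    CorpusProbabilities,
    FixtureSimilarity,
    Icon,
    LinSimilarity,
    Terminology,
    build_corpus_probabilities,
    concordant,
    dsc_crude,
    dsc_semantic,
    lin_similarity,
)
from iconalign.similarity import CorpusError

from _util import brute_lin, icon_from_primitives, random_counts, random_hierarchy


class TestCorpusProbabilities:
    def test_hand_computed_cumulative_probabilities(self, tiny_hierarchy):
        # direct occurrences B x4, C x4, D x2 under root -> {A -> {B, C}, D}
        probs = CorpusProbabilities(
            {"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False
        )
        assert probs.p("B") == pytest.approx(0.4)
        assert probs.p("C") == pytest.approx(0.4)
        assert probs.p("A") == pytest.approx(0.8)
        assert probs.p("D") == pytest.approx(0.2)
        assert probs.p(ROOT) == 1.0

    def test_smoothing_gives_positive_probabilities(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 1}, tiny_hierarchy, smoothing=True)
        for pid in tiny_hierarchy.ids():
            assert 0.0 < probs.p(pid) <= 1.0
        assert probs.p(ROOT) == 1.0

    def test_probability_monotone_toward_ancestors(self, rng):
        h = random_hierarchy(rng, n_nodes=30)
        probs = CorpusProbabilities(random_counts(rng, h), h)
        for pid in h.ids():
            parent = h.parent(pid)
            if parent != ROOT:
                assert probs.p(parent) >= probs.p(pid)

    def test_empty_corpus_rejected(self, tiny_hierarchy):
        with pytest.raises(CorpusError):
            CorpusProbabilities({}, tiny_hierarchy, smoothing=False)
        with pytest.raises(CorpusError, match="empty corpus"):
            build_corpus_probabilities([], {}, tiny_hierarchy)

    def test_each_alignment_record_is_one_occurrence(self, tiny_hierarchy):
        icon = Icon("i", {"central-pictogram": {"B"}})
        concepts = [Concept("X", "t"), Concept("Y", "t")]
        t = Terminology(
            "t", "poly", concepts,
            [AlignmentRecord("X", "i", "manual"), AlignmentRecord("Y", "i", "manual")],
        )
        per_rel = build_corpus_probabilities([t], {"i": icon}, tiny_hierarchy, smoothing=False)
        per_icon = build_corpus_probabilities(
            [t], {"i": icon}, tiny_hierarchy, smoothing=False, weighting="per_icon"
        )
        assert per_rel.counts["B"] == 2
        assert per_icon.counts["B"] == 1


class TestLinSimilarity:
    def test_identity_is_one(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False)
        for pid in tiny_hierarchy.ids():
            assert lin_similarity(pid, pid, probs, tiny_hierarchy) == 1.0

    def test_root_only_ancestry_is_zero(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False)
        assert lin_similarity("B", "D", probs, tiny_hierarchy) == 0.0

    def test_hand_computed_sibling_value(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False)
        expected = 2 * math.log(0.8) / (math.log(0.4) + math.log(0.4))  # ~0.244
        assert lin_similarity("B", "C", probs, tiny_hierarchy) == pytest.approx(expected)
        assert expected == pytest.approx(0.2435, abs=1e-4)

    def test_unknown_primitive_rejected(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 1}, tiny_hierarchy)
        with pytest.raises(CorpusError):
            lin_similarity("B", "nope", probs, tiny_hierarchy)

    def test_matches_brute_force_oracle(self, rng):
        """Implementation agrees with direct base-10 evaluation of the
        formula on random hierarchies and corpora (hence is log-base
        invariant), and is symmetric and bounded."""
        for _ in range(30):
            h = random_hierarchy(rng, n_nodes=15)
            counts = {pid: c + 1 for pid, c in random_counts(rng, h).items()}
            probs = CorpusProbabilities(counts, h, smoothing=False)
            prims = h.primitives()
            ids = h.ids()
            for p in ids:
                for q in ids:
                    got = lin_similarity(p, q, probs, h)
                    assert got == pytest.approx(brute_lin(prims, counts, p, q), abs=1e-12)
                    assert got == lin_similarity(q, p, probs, h)
                    assert 0.0 <= got <= 1.0

    def test_memoized_source_equals_plain_function(self, tiny_hierarchy):
        probs = CorpusProbabilities({"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False)
        sim = LinSimilarity(probs, tiny_hierarchy)
        assert sim("B", "C") == lin_similarity("B", "C", probs, tiny_hierarchy)
        assert sim("C", "B") == sim("B", "C")


class TestFixtureSimilarity:
    def test_identity_default_and_symmetry(self):
        sim = FixtureSimilarity({("a", "b"): 0.85})
        assert sim("x", "x") == 1.0
        assert sim("a", "b") == sim("b", "a") == 0.85
        assert sim("a", "z") == 0.0

    def test_strict_mode_raises_on_missing_pair(self):
        sim = FixtureSimilarity({("a", "b"): 0.5}, default=None)
        with pytest.raises(KeyError):
            sim("a", "z")


class TestDice:
    def test_demonstration_pair_crude_is_four_sevenths(self, thyroid_icons):
        mesh, icd = thyroid_icons
        assert dsc_crude(mesh, icd) == pytest.approx(4 / 7)
        assert dsc_crude(icd, mesh) == pytest.approx(4 / 7)

    def test_demonstration_pair_semantic(self, thyroid_icons, thyroid_sim):
        # best matches: 1 + 1 + 0.85 forward, 1 + 1 + 0.35 + 0.85 backward
        mesh, icd = thyroid_icons
        assert dsc_semantic(mesh, icd, thyroid_sim) == pytest.approx(6.05 / 7)
        assert not concordant(mesh, icd)

    def test_identical_icons_score_one(self, thyroid_icons, thyroid_sim):
        mesh, _ = thyroid_icons
        assert dsc_crude(mesh, mesh) == 1.0
        assert dsc_semantic(mesh, mesh, thyroid_sim) == 1.0
        assert concordant(mesh, mesh)

    def test_disjoint_and_root_only_icons_score_zero(self, tiny_hierarchy):
        a = Icon("a", {"central-pictogram": {"B"}})
        b = Icon("b", {"central-pictogram": {"D"}})
        probs = CorpusProbabilities({"B": 4, "C": 4, "D": 2}, tiny_hierarchy, smoothing=False)
        sim = LinSimilarity(probs, tiny_hierarchy)
        assert dsc_crude(a, b) == 0.0
        assert dsc_semantic(a, b, sim) == 0.0

    def test_empty_icons_rejected(self):
        empty = Icon("e", {})
        with pytest.raises(ValueError):
            dsc_crude(empty, empty)


# property suite on a fixed random hierarchy ----------------------------

_H = random_hierarchy(np.random.default_rng(7), n_nodes=24, n_components=3)
_COUNTS = {pid: c + 1 for pid, c in random_counts(np.random.default_rng(8), _H).items()}
_SIM = LinSimilarity(CorpusProbabilities(_COUNTS, _H, smoothing=False), _H)

prim_sets = st.sets(st.sampled_from(_H.ids()), min_size=1, max_size=6)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(pa=prim_sets, pb=prim_sets)
def test_semantic_dominates_crude_and_both_bounded(pa, pb):
    """For any icon pair, dsc_semantic >= dsc_crude (shared primitives
    contribute at least their crude indicator), both metrics are
    symmetric and lie in [0, 1], and concordance implies both equal 1."""
    a = icon_from_primitives(_H, "a", pa)
    b = icon_from_primitives(_H, "b", pb)
    crude = dsc_crude(a, b)
    sem = dsc_semantic(a, b, _SIM)
    assert 0.0 <= crude <= 1.0
    assert crude <= sem <= 1.0 + 1e-12
    assert crude == pytest.approx(dsc_crude(b, a))
    assert sem == pytest.approx(dsc_semantic(b, a, _SIM))
    if concordant(a, b):
        assert crude == 1.0 and sem == pytest.approx(1.0)
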
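import numpy as np
import pytest

from iconalign import (
    AlignmentRecord,
    CandidatePair,
    Concept,
    PairEvaluation,
    Terminology,
    evaluate_pairs,
    filter_single_icon_pairs,
    recover_concordant_count,
    summarize,
    wald_proportion_ci,
    worst_case_sensitivity,
)
from iconalign.evaluation import EvaluationError, mean_normal_ci

from _util import (
    brute_dsc_crude,
    brute_dsc_semantic,
    random_hierarchy,
    random_icon,
)
from iconalign import CorpusProbabilities, LinSimilarity
from _util import random_counts


def make_pair(ca, cb, na=1, nb=1):
    return CandidatePair(
        ca, cb,
        tuple(f"{ca}_i{k}" for k in range(na)),
        tuple(f"{cb}_i{k}" for k in range(nb)),
    )


class TestFilterSingleIconPairs:
    def test_counts_and_fraction(self):
        pairs = [make_pair("a1", "b1"), make_pair("a2", "b2", na=2),
                 make_pair("a3", "b3"), make_pair("a4", "b4")]
        retained, excluded, fraction = filter_single_icon_pairs(pairs)
        assert len(retained) == 3 and excluded == 1
        assert fraction == pytest.approx(0.75)

    def test_all_single_gives_fraction_one(self):
        retained, excluded, fraction = filter_single_icon_pairs([make_pair("a", "b")])
        assert (len(retained), excluded, fraction) == (1, 0, 1.0)

    def test_empty_input(self):
        retained, excluded, fraction = filter_single_icon_pairs([])
        assert retained == [] and excluded == 0 and fraction is None

    def test_published_scale_arithmetic(self):
        pairs = [make_pair(f"a{i}", f"b{i}") for i in range(1606)]
        pairs += [make_pair(f"a{i}", f"b{i}", nb=2) for i in range(1606, 1887)]
        _, excluded, fraction = filter_single_icon_pairs(pairs)
        assert excluded == 281
        assert round(100 * fraction, 1) == 85.1


class TestEvaluatePairs:
    def _world(self, rng, n_pairs=20):
        h = random_hierarchy(rng, n_nodes=25)
        icons = {}
        pairs = []
        concepts, records = [], []
        for i in range(n_pairs):
            ia = random_icon(rng, h, f"ia{i}")
            ib = random_icon(rng, h, f"ib{i}")
            icons[ia.id], icons[ib.id] = ia, ib
            concepts.append(Concept(f"A{i}", "a"))
            prov = "manual" if rng.random() < 0.5 else "automatic"
            records.append(AlignmentRecord(f"A{i}", ia.id, prov))
            pairs.append(CandidatePair(f"A{i}", f"B{i}", (ia.id,), (ib.id,)))
        term_a = Terminology("a", "poly", concepts, records)
        counts = {pid: c + 1 for pid, c in random_counts(rng, h).items()}
        sim = LinSimilarity(CorpusProbabilities(counts, h, smoothing=False), h)
        return h, icons, pairs, term_a, sim

    def test_matches_straight_line_reimplementation(self, rng):
        """Per-pair values equal an independent re-derivation of the crude
        and best-match semantic Dice formulas."""
        _, icons, pairs, term_a, sim = self._world(rng)
        evals = evaluate_pairs(pairs, icons, sim, term_a)
        assert len(evals) == len(pairs)
        for ev, pair in zip(evals, pairs):
            a, b = icons[pair.icons_a[0]], icons[pair.icons_b[0]]
            assert ev.dsc_crude == pytest.approx(brute_dsc_crude(a, b))
            assert ev.dsc_semantic == pytest.approx(brute_dsc_semantic(a, b, sim))
            assert ev.concordant == (a.assignment == b.assignment)
            assert ev.provenance == term_a.records_for(pair.concept_a)[0].provenance

    def test_missing_provenance_is_an_error(self, rng):
        _, icons, pairs, term_a, sim = self._world(rng, n_pairs=2)
        stripped = term_a.replace_alignments([])
        with pytest.raises(EvaluationError, match="provenance"):
            evaluate_pairs(pairs, icons, sim, stripped)

    def test_multi_icon_pair_is_an_error(self, rng):
        _, icons, pairs, term_a, sim = self._world(rng, n_pairs=1)
        bad = CandidatePair("A0", "B0", pairs[0].icons_a * 2, pairs[0].icons_b)
        with pytest.raises(EvaluationError, match="single-icon"):
            evaluate_pairs([bad], icons, sim, term_a)


def make_eval(i, provenance, concordant, crude, semantic):
    return PairEvaluation(
        f"A{i}", f"B{i}", f"ia{i}", f"ib{i}", provenance, concordant, crude, semantic
    )


class TestSummarize:
    def test_wald_ci_reproduces_published_interval(self):
        lo, hi = wald_proportion_ci(392, 528)
        assert round(100 * lo, 1) == 70.5
        assert round(100 * hi, 1) == 78.0
        assert recover_concordant_count(0.742, 528) == 392

    def test_all_concordant_degenerate(self):
        evals = [make_eval(i, "manual", True, 1.0, 1.0) for i in range(10)]
        rep = summarize(evals)
        s = rep.strata["all"]
        assert s.concordance == 1.0
        assert s.concordance_ci == (1.0, 1.0)
        assert s.mean_dsc_crude == 1.0 and s.dsc_crude_ci == (1.0, 1.0)
        assert rep.strata["automatic"] is None
        assert rep.p_concordance is None  # no second stratum, no test

    def test_identical_distributions_give_p_one(self):
        evals = [make_eval(i, "manual", i % 2 == 0, 0.5 + 0.1 * (i % 3), 0.8)
                 for i in range(12)]
        evals += [make_eval(100 + i, "automatic", i % 2 == 0, 0.5 + 0.1 * (i % 3), 0.8)
                  for i in range(12)]
        rep = summarize(evals)
        assert rep.p_concordance == pytest.approx(1.0)
        assert rep.p_dsc_crude == pytest.approx(1.0)
        assert rep.p_dsc_semantic == pytest.approx(1.0)

    def test_stratum_sizes_sum_and_means_nest(self, rng):
        evals = [
            make_eval(i, "manual" if rng.random() < 0.4 else "automatic",
                      bool(rng.random() < 0.7),
                      float(rng.random()), float(rng.random()))
            for i in range(200)
        ]
        rep = summarize(evals)
        s_all, s_m, s_a = rep.strata["all"], rep.strata["manual"], rep.strata["automatic"]
        assert s_all.n == s_m.n + s_a.n
        for attr in ("mean_dsc_crude", "mean_dsc_semantic", "concordance"):
            overall = getattr(s_all, attr)
            lo, hi = sorted((getattr(s_m, attr), getattr(s_a, attr)))
            assert lo - 1e-12 <= overall <= hi + 1e-12

    def test_bootstrap_ci_is_seeded_and_close_to_normal(self, rng):
        evals = [make_eval(i, "manual", bool(rng.random() < 0.7),
                           float(rng.random()), float(rng.random()))
                 for i in range(300)]
        rep1 = summarize(evals, ci_method="bootstrap", seed=5)
        rep2 = summarize(evals, ci_method="bootstrap", seed=5)
        assert rep1.strata["all"].dsc_crude_ci == rep2.strata["all"].dsc_crude_ci
        normal = summarize(evals).strata["all"].dsc_crude_ci
        boot = rep1.strata["all"].dsc_crude_ci
        assert normal[0] == pytest.approx(boot[0], abs=0.02)
        assert normal[1] == pytest.approx(boot[1], abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            summarize([])

    def test_mean_ci_single_value_degenerates(self):
        assert mean_normal_ci([0.4]) == (0.4, 0.4)


class TestWorstCaseSensitivity:
    def test_published_scale_figures(self):
        res = worst_case_sensitivity(528, 392, 0.93, 0.96, 42)
        assert round(100 * res.concordance, 1) == 68.8
        assert round(res.dsc_crude, 2) == 0.86
        assert round(res.dsc_semantic, 2) == 0.89

    def test_no_exclusions_changes_nothing(self):
        res = worst_case_sensitivity(100, 50, 0.9, 0.95, 0)
        assert res.concordance == 0.5
        assert res.dsc_crude == 0.9 and res.dsc_semantic == 0.95

    def test_monotone_dilution(self):
        values = [worst_case_sensitivity(100, 50, 0.9, 0.95, k) for k in range(0, 200, 10)]
        for prev, cur in zip(values, values[1:]):
            assert cur.concordance <= prev.concordance
            assert cur.dsc_crude <= prev.dsc_crude
            assert cur.dsc_semantic <= prev.dsc_semantic

    def test_zero_denominator_rejected(self):
        with pytest.raises(EvaluationError):
            worst_case_sensitivity(0, 0, 0.0, 0.0, 0)
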
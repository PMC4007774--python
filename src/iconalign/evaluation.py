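"""Cross-terminology agreement evaluation.

Pipeline stages: collect candidate concept pairs via shared cross ids,
discard pairs where either side is aligned to more than one icon, score
each retained pair with the three metrics (concordance, crude Dice,
semantic Dice), stratify by the provenance of the poly-hierarchic side's
alignment (manual vs automatic), and summarize with 95% confidence
intervals and two-sided between-stratum tests: Fisher's exact test on the
concordance 2x2 table and Wilcoxon rank-sum on each Dice distribution.

A worst-case sensitivity analysis treats the excluded (multi-icon) pairs
as if they had all been scored fully discordant (all three metrics 0) and
recomputes the overall figures on the diluted denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .icon_model import Icon
from .similarity import SimilaritySource, concordant, dsc_crude, dsc_semantic
from .terminology import Terminology, pair_by_cross_id

log = logging.getLogger(__name__)

STRATA = ("all", "manual", "automatic")


class EvaluationError(ValueError):
    """Raised for unresolvable pairs or missing provenance."""


@dataclass(frozen=True)
class CandidatePair:
    """A cross-linked concept pair with each side's aligned icon ids."""

    concept_a: str
    concept_b: str
    icons_a: tuple[str, ...]
    icons_b: tuple[str, ...]


@dataclass(frozen=True)
class PairEvaluation:
    """One retained pair's three metric values."""

    concept_a: str
    concept_b: str
    icon_a: str
    icon_b: str
    provenance: str
    concordant: bool
    dsc_crude: float
    dsc_semantic: float


@dataclass(frozen=True)
class StratumSummary:
    n: int
    concordant_count: int
    concordance: float
    concordance_ci: tuple[float, float]
    mean_dsc_crude: float
    dsc_crude_ci: tuple[float, float]
    mean_dsc_semantic: float
    dsc_semantic_ci: tuple[float, float]


@dataclass
class AgreementReport:
    """Stratified summary: per-stratum figures, tests, exclusion counts."""

    strata: dict[str, StratumSummary | None]
    p_concordance: float | None = None
    p_dsc_crude: float | None = None
    p_dsc_semantic: float | None = None
    excluded_pair_count: int = 0
    retained_fraction: float | None = None


def collect_candidate_pairs(a: Terminology, b: Terminology) -> list[CandidatePair]:
    """Pair concepts sharing a cross id; keep pairs aligned on both sides."""
    out = []
    for code_a, code_b in pair_by_cross_id(a, b):
        icons_a = a.icons_for(code_a)
        icons_b = b.icons_for(code_b)
        if icons_a and icons_b:
            out.append(CandidatePair(code_a, code_b, icons_a, icons_b))
    return out


def filter_single_icon_pairs(
    pairs: Sequence[CandidatePair],
) -> tuple[list[CandidatePair], int, float | None]:
    """Keep pairs with exactly one icon on each side.

    Returns (retained pairs, excluded count, retained fraction); the
    fraction is None on empty input.
    """
    retained = [p for p in pairs if len(p.icons_a) == 1 and len(p.icons_b) == 1]
    excluded = len(pairs) - len(retained)
    fraction = len(retained) / len(pairs) if pairs else None
    log.info("filter_single_icon_pairs: %d retained, %d excluded", len(retained), excluded)
    return retained, excluded, fraction


def evaluate_pairs(
    pairs: Sequence[CandidatePair],
    icons: Mapping[str, Icon],
    sim: SimilaritySource,
    provenance_source: Terminology,
) -> list[PairEvaluation]:
    """Score each single-icon pair with the three metrics.

    ``provenance_source`` is the terminology (the poly-hierarchic side)
    whose alignment record supplies the manual/automatic stratum label.
    """
    out = []
    for pair in pairs:
        if len(pair.icons_a) != 1 or len(pair.icons_b) != 1:
            raise EvaluationError(
                f"pair ({pair.concept_a}, {pair.concept_b}) is not single-icon"
            )
        icon_a_id, icon_b_id = pair.icons_a[0], pair.icons_b[0]
        try:
            icon_a, icon_b = icons[icon_a_id], icons[icon_b_id]
        except KeyError as exc:
            raise EvaluationError(f"unresolvable icon id {exc.args[0]!r}") from None
        provenance = None
        for rec in provenance_source.records_for(pair.concept_a):
            if rec.icon == icon_a_id:
                provenance = rec.provenance
                break
        if provenance is None:
            raise EvaluationError(
                f"no alignment record with provenance for concept {pair.concept_a!r} "
                f"and icon {icon_a_id!r}"
            )
        out.append(
            PairEvaluation(
                concept_a=pair.concept_a,
                concept_b=pair.concept_b,
                icon_a=icon_a_id,
                icon_b=icon_b_id,
                provenance=provenance,
                concordant=concordant(icon_a, icon_b),
                dsc_crude=dsc_crude(icon_a, icon_b),
                dsc_semantic=dsc_semantic(icon_a, icon_b, sim),
            )
        )
    return out


Z_95 = float(stats.norm.ppf(0.975))


def wald_proportion_ci(count: int, n: int) -> tuple[float, float]:
    """Wald (normal-approximation) 95% CI for a proportion, clipped to [0, 1]."""
    lo, hi = proportion_confint(count, n, alpha=0.05, method="normal")
    return (max(0.0, float(lo)), min(1.0, float(hi)))


def mean_normal_ci(values: Sequence[float]) -> tuple[float, float]:
    """Normal-approximation 95% CI of the mean (sample SD, z quantile)."""
    arr = np.asarray(values, dtype=float)
    m = float(arr.mean())
    if arr.size < 2:
        return (m, m)
    half = Z_95 * float(arr.std(ddof=1)) / np.sqrt(arr.size)
    return (m - half, m + half)


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    if values.size < 2:
        m = float(values.mean())
        return (m, m)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return (float(lo), float(hi))


def _summarize_stratum(
    evals: Sequence[PairEvaluation],
    *,
    ci_method: str,
    rng: np.random.Generator | None,
    n_boot: int,
) -> StratumSummary:
    n = len(evals)
    conc = sum(1 for e in evals if e.concordant)
    crude = np.array([e.dsc_crude for e in evals], dtype=float)
    sem = np.array([e.dsc_semantic for e in evals], dtype=float)
    if ci_method == "bootstrap":
        assert rng is not None
        conc_arr = np.array([1.0 if e.concordant else 0.0 for e in evals])
        conc_ci = _bootstrap_ci(conc_arr, rng, n_boot)
        crude_ci = _bootstrap_ci(crude, rng, n_boot)
        sem_ci = _bootstrap_ci(sem, rng, n_boot)
    else:
        conc_ci = wald_proportion_ci(conc, n)
        crude_ci = mean_normal_ci(crude)
        sem_ci = mean_normal_ci(sem)
    return StratumSummary(
        n=n,
        concordant_count=conc,
        concordance=conc / n,
        concordance_ci=conc_ci,
        mean_dsc_crude=float(crude.mean()),
        dsc_crude_ci=crude_ci,
        mean_dsc_semantic=float(sem.mean()),
        dsc_semantic_ci=sem_ci,
    )


def summarize(
    evals: Sequence[PairEvaluation],
    *,
    ci_method: str = "normal",
    n_bootstrap: int = 2000,
    seed: int = 0,
    excluded_pair_count: int = 0,
    retained_fraction: float | None = None,
) -> AgreementReport:
    """Stratified agreement report with CIs and manual-vs-automatic tests.

    Strata are ``all``, ``manual`` and ``automatic``; an empty stratum is
    reported as absent (None) and no test is run. ``ci_method`` is
    ``"normal"`` (Wald for the proportion, normal approximation for the
    Dice means) or ``"bootstrap"`` (seeded percentile bootstrap).
    """
    if not evals:
        raise EvaluationError("no pair evaluations to summarize")
    if ci_method not in ("normal", "bootstrap"):
        raise EvaluationError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed) if ci_method == "bootstrap" else None

    groups: dict[str, list[PairEvaluation]] = {
        "all": list(evals),
        "manual": [e for e in evals if e.provenance == "manual"],
        "automatic": [e for e in evals if e.provenance == "automatic"],
    }
    strata: dict[str, StratumSummary | None] = {}
    for name in STRATA:
        grp = groups[name]
        strata[name] = (
            _summarize_stratum(grp, ci_method=ci_method, rng=rng, n_boot=n_bootstrap)
            if grp
            else None
        )

    report = AgreementReport(
        strata=strata,
        excluded_pair_count=excluded_pair_count,
        retained_fraction=retained_fraction,
    )
    man, auto = groups["manual"], groups["automatic"]
    if man and auto:
        man_c = sum(1 for e in man if e.concordant)
        auto_c = sum(1 for e in auto if e.concordant)
        table = [[man_c, len(man) - man_c], [auto_c, len(auto) - auto_c]]
        report.p_concordance = float(stats.fisher_exact(table, alternative="two-sided")[1])
        report.p_dsc_crude = float(
            stats.ranksums([e.dsc_crude for e in man], [e.dsc_crude for e in auto]).pvalue
        )
        report.p_dsc_semantic = float(
            stats.ranksums(
                [e.dsc_semantic for e in man], [e.dsc_semantic for e in auto]
            ).pvalue
        )
    return report


@dataclass(frozen=True)
class SensitivityResult:
    """Worst-case figures with excluded pairs scored fully discordant."""

    concordance: float
    dsc_crude: float
    dsc_semantic: float


def worst_case_sensitivity(
    n: int,
    concordant_count: int,
    mean_dsc_crude: float,
    mean_dsc_semantic: float,
    excluded_n: int,
) -> SensitivityResult:
    """Dilute the summary figures assuming every excluded pair scored 0.

    Adjusted concordance = concordant / (n + excluded); adjusted means are
    rescaled by n / (n + excluded). Monotone non-increasing in
    ``excluded_n`` for all three metrics.
    """
    if excluded_n < 0:
        raise EvaluationError("excluded_n must be non-negative")
    denom = n + excluded_n
    if denom <= 0:
        raise EvaluationError("n + excluded_n must be positive")
    return SensitivityResult(
        concordance=concordant_count / denom,
        dsc_crude=mean_dsc_crude * n / denom,
        dsc_semantic=mean_dsc_semantic * n / denom,
    )


def recover_concordant_count(proportion: float, n: int) -> int:
    """Integer concordant count behind a printed proportion: round(p * n)."""
    return int(round(proportion * n))
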
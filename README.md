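# iconalign

Agreement metrics for *compositional medical icons* independently aligned to
two hierarchical terminologies.

Iconic languages such as VCM (Visualization of Concepts in Medicine) build an
icon for a medical concept out of a small vocabulary of graphical
**primitives** — a central color, a shape, a central pictogram, a top-right
color and top-right pictogram(s) — where the primitives themselves sit in a
shallow hierarchy (e.g. *Thyroid* below *Endocrine system*). Before such
icons can be shown in an electronic health record, each terminology used by
the record (a MeSH-like thesaurus, an ICD10-like classification, …) must be
*aligned* to the iconic language: every concept gets one or more icons,
either by hand or by inheriting the icons of its closest manually aligned
ancestor. Alignment errors can propagate into clinical displays, and there
is usually no gold standard to evaluate against.

`iconalign` implements the standard proxy: **inter-alignment agreement**.
Concepts of two terminologies that share a cross identifier (a UMLS-style
CUI) should receive equivalent icons from both alignments; the degree to
which they do is measured per pair with three metrics:

* **concordance** — binary: are the two icons identical?
* **crude Dice** — on the flattened primitive sets,

  `DSC_crude(I1, I2) = 2 |Pr(I1) ∩ Pr(I2)| / (|Pr(I1)| + |Pr(I2)|)`

* **semantic Dice** — exact overlap replaced by the best-match Lin
  similarity in both directions,

  `DSC_semantic(I1, I2) = (Σ_i max_j sim(Pr_i, Pr_j) + Σ_j max_i sim(Pr_i, Pr_j)) / (|Pr(I1)| + |Pr(I2)|)`

  with `sim(Pr_i, Pr_j) = 2 log p(Pr*) / (log p(Pr_i) + log p(Pr_j))`, where
  `Pr*` is the lowest-probability common ancestor and `p(Pr)` the probability
  of meeting `Pr` (or a descendant) in the corpus of all alignment relations.
  `sim` is 1 for identical primitives and 0 when only the root is shared, so
  related-but-distinct primitives (*Thyroid* vs *Endocrine system*) are
  partially credited instead of being scored as disagreement.

The package also provides the closest-ancestor (path-length) icon-inheritance
algorithm for poly-hierarchies, the pairing/filtering/stratification pipeline
(manual vs automatic provenance, Wald/normal 95% CIs, Fisher exact and
Wilcoxon rank-sum tests), a worst-case sensitivity analysis for excluded
multi-icon pairs, and a seedable synthetic-world generator, since real
MeSH/ICD10/UMLS content is proprietary and cannot ship here.

## Worked example

A packaged fixture holds one cross-linked concept pair for subacute
thyroiditis: the thesaurus side used the broad *Endocrine system* pictogram,
the classification side the narrower *Thyroid* plus an *Inflammation*
annotation, with fixture similarities sim(endocrine system, thyroid) = 0.85
and sim(disease, inflammation) = 0.35:

```text
$ iconalign worked-example
concordant:   False
DSC_crude:    0.5714 (= 4/7)
DSC_semantic: 0.8643 (= 6.05/7)
```

The icons share 2 of 3+4 primitives (crude Dice 4/7 ≈ 0.57), but almost all
of the residual disagreement is between semantically close primitives, so
the semantic Dice rises to 6.05/7 ≈ 0.86.

## Synthetic end-to-end run

Synthetic worlds start every cross-linked pair from one shared "true" icon
and perturb the copies with a configurable discordance rate δ (swap one
primitive for a sibling, or generalize it to its parent). A third of the
poly-side concepts are aligned manually; the rest inherit their icons from a
manually aligned ancestor:

```python
import iconalign as ia
from iconalign.pipeline import render_report_text

world = ia.generate_world(ia.SyntheticConfig(seed=42, discordance_rate=0.25))
report, pairs = ia.evaluate_world(world)
print(render_report_text(report))
```

```text
Metric              | Total (n = 560) | Manual (n = 185) | Automatic (n = 375) | p
Concordance         | 65.0% [61.0%-69.0%] | 76.8% [70.7%-82.8%] | 59.2% [54.2%-64.2%] | < 10^-4
DSC crude           | 0.90 [0.88-0.91] | 0.93 [0.91-0.95] | 0.88 [0.86-0.90] | 0.0006
DSC semantic        | 0.97 [0.96-0.97] | 0.98 [0.97-0.98] | 0.96 [0.96-0.97] | 0.0008
Excluded multi-icon pairs: 0 (retained fraction 100.0%)
```

560 concept pairs were scored; the manually aligned stratum agrees better
than the inherited (automatic) one on all three metrics, the semantic Dice
sits above the crude Dice, and the Fisher/Wilcoxon p-values flag the
manual–automatic difference. At δ = 0 all three metrics are exactly 1.

The same pipeline runs from TSV files via the CLI
(`iconalign simulate`, `iconalign evaluate`, `iconalign inherit`,
`iconalign sweep`, `iconalign validate`); see `iconalign --help`.

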
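# medikb

Construction and evaluation of a **medication–indication knowledgebase** in
the style of MEDI-2: linking the drugs of an electronic health record
(RxNorm RxCUIs) to the conditions they treat (ICD-9-CM / ICD-10-CM codes,
with the underlying UMLS CUIs kept alongside), by integrating six public
resources — structured terminology relationships (RxNorm), a drug-label
table (SIDER-style), and four free-text article directories (Mayo Clinic,
MedlinePlus, WebMD, Wikipedia archetypes).

It is written for clinical-informatics researchers who need a computable
drug→indication map for EHR research (drug repurposing, quality-of-care
studies, phenotyping) and who want the full pipeline — extraction,
normalization, aggregation with per-resource provenance, high-precision
subsetting and review-based precision estimation — reproducible and
testable offline.

## What the pipeline does

1. **Ingest** — structured disorder→drug relationships
   (`may_be_treated_by`, `may_be_prevented_by`, `may_be_diagnosed_by`) from
   the prescribable subset of the drug graph; (drug name, indication CUI)
   rows resolved by exact-after-normalization string matching; and
   sectioned articles whose titles are resolved to drug concepts.
2. **Extract** — a deterministic dictionary indexer finds lexicon concepts
   in article text (case-insensitive, token-boundary, longest-match-wins),
   NegEx-style triggers drop negated mentions, side-effect/contraindication
   sections are excluded, and only six indication-bearing semantic types
   survive (Disease or Syndrome, Congenital/Acquired/Anatomical
   Abnormality, Neoplastic Process, Virus).
3. **Normalize** — every drug is grouped to its generic ingredient(s)
   (combined multi-ingredient generic when one exists, otherwise component
   split); indication CUIs map to ICD-9-CM and ICD-10-CM via the concept
   crosswalk, falling back to SNOMED CT bridging; each ICD code is a
   distinct indication, each ICD version a distinct pair.
4. **Aggregate** — identical assertions merge with resource-set union into
   a `PairTable`; the **high-precision subset (HPS)** keeps pairs asserted
   by the anchor resource (RxNorm) *or* by ≥ 3 other resources; editions
   can be union-merged under source flags; the release is a deterministic
   sorted TSV.
5. **Evaluate** — manual-review verdicts (TRUE / FALSE / AMBIGUOUS,
   ambiguous excluded) give per-stratum positive predictive values, and
   combinations are estimated size-weighted:

   ```
   Precision(R) = Σ_{r∈R} size(r) · PPV(r) / Σ_{r∈R} size(r)
   ```

   with PPVs rounded to two decimals before weighting by default
   (`rounding=None` for the exact-fraction variant). A recall harness
   scores a curated indication list per edition.

A first-class synthetic-data generator (`medikb.fixtures`) fabricates a
coherent miniature universe — lexicon, drug graph, crosswalks, structured
tables, articles with planted indications, negations, excluded-section
decoys and independent per-resource noise — with logged ground truth, so
end-to-end precision and recall of a build are exactly computable.

## Worked example

Rebuild the published evaluation table from its review tallies:

```
$ medikb precision
stratum	size	reviewed	true_positive	precision
RxNorm	25051	91	85	0.93
...
exactly 1 (excl. RxNorm)	135787	174	87	0.50
...
>= 3	9437			0.90
overall	186064			0.60
HPS	34488			0.92
```

Reading: RxNorm pairs review at PPV 85/91 = 0.93; pairs seen in exactly one
non-RxNorm resource review at 0.50; weighting the ≥ 3-resource strata by
size gives 0.90, the whole knowledgebase 0.60, and the high-precision
subset (25,051 RxNorm-anchored + 9,437 corroborated pairs = 34,488) 0.92 —
corroboration across independent resources buys precision.

The same machinery end-to-end on a synthetic universe:

```python
from medikb import FixtureSpec, select_hps
from medikb.fixtures import generate, score_against_truth
from medikb.pipeline import build_from_bundle

bundle = generate(FixtureSpec(seed=42, noise_rate=0.25))
table = build_from_bundle(bundle)
score = score_against_truth(table, bundle.truth)
print(len(table), len(select_hps(table)), round(score.precision, 2), score.recall)
# 252 98 0.61 1.0
```

252 pairs are built, every planted true pair is recovered (recall 1.0), and
at 25% independent decoy noise overall precision is 0.61 while the
high-precision subset runs cleaner — the pattern the HPS rule exploits.
With `noise_rate=0` both precision and recall are exactly 1.0.

Command line: `medikb build / hps / merge / stats / sample / precision /
recall / fixtures` (see `medikb --help`).

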
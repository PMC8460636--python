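# Methods

## Problem and data model

The package links ingredient-level drug concepts (RxCUIs) to the conditions
they treat, prevent or help diagnose, coded in ICD-9-CM and ICD-10-CM with
the mediating UMLS CUIs preserved. An assertion is a **pair**
`(rxcui, icd_version, code)` — or `(rxcui, cui)` in the UMLS-level stream —
carrying the set of resources that assert it. Six resource archetypes feed
the build: one structured terminology-relationship table, one drug-label
name/CUI table, and four free-text article directories.

Identity conventions that everything downstream relies on:

* ICD codes are stored dotted (`519.11`, `K86.9`); ICD-9 external-cause
  codes dot after the fourth character, everything else after the third;
  3-character category codes carry no dot. Normalization happens at the
  loading boundary so joins never miss on formatting.
* ICD-9 and ICD-10 are distinguished by an explicit version field, never
  inferred from code shape (V/E codes collide across versions), and the two
  versions of one assertion are **two pairs** — counting follows suit.
* A CUI mapping to several ICD codes yields one pair per code.
* CUI identifiers are validated only for the `C` prefix, not length.

## Extraction (the concept-indexer stand-in)

Article text is matched against the concept lexicon by a deterministic
dictionary indexer: tokens are maximal alphanumeric runs, case-folded by
lowercasing, no stemming; matching is longest-match-wins scanning left to
right, so a shorter concept nested in a chosen longer one ("cancer" inside
"breast cancer") is suppressed, and an ambiguous string yields one mention
per concept. The production NLP system it stands in for is treated as a
black box elsewhere; here the contract is what matters — concepts found,
negated mentions excluded — and a deterministic indexer makes the pipeline
exactly testable. Its behaviour is pinned by an exhaustive-substring oracle
on randomized instances.

Negation is NegEx-style: pre-scope triggers ("no", "not", "without",
"denies", "no evidence of", ...) negate mentions starting within a
5-token window (configurable) unless a scope terminator ("but", "however",
".", ";") intervenes; post-scope triggers ("ruled out", "unlikely") mirror
this to the left. Sections whose headings contain "side effect", "adverse",
"contraindication" or "warning" (case-insensitive substrings) are dropped
before indexing; "precautions" is deliberately **not** excluded by default.
Mentions survive only if non-negated and typed in the indication whitelist:
Disease or Syndrome, Congenital Abnormality, Acquired Abnormality,
Anatomical Abnormality, Neoplastic Process, Virus.

Structured sources bypass extraction and the semantic-type filter entirely
(their indications already arrive as curated CUIs), and the prescribable
filter applies only to the structured relationship source — consumer
resources legitimately carry supplements and withdrawn drugs.

## Normalization

Medication names resolve by exact matching after light normalization
(lowercase, collapse whitespace, strip surrounding punctuation, unify `/`
spacing). Matching is deliberately not fuzzy: fuzzy hits would inject
unauditable pairs. Ambiguity is preserved — a name matching several
concepts contributes its indications to each.

Generic-ingredient grouping: an ingredient-level concept maps to itself; a
product with a combined multi-ingredient generic maps to that generic;
otherwise a single ingredient, or a component split. Grouping is idempotent
(outputs are fixed points). Concepts with no path to an ingredient are
dropped and counted.

CUI→ICD mapping resolves each ICD version independently: direct crosswalk
first, else the union of SNOMED CT bridge mappings over the CUI's SNOMED
concepts; `via_snomed` flags record when the fallback fired. Empty results
are legal (the pair then lives only in the CUI-level stream, which is
released alongside the ICD streams for NLP consumers).

## Aggregation, HPS, merging

Pairs merge by identity with resource-set and relation-flag union;
aggregation is associative and order-independent. Support strata count the
resources per pair, optionally excluding the anchor resource; pairs
supported only by the excluded resource fall out of every stratum, which
gives the conservation identity `Σ_k strata(k) + anchor-only = total`.

The high-precision subset keeps a pair iff the anchor resource asserts it
**or** at least `min_other_resources` (default 3) non-anchor resources do —
the ≥3 count never includes the anchor. HPS membership is evaluated on ICD
pairs and CUI-level pairs alike. Union merges of knowledgebase editions
keep per-edition source flags; on conflicting drug names the first table
wins with a warning.

The release TSV has fixed column order (identity, one boolean per resource,
`N_OTHER_RESOURCES`, `HPS`, `MEDI_SOURCE`) and fixed sort order (numeric
RxCUI, version, code), so equal tables serialize byte-identically.

## Precision estimation

Reviews carry verdicts TRUE / FALSE / AMBIGUOUS; ambiguous pairs (e.g.
catch-all ICD codes) are excluded from denominators, so
`PPV = TRUE / (TRUE + FALSE)`. Combinations of strata are estimated by the
size-weighted mean `Σ size(r)·PPV(r) / Σ size(r)`. PPVs are rounded to two
decimals before weighting **by default**: printed two-decimal tables are
reproduced exactly that way (the ≥4-resource combination prints 0.92 with
rounded PPVs but 0.93 with exact fractions), and the sensitivity is bounded
(≤ 0.005 on these inputs) with `rounding=None` exposed. The estimator is
provably inside `[min PPV, max PPV]`, order-invariant and scale-invariant —
property-tested.

The published MEDI-2 review tallies and stratum sizes ship as input
constants; every precision figure is recomputed from them at run time.
Review sampling is uniform without replacement over a deterministic pair
ordering, reproducible under a seed. The recall harness consumes human
verdict files (found/not-found per edition) and never auto-judges truth;
the default reference-drug list is propranolol, methotrexate, sildenafil,
gabapentin and estradiol.

## The synthetic-data generator

`medikb.fixtures.generate` emulates the *structure* of the live inputs, not
their content: pseudo-word drug and disorder vocabularies (disorders get
multi-word synonyms to exercise longest-match), a drug graph with brands,
combined generics and component-split products, crosswalks with a
configurable SNOMED-only fraction, and per-resource plantings of each true
pair at the default coverage probabilities (RxNorm 0.50, WebMD 0.40, Mayo
Clinic/Wikipedia 0.35, MedlinePlus/SIDER 0.30 — chosen so a typical pair is
seen by one to three resources, the regime in which corroboration is
informative). 10% of ingredients are non-prescribable and are never planted
in the structured source, mirroring the prescribable filter.

**Noise model.** Each planting slot independently becomes, with probability
`noise_rate`, a decoy assertion of a disorder the drug does not treat.
Independence across resources is a modeling choice (the real phenomenon's
mechanism is unobserved): it is exactly what makes multi-resource support
informative. Two consequences are built in rather than accidental: the
single-resource stratum is *enriched* in decoys (true pairs spread upward
across strata, decoys almost never coincide), so its precision sits well
below the per-resource assertion precision `1 − noise_rate`; its analytic
(Poisson-binomial) expectation is what the tests check. Articles
additionally carry negated mentions, excluded-section mentions and
non-whitelisted-concept mentions of *non-indicated* disorders — pure decoys
that a correct extractor must drop, so at `noise_rate=0` end-to-end
precision and recall are exactly 1.0 against the planted truth.

What the generator does **not** emulate: real medical vocabulary and its
ambiguity, derivational/inflectional variation, sentence complexity,
correlated errors between resources that copy from each other, and scrape
artifacts. Passing tests therefore certify the pipeline's logic and
bookkeeping, not extraction accuracy on real consumer-health prose.

## Numerical and degenerate-input conventions

Ties in longest-match resolve leftmost-first; ambiguous matches emit all
concepts sorted by CUI. Empty ICD mappings, empty match sets and empty
strata are legal data outcomes; empty review sets, zero stratum sizes and
unknown CUIs in mentions are errors. All randomness (sampling, generation)
flows through explicit integer seeds; nothing reads global RNG state.

## Problem sizes

Default test and acceptance universes use 12–16 ingredients, ~30–40
disorders and a few hundred built pairs per seed, pooled over up to 20
seeds for stratified-precision checks — large enough for the binomial error
bands the assertions use, small enough that the whole suite runs in
seconds. Published-table arithmetic is exact desk arithmetic at the printed
sizes (186,064 pairs; HPS 34,488 = 25,051 anchor + 9,437 corroborated).

## Known limitations

* Name matching is exact; misspelled or reformatted drug names drop out
  (counted, not recovered).
* The indexer has no word-sense disambiguation or acronym expansion.
* Negation handling is trigger/window-based; long-range or morphological
  negation escapes it.
* The full published knowledgebase content (3,031 medications) is not
  reproducible here — it requires licensed terminology releases and live
  site scraping, both out of scope; the released arithmetic and all
  pipeline behavior are.
* Recall against clinical truth requires human curation; the harness only
  scores supplied verdicts.
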
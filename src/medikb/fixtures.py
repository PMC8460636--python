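"""Synthetic mini-universe generator with recorded ground truth.

Real builds of a medication-indication knowledgebase consume a licensed
terminology release, a drug-concept graph and scraped consumer-health
articles — none of which can ship with the package.  This module fabricates
a coherent miniature replacement: a disorder lexicon with multi-word
synonyms, a drug graph with brands and multi-ingredient products, CUI->ICD
crosswalks with a controllable SNOMED-only fraction, structured
relationship rows, side-effect-resource-style name/CUI rows, and sectioned
articles in which every planted indication is embedded in a
natural-language template sentence.

Everything planted is logged in a :class:`GroundTruth` object, so
end-to-end precision and recall of a build are exactly computable.  Noise
is injected independently per resource: each planting slot becomes, with
probability ``noise_rate``, a decoy assertion of a disorder the drug does
not treat.  Independent noise is what makes corroboration across resources
informative, and it is the mechanism behind the qualitative pattern that
stratum precision rises with support count.  Articles additionally carry
negated mentions, mentions in excluded (side-effect) sections and mentions
of non-whitelisted concepts — all decoys a correct extractor must drop.

Generation is deterministic under ``FixtureSpec.seed``: the same spec
yields byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from .source_ingest import (
    Article,
    RelationshipRow,
    write_article_corpus,
    write_name_cui_rows,
    write_relationship_rows,
)
from .terminology import (
    ConceptRecord,
    CrossWalk,
    MedConcept,
    RxGraph,
    write_crosswalk,
    write_lexicon,
    write_rxgraph,
)

ARTICLE_RESOURCES = ("Mayo Clinic", "MedlinePlus", "WebMD", "Wikipedia")

DEFAULT_COVERAGE = {
    "RxNorm": 0.50,
    "Mayo Clinic": 0.35,
    "MedlinePlus": 0.30,
    "SIDER 4.1": 0.30,
    "WebMD": 0.40,
    "Wikipedia": 0.35,
}

_CLEAN_TEMPLATES = (
    "{drug} is used to treat {disorder}.",
    "Doctors prescribe {drug} for patients suffering from {disorder}.",
    "{drug} is indicated for the management of {disorder}.",
    "Clinical guidelines recommend {drug} in adults with {disorder}.",
)

_NEGATED_TEMPLATES = (
    "There is no evidence of benefit in {disorder}.",
    "This medicine does not treat {disorder}.",
    "Use in {disorder} has been ruled out.",
)

_SUBSTANCE_TEMPLATES = (
    "Serum {substance} levels may change during therapy.",
    "Avoid combining this medicine with {substance}.",
)

_DISORDER_ADJ = (
    "cardiac", "renal", "hepatic", "neural", "dermal", "ocular",
    "gastric", "spinal", "arterial", "bronchial", "lymphatic", "osseous",
)
_DISORDER_NOUN = (
    "flumenosis", "taxopathy", "grelitis", "vastoma", "norpexia",
    "quilosis", "brenoma", "stalgia", "fevrosis", "lumenitis",
    "drexia", "polunosis",
)
_DRUG_PRE = ("dor", "vel", "zan", "mir", "tal", "fex", "lor", "quin", "bas", "nov", "per", "sul")
_DRUG_SUF = ("pril", "olol", "mab", "zol", "statin", "caine", "mide", "parin", "vir", "tinib", "oxacin", "micin")
_BRAND_PRE = ("Axo", "Belv", "Cort", "Dyna", "Evo", "Flux", "Gemo", "Halo", "Ixa", "Juv")
_BRAND_SUF = ("dex", "ran", "via", "lon", "tis", "pax", "zia", "mur", "neo", "qel")
_SUBSTANCE_WORDS = ("kalemine", "ferrodox", "lipotran", "gluconex", "zincovar", "cupralin")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic universe."""

    n_ingredients: int = 12
    n_brands: int = 8
    n_multi: int = 4
    n_disorders: int = 30
    indications_min: int = 2
    indications_max: int = 5
    coverage: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    snomed_only_fraction: float = 0.2
    multi_icd10_fraction: float = 0.15
    noise_rate: float = 0.0
    negated_fraction: float = 0.15
    excluded_section_fraction: float = 0.15
    substance_decoy_fraction: float = 0.25
    nonprescribable_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "snomed_only_fraction", "multi_icd10_fraction", "noise_rate",
            "negated_fraction", "excluded_section_fraction",
            "substance_decoy_fraction", "nonprescribable_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_ingredients, self.n_disorders) <= 0:
            raise ValueError("need at least one ingredient and one disorder")
        if self.n_disorders < self.indications_max + 1:
            raise ValueError("too few disorders to draw indications and decoys from")
        if not 1 <= self.indications_min <= self.indications_max:
            raise ValueError("bad indications_min/max")
        for r, p in self.coverage.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"coverage[{r!r}] must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, per resource, with per-mention intent flags."""

    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    support: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    decoy_support: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    # (resource, rxcui, cui, kind); kind in
    # {clean, noise_decoy, negated, excluded_section, substance_decoy}
    mentions: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def planted_true_pairs(self) -> set[tuple[str, str]]:
        """True pairs actually planted in at least one resource."""
        out: set[tuple[str, str]] = set()
        for pairs in self.support.values():
            out |= pairs
        return out

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """Everything a perfect extractor would recover (true + noise decoys)."""
        out = self.planted_true_pairs
        for pairs in self.decoy_support.values():
            out |= pairs
        return out

    def to_json(self) -> str:
        payload = {
            "true_pairs": sorted(self.true_pairs),
            "support": {r: sorted(v) for r, v in sorted(self.support.items())},
            "decoy_support": {r: sorted(v) for r, v in sorted(self.decoy_support.items())},
            "mentions": self.mentions,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            true_pairs={tuple(p) for p in payload["true_pairs"]},
            support={r: {tuple(p) for p in v} for r, v in payload["support"].items()},
            decoy_support={r: {tuple(p) for p in v} for r, v in payload["decoy_support"].items()},
            mentions=[tuple(m) for m in payload["mentions"]],
        )


@dataclass
class FixtureBundle:
    """In-memory fixture universe plus its ground truth."""

    spec: FixtureSpec
    lexicon: dict[str, ConceptRecord]
    rxgraph: RxGraph
    crosswalk: CrossWalk
    relationship_rows: list[RelationshipRow]
    sider_rows: list[tuple[str, str]]
    articles: list[Article]
    truth: GroundTruth

    @property
    def drug_names(self) -> dict[str, str]:
        return {rxcui: c.name for rxcui, c in self.rxgraph.concepts.items()}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_lexicon(self.lexicon, directory / "lexicon.tsv")
        write_rxgraph(self.rxgraph, directory / "rxgraph.tsv")
        write_crosswalk(self.crosswalk, directory)
        write_relationship_rows(self.relationship_rows, directory / "structured_rxnorm.tsv")
        write_name_cui_rows(self.sider_rows, directory / "sider.tsv")
        write_article_corpus(self.articles, directory / "articles")
        (directory / "ground_truth.json").write_text(self.truth.to_json(), encoding="utf-8")
        (directory / "fixture_spec.json").write_text(
            json.dumps(asdict(self.spec), indent=1, sort_keys=True), encoding="utf-8"
        )


def _unique_names(rng: random.Random, prefixes, suffixes, n: int) -> list[str]:
    combos = [p + s for p in prefixes for s in suffixes]
    if n > len(combos):
        raise ValueError(f"cannot generate {n} unique names from the pools")
    rng.shuffle(combos)
    return combos[:n]


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate one universe under ``spec`` (deterministic in ``spec.seed``)."""
    spec.validate()
    rng = random.Random(spec.seed)

    # --- disorder lexicon -------------------------------------------------
    lexicon: dict[str, ConceptRecord] = {}
    disorder_cuis: list[str] = []
    combos = [f"{a} {n}" for a in _DISORDER_ADJ for n in _DISORDER_NOUN]
    if spec.n_disorders > len(combos):
        raise ValueError("too many disorders for the name pools")
    rng.shuffle(combos)
    whitelist_types = (
        "Disease or Syndrome", "Disease or Syndrome", "Disease or Syndrome",
        "Neoplastic Process", "Acquired Abnormality", "Congenital Abnormality",
    )
    for i in range(spec.n_disorders):
        cui = f"C{1000001 + i}"
        name = combos[i]
        synonyms = [f"chronic {name}"]
        if rng.random() < 0.5:
            synonyms.append(f"{name} of the {rng.choice(('heart', 'liver', 'skin', 'lung'))}")
        lexicon[cui] = ConceptRecord(
            cui=cui,
            preferred_name=name,
            synonyms=tuple(synonyms),
            semantic_types=frozenset({whitelist_types[i % len(whitelist_types)]}),
        )
        disorder_cuis.append(cui)

    # non-whitelisted substance concepts (must be filtered out downstream)
    substance_cuis: list[str] = []
    for i, word in enumerate(_SUBSTANCE_WORDS):
        cui = f"C{2000001 + i}"
        lexicon[cui] = ConceptRecord(
            cui=cui, preferred_name=word,
            semantic_types=frozenset({"Pharmacologic Substance"}),
        )
        substance_cuis.append(cui)

    # --- crosswalk --------------------------------------------------------
    crosswalk = CrossWalk()
    for i, cui in enumerate(disorder_cuis):
        icd9 = frozenset({f"{300 + i}.{i % 10}"})
        stem10 = f"{chr(65 + i % 26)}{i // 26:02d}"
        codes10 = {f"{stem10}.{i % 10}"}
        if rng.random() < spec.multi_icd10_fraction:
            codes10.add(f"{stem10}.{(i + 1) % 10}")
        snomed_id = f"S{700001 + i}"
        crosswalk.cui_to_snomed[cui] = frozenset({snomed_id})
        if rng.random() < spec.snomed_only_fraction:
            crosswalk.snomed_to_icd9[snomed_id] = icd9
            crosswalk.snomed_to_icd10[snomed_id] = frozenset(codes10)
        else:
            crosswalk.cui_to_icd9[cui] = icd9
            crosswalk.cui_to_icd10[cui] = frozenset(codes10)

    # --- drug graph -------------------------------------------------------
    rxgraph = RxGraph()
    ingredient_names = _unique_names(rng, _DRUG_PRE, _DRUG_SUF, spec.n_ingredients)
    ingredients: list[str] = []
    for i, name in enumerate(ingredient_names):
        rxcui = str(1001 + i)
        prescribable = rng.random() >= spec.nonprescribable_fraction
        rxgraph.add(MedConcept(rxcui=rxcui, name=name, term_type="INGREDIENT",
                               prescribable=prescribable))
        ingredients.append(rxcui)

    brands_of: dict[str, list[str]] = {i: [] for i in ingredients}
    brand_names = _unique_names(rng, _BRAND_PRE, _BRAND_SUF, spec.n_brands)
    for j, name in enumerate(brand_names):
        rxcui = str(5001 + j)
        target = ingredients[j % len(ingredients)]
        rxgraph.add(
            MedConcept(rxcui=rxcui, name=name, term_type="BRAND",
                       prescribable=rxgraph.concepts[target].prescribable),
            ingredients=[target],
        )
        brands_of[target].append(rxcui)

    # multi-ingredient products: even index -> combined generic exists,
    # odd index -> product splits into its component ingredients
    multi_generics: list[str] = []
    for j in range(spec.n_multi):
        a = ingredients[(2 * j) % len(ingredients)]
        b = ingredients[(2 * j + 1) % len(ingredients)]
        if a == b:
            continue
        product_rxcui = str(6001 + j)
        product_name = f"{rxgraph.name_of(a)} with {rxgraph.name_of(b)} tablet"
        prescribable = rxgraph.concepts[a].prescribable and rxgraph.concepts[b].prescribable
        if j % 2 == 0:
            generic_rxcui = str(7001 + j)
            generic_name = f"{rxgraph.name_of(a)} / {rxgraph.name_of(b)}"
            rxgraph.add(MedConcept(rxcui=generic_rxcui, name=generic_name,
                                   term_type="MULTI_INGREDIENT", prescribable=prescribable))
            rxgraph.add(
                MedConcept(rxcui=product_rxcui, name=product_name,
                           term_type="CLINICAL_DRUG", prescribable=prescribable),
                ingredients=[generic_rxcui],
            )
            multi_generics.append(generic_rxcui)
        else:
            rxgraph.add(
                MedConcept(rxcui=product_rxcui, name=product_name,
                           term_type="CLINICAL_DRUG", prescribable=prescribable),
                ingredients=[a, b],
            )
    rxgraph.validate()

    # --- true pairs -------------------------------------------------------
    truth = GroundTruth(
        support={r: set() for r in spec.coverage},
        decoy_support={r: set() for r in spec.coverage},
    )
    drug_entities = ingredients + multi_generics
    indications: dict[str, list[str]] = {}
    for d in drug_entities:
        k = rng.randint(spec.indications_min, spec.indications_max)
        chosen = rng.sample(disorder_cuis, k)
        indications[d] = chosen
        truth.true_pairs.update((d, c) for c in chosen)

    def draw_decoy(d: str) -> str:
        pool = [c for c in disorder_cuis if c not in indications[d]]
        return rng.choice(pool)

    # --- planting slots per resource --------------------------------------
    # planted[resource][drug] -> list of (cui, is_decoy)
    planted: dict[str, dict[str, list[tuple[str, bool]]]] = {
        r: {} for r in spec.coverage
    }
    for d in drug_entities:
        for c in indications[d]:
            for resource in sorted(spec.coverage):
                if resource == "RxNorm" and not rxgraph.concepts[d].prescribable:
                    continue  # the prescribable filter would drop the row anyway
                if rng.random() >= spec.coverage[resource]:
                    continue
                if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                    decoy = draw_decoy(d)
                    planted[resource].setdefault(d, []).append((decoy, True))
                    truth.decoy_support[resource].add((d, decoy))
                    truth.mentions.append((resource, d, decoy, "noise_decoy"))
                else:
                    planted[resource].setdefault(d, []).append((c, False))
                    truth.support[resource].add((d, c))
                    truth.mentions.append((resource, d, c, "clean"))

    # --- structured RxNorm-style rows --------------------------------------
    relationship_rows: list[RelationshipRow] = []
    relations = ("may_be_treated_by",) * 4 + ("may_be_prevented_by", "may_be_diagnosed_by")
    for d in drug_entities:
        for cui, _ in planted["RxNorm"].get(d, []):
            subject = d
            if brands_of.get(d) and rng.random() < 0.3:
                subject = rng.choice(brands_of[d])
            relationship_rows.append(
                RelationshipRow(subject_cui=cui, relation=rng.choice(relations),
                                object_rxcui=subject)
            )

    # --- SIDER-style name/CUI rows -----------------------------------------
    sider_rows: list[tuple[str, str]] = []
    for d in drug_entities:
        for cui, _ in planted["SIDER 4.1"].get(d, []):
            name = rxgraph.name_of(d)
            if brands_of.get(d) and rng.random() < 0.3:
                name = rxgraph.name_of(rng.choice(brands_of[d]))
            if rng.random() < 0.3:
                name = name.upper()
            sider_rows.append((name, cui))

    # --- articles -----------------------------------------------------------
    def disorder_surface(cui: str) -> str:
        rec = lexicon[cui]
        return rng.choice(rec.all_names)

    articles: list[Article] = []
    for resource in ARTICLE_RESOURCES:
        for d in drug_entities:
            slots = planted[resource].get(d)
            if not slots:
                continue
            title = rxgraph.name_of(d)
            if brands_of.get(d) and rng.random() < 0.3:
                title = rxgraph.name_of(rng.choice(brands_of[d]))
            uses: list[str] = []
            for cui, _ in slots:
                template = rng.choice(_CLEAN_TEMPLATES)
                uses.append(template.format(drug=title.capitalize(),
                                            disorder=disorder_surface(cui)))
            if rng.random() < spec.negated_fraction:
                decoy = draw_decoy(d)
                uses.append(rng.choice(_NEGATED_TEMPLATES).format(
                    disorder=disorder_surface(decoy)))
                truth.mentions.append((resource, d, decoy, "negated"))
            if rng.random() < spec.substance_decoy_fraction:
                sub = rng.choice(substance_cuis)
                uses.append(rng.choice(_SUBSTANCE_TEMPLATES).format(
                    substance=lexicon[sub].preferred_name))
                truth.mentions.append((resource, d, sub, "substance_decoy"))
            sections = [("Uses", " ".join(uses))]
            if rng.random() < spec.excluded_section_fraction:
                decoy = draw_decoy(d)
                sections.append(
                    ("Side Effects",
                     f"Treatment may cause {disorder_surface(decoy)} in rare cases.")
                )
                truth.mentions.append((resource, d, decoy, "excluded_section"))
            sections.append(("Storage", "Store at room temperature away from moisture."))
            articles.append(Article(resource=resource, title=title,
                                    sections=tuple(sections)))

    return FixtureBundle(
        spec=spec,
        lexicon=lexicon,
        rxgraph=rxgraph,
        crosswalk=crosswalk,
        relationship_rows=relationship_rows,
        sider_rows=sider_rows,
        articles=articles,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Scoring a build against the ground truth


@dataclass(frozen=True)
class StratumScore:
    n_true: int
    n_total: int

    @property
    def precision(self) -> float:
        return self.n_true / self.n_total if self.n_total else float("nan")


@dataclass
class ScoreReport:
    """End-to-end bookkeeping of a built table against planted truth."""

    n_built: int
    n_true_built: int
    n_planted_true: int
    per_stratum: dict[int, StratumScore]

    @property
    def precision(self) -> float:
        return self.n_true_built / self.n_built if self.n_built else float("nan")

    @property
    def recall(self) -> float:
        """Planted true pairs recovered (of those planted in >= 1 resource)."""
        return self.n_true_built / self.n_planted_true if self.n_planted_true else float("nan")


def score_against_truth(built, truth: GroundTruth) -> ScoreReport:
    """Compare the CUI-level stream of a built :class:`PairTable` with the
    planted ground truth, overall and per support-count stratum."""
    from .aggregation import PairTable, cui_stream

    if not isinstance(built, PairTable):
        raise TypeError("built must be a PairTable")
    universe_pairs = truth.planted_pairs
    built_pairs: dict[tuple[str, str], int] = {}
    for pair in cui_stream(built):
        for cui in pair.cuis:
            built_pairs[(pair.rxcui, cui)] = len(pair.resources)
    unknown = {p for p in built_pairs if p not in universe_pairs}
    # anything built that was never planted in any form is a universe mismatch
    # unless it arose from extraction error; report it in stratum bookkeeping
    per_stratum: dict[int, list[bool]] = {}
    n_true_built = 0
    for key, k in built_pairs.items():
        is_true = key in truth.true_pairs
        n_true_built += is_true
        per_stratum.setdefault(k, []).append(is_true)
    report = ScoreReport(
        n_built=len(built_pairs),
        n_true_built=n_true_built,
        n_planted_true=len(truth.planted_true_pairs),
        per_stratum={
            k: StratumScore(n_true=sum(v), n_total=len(v))
            for k, v in sorted(per_stratum.items())
        },
    )
    if unknown and len(unknown) > 0.5 * max(len(universe_pairs), 1):
        raise ValueError("built table does not share the fixture universe")
    return report
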
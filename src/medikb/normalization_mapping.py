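"""Medication-name matching, generic-ingredient grouping and CUI->ICD mapping.

Three normalization steps sit between raw source triples and the aggregated
pair table:

* free-text medication names (article titles, side-effect-resource rows) are
  resolved to RxCUIs by exact string matching after light normalization;
* every drug concept is grouped to its generic ingredient(s) — a combined
  multi-ingredient generic when one exists, otherwise the single-ingredient
  components;
* indication CUIs are mapped to ICD-9-CM and ICD-10-CM codes, falling back
  to SNOMED CT bridging when a direct mapping is absent.  Each ICD code a
  CUI maps to counts as a distinct indication, and the two ICD versions are
  kept as distinct pairs throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

from .terminology import ConceptRecord, CrossWalk, RxGraph

if TYPE_CHECKING:  # pragma: no cover
    from .source_ingest import RawTriple

logger = logging.getLogger(__name__)

#: icd_version labels used on pair records; the CUI stream carries the
#: UMLS-level pairs that accompany the ICD-coded release.
VERSION_9 = "9"
VERSION_10 = "10"
VERSION_CUI = "CUI"

#: Grouping routes, in the order they are attempted.
ALREADY_INGREDIENT = "ALREADY_INGREDIENT"
SINGLE_INGREDIENT_MAP = "SINGLE_INGREDIENT_MAP"
MULTI_INGREDIENT_MAP = "MULTI_INGREDIENT_MAP"
COMPONENT_SPLIT = "COMPONENT_SPLIT"


class GroupingFailure(LookupError):
    """A drug concept with no path to an ingredient-level concept."""


@dataclass(frozen=True)
class GroupingResult:
    input_rxcui: str
    ingredient_rxcuis: frozenset[str]
    route: str


@dataclass(frozen=True)
class IcdMappingResult:
    """ICD codes for one CUI, per version, with fallback provenance.

    ``via_snomed_9`` / ``via_snomed_10`` are true only when the direct
    CUI->ICD lookup for that version was empty and SNOMED bridging supplied
    the codes.
    """

    cui: str
    icd9: frozenset[str]
    icd10: frozenset[str]
    via_snomed_9: bool = False
    via_snomed_10: bool = False


@dataclass(frozen=True)
class PairRecord:
    """One normalized medication-indication assertion from one resource."""

    rxcui: str
    cui: str
    icd_version: str
    code: str
    resource: str
    relation_flag: str = ""
    via_snomed: bool = False


_PUNCT_STRIP = " \t\r\n\"'.,;:()[]"


def normalize_name(name: str) -> str:
    """Lowercase, collapse whitespace, strip surrounding punctuation and
    unify slash spacing — the equivalence used for exact name matching."""
    name = name.strip(_PUNCT_STRIP).lower()
    name = re.sub(r"\s*/\s*", " / ", name)
    name = re.sub(r"\s+", " ", name)
    return name


class NameMatcher:
    """Exact-after-normalization index from drug names to RxCUIs."""

    def __init__(self, rxgraph: RxGraph) -> None:
        self._index: dict[str, frozenset[str]] = {}
        acc: dict[str, set[str]] = {}
        for concept in rxgraph.concepts.values():
            for name in (concept.name, *concept.synonyms):
                acc.setdefault(normalize_name(name), set()).add(concept.rxcui)
        self._index = {k: frozenset(v) for k, v in acc.items()}

    def match(self, name: str) -> frozenset[str]:
        if not name or not name.strip():
            raise ValueError("empty medication name")
        return self._index.get(normalize_name(name), frozenset())


def match_medication_name(
    name: str,
    rxgraph: RxGraph,
    lexicon: Mapping[str, ConceptRecord] | None = None,
    _cache: dict[int, NameMatcher] = {},
) -> frozenset[str]:
    """Resolve a medication name to the set of RxCUIs bearing it.

    Matching is exact and case-insensitive after :func:`normalize_name`;
    ambiguity is returned, not resolved — all matching RxCUIs come back and
    the caller decides.  An empty set means no match.  ``lexicon`` is
    accepted for signature compatibility; drug synonyms live on the graph.
    """
    key = id(rxgraph)
    matcher = _cache.get(key)
    if matcher is None:
        _cache.clear()  # one graph at a time is the common case
        matcher = _cache[key] = NameMatcher(rxgraph)
    return matcher.match(name)


def group_to_ingredient(rxcui: str, rxgraph: RxGraph) -> GroupingResult:
    """Group a drug concept to its generic ingredient(s).

    An ingredient-level concept maps to itself.  A product with a combined
    multi-ingredient generic maps to that generic; otherwise a product maps
    to its single ingredient, or splits into its component ingredients.
    """
    concept = rxgraph.concepts.get(rxcui)
    if concept is None:
        raise GroupingFailure(f"unknown rxcui {rxcui}")
    if concept.is_ingredient_level:
        return GroupingResult(rxcui, frozenset({rxcui}), ALREADY_INGREDIENT)
    targets = rxgraph.ingredient_of.get(rxcui, frozenset())
    if not targets:
        raise GroupingFailure(f"rxcui {rxcui} has no ingredient edges")
    multi = {t for t in targets if rxgraph.concepts[t].term_type == "MULTI_INGREDIENT"}
    if multi:
        return GroupingResult(rxcui, frozenset(multi), MULTI_INGREDIENT_MAP)
    if len(targets) == 1:
        return GroupingResult(rxcui, frozenset(targets), SINGLE_INGREDIENT_MAP)
    return GroupingResult(rxcui, frozenset(targets), COMPONENT_SPLIT)


def map_cui_to_icd(cui: str, crosswalk: CrossWalk) -> IcdMappingResult:
    """Map an indication CUI to ICD-9-CM and ICD-10-CM code sets.

    Each ICD version is resolved independently: the direct CUI->ICD table
    when it has entries, else the union over the CUI's SNOMED CT concepts
    of the SNOMED->ICD table.  Empty sets are a legal outcome.
    """
    snomed_ids = crosswalk.cui_to_snomed.get(cui, frozenset())

    def resolve(direct: Mapping[str, frozenset[str]], bridge: Mapping[str, frozenset[str]]):
        codes = direct.get(cui, frozenset())
        if codes:
            return codes, False
        via: set[str] = set()
        for sid in snomed_ids:
            via.update(bridge.get(sid, frozenset()))
        return frozenset(via), bool(via)

    icd9, via9 = resolve(crosswalk.cui_to_icd9, crosswalk.snomed_to_icd9)
    icd10, via10 = resolve(crosswalk.cui_to_icd10, crosswalk.snomed_to_icd10)
    return IcdMappingResult(cui=cui, icd9=icd9, icd10=icd10,
                            via_snomed_9=via9, via_snomed_10=via10)


@dataclass
class NormalizationStats:
    grouping_failures: int = 0
    unmapped_cuis: int = 0


def normalize_triples(
    triples: Iterable["RawTriple"],
    rxgraph: RxGraph,
    crosswalk: CrossWalk,
    stats: NormalizationStats | None = None,
) -> list[PairRecord]:
    """Group each raw triple to ingredient level and expand to coded pairs.

    Every triple yields one CUI-level record per ingredient (the UMLS
    stream, ``icd_version="CUI"``) plus one record per (ingredient, ICD
    version, ICD code).  Triples whose drug cannot be grouped are dropped
    and counted.
    """
    stats = stats if stats is not None else NormalizationStats()
    out: list[PairRecord] = []
    icd_cache: dict[str, IcdMappingResult] = {}
    for triple in triples:
        try:
            grouping = group_to_ingredient(triple.rxcui, rxgraph)
        except GroupingFailure:
            stats.grouping_failures += 1
            logger.warning("dropping triple for ungroupable rxcui %s", triple.rxcui)
            continue
        mapping = icd_cache.get(triple.indication_cui)
        if mapping is None:
            mapping = icd_cache[triple.indication_cui] = map_cui_to_icd(
                triple.indication_cui, crosswalk
            )
        if not mapping.icd9 and not mapping.icd10:
            stats.unmapped_cuis += 1
        for ingredient in sorted(grouping.ingredient_rxcuis):
            out.append(
                PairRecord(
                    rxcui=ingredient,
                    cui=triple.indication_cui,
                    icd_version=VERSION_CUI,
                    code="",
                    resource=triple.resource,
                    relation_flag=triple.relation_flag,
                )
            )
            for version, codes, via in (
                (VERSION_9, mapping.icd9, mapping.via_snomed_9),
                (VERSION_10, mapping.icd10, mapping.via_snomed_10),
            ):
                for code in sorted(codes):
                    out.append(
                        PairRecord(
                            rxcui=ingredient,
                            cui=triple.indication_cui,
                            icd_version=version,
                            code=code,
                            resource=triple.resource,
                            relation_flag=triple.relation_flag,
                            via_snomed=via,
                        )
                    )
    return out
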
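"""End-to-end knowledgebase build: sources -> triples -> normalized pairs -> table.

Structured relationship rows (with the prescribable filter), name/CUI rows
and free-text articles are ingested, article text goes through concept
extraction, all raw triples are grouped to generic ingredients and expanded
to ICD-coded pairs, and the per-resource streams are aggregated into one
provenance-tracked :class:`~medikb.aggregation.PairTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .aggregation import PairTable, aggregate
from .concept_extraction import ExtractionConfig
from .normalization_mapping import NormalizationStats, normalize_triples
from .source_ingest import (
    Article,
    IngestStats,
    RESOURCES,
    RelationshipRow,
    extract_article_triples,
    extract_structured_relationships,
    ingest_name_cui_table,
    load_article_corpus,
    load_name_cui_rows,
    load_relationship_rows,
)
from .terminology import (
    ConceptRecord,
    CrossWalk,
    RxGraph,
    load_crosswalk,
    load_lexicon,
    load_rxgraph,
)


@dataclass
class BuildStats:
    ingest: IngestStats = field(default_factory=IngestStats)
    normalization: NormalizationStats = field(default_factory=NormalizationStats)
    raw_triples: int = 0


def build_pair_table(
    lexicon: Mapping[str, ConceptRecord],
    rxgraph: RxGraph,
    crosswalk: CrossWalk,
    relationship_rows: Sequence[RelationshipRow] = (),
    name_cui_rows: Sequence[tuple[str, str]] = (),
    articles: Sequence[Article] = (),
    config: ExtractionConfig | None = None,
    prescribable_only: bool = True,
    resource_universe: Sequence[str] = RESOURCES,
    stats: BuildStats | None = None,
) -> PairTable:
    """Build the aggregated pair table from the three source archetypes."""
    stats = stats if stats is not None else BuildStats()
    config = config or ExtractionConfig()
    triples = []
    triples += extract_structured_relationships(
        relationship_rows, rxgraph, prescribable_only=prescribable_only,
        stats=stats.ingest,
    )
    triples += ingest_name_cui_table(name_cui_rows, lexicon, rxgraph, stats=stats.ingest)
    triples += extract_article_triples(articles, rxgraph, lexicon, config,
                                       stats=stats.ingest)
    stats.raw_triples = len(triples)
    records = normalize_triples(triples, rxgraph, crosswalk, stats=stats.normalization)
    drug_names = {rxcui: c.name for rxcui, c in rxgraph.concepts.items()}
    table = aggregate(records, drug_names=drug_names, resource_universe=resource_universe)
    table.provenance["n_raw_triples"] = stats.raw_triples
    table.provenance["grouping_failures"] = stats.normalization.grouping_failures
    return table


def build_from_bundle(bundle, config: ExtractionConfig | None = None,
                      stats: BuildStats | None = None) -> PairTable:
    """Build directly from an in-memory fixture bundle."""
    return build_pair_table(
        lexicon=bundle.lexicon,
        rxgraph=bundle.rxgraph,
        crosswalk=bundle.crosswalk,
        relationship_rows=bundle.relationship_rows,
        name_cui_rows=bundle.sider_rows,
        articles=bundle.articles,
        config=config,
        resource_universe=tuple(sorted(bundle.spec.coverage)),
        stats=stats,
    )


def build_from_dir(directory: str | Path, config: ExtractionConfig | None = None,
                   stats: BuildStats | None = None) -> PairTable:
    """Build from a directory in the fixture file layout (lexicon.tsv,
    rxgraph.tsv, crosswalk_*.tsv, structured_rxnorm.tsv, sider.tsv,
    articles/)."""
    directory = Path(directory)
    lexicon = load_lexicon(directory / "lexicon.tsv")
    rxgraph = load_rxgraph(directory / "rxgraph.tsv")
    crosswalk = load_crosswalk(directory)
    rel_path = directory / "structured_rxnorm.tsv"
    sider_path = directory / "sider.tsv"
    articles_dir = directory / "articles"
    articles = load_article_corpus(articles_dir) if (articles_dir / "manifest.tsv").exists() else []
    universe = sorted(
        set(RESOURCES) | {a.resource for a in articles}
    ) if articles else list(RESOURCES)
    return build_pair_table(
        lexicon=lexicon,
        rxgraph=rxgraph,
        crosswalk=crosswalk,
        relationship_rows=load_relationship_rows(rel_path) if rel_path.exists() else [],
        name_cui_rows=load_name_cui_rows(sider_path) if sider_path.exists() else [],
        articles=articles,
        config=config,
        resource_universe=tuple(universe),
        stats=stats,
    )
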
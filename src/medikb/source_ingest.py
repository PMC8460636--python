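"""Ingestion of the six resource archetypes into raw medication-indication triples.

Two resources are structured: an RxNorm-style table of disorder-to-drug
relationships (``may_be_treated_by``, ``may_be_prevented_by``,
``may_be_diagnosed_by`` — the diagnosed-by flag is kept because it carries
true indications such as levothyroxine for disorders of the thyroid gland),
and a side-effect-resource-style table of (drug name, indication CUI) rows.
The other four (consumer-health and encyclopedia articles) arrive as
sectioned free-text articles whose titles are resolved to drugs; their
bodies go through :mod:`medikb.concept_extraction`.

Structured sources bypass concept extraction and the semantic-type filter:
their indications already arrive as CUIs.  The prescribable filter applies
to the structured RxNorm-style source only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .normalization_mapping import match_medication_name
from .terminology import ConceptRecord, RxGraph

if TYPE_CHECKING:  # pragma: no cover
    from .concept_extraction import ExtractionConfig

logger = logging.getLogger(__name__)

#: The six resources, in release-column order.
RESOURCES = ("RxNorm", "Mayo Clinic", "MedlinePlus", "SIDER 4.1", "WebMD", "Wikipedia")

RELATIONS = ("may_be_treated_by", "may_be_prevented_by", "may_be_diagnosed_by")


@dataclass(frozen=True)
class RelationshipRow:
    """A structured disorder->drug relationship row."""

    subject_cui: str
    relation: str
    object_rxcui: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class Article:
    """A drug article: resource, title and ordered (heading, body) sections."""

    resource: str
    title: str
    sections: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class RawTriple:
    """One pre-grouping (drug, indication CUI, resource) assertion."""

    rxcui: str
    indication_cui: str
    resource: str
    relation_flag: str = ""


@dataclass
class IngestStats:
    unknown_rxcui: int = 0
    non_prescribable: int = 0
    unresolved_names: int = 0
    unresolved_titles: int = 0


def extract_structured_relationships(
    rows: Iterable[RelationshipRow],
    rxgraph: RxGraph,
    prescribable_only: bool = True,
    resource: str = "RxNorm",
    stats: IngestStats | None = None,
) -> list[RawTriple]:
    """Turn relationship rows into triples, preserving the relation flag.

    Rows referencing unknown drugs are skipped and counted; when
    ``prescribable_only`` is set, drugs not flagged prescribable are dropped.
    """
    stats = stats if stats is not None else IngestStats()
    triples: list[RawTriple] = []
    for row in rows:
        concept = rxgraph.concepts.get(row.object_rxcui)
        if concept is None:
            stats.unknown_rxcui += 1
            logger.warning("skipping relationship row with unknown rxcui %s", row.object_rxcui)
            continue
        if prescribable_only and not concept.prescribable:
            stats.non_prescribable += 1
            continue
        triples.append(
            RawTriple(
                rxcui=row.object_rxcui,
                indication_cui=row.subject_cui,
                resource=resource,
                relation_flag=row.relation,
            )
        )
    return triples


def ingest_name_cui_table(
    rows: Iterable[tuple[str, str]],
    lexicon: Mapping[str, ConceptRecord],
    rxgraph: RxGraph,
    resource: str = "SIDER 4.1",
    stats: IngestStats | None = None,
) -> list[RawTriple]:
    """Turn (drug name, indication CUI) rows into triples.

    Drug names are resolved with the exact-after-normalization name matcher;
    a name matching several RxCUIs contributes the indication to each;
    unresolved names are dropped and counted.
    """
    stats = stats if stats is not None else IngestStats()
    triples: list[RawTriple] = []
    for name, cui in rows:
        rxcuis = match_medication_name(name, rxgraph, lexicon)
        if not rxcuis:
            stats.unresolved_names += 1
            continue
        for rxcui in sorted(rxcuis):
            triples.append(RawTriple(rxcui=rxcui, indication_cui=cui, resource=resource))
    return triples


def attach_articles(
    articles: Iterable[Article],
    rxgraph: RxGraph,
    stats: IngestStats | None = None,
) -> list[tuple[str, Article]]:
    """Resolve article titles to RxCUIs.

    An article whose title maps to several RxCUIs is attached once per
    RxCUI (it contributes the same indications to each); articles with
    unresolvable titles are dropped and counted.
    """
    stats = stats if stats is not None else IngestStats()
    attached: list[tuple[str, Article]] = []
    for article in articles:
        rxcuis = match_medication_name(article.title, rxgraph)
        if not rxcuis:
            stats.unresolved_titles += 1
            logger.info("no drug concept for article title %r", article.title)
            continue
        for rxcui in sorted(rxcuis):
            attached.append((rxcui, article))
    return attached


def extract_article_triples(
    articles: Iterable[Article],
    rxgraph: RxGraph,
    lexicon: Mapping[str, ConceptRecord],
    config: "ExtractionConfig | None" = None,
    stats: IngestStats | None = None,
) -> list[RawTriple]:
    """Attach articles to drugs and run concept extraction on each."""
    from .concept_extraction import extract_article_indications

    triples: list[RawTriple] = []
    for rxcui, article in attach_articles(articles, rxgraph, stats=stats):
        triples.extend(extract_article_indications(rxcui, article, lexicon, config))
    return triples


# ---------------------------------------------------------------------------
# File formats

RELATIONSHIP_COLUMNS = ["SUBJECT_CUI", "RELATION", "RXCUI"]
NAME_CUI_COLUMNS = ["DRUG_NAME", "CUI"]
MANIFEST_COLUMNS = ["RESOURCE", "TITLE", "FILE"]


def load_relationship_rows(path: str | Path) -> list[RelationshipRow]:
    from .terminology import _read_tsv

    return [
        RelationshipRow(subject_cui=cui, relation=rel, object_rxcui=rxcui)
        for _, (cui, rel, rxcui) in _read_tsv(path, RELATIONSHIP_COLUMNS)
    ]


def write_relationship_rows(rows: Sequence[RelationshipRow], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RELATIONSHIP_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.subject_cui}\t{r.relation}\t{r.object_rxcui}\n")


def load_name_cui_rows(path: str | Path) -> list[tuple[str, str]]:
    from .terminology import _read_tsv

    return [(name, cui) for _, (name, cui) in _read_tsv(path, NAME_CUI_COLUMNS)]


def write_name_cui_rows(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(NAME_CUI_COLUMNS) + "\n")
        for name, cui in rows:
            fh.write(f"{name}\t{cui}\n")


def format_article_text(article: Article) -> str:
    """Serialize an article with ``== heading ==`` section markers."""
    parts = []
    for heading, body in article.sections:
        parts.append(f"== {heading} ==\n{body}\n")
    return "\n".join(parts)


def parse_article_text(resource: str, title: str, text: str) -> Article:
    sections: list[tuple[str, str]] = []
    heading: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("== ") and stripped.endswith(" =="):
            if heading is not None:
                sections.append((heading, "\n".join(body).strip()))
            heading = stripped[3:-3].strip()
            body = []
        elif heading is not None:
            body.append(line)
    if heading is not None:
        sections.append((heading, "\n".join(body).strip()))
    if not sections:
        raise ValueError(f"article {title!r} has no '== heading ==' sections")
    return Article(resource=resource, title=title, sections=tuple(sections))


def write_article_corpus(articles: Sequence[Article], directory: str | Path) -> None:
    """Write articles as text files plus a manifest TSV (RESOURCE, TITLE, FILE)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "manifest.tsv").open("w", encoding="utf-8") as manifest:
        manifest.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for i, article in enumerate(articles):
            fname = f"article_{i:04d}.txt"
            (directory / fname).write_text(format_article_text(article), encoding="utf-8")
            manifest.write(f"{article.resource}\t{article.title}\t{fname}\n")


def load_article_corpus(directory: str | Path) -> list[Article]:
    from .terminology import _read_tsv

    directory = Path(directory)
    articles = []
    for _, (resource, title, fname) in _read_tsv(directory / "manifest.tsv", MANIFEST_COLUMNS):
        text = (directory / fname).read_text(encoding="utf-8")
        articles.append(parse_article_text(resource, title, text))
    return articles
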
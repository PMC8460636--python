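"""Dictionary-based indication extraction from drug-article text.

A deterministic stand-in for a clinical concept indexer: find lexicon
concepts in article text by case-insensitive, token-boundary-respecting,
longest-match-wins dictionary matching; drop mentions under negation
triggers; drop sections about side effects or contraindications; and keep
only concepts whose semantic types fall in the indication whitelist
(Disease or Syndrome, Congenital Abnormality, Acquired Abnormality,
Anatomical Abnormality, Neoplastic Process, Virus).

Tokenization splits on non-alphanumeric runs and case-folds with simple
lowercasing; there is no stemming — inflection is the lexicon's job.
Negation is trigger-based in the NegEx style: a pre-scope trigger ("no",
"without", "no evidence of", ...) negates mentions within a fixed token
window unless a scope terminator ("but", ".", ";") intervenes; post-scope
triggers ("ruled out", "unlikely") work symmetrically to the right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .terminology import ConceptRecord

if TYPE_CHECKING:  # pragma: no cover
    from .source_ingest import Article, RawTriple

#: Semantic types admitted as indications.
DEFAULT_SEMANTIC_WHITELIST = frozenset(
    {
        "Disease or Syndrome",
        "Congenital Abnormality",
        "Acquired Abnormality",
        "Anatomical Abnormality",
        "Neoplastic Process",
        "Virus",
    }
)

#: Section headings removed before indexing (case-insensitive substrings).
DEFAULT_EXCLUDED_SECTIONS = ("side effect", "adverse", "contraindication", "warning")

#: (trigger phrase, scope direction); PRE looks rightward from the trigger.
DEFAULT_NEGATION_TRIGGERS: tuple[tuple[str, str], ...] = (
    ("no evidence of", "PRE"),
    ("no history of", "PRE"),
    ("rules out", "PRE"),
    ("rule out", "PRE"),
    ("denies", "PRE"),
    ("without", "PRE"),
    ("not", "PRE"),
    ("no", "PRE"),
    ("never", "PRE"),
    ("free of", "PRE"),
    ("ruled out", "POST"),
    ("unlikely", "POST"),
    ("was excluded", "POST"),
)

#: Tokens that terminate negation scope.
SCOPE_TERMINATORS = frozenset({"but", ".", ";", "however", "except"})

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_SCOPE_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[.;]")


@dataclass(frozen=True)
class ConceptMention:
    """One matched concept span in a section body (0-based, half-open)."""

    cui: str
    matched_text: str
    start: int
    end: int
    section_heading: str = ""
    negated: bool = False


@dataclass(frozen=True)
class ExtractionConfig:
    excluded_section_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_SECTIONS
    negation_triggers: tuple[tuple[str, str], ...] = DEFAULT_NEGATION_TRIGGERS
    negation_window: int = 5
    semantic_type_whitelist: frozenset[str] = DEFAULT_SEMANTIC_WHITELIST


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Alphanumeric tokens as (lowercased token, start, end)."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _phrase_key(name: str) -> tuple[str, ...]:
    return tuple(t for t, _, _ in tokenize(name))


class ConceptIndexer:
    """Longest-match dictionary matcher over a concept lexicon.

    The lexicon's preferred names and synonyms are tokenized into phrase
    keys; matching scans left to right over the text's tokens, taking the
    longest phrase starting at each position and suppressing any shorter or
    overlapping match inside the chosen span.  A string naming several
    concepts yields one mention per concept over the same span.
    """

    def __init__(self, lexicon: Mapping[str, ConceptRecord]) -> None:
        if not lexicon:
            raise ValueError("empty lexicon")
        phrases: dict[tuple[str, ...], set[str]] = {}
        for record in lexicon.values():
            for name in record.all_names:
                key = _phrase_key(name)
                if key:
                    phrases.setdefault(key, set()).add(record.cui)
        self._phrases = {k: frozenset(v) for k, v in phrases.items()}
        self._max_len = max(map(len, self._phrases), default=0)

    def find(self, text: str, section_heading: str = "") -> list[ConceptMention]:
        tokens = tokenize(text)
        mentions: list[ConceptMention] = []
        i = 0
        n = len(tokens)
        while i < n:
            best = 0
            best_cuis: frozenset[str] = frozenset()
            limit = min(self._max_len, n - i)
            for length in range(limit, 0, -1):
                key = tuple(t for t, _, _ in tokens[i : i + length])
                cuis = self._phrases.get(key)
                if cuis:
                    best, best_cuis = length, cuis
                    break
            if best:
                start = tokens[i][1]
                end = tokens[i + best - 1][2]
                span = text[start:end]
                for cui in sorted(best_cuis):
                    mentions.append(
                        ConceptMention(cui=cui, matched_text=span, start=start,
                                       end=end, section_heading=section_heading)
                    )
                i += best
            else:
                i += 1
        return mentions


def index_concepts(
    text: str,
    lexicon: Mapping[str, ConceptRecord],
    section_heading: str = "",
) -> list[ConceptMention]:
    """Find lexicon concepts in ``text`` (see :class:`ConceptIndexer`)."""
    return ConceptIndexer(lexicon).find(text, section_heading)


def exclude_sections(article: "Article", config: ExtractionConfig) -> "Article":
    """Drop sections whose heading matches an excluded pattern
    (case-insensitive substring); survivor order is preserved."""
    patterns = [p.lower() for p in config.excluded_section_patterns]
    kept = [
        (heading, body)
        for heading, body in article.sections
        if not any(p in heading.lower() for p in patterns)
    ]
    return replace(article, sections=tuple(kept))


def detect_negation(
    mentions: Sequence[ConceptMention],
    text: str,
    config: ExtractionConfig,
) -> list[ConceptMention]:
    """Flag mentions inside the scope of a negation trigger.

    A PRE trigger negates a mention beginning within ``negation_window``
    tokens after the trigger's end; a POST trigger negates a mention ending
    within the window before the trigger's start.  Scope terminator tokens
    between trigger and mention cancel the negation.
    """
    scope_tokens = [
        (m.group(0).lower(), m.start(), m.end())
        for m in _SCOPE_TOKEN_RE.finditer(text)
    ]
    word_of = {idx: tok for idx, (tok, _, _) in enumerate(scope_tokens)}

    triggers: list[tuple[int, int, str]] = []  # (first token idx, last idx, direction)
    for phrase, direction in config.negation_triggers:
        words = phrase.lower().split()
        for i in range(len(scope_tokens) - len(words) + 1):
            if all(word_of[i + j] == words[j] for j in range(len(words))):
                triggers.append((i, i + len(words) - 1, direction))

    def token_index_at(char_pos: int, *, after: bool) -> int:
        # index of first token starting at/after pos, or last ending at/before
        if after:
            for idx, (_, s, _) in enumerate(scope_tokens):
                if s >= char_pos:
                    return idx
            return len(scope_tokens)
        last = -1
        for idx, (_, _, e) in enumerate(scope_tokens):
            if e <= char_pos:
                last = idx
        return last

    out: list[ConceptMention] = []
    for mention in mentions:
        m_first = token_index_at(mention.start, after=True)
        m_last = token_index_at(mention.end, after=False)
        negated = False
        for t_first, t_last, direction in triggers:
            if direction == "PRE" and t_last < m_first:
                gap = range(t_last + 1, m_first)
                if m_first - t_last - 1 < config.negation_window and not any(
                    word_of[g] in SCOPE_TERMINATORS for g in gap
                ):
                    negated = True
                    break
            elif direction == "POST" and t_first > m_last:
                gap = range(m_last + 1, t_first)
                if t_first - m_last - 1 < config.negation_window and not any(
                    word_of[g] in SCOPE_TERMINATORS for g in gap
                ):
                    negated = True
                    break
        out.append(replace(mention, negated=negated) if negated != mention.negated else mention)
    return out


def filter_semantic_types(
    mentions: Iterable[ConceptMention],
    lexicon: Mapping[str, ConceptRecord],
    config: ExtractionConfig,
) -> list[ConceptMention]:
    """Keep non-negated mentions whose concept has a whitelisted semantic type."""
    out = []
    for mention in mentions:
        record = lexicon.get(mention.cui)
        if record is None:
            raise KeyError(f"mention cui {mention.cui} not in lexicon")
        if not mention.negated and record.semantic_types & config.semantic_type_whitelist:
            out.append(mention)
    return out


def extract_article_mentions(
    article: "Article",
    lexicon: Mapping[str, ConceptRecord],
    config: ExtractionConfig | None = None,
) -> list[ConceptMention]:
    """Full per-article mention stream: section exclusion, indexing,
    negation flagging and semantic-type filtering."""
    config = config or ExtractionConfig()
    indexer = ConceptIndexer(lexicon)
    kept: list[ConceptMention] = []
    trimmed = exclude_sections(article, config)
    for heading, body in trimmed.sections:
        mentions = indexer.find(body, section_heading=heading)
        mentions = detect_negation(mentions, body, config)
        kept.extend(filter_semantic_types(mentions, lexicon, config))
    return kept


def extract_article_indications(
    rxcui: str,
    article: "Article",
    lexicon: Mapping[str, ConceptRecord],
    config: ExtractionConfig | None = None,
) -> list["RawTriple"]:
    """Deduplicated (rxcui, indication CUI, resource) triples for one article."""
    from .source_ingest import RawTriple

    seen: set[str] = set()
    triples: list[RawTriple] = []
    for mention in extract_article_mentions(article, lexicon, config):
        if mention.cui not in seen:
            seen.add(mention.cui)
            triples.append(
                RawTriple(rxcui=rxcui, indication_cui=mention.cui,
                          resource=article.resource)
            )
    return triples


def write_mentions_tsv(mentions: Iterable[ConceptMention], path) -> None:
    """Audit dump: CUI, TEXT, START, END, SECTION, NEGATED."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("CUI\tTEXT\tSTART\tEND\tSECTION\tNEGATED\n")
        for m in mentions:
            fh.write(
                f"{m.cui}\t{m.matched_text}\t{m.start}\t{m.end}\t"
                f"{m.section_heading}\t{int(m.negated)}\n"
            )
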
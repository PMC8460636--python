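"""Data model and loaders for the terminology universe.

The pipeline consumes four kinds of terminology inputs: a concept lexicon
(UMLS-style CUIs with names, synonyms and semantic types), a drug-concept
graph (RxNorm-style RxCUIs with term types, prescribable flags and
generic-ingredient edges), and crosswalks from CUIs and SNOMED CT
identifiers to ICD-9-CM / ICD-10-CM codes.

Files are a documented TSV dialect: one header line, UTF-8, tab-separated
columns, pipe-separated multi-valued cells.  ICD codes are stored in dotted
canonical form internally and in all written files; ICD-9-CM and ICD-10-CM
are always distinguished by an explicit version field, never inferred from
code shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Drug-concept term types.
TERM_TYPES = ("INGREDIENT", "MULTI_INGREDIENT", "BRAND", "CLINICAL_DRUG", "OTHER")

_MULTI_SEP = "|"


class TerminologyError(ValueError):
    """Malformed terminology input (bad row, duplicate identifier, ...)."""


@dataclass(frozen=True)
class ConceptRecord:
    """A concept: CUI, preferred name, synonyms and semantic types."""

    cui: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    semantic_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cui.startswith("C"):
            raise TerminologyError(f"CUI must start with 'C': {self.cui!r}")
        if not self.preferred_name:
            raise TerminologyError(f"empty preferred name for {self.cui}")

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


@dataclass(frozen=True)
class MedConcept:
    """A drug concept: RxCUI, name, term type, prescribable flag."""

    rxcui: str
    name: str
    term_type: str
    prescribable: bool = True
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.term_type not in TERM_TYPES:
            raise TerminologyError(
                f"term_type {self.term_type!r} not in {TERM_TYPES}"
            )

    @property
    def is_ingredient_level(self) -> bool:
        return self.term_type in ("INGREDIENT", "MULTI_INGREDIENT")


@dataclass
class RxGraph:
    """Drug concepts plus edges from each concept to its generic ingredient(s).

    ``ingredient_of[rxcui]`` is the set of ingredient-level RxCUIs a concept
    groups to; ingredient-level concepts map to themselves.
    """

    concepts: dict[str, MedConcept] = field(default_factory=dict)
    ingredient_of: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, concept: MedConcept, ingredients: Iterable[str] = ()) -> None:
        if concept.rxcui in self.concepts:
            raise TerminologyError(f"duplicate rxcui {concept.rxcui}")
        self.concepts[concept.rxcui] = concept
        targets = frozenset(ingredients)
        if concept.is_ingredient_level:
            targets = targets | {concept.rxcui}
        self.ingredient_of[concept.rxcui] = targets

    def validate(self) -> None:
        """Check that every ingredient edge lands on an ingredient-level concept."""
        for rxcui, targets in self.ingredient_of.items():
            for t in targets:
                if t not in self.concepts:
                    raise TerminologyError(
                        f"ingredient edge {rxcui} -> {t}: unknown target"
                    )
                if not self.concepts[t].is_ingredient_level:
                    raise TerminologyError(
                        f"ingredient edge {rxcui} -> {t}: target is "
                        f"{self.concepts[t].term_type}, not ingredient-level"
                    )
            if self.concepts[rxcui].is_ingredient_level and rxcui not in targets:
                raise TerminologyError(
                    f"ingredient-level concept {rxcui} does not map to itself"
                )

    def name_of(self, rxcui: str) -> str:
        return self.concepts[rxcui].name


@dataclass
class CrossWalk:
    """CUI->ICD and SNOMED->ICD mapping tables, codes in dotted form."""

    cui_to_icd9: dict[str, frozenset[str]] = field(default_factory=dict)
    cui_to_icd10: dict[str, frozenset[str]] = field(default_factory=dict)
    cui_to_snomed: dict[str, frozenset[str]] = field(default_factory=dict)
    snomed_to_icd9: dict[str, frozenset[str]] = field(default_factory=dict)
    snomed_to_icd10: dict[str, frozenset[str]] = field(default_factory=dict)


def normalize_icd(code: str, version: int) -> str:
    """Canonicalize an ICD code to dotted form.

    ICD-10-CM and numeric ICD-9-CM codes take a dot after the third
    character; ICD-9-CM external-cause (E) codes take it after the fourth.
    Codes of three or fewer characters (category codes) carry no dot.

    Raises :class:`TerminologyError` for codes that cannot be normalized.
    """
    code = code.strip().upper()
    if not code or " " in code:
        raise TerminologyError(f"unnormalizable ICD code {code!r}")
    if "." in code:
        stem, _, suffix = code.partition(".")
        if not stem or not suffix or "." in suffix:
            raise TerminologyError(f"unnormalizable ICD code {code!r}")
        return code
    head = 4 if (version == 9 and code.startswith("E")) else 3
    if len(code) <= head:
        return code
    return f"{code[:head]}.{code[head:]}"


# ---------------------------------------------------------------------------
# TSV I/O


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(v for v in cell.split(_MULTI_SEP) if v) if cell else ()


def _read_tsv(path: str | Path, expected_columns: list[str]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected_columns:
            raise TerminologyError(
                f"{path}: expected columns {expected_columns}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(expected_columns):
                raise TerminologyError(
                    f"{path}:{lineno}: expected {len(expected_columns)} "
                    f"columns, found {len(cells)}"
                )
            yield lineno, cells


LEXICON_COLUMNS = ["CUI", "PREFERRED_NAME", "SYNONYMS", "SEMANTIC_TYPES"]
RXGRAPH_COLUMNS = ["RXCUI", "NAME", "TTY", "PRESCRIBABLE", "SYNONYMS", "INGREDIENT_RXCUIS"]
CROSSWALK_COLUMNS = ["SOURCE_ID", "TARGET_ID"]

#: File-name stems of the five crosswalk tables.
CROSSWALK_PARTS = (
    "cui_icd9",
    "cui_icd10",
    "cui_snomed",
    "snomed_icd9",
    "snomed_icd10",
)


def load_lexicon(path: str | Path) -> dict[str, ConceptRecord]:
    """Load a concept lexicon TSV into a cui -> :class:`ConceptRecord` map.

    Multiple rows with the same CUI are merged: synonyms and semantic types
    are unioned; a conflicting preferred name is an error.
    """
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    stypes: dict[str, set[str]] = {}
    for lineno, (cui, name, syns, types) in _read_tsv(path, LEXICON_COLUMNS):
        if not cui or not name:
            raise TerminologyError(f"{path}:{lineno}: empty CUI or name")
        if cui in names and names[cui] != name:
            raise TerminologyError(
                f"{path}:{lineno}: cui {cui} has conflicting preferred names "
                f"{names[cui]!r} / {name!r}"
            )
        names[cui] = name
        bucket = synonyms.setdefault(cui, [])
        for s in _split_multi(syns):
            if s not in bucket:
                bucket.append(s)
        stypes.setdefault(cui, set()).update(_split_multi(types))
    return {
        cui: ConceptRecord(
            cui=cui,
            preferred_name=names[cui],
            synonyms=tuple(synonyms[cui]),
            semantic_types=frozenset(stypes[cui]),
        )
        for cui in names
    }


def write_lexicon(lexicon: Mapping[str, ConceptRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(LEXICON_COLUMNS) + "\n")
        for cui in sorted(lexicon):
            rec = lexicon[cui]
            fh.write(
                "\t".join(
                    (
                        rec.cui,
                        rec.preferred_name,
                        _MULTI_SEP.join(rec.synonyms),
                        _MULTI_SEP.join(sorted(rec.semantic_types)),
                    )
                )
                + "\n"
            )


def load_rxgraph(path: str | Path) -> RxGraph:
    """Load the drug-concept graph TSV and validate its ingredient edges."""
    graph = RxGraph()
    for lineno, (rxcui, name, tty, presc, syns, ings) in _read_tsv(path, RXGRAPH_COLUMNS):
        if presc not in ("0", "1"):
            raise TerminologyError(f"{path}:{lineno}: PRESCRIBABLE must be 0 or 1")
        try:
            graph.add(
                MedConcept(
                    rxcui=rxcui,
                    name=name,
                    term_type=tty,
                    prescribable=presc == "1",
                    synonyms=_split_multi(syns),
                ),
                ingredients=_split_multi(ings),
            )
        except TerminologyError as exc:
            raise TerminologyError(f"{path}:{lineno}: {exc}") from exc
    graph.validate()
    return graph


def write_rxgraph(graph: RxGraph, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RXGRAPH_COLUMNS) + "\n")
        for rxcui in sorted(graph.concepts, key=_rxcui_key):
            c = graph.concepts[rxcui]
            edges = graph.ingredient_of[rxcui] - {rxcui}
            fh.write(
                "\t".join(
                    (
                        c.rxcui,
                        c.name,
                        c.term_type,
                        "1" if c.prescribable else "0",
                        _MULTI_SEP.join(c.synonyms),
                        _MULTI_SEP.join(sorted(edges, key=_rxcui_key)),
                    )
                )
                + "\n"
            )


def _rxcui_key(rxcui: str) -> tuple[int, str]:
    return (int(rxcui), "") if rxcui.isdigit() else (1 << 62, rxcui)


def load_crosswalk(directory: str | Path) -> CrossWalk:
    """Load the five crosswalk TSVs from ``directory``.

    Files are named ``crosswalk_<part>.tsv`` for each part in
    :data:`CROSSWALK_PARTS`; a missing file leaves that map empty.  ICD
    target codes are normalized to dotted form; a code that cannot be
    normalized is skipped with a logged warning.
    """
    directory = Path(directory)
    walk = CrossWalk()
    targets = {
        "cui_icd9": (walk.cui_to_icd9, 9),
        "cui_icd10": (walk.cui_to_icd10, 10),
        "cui_snomed": (walk.cui_to_snomed, None),
        "snomed_icd9": (walk.snomed_to_icd9, 9),
        "snomed_icd10": (walk.snomed_to_icd10, 10),
    }
    for part, (mapping, version) in targets.items():
        path = directory / f"crosswalk_{part}.tsv"
        if not path.exists():
            continue
        acc: dict[str, set[str]] = {}
        skipped = 0
        for lineno, (source, target) in _read_tsv(path, CROSSWALK_COLUMNS):
            if version is not None:
                try:
                    target = normalize_icd(target, version)
                except TerminologyError:
                    skipped += 1
                    logger.warning("%s:%d: skipping unnormalizable code %r", path, lineno, target)
                    continue
            if not target:
                skipped += 1
                continue
            acc.setdefault(source, set()).add(target)
        if skipped:
            logger.warning("%s: skipped %d rows", path, skipped)
        mapping.update({k: frozenset(v) for k, v in acc.items()})
    return walk


def write_crosswalk(walk: CrossWalk, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    parts = {
        "cui_icd9": walk.cui_to_icd9,
        "cui_icd10": walk.cui_to_icd10,
        "cui_snomed": walk.cui_to_snomed,
        "snomed_icd9": walk.snomed_to_icd9,
        "snomed_icd10": walk.snomed_to_icd10,
    }
    for part, mapping in parts.items():
        with (directory / f"crosswalk_{part}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("\t".join(CROSSWALK_COLUMNS) + "\n")
            for source in sorted(mapping):
                for target in sorted(mapping[source]):
                    fh.write(f"{source}\t{target}\n")
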
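"""Provenance-tracked aggregation of medication-indication pairs.

Per-resource pair streams are merged into a :class:`PairTable` keyed on
(ingredient RxCUI, ICD version, code) — or on the CUI for the UMLS-level
stream — with the set of supporting resources carried on every pair.  On
top of the table sit the support-count strata, the high-precision subset
(pairs asserted by the anchor resource or by at least ``min_other_resources``
others), the union merge that combines knowledgebase editions under source
flags, exact-subset overlap counts for Venn-style reporting, and a
deterministic TSV release writer/reader.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .normalization_mapping import PairRecord, VERSION_10, VERSION_9, VERSION_CUI
from .source_ingest import RESOURCES

logger = logging.getLogger(__name__)

PairKey = tuple[str, str, str]


@dataclass(frozen=True)
class MedIndPair:
    """One aggregated medication-indication assertion with provenance."""

    rxcui: str
    drug_name: str
    cuis: frozenset[str]
    icd_version: str
    code: str
    resources: frozenset[str]
    relation_flags: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    @property
    def key(self) -> PairKey:
        ind = self.code if self.icd_version != VERSION_CUI else min(self.cuis)
        return (self.rxcui, self.icd_version, ind)

    @property
    def cui(self) -> str:
        """Representative CUI (the full set is in ``cuis``)."""
        return min(self.cuis)


@dataclass(frozen=True)
class HpsRule:
    """High-precision-subset rule: anchored on one high-precision resource,
    or corroboration by at least ``min_other_resources`` other resources."""

    anchor_resource: str = "RxNorm"
    min_other_resources: int = 3

    def __post_init__(self) -> None:
        if self.min_other_resources < 1:
            raise ValueError("min_other_resources must be >= 1")

    def admits(self, resources: frozenset[str]) -> bool:
        return (
            self.anchor_resource in resources
            or len(resources - {self.anchor_resource}) >= self.min_other_resources
        )


@dataclass
class PairTable:
    """The aggregated knowledgebase: pairs keyed by identity, plus provenance."""

    pairs: dict[PairKey, MedIndPair] = field(default_factory=dict)
    resource_universe: tuple[str, ...] = RESOURCES
    provenance: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs.values())

    def validate(self) -> None:
        universe = set(self.resource_universe)
        for pair in self:
            if not pair.resources:
                raise ValueError(f"pair {pair.key} has no supporting resource")
            if not pair.resources <= universe:
                raise ValueError(
                    f"pair {pair.key} resources {set(pair.resources)} outside "
                    f"universe {universe}"
                )

    def medications(self) -> set[str]:
        return {p.rxcui for p in self}

    def subset(self, predicate) -> "PairTable":
        return PairTable(
            pairs={k: p for k, p in self.pairs.items() if predicate(p)},
            resource_universe=self.resource_universe,
            provenance=dict(self.provenance),
        )

    def sorted_pairs(self) -> list[MedIndPair]:
        def sort_key(p: MedIndPair):
            rx = (0, int(p.rxcui), "") if p.rxcui.isdigit() else (1, 0, p.rxcui)
            return (*rx, p.icd_version, p.code, min(p.cuis))

        return sorted(self.pairs.values(), key=sort_key)


def _merge_pair(existing: MedIndPair, new: MedIndPair) -> MedIndPair:
    return replace(
        existing,
        cuis=existing.cuis | new.cuis,
        resources=existing.resources | new.resources,
        relation_flags=existing.relation_flags | new.relation_flags,
        sources=existing.sources | new.sources,
    )


def aggregate(
    records: Iterable[PairRecord],
    drug_names: Mapping[str, str] | None = None,
    resource_universe: Sequence[str] = RESOURCES,
    source_label: str = "",
) -> PairTable:
    """Merge normalized per-resource pair records into a :class:`PairTable`.

    Identical (rxcui, version, code) assertions from different resources
    merge with resource-set and relation-flag union; the result is
    independent of record order.
    """
    drug_names = drug_names or {}
    table = PairTable(resource_universe=tuple(resource_universe))
    sources = frozenset({source_label}) if source_label else frozenset()
    for rec in records:
        pair = MedIndPair(
            rxcui=rec.rxcui,
            drug_name=drug_names.get(rec.rxcui, ""),
            cuis=frozenset({rec.cui}),
            icd_version=rec.icd_version,
            code=rec.code,
            resources=frozenset({rec.resource}),
            relation_flags=frozenset({rec.relation_flag} if rec.relation_flag else ()),
            sources=sources,
        )
        key = pair.key
        table.pairs[key] = _merge_pair(table.pairs[key], pair) if key in table.pairs else pair
    table.validate()
    return table


def stratify_by_support(table: PairTable, exclude: str | None = None) -> dict[int, int]:
    """Pair counts by number of supporting resources (exactly k).

    With ``exclude`` given, that resource is removed from every support set
    first; pairs supported only by it fall out of every stratum.
    """
    counts: Counter[int] = Counter()
    for pair in table:
        k = len(pair.resources - {exclude} if exclude else pair.resources)
        if k > 0:
            counts[k] += 1
    return dict(counts)


def select_hps(table: PairTable, rule: HpsRule | None = None) -> PairTable:
    """The high-precision subset under ``rule``."""
    rule = rule or HpsRule()
    if rule.anchor_resource not in table.resource_universe:
        raise ValueError(f"anchor {rule.anchor_resource!r} not in resource universe")
    out = table.subset(lambda p: rule.admits(p.resources))
    out.provenance["hps_rule"] = (rule.anchor_resource, rule.min_other_resources)
    return out


def merge_union(tables: Sequence[PairTable], labels: Sequence[str]) -> PairTable:
    """Set union of pair tables, each pair flagged with the labels of the
    tables that contained it (the combined-edition merge)."""
    if len(tables) != len(labels):
        raise ValueError("one label per table required")
    universe: list[str] = []
    for t in tables:
        for r in t.resource_universe:
            if r not in universe:
                universe.append(r)
    merged = PairTable(resource_universe=tuple(universe))
    for table, label in zip(tables, labels):
        for pair in table:
            tagged = replace(pair, sources=pair.sources | {label})
            key = tagged.key
            if key in merged.pairs:
                existing = merged.pairs[key]
                if existing.drug_name and tagged.drug_name and existing.drug_name != tagged.drug_name:
                    logger.warning(
                        "conflicting drug names for rxcui %s: keeping %r, ignoring %r",
                        pair.rxcui, existing.drug_name, tagged.drug_name,
                    )
                merged.pairs[key] = _merge_pair(existing, tagged)
            else:
                merged.pairs[key] = tagged
    merged.validate()
    return merged


def overlap_counts(table: PairTable, by: str = "pair") -> dict[frozenset[str], int]:
    """Exact-subset partition counts over the resource power set.

    ``by="pair"`` counts pairs per exact support set; ``by="medication"``
    counts distinct drugs, a drug's support set being the union of the
    support sets of its pairs.
    """
    counts: Counter[frozenset[str]] = Counter()
    if by == "pair":
        for pair in table:
            counts[pair.resources] += 1
    elif by == "medication":
        support: dict[str, frozenset[str]] = {}
        for pair in table:
            support[pair.rxcui] = support.get(pair.rxcui, frozenset()) | pair.resources
        for resources in support.values():
            counts[resources] += 1
    else:
        raise ValueError("by must be 'pair' or 'medication'")
    return dict(counts)


# ---------------------------------------------------------------------------
# Release files

#: Canonical column names for the six standard resources.
_RESOURCE_COLUMNS = {
    "RxNorm": "RXNORM",
    "Mayo Clinic": "MAYO",
    "MedlinePlus": "MEDLINEPLUS",
    "SIDER 4.1": "SIDER",
    "WebMD": "WEBMD",
    "Wikipedia": "WIKIPEDIA",
}
_COLUMN_RESOURCES = {v: k for k, v in _RESOURCE_COLUMNS.items()}

_FIXED_HEAD = ["RXCUI", "DRUG_NAME", "CUI", "ICD_VERSION", "CODE"]
_FIXED_TAIL = ["N_OTHER_RESOURCES", "HPS", "MEDI_SOURCE"]


def _resource_column(resource: str) -> str:
    return _RESOURCE_COLUMNS.get(resource, resource)


def write_release(table: PairTable, path: str | Path, rule: HpsRule | None = None) -> None:
    """Write the release TSV: one row per pair, one boolean column per
    resource, the other-resource support count, the HPS flag and the
    edition source flags.  Rows are sorted by (rxcui, version, code) so the
    file is byte-identical across runs on equal tables."""
    rule = rule or HpsRule()
    columns = _FIXED_HEAD + [_resource_column(r) for r in table.resource_universe] + _FIXED_TAIL
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for pair in table.sorted_pairs():
            row = [
                pair.rxcui,
                pair.drug_name,
                "|".join(sorted(pair.cuis)),
                pair.icd_version,
                pair.code,
            ]
            row += ["1" if r in pair.resources else "0" for r in table.resource_universe]
            row += [
                str(len(pair.resources - {rule.anchor_resource})),
                "1" if rule.admits(pair.resources) else "0",
                "|".join(sorted(pair.sources)),
            ]
            fh.write("\t".join(row) + "\n")


def read_release(path: str | Path) -> PairTable:
    """Read a release TSV back into a :class:`PairTable` (lossless for the
    pair identities, provenance sets and drug names)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_FIXED_HEAD)] != _FIXED_HEAD or header[-len(_FIXED_TAIL):] != _FIXED_TAIL:
            raise ValueError(f"{path}:1: unrecognized release header")
        resource_cols = header[len(_FIXED_HEAD) : -len(_FIXED_TAIL)]
        universe = tuple(_COLUMN_RESOURCES.get(c, c) for c in resource_cols)
        table = PairTable(resource_universe=universe)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
            rxcui, drug_name, cuis, version, code = cells[: len(_FIXED_HEAD)]
            flags = cells[len(_FIXED_HEAD) : -len(_FIXED_TAIL)]
            sources = cells[-1]
            pair = MedIndPair(
                rxcui=rxcui,
                drug_name=drug_name,
                cuis=frozenset(cuis.split("|")) if cuis else frozenset(),
                icd_version=version,
                code=code,
                resources=frozenset(r for r, f in zip(universe, flags) if f == "1"),
                sources=frozenset(sources.split("|")) if sources else frozenset(),
            )
            if pair.key in table.pairs:
                raise ValueError(f"{path}:{lineno}: duplicate pair {pair.key}")
            table.pairs[pair.key] = pair
    table.validate()
    return table


def icd_stream(table: PairTable) -> PairTable:
    """The ICD-coded pairs only (both versions)."""
    return table.subset(lambda p: p.icd_version in (VERSION_9, VERSION_10))


def cui_stream(table: PairTable) -> PairTable:
    """The UMLS-level pairs only."""
    return table.subset(lambda p: p.icd_version == VERSION_CUI)
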
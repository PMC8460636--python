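"""Manual-review sampling, PPV arithmetic and weighted precision estimation.

Precision of the knowledgebase is estimated from manual review: random
subsets of pairs are drawn per resource and per support-count stratum,
reviewers mark each pair TRUE / FALSE / AMBIGUOUS (ambiguous pairs — e.g.
catch-all ICD codes — are excluded from denominators), and the per-stratum
positive predictive values are combined size-weighted:

    Precision(R) = sum_r size(r) * PPV(r) / sum_r size(r)

over the strata r in the combination R.  By default each PPV is rounded to
two decimals before weighting, which reproduces published two-decimal
tables; ``rounding=None`` gives the exact-fraction variant.

The module also ships the published MEDI-2 evaluation counts (stratum sizes
and review tallies) as input data, and a small recall harness that scores a
curated indication list for a handful of reference drugs against each
knowledgebase edition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .aggregation import HpsRule, MedIndPair, PairTable, stratify_by_support

VERDICTS = ("TRUE", "FALSE", "AMBIGUOUS", "PENDING")


@dataclass(frozen=True)
class ReviewRecord:
    pair_id: str
    verdict: str = "PENDING"
    rxcui: str = ""
    code: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict {self.verdict!r} not in {VERDICTS}")


@dataclass
class ReviewSet:
    """Verdicts for one reviewed stratum."""

    records: list[ReviewRecord]
    stratum: str = ""
    seed: int | None = None

    @property
    def usable(self) -> list[ReviewRecord]:
        return [r for r in self.records if r.verdict in ("TRUE", "FALSE")]


@dataclass(frozen=True)
class ResourceStats:
    """Size and review tallies for one stratum/resource.

    ``size`` is the number of pairs in the stratum; ``reviewed`` counts
    usable (non-ambiguous) reviews and ``true_positive`` the TRUE ones.
    ``ppv_override`` supplies a PPV directly when review counts are not
    available (e.g. a figure carried over from an earlier edition).
    """

    label: str
    size: int
    reviewed: int = 0
    true_positive: int = 0
    ppv_override: float | None = None

    def __post_init__(self) -> None:
        if self.true_positive > self.reviewed:
            raise ValueError(f"{self.label}: true_positive > reviewed")
        if self.ppv_override is not None and not 0.0 <= self.ppv_override <= 1.0:
            raise ValueError(f"{self.label}: ppv must be in [0, 1]")

    @property
    def ppv(self) -> float:
        if self.ppv_override is not None:
            return self.ppv_override
        if self.reviewed == 0:
            raise ValueError(f"{self.label}: no usable reviews")
        return self.true_positive / self.reviewed


def sample_for_review(
    table: PairTable,
    stratum: Callable[[MedIndPair], bool],
    n: int,
    seed: int,
    label: str = "",
) -> ReviewSet:
    """Uniform without-replacement sample of ``n`` pairs from a stratum,
    reproducible under ``seed``; a stratum smaller than ``n`` is returned
    whole."""
    eligible = [p for p in table.sorted_pairs() if stratum(p)]
    if not eligible:
        raise ValueError(f"empty review stratum {label!r}")
    if len(eligible) <= n:
        chosen = eligible
    else:
        chosen = random.Random(seed).sample(eligible, n)
    records = [
        ReviewRecord(
            pair_id="|".join(p.key), rxcui=p.rxcui,
            code=p.code or min(p.cuis),
        )
        for p in chosen
    ]
    return ReviewSet(records=records, stratum=label, seed=seed)


def ppv(review: ReviewSet) -> float:
    """True positives over usable (non-ambiguous) reviews."""
    usable = review.usable
    if not usable:
        raise ValueError(f"review set {review.stratum!r} has no usable records")
    return sum(r.verdict == "TRUE" for r in usable) / len(usable)


def weighted_precision(
    strata: Sequence[ResourceStats],
    rounding: int | None = 2,
) -> float:
    """Size-weighted precision over strata; PPVs rounded first when
    ``rounding`` is given (default 2, matching printed tables)."""
    if not strata:
        raise ValueError("no strata")
    total = sum(s.size for s in strata)
    if total <= 0:
        raise ValueError("zero total stratum size")
    if any(s.size <= 0 for s in strata):
        raise ValueError("stratum sizes must be positive")

    def p(s: ResourceStats) -> float:
        return round(s.ppv, rounding) if rounding is not None else s.ppv

    return sum(s.size * p(s) for s in strata) / total


# ---------------------------------------------------------------------------
# Precision report (per-resource, per-stratum, >=k, overall, HPS)


@dataclass
class PrecisionReport:
    """All derived precision figures for one knowledgebase build."""

    resources: list[ResourceStats]
    anchor: ResourceStats
    exact_strata: list[ResourceStats]  # exactly-k excluding the anchor, k ascending
    rounding: int | None = 2
    rule: HpsRule = field(default_factory=HpsRule)

    def ge_precision(self, k: int) -> float:
        strata = [s for s in self.exact_strata if int(s.label) >= k]
        return weighted_precision(strata, self.rounding)

    def ge_size(self, k: int) -> int:
        return sum(s.size for s in self.exact_strata if int(s.label) >= k)

    @property
    def overall_precision(self) -> float:
        return weighted_precision([self.anchor, *self.exact_strata], self.rounding)

    @property
    def overall_size(self) -> int:
        return self.anchor.size + sum(s.size for s in self.exact_strata)

    @property
    def hps_precision(self) -> float:
        strata = [self.anchor] + [
            s for s in self.exact_strata if int(s.label) >= self.rule.min_other_resources
        ]
        return weighted_precision(strata, self.rounding)

    @property
    def hps_size(self) -> int:
        """Anchor-stratum size plus the >=threshold strata sizes."""
        return self.anchor.size + self.ge_size(self.rule.min_other_resources)

    def to_dict(self) -> dict:
        max_k = max((int(s.label) for s in self.exact_strata), default=0)
        return {
            "per_resource_ppv": {s.label: round(s.ppv, 2) for s in self.resources},
            "exact_stratum_ppv": {s.label: round(s.ppv, 2) for s in self.exact_strata},
            "exact_stratum_size": {s.label: s.size for s in self.exact_strata},
            "ge_precision": {str(k): round(self.ge_precision(k), 2) for k in range(1, max_k)},
            "overall_precision": round(self.overall_precision, 2),
            "hps_precision": round(self.hps_precision, 2),
            "overall_size": self.overall_size,
            "hps_size": self.hps_size,
        }

    def summary(self) -> str:
        lines = ["stratum\tsize\treviewed\ttrue_positive\tprecision"]
        for s in self.resources:
            lines.append(f"{s.label}\t{s.size}\t{s.reviewed}\t{s.true_positive}\t{s.ppv:.2f}")
        for s in self.exact_strata:
            lines.append(
                f"exactly {s.label} (excl. {self.rule.anchor_resource})\t"
                f"{s.size}\t{s.reviewed}\t{s.true_positive}\t{s.ppv:.2f}"
            )
        max_k = max((int(s.label) for s in self.exact_strata), default=0)
        for k in range(1, max_k):
            lines.append(f">= {k}\t{self.ge_size(k)}\t\t\t{self.ge_precision(k):.2f}")
        lines.append(f"overall\t{self.overall_size}\t\t\t{self.overall_precision:.2f}")
        lines.append(f"HPS\t{self.hps_size}\t\t\t{self.hps_precision:.2f}")
        return "\n".join(lines)


def build_precision_report(
    resources: Sequence[ResourceStats],
    exact_strata: Sequence[ResourceStats],
    anchor_label: str = "RxNorm",
    rounding: int | None = 2,
    rule: HpsRule | None = None,
) -> PrecisionReport:
    """Assemble a report from per-resource and exactly-k review tallies.

    ``exact_strata`` are the exactly-k strata *excluding* the anchor
    resource, labelled "1", "2", ...; the anchor's own stats are taken from
    ``resources`` by label.
    """
    anchor = next((s for s in resources if s.label == anchor_label), None)
    if anchor is None:
        raise ValueError(f"anchor stratum {anchor_label!r} missing from resources")
    strata = sorted(exact_strata, key=lambda s: int(s.label))
    if [s.label for s in strata] != [str(k) for k in range(1, len(strata) + 1)]:
        raise ValueError("exact strata must be labelled '1'..'K' contiguously")
    return PrecisionReport(
        resources=list(resources),
        anchor=anchor,
        exact_strata=strata,
        rounding=rounding,
        rule=rule or HpsRule(anchor_resource=anchor_label),
    )


def precision_table(
    table: PairTable,
    reviews: Mapping[str, ReviewSet],
    rule: HpsRule | None = None,
    rounding: int | None = 2,
) -> PrecisionReport:
    """Precision report for a built table, stratum sizes from the table and
    PPVs from review sets.

    ``reviews`` must hold one ReviewSet per resource (keyed by resource
    name) and one per exactly-k stratum excluding the anchor (keyed "1",
    "2", ... up to the largest occupied stratum).
    """
    rule = rule or HpsRule()
    resources = []
    for name in table.resource_universe:
        if name not in reviews:
            raise KeyError(f"missing review set for resource {name!r}")
        stats_size = len(table.subset(lambda p, n=name: n in p.resources))
        rec = reviews[name]
        usable = rec.usable
        resources.append(
            ResourceStats(
                label=name, size=stats_size, reviewed=len(usable),
                true_positive=sum(r.verdict == "TRUE" for r in usable),
            )
        )
    histogram = stratify_by_support(table, exclude=rule.anchor_resource)
    exact = []
    for k in range(1, max(histogram, default=0) + 1):
        if histogram.get(k, 0) == 0:
            continue
        key = str(k)
        if key not in reviews:
            raise KeyError(f"missing review set for stratum {key!r}")
        usable = reviews[key].usable
        exact.append(
            ResourceStats(
                label=key, size=histogram[k], reviewed=len(usable),
                true_positive=sum(r.verdict == "TRUE" for r in usable),
            )
        )
    # contiguity for the report: occupied strata must be 1..K
    exact = [
        ResourceStats(label=str(i + 1), size=s.size, reviewed=s.reviewed,
                      true_positive=s.true_positive)
        for i, s in enumerate(exact)
    ]
    return build_precision_report(
        resources, exact, anchor_label=rule.anchor_resource,
        rounding=rounding, rule=rule,
    )


# ---------------------------------------------------------------------------
# Recall harness


#: Default reference drugs for recall estimation: common medications with
#: indications spanning several clinical domains.
RECALL_MEDICATIONS = ("propranolol", "methotrexate", "sildenafil", "gabapentin", "estradiol")


@dataclass(frozen=True)
class RecallItem:
    """One curated indication and where it was found."""

    medication: str
    indication: str
    found_in: Mapping[str, bool]


def recall(items: Sequence[RecallItem], resource_label: str) -> float:
    """Fraction of curated indications found in ``resource_label``."""
    if not items:
        raise ValueError("no recall items")
    for item in items:
        if resource_label not in item.found_in:
            raise KeyError(
                f"item ({item.medication}, {item.indication}) has no entry "
                f"for {resource_label!r}"
            )
    return sum(bool(item.found_in[resource_label]) for item in items) / len(items)


# ---------------------------------------------------------------------------
# Review-file I/O (PAIR_ID, RXCUI, CODE, VERDICT, NOTE)

REVIEW_COLUMNS = ["PAIR_ID", "RXCUI", "CODE", "VERDICT", "NOTE"]


def write_review_tsv(review: ReviewSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(REVIEW_COLUMNS) + "\n")
        for r in review.records:
            fh.write(f"{r.pair_id}\t{r.rxcui}\t{r.code}\t{r.verdict}\t{r.note}\n")


def load_review_tsv(path: str | Path, stratum: str = "") -> ReviewSet:
    from .terminology import _read_tsv

    records = [
        ReviewRecord(pair_id=pid, rxcui=rxcui, code=code, verdict=verdict, note=note)
        for _, (pid, rxcui, code, verdict, note) in _read_tsv(Path(path), REVIEW_COLUMNS)
    ]
    return ReviewSet(records=records, stratum=stratum)


# ---------------------------------------------------------------------------
# Published MEDI-2 evaluation inputs
#
# Stratum sizes and manual-review tallies from the published MEDI-2
# evaluation (per-resource reviews, and exactly-k strata excluding RxNorm).
# These are input data; every precision figure is computed from them.

MEDI2_RESOURCE_REVIEW = (
    # label, pair count, usable reviews, true positives
    ("RxNorm", 25051, 91, 85),
    ("Mayo Clinic", 34220, 106, 86),
    ("MedlinePlus", 38323, 105, 82),
    ("SIDER 4.1", 39116, 102, 78),
    ("WebMD", 77035, 126, 95),
    ("Wikipedia", 52325, 111, 82),
)

MEDI2_STRATUM_REVIEW = (
    # exactly-k excluding RxNorm: k, pair count, usable reviews, true positives
    (1, 135787, 174, 87),
    (2, 15789, 88, 65),
    (3, 5863, 63, 56),
    (4, 2451, 60, 56),
    (5, 1123, 57, 52),
)


def medi2_precision_report(rounding: int | None = 2) -> PrecisionReport:
    """The precision report computed from the published MEDI-2 review counts."""
    resources = [
        ResourceStats(label=l, size=s, reviewed=r, true_positive=t)
        for l, s, r, t in MEDI2_RESOURCE_REVIEW
    ]
    strata = [
        ResourceStats(label=str(k), size=s, reviewed=r, true_positive=t)
        for k, s, r, t in MEDI2_STRATUM_REVIEW
    ]
    return build_precision_report(resources, strata, rounding=rounding)
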
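import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medikb.aggregation import HpsRule
from medikb.evaluation import (
    RecallItem,
    ResourceStats,
    ReviewRecord,
    ReviewSet,
    build_precision_report,
    load_review_tsv,
    medi2_precision_report,
    ppv,
    precision_table,
    recall,
    sample_for_review,
    weighted_precision,
    write_review_tsv,
)


def review_of(n_true, n_false, n_ambiguous=0):
    records = (
        [ReviewRecord(pair_id=f"t{i}", verdict="TRUE") for i in range(n_true)]
        + [ReviewRecord(pair_id=f"f{i}", verdict="FALSE") for i in range(n_false)]
        + [ReviewRecord(pair_id=f"a{i}", verdict="AMBIGUOUS") for i in range(n_ambiguous)]
    )
    return ReviewSet(records=records)


@pytest.mark.parametrize(
    "n_true, n_usable, expected",
    [(85, 91, 0.93), (82, 111, 0.74), (0, 10, 0.0), (87, 174, 0.50)],
)
def test_ppv_arithmetic(n_true, n_usable, expected):
    assert round(ppv(review_of(n_true, n_usable - n_true)), 2) == expected


def test_ambiguous_excluded_from_denominator():
    # filter/compute commutation: dropping AMBIGUOUS first changes nothing
    with_amb = review_of(8, 2, n_ambiguous=5)
    filtered = ReviewSet(records=with_amb.usable)
    assert ppv(with_amb) == ppv(filtered) == 0.8


def test_ppv_requires_usable_records():
    with pytest.raises(ValueError):
        ppv(review_of(0, 0, n_ambiguous=3))


def test_weighted_precision_known_strata():
    # >=3-resources combination from the published stratum sizes
    strata = [
        ResourceStats("3", 5863, 63, 56),
        ResourceStats("4", 2451, 60, 56),
        ResourceStats("5", 1123, 57, 52),
    ]
    assert round(weighted_precision(strata), 2) == 0.90
    # >=1: all five excluding-anchor strata
    ge1 = [
        ResourceStats("1", 135787, 174, 87),
        ResourceStats("2", 15789, 88, 65),
    ] + strata
    assert round(weighted_precision(ge1), 2) == 0.55
    single = [ResourceStats("x", 123, 50, 41)]
    assert weighted_precision(single, rounding=None) == 41 / 50


def test_weighted_precision_rounding_sensitivity():
    # two-decimal PPVs shift the >=4 combination by under half a point
    strata = [ResourceStats("4", 2451, 60, 56), ResourceStats("5", 1123, 57, 52)]
    rounded = weighted_precision(strata, rounding=2)
    exact = weighted_precision(strata, rounding=None)
    assert abs(rounded - exact) <= 0.005
    assert round(rounded, 2) == 0.92


def test_weighted_precision_input_validation():
    with pytest.raises(ValueError):
        weighted_precision([])
    with pytest.raises(ValueError):
        weighted_precision([ResourceStats("x", 0, 1, 1)])
    with pytest.raises(ValueError):
        ResourceStats("x", 10, 5, 6)  # tp > reviewed


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    strata=st.lists(
        st.tuples(st.integers(1, 10_000), st.integers(1, 200)).map(
            lambda t: ResourceStats("s", t[0], t[1], random.Random(t[0] * 211 + t[1]).randint(0, t[1]))
        ),
        min_size=1, max_size=6,
    ),
    scale=st.integers(2, 9),
)
def test_weighted_precision_invariants(strata, scale):
    for rounding in (2, None):
        w = weighted_precision(strata, rounding=rounding)
        ppvs = [round(s.ppv, rounding) if rounding else s.ppv for s in strata]
        assert min(ppvs) - 1e-12 <= w <= max(ppvs) + 1e-12
        # order invariance
        assert weighted_precision(list(reversed(strata)), rounding=rounding) == pytest.approx(w)
        # uniform size scaling invariance
        scaled = [
            ResourceStats(s.label, s.size * scale, s.reviewed, s.true_positive)
            for s in strata
        ]
        assert weighted_precision(scaled, rounding=rounding) == pytest.approx(w)


def test_merging_equal_ppv_strata_is_neutral():
    a = ResourceStats("a", 100, 50, 40)
    b = ResourceStats("b", 300, 25, 20)
    merged = ResourceStats("ab", 400, 75, 60)
    assert weighted_precision([a, b], rounding=None) == pytest.approx(
        weighted_precision([merged], rounding=None)
    )


def test_published_report_reproduces_printed_table():
    report = medi2_precision_report()
    assert {s.label: round(s.ppv, 2) for s in report.resources} == {
        "RxNorm": 0.93, "Mayo Clinic": 0.81, "MedlinePlus": 0.78,
        "SIDER 4.1": 0.76, "WebMD": 0.75, "Wikipedia": 0.74,
    }
    assert {s.label: round(s.ppv, 2) for s in report.exact_strata} == {
        "1": 0.50, "2": 0.74, "3": 0.89, "4": 0.93, "5": 0.91,
    }
    assert [round(report.ge_precision(k), 2) for k in (1, 2, 3, 4)] == \
        [0.55, 0.80, 0.90, 0.92]
    assert round(report.overall_precision, 2) == 0.60
    assert round(report.hps_precision, 2) == 0.92
    assert report.overall_size == 186_064
    assert report.hps_size == 34_488
    # unrounded variant stays within half a point everywhere
    exact = medi2_precision_report(rounding=None)
    for k in (1, 2, 3, 4):
        assert abs(exact.ge_precision(k) - report.ge_precision(k)) <= 0.005
    assert abs(exact.overall_precision - report.overall_precision) <= 0.005


def test_report_requires_anchor_and_contiguous_strata():
    with pytest.raises(ValueError, match="anchor"):
        build_precision_report([ResourceStats("WebMD", 10, 5, 4)],
                               [ResourceStats("1", 5, 5, 4)])
    with pytest.raises(ValueError, match="contiguous"):
        build_precision_report(
            [ResourceStats("RxNorm", 10, 5, 4)],
            [ResourceStats("1", 5, 5, 4), ResourceStats("3", 5, 5, 4)],
        )


def test_all_true_reviews_give_unit_precisions():
    resources = [ResourceStats(l, 100, 10, 10)
                 for l in ("RxNorm", "WebMD", "Mayo Clinic")]
    strata = [ResourceStats(str(k), 50, 10, 10) for k in (1, 2, 3)]
    report = build_precision_report(resources, strata)
    assert report.overall_precision == report.hps_precision == 1.0
    assert all(report.ge_precision(k) == 1.0 for k in (1, 2))


def test_sampling_reproducible_and_distinct(noisy_bundle):
    from medikb.pipeline import build_from_bundle

    table = build_from_bundle(noisy_bundle)
    pick = lambda p: "WebMD" in p.resources
    a = sample_for_review(table, pick, n=20, seed=5, label="WebMD")
    b = sample_for_review(table, pick, n=20, seed=5, label="WebMD")
    c = sample_for_review(table, pick, n=20, seed=6, label="WebMD")
    ids = lambda r: [x.pair_id for x in r.records]
    assert ids(a) == ids(b)
    assert len(set(ids(a))) == 20
    assert ids(a) != ids(c)  # different seed, different sample
    small = sample_for_review(table, lambda p: False or "RxNorm" in p.resources,
                              n=10**6, seed=1)
    assert len(small.records) == sum(1 for p in table if "RxNorm" in p.resources)
    with pytest.raises(ValueError):
        sample_for_review(table, lambda p: False, n=5, seed=1)


def test_precision_table_from_reviews(noisy_bundle):
    """End-to-end: build a noisy table, auto-judge reviews from ground truth,
    and check the report's strata match the table's own histogram."""
    from medikb.aggregation import stratify_by_support
    from medikb.pipeline import build_from_bundle

    table = build_from_bundle(noisy_bundle)
    truth = noisy_bundle.truth

    def verdict(pair):
        return "TRUE" if any(
            (pair.rxcui, c) in truth.true_pairs for c in pair.cuis
        ) else "FALSE"

    def judged(stratum, label, seed):
        sampled = sample_for_review(table, stratum, n=40, seed=seed, label=label)
        by_id = {"|".join(p.key): p for p in table}
        return ReviewSet(
            records=[
                ReviewRecord(pair_id=r.pair_id, verdict=verdict(by_id[r.pair_id]))
                for r in sampled.records
            ],
            stratum=label,
        )

    reviews = {}
    for i, name in enumerate(table.resource_universe):
        reviews[name] = judged(lambda p, n=name: n in p.resources, name, seed=i)
    histogram = stratify_by_support(table, exclude="RxNorm")
    for k in histogram:
        reviews[str(k)] = judged(
            lambda p, k=k: len(p.resources - {"RxNorm"}) == k, str(k), seed=100 + k
        )
    report = precision_table(table, reviews, rule=HpsRule())
    assert sum(s.size for s in report.exact_strata) == sum(histogram.values())
    n_anchor = sum(1 for p in table if "RxNorm" in p.resources)
    assert report.anchor.size == n_anchor
    assert report.overall_size == n_anchor + sum(histogram.values())
    assert 0.0 <= report.overall_precision <= 1.0
    with pytest.raises(KeyError, match="WebMD"):
        precision_table(table, {k: v for k, v in reviews.items() if k != "WebMD"})


def test_recall_arithmetic():
    items = [
        RecallItem("propranolol", f"ind{i}", {"MEDI-1": i < 16, "MEDI-2": i < 19})
        for i in range(20)
    ]
    assert recall(items, "MEDI-2") == 0.95
    assert recall(items, "MEDI-1") == 0.80
    assert recall([RecallItem("m", "i", {"MEDI-1": False})], "MEDI-1") == 0.0
    with pytest.raises(KeyError):
        recall(items, "MEDI-C")
    with pytest.raises(ValueError):
        recall([], "MEDI-1")


def test_recall_against_fixture_knowledgebase(clean_bundle):
    """Curated list = planted truth for one drug; knowledgebase coverage
    equals the planted per-resource support."""
    from medikb.aggregation import cui_stream
    from medikb.pipeline import build_from_bundle

    table = build_from_bundle(clean_bundle)
    built = {(p.rxcui, c) for p in cui_stream(table) for c in p.cuis}
    truth = clean_bundle.truth
    items = [
        RecallItem(d, c, {"built": (d, c) in built})
        for d, c in sorted(truth.true_pairs)
    ]
    expected = len(truth.planted_true_pairs & truth.true_pairs) / len(truth.true_pairs)
    assert recall(items, "built") == pytest.approx(expected)


def test_review_tsv_round_trip(tmp_path):
    review = ReviewSet(
        records=[
            ReviewRecord(pair_id="100|10|A00.0", rxcui="100", code="A00.0",
                         verdict="TRUE", note="ok"),
            ReviewRecord(pair_id="101|9|300.0", rxcui="101", code="300.0",
                         verdict="AMBIGUOUS", note="too broad"),
        ],
        stratum="WebMD",
    )
    path = tmp_path / "review.tsv"
    write_review_tsv(review, path)
    back = load_review_tsv(path, stratum="WebMD")
    assert back.records == review.records
    with pytest.raises(ValueError):
        ReviewRecord(pair_id="x", verdict="MAYBE")
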
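import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medikb.aggregation import (
    HpsRule,
    MedIndPair,
    PairTable,
    aggregate,
    cui_stream,
    merge_union,
    overlap_counts,
    read_release,
    select_hps,
    stratify_by_support,
    write_release,
)
from medikb.normalization_mapping import PairRecord

RESOURCES = ("RxNorm", "Mayo Clinic", "MedlinePlus", "SIDER 4.1", "WebMD", "Wikipedia")


def rec(rxcui="101", cui="C1", version="10", code="A00.0", resource="WebMD", flag=""):
    return PairRecord(rxcui=rxcui, cui=cui, icd_version=version, code=code,
                      resource=resource, relation_flag=flag)


def make_table(support_sets, version="10"):
    """One pair per entry; entry i supported by support_sets[i]."""
    records = [
        rec(rxcui=str(100 + i), cui=f"C{i}", code=f"A{i:02d}.0", resource=r)
        for i, resources in enumerate(support_sets)
        for r in resources
    ]
    return aggregate(records, resource_universe=RESOURCES)


def test_aggregate_unions_resources_and_flags():
    records = [
        rec(resource="WebMD"),
        rec(resource="Mayo Clinic"),
        rec(resource="RxNorm", flag="may_be_treated_by"),
    ]
    table = aggregate(records, resource_universe=RESOURCES)
    assert len(table) == 1
    [pair] = list(table)
    assert pair.resources == {"WebMD", "Mayo Clinic", "RxNorm"}
    assert pair.relation_flags == {"may_be_treated_by"}


def test_aggregate_disjoint_streams():
    table = make_table([{r} for r in RESOURCES])
    assert len(table) == 6
    assert all(len(p.resources) == 1 for p in table)


def test_aggregate_order_independent():
    rng = random.Random(0)
    records = [
        rec(rxcui=str(100 + i % 5), cui=f"C{i % 7}", code=f"B{i % 7}.1", resource=r)
        for i in range(20)
        for r in rng.sample(RESOURCES, rng.randint(1, 3))
    ]
    tables = []
    for _ in range(3):
        shuffled = records[:]
        rng.shuffle(shuffled)
        tables.append(aggregate(shuffled, resource_universe=RESOURCES))
    assert tables[0].pairs == tables[1].pairs == tables[2].pairs


def test_stratify_exclude_semantics():
    table = make_table([
        {"RxNorm", "WebMD", "Mayo Clinic"},   # k=2 excluding RxNorm
        {"RxNorm"},                            # uncounted when excluded
        {"WebMD"},                             # k=1
    ])
    assert stratify_by_support(table, exclude="RxNorm") == {1: 1, 2: 1}
    assert stratify_by_support(table) == {3: 1, 1: 2}


def test_stratify_planted_histogram():
    design = {1: 10, 2: 5, 3: 3, 4: 1, 5: 1}
    support = []
    others = [r for r in RESOURCES if r != "RxNorm"]
    for k, n in design.items():
        support += [set(others[:k]) for _ in range(n)]
    table = make_table(support)
    assert stratify_by_support(table, exclude="RxNorm") == design


@pytest.mark.parametrize(
    "resources, kept",
    [({"RxNorm"}, True),
     ({"WebMD", "Mayo Clinic"}, False),
     ({"WebMD", "Mayo Clinic", "Wikipedia"}, True),
     ({"RxNorm", "WebMD"}, True)],
)
def test_hps_rule(resources, kept):
    table = make_table([resources])
    assert (len(select_hps(table, HpsRule())) == 1) is kept


def test_hps_rule_validation():
    with pytest.raises(ValueError):
        HpsRule(min_other_resources=0)
    with pytest.raises(ValueError):
        select_hps(make_table([{"WebMD"}]), HpsRule(anchor_resource="NotThere"))


def test_merge_union_labels_and_sizes():
    a = make_table([{"RxNorm"}, {"WebMD"}])
    b_records = [rec(rxcui="100", cui="C0", code="A00.0", resource="RxNorm"),
                 rec(rxcui="900", cui="C9", code="Z99.9", resource="Wikipedia")]
    b = aggregate(b_records, resource_universe=RESOURCES)
    merged = merge_union([a, b], ["MEDI-1", "MEDI-2"])
    assert len(merged) == 3  # 2 + 2 - 1 shared
    by_key = {p.key: p for p in merged}
    shared = by_key[("100", "10", "A00.0")]
    assert shared.sources == {"MEDI-1", "MEDI-2"}
    only_b = by_key[("900", "10", "Z99.9")]
    assert only_b.sources == {"MEDI-2"}


def test_merge_union_inclusion_exclusion():
    rng = random.Random(4)
    def table_with(ids):
        return aggregate(
            [rec(rxcui=str(100 + i), cui=f"C{i}", code=f"A{i:02d}.0",
                 resource=rng.choice(RESOURCES)) for i in ids],
            resource_universe=RESOURCES,
        )
    a_ids = set(range(56))
    b_ids = set(range(36, 156))  # 20 shared
    merged = merge_union([table_with(sorted(a_ids)), table_with(sorted(b_ids))],
                         ["MEDI-1", "MEDI-2"])
    assert len(merged) == len(a_ids | b_ids) == 156


def test_overlap_counts_modes():
    table = make_table([
        {"WebMD"},
        {"WebMD"},
        {"RxNorm", "WebMD"},
    ])
    by_pair = overlap_counts(table, by="pair")
    assert by_pair == {frozenset({"WebMD"}): 2, frozenset({"RxNorm", "WebMD"}): 1}
    # medication mode: each pair above has a distinct drug
    by_med = overlap_counts(table, by="medication")
    assert sum(by_med.values()) == len(table.medications())
    assert by_med[frozenset({"WebMD"})] == 2  # drug found only via WebMD
    assert overlap_counts(PairTable(resource_universe=RESOURCES), by="pair") == {}
    with pytest.raises(ValueError):
        overlap_counts(table, by="drug")


def test_overlap_counts_sum_to_entity_totals(noisy_bundle):
    from medikb.pipeline import build_from_bundle

    table = build_from_bundle(noisy_bundle)
    assert sum(overlap_counts(table, by="pair").values()) == len(table)
    assert sum(overlap_counts(table, by="medication").values()) == len(table.medications())


# ---------------------------------------------------------------------------
# Random-table properties

def random_table(rng):
    support = [
        set(rng.sample(RESOURCES, rng.randint(1, len(RESOURCES))))
        for _ in range(rng.randint(1, 60))
    ]
    return make_table(support)


@pytest.mark.parametrize("seed", range(4))
def test_hps_complement_and_stratum_sum(seed):
    rng = random.Random(seed)
    rule = HpsRule()
    for _ in range(25):
        table = random_table(rng)
        hps = select_hps(table, rule)
        assert set(hps.pairs) <= set(table.pairs)
        for key, pair in table.pairs.items():
            in_hps = key in hps.pairs
            qualifies = ("RxNorm" in pair.resources
                         or len(pair.resources - {"RxNorm"}) >= 3)
            assert in_hps == qualifies
        # stratum-sum conservation: excluded-anchor strata + anchor-only = total
        histogram = stratify_by_support(table, exclude="RxNorm")
        anchor_only = sum(1 for p in table if p.resources == {"RxNorm"})
        assert sum(histogram.values()) + anchor_only == len(table)


def test_release_round_trip(tmp_path):
    rng = random.Random(1)
    table = random_table(rng)
    path = tmp_path / "release.tsv"
    write_release(table, path)
    back = read_release(path)
    assert set(back.pairs) == set(table.pairs)
    for key, pair in table.pairs.items():
        got = back.pairs[key]
        assert got.resources == pair.resources
        assert got.cuis == pair.cuis
        assert got.code == pair.code


def test_release_hps_flag_matches_selection(tmp_path):
    table = random_table(random.Random(2))
    rule = HpsRule()
    path = tmp_path / "release.tsv"
    write_release(table, path, rule=rule)
    hps_keys = set(select_hps(table, rule).pairs)
    header, *rows = path.read_text().splitlines()
    cols = header.split("\t")
    for row in rows:
        cells = dict(zip(cols, row.split("\t")))
        key = (cells["RXCUI"], cells["ICD_VERSION"],
               cells["CODE"] or cells["CUI"].split("|")[0])
        assert (cells["HPS"] == "1") == (key in hps_keys)
        assert cells["N_OTHER_RESOURCES"] == str(
            len(table.pairs[key].resources - {"RxNorm"}))


def test_release_bytes_deterministic(tmp_path):
    table = random_table(random.Random(3))
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_release(table, p1)
    # rebuild an equal table from shuffled records and rewrite
    records = [
        rec(rxcui=p.rxcui, cui=min(p.cuis), version=p.icd_version,
            code=p.code, resource=r)
        for p in table for r in sorted(p.resources)
    ]
    random.Random(99).shuffle(records)
    write_release(aggregate(records, resource_universe=RESOURCES), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_malformed_release_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    write_release(make_table([{"WebMD"}]), path)
    text = path.read_text().splitlines()
    text.append("too\tfew\tcells")
    path.write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match=":3"):
        read_release(path)


def test_cui_stream_has_own_hps_flag(tmp_path):
    records = [
        rec(rxcui="100", cui="C1", version="CUI", code="", resource="RxNorm"),
        rec(rxcui="101", cui="C2", version="CUI", code="", resource="WebMD"),
    ]
    table = aggregate(records, resource_universe=RESOURCES)
    path = tmp_path / "r.tsv"
    write_release(table, path)
    rows = path.read_text().splitlines()[1:]
    flags = {r.split("\t")[0]: r.split("\t")[-2] for r in rows}
    assert flags == {"100": "1", "101": "0"}
    assert len(cui_stream(table)) == 2


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    support=st.lists(
        st.frozensets(st.sampled_from(RESOURCES), min_size=1, max_size=6),
        min_size=1, max_size=30,
    ),
    min_other=st.integers(min_value=1, max_value=5),
)
def test_hps_subset_property(support, min_other):
    table = make_table(support)
    rule = HpsRule(min_other_resources=min_other)
    hps = select_hps(table, rule)
    dropped = set(table.pairs) - set(hps.pairs)
    for key in dropped:
        resources = table.pairs[key].resources
        assert "RxNorm" not in resources
        assert len(resources - {"RxNorm"}) < min_other
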
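"""Dialect readers and the five source-specific filter rules.

Every filter is checked against a one-line brute-force predicate on the same
rows, plus the documented boundary cases.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oreganokg.binder import SourceRecord, normalize_xref
from oreganokg.schema import NodeKind
from oreganokg.wrappers import (
    FREQUENCY_BANDS,
    EndpointRef,
    RelationRow,
    extract,
    filter_atc_codes,
    filter_hpo_links,
    filter_npass_human,
    filter_pharmgkb_evidence,
    filter_uniprot,
    resolve_frequency,
    restrict_omim_via_umls,
)


def row(pred="has_target", **attrs):
    return RelationRow(EndpointRef("x", "s"), pred, EndpointRef("x", "o"), attrs)


# --------------------------------------------------------------------------
# frequency resolution
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        ("3/10", 0.3),
        ("29/100", 0.29),
        ("30%", 0.30),
        ("29%", 0.29),
        ("Occasional", 0.05),
        ("Frequent", 0.30),
        ("Very frequent", 0.80),
        ("Obligate", 1.0),
        ("Excluded", 0.0),
        ("", None),
        (None, None),
        ("garbled", None),
        ("1/0", None),
    ],
)
def test_resolve_frequency(text, expected):
    assert resolve_frequency(text) == expected


def test_frequency_bands_bounds():
    bounds = {b.label: (b.lower, b.upper) for b in FREQUENCY_BANDS}
    assert bounds == {
        "Excluded": (0.0, 0.0),
        "Very rare": (0.01, 0.04),
        "Occasional": (0.05, 0.29),
        "Frequent": (0.30, 0.79),
        "Very frequent": (0.80, 0.99),
        "Obligate": (1.0, 1.0),
    }


# --------------------------------------------------------------------------
# filters vs brute force
# --------------------------------------------------------------------------


def test_human_organism_filter():
    rows = [row(organism=o) for o in ("Homo sapiens", "Bos taurus", "Saccharomyces cerevisiae")]
    rows.append(row())  # missing organism -> dropped
    kept = filter_npass_human(rows)
    assert kept == [r for r in rows if r.attributes.get("organism") == "Homo sapiens"]
    assert len(kept) == 1


def test_atc_length_filter():
    assert filter_atc_codes(["A10BA02", "A10"]) == ["A10BA02"]
    assert filter_atc_codes([]) == []
    codes = ["x" * n for n in (1, 3, 4, 5, 7, 7, 8)]
    assert filter_atc_codes(codes) == [c for c in codes if len(c) == 7]


def test_pharmgkb_evidence_filter():
    rows = [row("is_affecting", evidence=lv) for lv in ("1A", "3", "2B", "4", "1B", "2A", "banana")]
    kept = filter_pharmgkb_evidence(rows)
    assert kept == [r for r in rows if r.attributes["evidence"] in {"1A", "1B", "2A", "2B"}]
    assert len(kept) == 4


@pytest.mark.parametrize(
    "frequency, evidence, survives",
    [
        ("29%", None, False),
        ("30%", None, True),
        (None, "IEA", False),
        (None, "TAS", True),
        (None, "PCS", True),
        ("Occasional", None, False),
        ("Frequent", None, True),
        ("29%", "TAS", False),   # sub-threshold frequency beats good evidence
        ("garbled", "PCS", True),  # unparseable falls back to the evidence rule
    ],
)
def test_hpo_link_filter_boundaries(frequency, evidence, survives):
    attrs = {}
    if frequency is not None:
        attrs["frequency"] = frequency
    if evidence is not None:
        attrs["evidence"] = evidence
    r = row("has_phenotype", **attrs)
    assert (filter_hpo_links([r]) == [r]) is survives


def test_restrict_omim_via_umls():
    pivot = [
        ("C1", "omim", "100"), ("C1", "hpo_disease", "HD1"),
        ("C2", "omim", "200"),                      # no disease link
        ("C3", "omim", "300"), ("C3", "hpo_disease", "HDX"),  # unknown disease
    ]
    assert restrict_omim_via_umls({"100", "200", "300"}, {"HD1"}, pivot) == {"100"}
    assert restrict_omim_via_umls({"100"}, {"HD1"}, []) == set()


def test_uniprot_filter_drops_unreviewed_and_unknown_endpoints():
    known = {normalize_xref("uniprot", "P1"), normalize_xref("hgnc", "HGNC:1")}
    recs = [
        SourceRecord("uniprot", "P1", NodeKind.TARGET, "", frozenset({("uniprot", "P1")}),
                     {"dataset": "Swiss-Prot"}),
        SourceRecord("uniprot", "P2", NodeKind.TARGET, "", frozenset({("uniprot", "P2")}),
                     {"dataset": "TrEMBL"}),
        SourceRecord("uniprot", "P3", NodeKind.TARGET, "", frozenset({("uniprot", "P3")}),
                     {"dataset": "Swiss-Prot"}),
    ]
    links = [
        RelationRow(EndpointRef("uniprot-local", "P1"), "gene_product_of", EndpointRef("hgnc", "HGNC:1")),
        RelationRow(EndpointRef("uniprot-local", "P2"), "gene_product_of", EndpointRef("hgnc", "HGNC:1")),
        RelationRow(EndpointRef("uniprot-local", "P3"), "gene_product_of", EndpointRef("hgnc", "HGNC:1")),
        RelationRow(EndpointRef("uniprot-local", "P1"), "gene_product_of", EndpointRef("hgnc", "HGNC:999")),
    ]
    kept_recs, kept_links = filter_uniprot(recs, links, known)
    assert [r.local_id for r in kept_recs] == ["P1", "P3"]  # reviewed only
    # P2 unreviewed, P3 has no known xref, HGNC:999 unknown
    assert kept_links == links[:1]


_attr_rows = st.lists(
    st.builds(
        row,
        pred=st.just("has_phenotype"),
        frequency=st.sampled_from(["1/4", "3/4", "55%", "10%", "Frequent", "Occasional", "", "n/a"]),
        evidence=st.sampled_from(["TAS", "PCS", "IEA", ""]),
    ),
    max_size=30,
)


@settings(deadline=None, max_examples=40)
@given(_attr_rows)
def test_filters_are_idempotent_subsets(rows):
    """Filters are pure: output is a sub-list of input; twice == once."""
    for f in (filter_hpo_links, filter_pharmgkb_evidence, filter_npass_human):
        once = f(rows)
        assert f(once) == once
        it = iter(rows)
        assert all(any(r is x for x in it) for r in once)  # order-preserving subset


# --------------------------------------------------------------------------
# extraction on tiny hand-written dumps
# --------------------------------------------------------------------------


def test_extract_empty_dump(tmp_path):
    path = tmp_path / "sider.tsv"
    path.write_text("", encoding="utf-8")
    res = extract(path, "sider")
    assert (res.relations, res.records) == ([], [])


def test_extract_drug_source(tmp_path):
    drugs = ['<drugbank version="1">']
    for i in range(5):
        tgt = f'<target id="T{i % 3}" organism="Homo sapiens"><name>t</name></target>' if i < 4 else ""
        drugs.append(f'<drug id="D{i}"><name>d{i}</name>{tgt}</drug>')
    drugs.append("</drugbank>")
    path = tmp_path / "drugbank.xml"
    path.write_text("\n".join(drugs), encoding="utf-8")
    res = extract(path, "drugbank")
    assert len([r for r in res.relations if r.predicate == "has_target"]) == 4
    assert len(res.records) == 8  # 5 compounds + 3 distinct targets


def test_extract_side_effect_source(tmp_path):
    lines = [
        "indication\tI1\theadache\tumls:C1",
        "side_effect\tE1\tnausea\tumls:C2",
        "side_effect\tE2\trash\tumls:C3",
    ]
    for d in ("D1", "D2"):
        lines.append(f"drug\t{d}\tdrug\tcas:1-{d}")
        lines.append(f"link\t{d}\thas_indication\tI1")
        lines.append(f"link\t{d}\thas_side_effect\tE1")
        lines.append(f"link\t{d}\thas_side_effect\tE2")
    path = tmp_path / "sider.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    res = extract(path, "sider")
    preds = [r.predicate for r in res.relations]
    assert preds.count("has_indication") == 2
    assert preds.count("has_side_effect") == 4


def test_extract_skips_malformed_rows(tmp_path):
    path = tmp_path / "sider.tsv"
    path.write_text("drug\tD1\tname\t\nmystery\trow\nlink\tD1\n", encoding="utf-8")
    res = extract(path, "sider")
    assert len(res.records) == 1
    assert res.skipped["unknown_row_type"] == 1
    assert res.skipped["link_malformed"] == 1


def test_extract_unreadable_file_is_hard_error(tmp_path):
    with pytest.raises(OSError):
        extract(tmp_path / "missing.tsv", "sider")


def test_wrappers_emit_only_attributed_predicates(suite):
    from oreganokg.wrappers import SOURCE_PREDICATES

    manifest, _ = suite
    for source in SOURCE_PREDICATES:
        res = extract(manifest[source], source)
        assert {r.predicate for r in res.relations} <= SOURCE_PREDICATES[source]
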
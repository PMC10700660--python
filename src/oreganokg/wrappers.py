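"""Per-source readers and the source-specific filtering rules.

Each of the seven knowledge sources has its own dialect — XML-like record
files for the drug and protein sources, row-typed TSV tables for the
pharmacogenomic, side-effect, pathway, natural-compound and
phenotype-annotation sources, and an OBO ontology for the phenotype
hierarchy.  A wrapper scans one dump and emits (a) relation rows over
source-local identifiers and (b) cross-reference records for the binder.

Filters are pure functions on row lists (output is always a subset of the
input, order preserved, idempotent):

* natural-compound targets restricted to Homo sapiens;
* ATC codes restricted to the 7-character substance level (shorter codes
  denote drug classes);
* pharmacogenomic clinical annotations restricted to evidence levels
  1A/1B/2A/2B;
* disease-phenotype links kept when the frequency of occurrence is >= 30%,
  falling back to TAS/PCS evidence only when no frequency is given;
* protein-source links restricted to endpoints already present in the graph,
  and protein records to the reviewed (Swiss-Prot) dataset.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import obonet
from lxml import etree

from .binder import SourceRecord, XRefKey, normalize_xref
from .schema import NodeKind

log = logging.getLogger(__name__)

SOURCES = ("drugbank", "sider", "npass", "pharmgkb", "hpo", "reactome", "uniprot")
PIVOTS = ("umls", "orphanet")

#: Predicates each source is allowed to emit (the attribution of relation
#: patterns to sources; a wrapper skips link rows outside its set).
SOURCE_PREDICATES: dict[str, frozenset[str]] = {
    "drugbank": frozenset(
        {"has_target", "has_code", "subclass_of", "increases_efficacy", "decreases_efficacy"}
    ),
    "sider": frozenset({"has_indication", "has_side_effect"}),
    "npass": frozenset(
        {
            "has_target",
            "has_activity",
            "increases_activity",
            "decreases_activity",
            "has_effect",
            "increases_effect",
            "decreases_effect",
        }
    ),
    "pharmgkb": frozenset({"is_affecting", "is_substance_that_treats", "causes_condition"}),
    "hpo": frozenset({"has_phenotype", "causes_condition"}),
    "reactome": frozenset({"acts_within"}),
    "uniprot": frozenset({"gene_product_of"}),
}

HUMAN_ORGANISM = "Homo sapiens"
ATC_CODE_LENGTH = 7
PHARMGKB_ACCEPTED_LEVELS = frozenset({"1A", "1B", "2A", "2B"})
HPO_ACCEPTED_EVIDENCE = frozenset({"TAS", "PCS"})
HPO_FREQUENCY_THRESHOLD = 0.30


@dataclass(frozen=True)
class FrequencyBand:
    label: str
    lower: float
    upper: float


#: The qualitative frequency-of-occurrence bands of phenotype annotations.
FREQUENCY_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("Excluded", 0.0, 0.0),
    FrequencyBand("Very rare", 0.01, 0.04),
    FrequencyBand("Occasional", 0.05, 0.29),
    FrequencyBand("Frequent", 0.30, 0.79),
    FrequencyBand("Very frequent", 0.80, 0.99),
    FrequencyBand("Obligate", 1.0, 1.0),
)
_BAND_BY_LABEL = {b.label.lower(): b for b in FREQUENCY_BANDS}


class EndpointRef(NamedTuple):
    """A relation endpoint before global resolution: either a source-local
    identifier (namespace = source name) or an external cross-reference."""

    namespace: str
    identifier: str


@dataclass(frozen=True)
class RelationRow:
    subject: EndpointRef
    predicate: str
    object: EndpointRef
    attributes: Mapping[str, str] = field(default_factory=dict)


@dataclass
class ExtractResult:
    relations: list[RelationRow]
    records: list[SourceRecord]
    skipped: Counter

    def __iter__(self):  # allow (relations, records) unpacking per the op contract
        return iter((self.relations, self.records))


# --------------------------------------------------------------------------
# frequency / evidence parsing
# --------------------------------------------------------------------------

_RATIO_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")
_PERCENT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%\s*$")


def resolve_frequency(text: str | None) -> float | None:
    """Resolve a frequency annotation to a fraction in [0, 1].

    Accepts ``n/m`` ratios, percentages, and qualitative band labels (a band
    resolves to its lower bound).  Returns None when absent or unparseable.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    m = _RATIO_RE.match(text)
    if m:
        num, den = int(m.group(1)), int(m.group(2))
        return num / den if den else None
    m = _PERCENT_RE.match(text)
    if m:
        return float(m.group(1)) / 100.0
    band = _BAND_BY_LABEL.get(text.lower())
    if band is not None:
        return band.lower
    return None


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------


def filter_npass_human(rows: Sequence[RelationRow]) -> list[RelationRow]:
    """Keep compound-target rows whose target organism is Homo sapiens.

    Rows missing the organism attribute are dropped (conservative)."""
    return [r for r in rows if r.attributes.get("organism") == HUMAN_ORGANISM]


def filter_atc_codes(codes: Iterable[str]) -> list[str]:
    """Keep 7-character substance-level ATC codes; shorter codes are classes."""
    return [c for c in codes if len(c) == ATC_CODE_LENGTH]


def filter_pharmgkb_evidence(rows: Sequence[RelationRow]) -> list[RelationRow]:
    """Keep clinical annotations with evidence level 1A, 1B, 2A or 2B."""
    return [r for r in rows if r.attributes.get("evidence") in PHARMGKB_ACCEPTED_LEVELS]


def _hpo_row_survives(frequency: str | None, evidence: str | None) -> bool:
    freq = resolve_frequency(frequency)
    if freq is not None:
        return freq >= HPO_FREQUENCY_THRESHOLD
    return evidence in HPO_ACCEPTED_EVIDENCE


def filter_hpo_links(rows: Sequence[RelationRow]) -> list[RelationRow]:
    """Keep disease-phenotype links with frequency >= 30%; when no frequency
    is available, keep TAS/PCS-evidenced links.  A sub-threshold frequency
    drops the row even if the evidence is TAS/PCS."""
    return [
        r
        for r in rows
        if _hpo_row_survives(r.attributes.get("frequency"), r.attributes.get("evidence"))
    ]


def restrict_omim_via_umls(
    omim_ids: set[str],
    hpo_disease_xrefs: set[str],
    umls_pivot: Sequence[tuple[str, str, str]],
) -> set[str]:
    """OMIM identifiers reachable from an integrated HPO disease through the
    UMLS pivot (concept -> {omim, hpo_disease} mappings)."""
    by_concept: dict[str, dict[str, set[str]]] = {}
    for concept, namespace, identifier in umls_pivot:
        by_concept.setdefault(concept, {}).setdefault(namespace.lower(), set()).add(identifier)
    kept: set[str] = set()
    for maps in by_concept.values():
        if maps.get("hpo_disease", set()) & hpo_disease_xrefs:
            kept |= maps.get("omim", set()) & omim_ids
    return kept


def filter_uniprot(
    records: Sequence[SourceRecord],
    links: Sequence[RelationRow],
    known_nodes: set[XRefKey],
) -> tuple[list[SourceRecord], list[RelationRow]]:
    """Drop unreviewed (non-Swiss-Prot) protein records, and keep only links
    whose both endpoints resolve to nodes already present in the graph."""
    kept_records = [r for r in records if r.attributes.get("dataset") == "Swiss-Prot"]
    reviewed_by_id = {r.local_id: r for r in kept_records}

    def endpoint_known(ref: EndpointRef) -> bool:
        if ref.namespace == "uniprot-local":
            rec = reviewed_by_id.get(ref.identifier)
            return rec is not None and bool(rec.normalized_xrefs() & known_nodes)
        return normalize_xref(ref.namespace, ref.identifier) in known_nodes

    kept_links = [l for l in links if endpoint_known(l.subject) and endpoint_known(l.object)]
    return kept_records, kept_links


# --------------------------------------------------------------------------
# dialect readers
# --------------------------------------------------------------------------


def _parse_xref_field(text: str) -> frozenset[XRefKey]:
    """Parse ``ns:id;ns:id`` cross-reference cells."""
    keys = set()
    for chunk in (text or "").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        ns, sep, ident = chunk.partition(":")
        if sep and ident:
            keys.add(normalize_xref(ns, ident))
    return frozenset(keys)


def _local_ref(source: str, local_id: str) -> EndpointRef:
    return EndpointRef(f"{source}-local", local_id)


def _read_drugbank(path: Path) -> ExtractResult:
    relations: list[RelationRow] = []
    records: list[SourceRecord] = []
    skipped: Counter = Counter()
    root = etree.parse(str(path)).getroot()
    seen_targets: set[str] = set()
    for drug in root.iterfind("drug"):
        drug_id = drug.get("id")
        if not drug_id:
            skipped["drug_missing_id"] += 1
            continue
        name = drug.findtext("name", default="")
        xrefs = {normalize_xref(x.get("ns", ""), x.get("id", "")) for x in drug.iterfind("xref")}
        dref = _local_ref("drugbank", drug_id)
        atc_codes = []
        for atc in drug.iterfind("atc"):
            code = atc.get("code", "")
            if not code:
                skipped["atc_missing_code"] += 1
                continue
            atc_codes.append(code)
            relations.append(RelationRow(dref, "has_code", EndpointRef("atc", code)))
            child = code
            for parent in atc.iterfind("parent"):
                pcode = parent.get("code", "")
                if pcode:
                    relations.append(
                        RelationRow(EndpointRef("atc", child), "subclass_of", EndpointRef("atc", pcode))
                    )
                    child = pcode
        xrefs |= {normalize_xref("atc", c) for c in atc_codes}
        records.append(SourceRecord("drugbank", drug_id, NodeKind.COMPOUND, name, frozenset(xrefs)))
        for target in drug.iterfind("target"):
            tid = target.get("id")
            if not tid:
                skipped["target_missing_id"] += 1
                continue
            if tid not in seen_targets:
                seen_targets.add(tid)
                txrefs = frozenset(
                    normalize_xref(x.get("ns", ""), x.get("id", "")) for x in target.iterfind("xref")
                )
                records.append(
                    SourceRecord(
                        "drugbank",
                        tid,
                        NodeKind.TARGET,
                        target.findtext("name", default=""),
                        txrefs,
                        {"organism": target.get("organism", "")},
                    )
                )
            relations.append(
                RelationRow(
                    dref,
                    "has_target",
                    _local_ref("drugbank", tid),
                    {"organism": target.get("organism", "")},
                )
            )
        for inter in drug.iterfind("interaction"):
            other, itype = inter.get("drug"), inter.get("type", "")
            if not other or itype not in SOURCE_PREDICATES["drugbank"]:
                skipped["interaction_malformed"] += 1
                continue
            relations.append(RelationRow(dref, itype, _local_ref("drugbank", other)))
    return ExtractResult(relations, records, skipped)


def _read_uniprot(path: Path) -> ExtractResult:
    relations: list[RelationRow] = []
    records: list[SourceRecord] = []
    skipped: Counter = Counter()
    root = etree.parse(str(path)).getroot()
    for entry in root.iterfind("entry"):
        acc = entry.get("id")
        if not acc:
            skipped["entry_missing_id"] += 1
            continue
        xrefs = {normalize_xref(x.get("ns", ""), x.get("id", "")) for x in entry.iterfind("xref")}
        xrefs.add(normalize_xref("uniprot", acc))
        records.append(
            SourceRecord(
                "uniprot",
                acc,
                NodeKind.TARGET,
                entry.findtext("name", default=""),
                frozenset(xrefs),
                {
                    "dataset": entry.get("dataset", ""),
                    "organism": entry.findtext("organism", default=""),
                },
            )
        )
        for gene in entry.iterfind("gene"):
            ns, ident = gene.get("ns", ""), gene.get("id", "")
            if not ns or not ident:
                skipped["gene_malformed"] += 1
                continue
            relations.append(
                RelationRow(_local_ref("uniprot", acc), "gene_product_of", EndpointRef(ns, ident))
            )
    return ExtractResult(relations, records, skipped)


# Row-typed TSV dialect: the first cell names the record type.  Entity rows
# are (type, local_id, name, xrefs[, extra...]); link rows are
# (link, subject, predicate, object[, attr...]).
_TSV_ENTITY_KINDS: dict[str, dict[str, NodeKind]] = {
    "sider": {"drug": NodeKind.COMPOUND, "indication": NodeKind.INDICATION,
              "side_effect": NodeKind.SIDE_EFFECT},
    "npass": {"compound": NodeKind.COMPOUND, "target": NodeKind.TARGET,
              "activity": NodeKind.ACTIVITY, "effect": NodeKind.EFFECT},
    "pharmgkb": {"compound": NodeKind.COMPOUND, "gene": NodeKind.GENE,
                 "disease": NodeKind.DISEASE},
    "reactome": {"pathway": NodeKind.PATHWAY, "gene": NodeKind.GENE},
    "hpo": {"disease": NodeKind.DISEASE, "gene": NodeKind.GENE},
}

# which trailing link-row cell becomes which attribute, per source
_TSV_LINK_ATTR: dict[str, str] = {
    "npass": "organism",
    "pharmgkb": "evidence",
}


def _read_rowtyped_tsv(path: Path, source: str) -> ExtractResult:
    relations: list[RelationRow] = []
    records: list[SourceRecord] = []
    skipped: Counter = Counter()
    entity_kinds = _TSV_ENTITY_KINDS[source]
    allowed = SOURCE_PREDICATES[source]
    local_kind: dict[str, NodeKind] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            rtype = cells[0]
            if rtype in entity_kinds:
                if len(cells) < 3:
                    skipped[f"{rtype}_malformed"] += 1
                    continue
                local_id, name = cells[1], cells[2]
                xrefs = _parse_xref_field(cells[3]) if len(cells) > 3 else frozenset()
                attrs: dict[str, str] = {}
                if source == "npass" and rtype == "target" and len(cells) > 4:
                    attrs["organism"] = cells[4]
                records.append(
                    SourceRecord(source, local_id, entity_kinds[rtype], name, xrefs, attrs)
                )
                local_kind[local_id] = entity_kinds[rtype]
            elif rtype == "link" or rtype == "ann" or rtype == "pheno_ann" or rtype == "gene_ann":
                row = _parse_tsv_link(cells, source, allowed, lineno)
                if row is None:
                    skipped["link_malformed"] += 1
                else:
                    relations.append(row)
            else:
                skipped["unknown_row_type"] += 1
                log.debug("%s:%d unknown row type %r", path, lineno, rtype)
    return ExtractResult(relations, records, skipped)


def _parse_tsv_link(
    cells: list[str], source: str, allowed: frozenset[str], lineno: int
) -> RelationRow | None:
    rtype = cells[0]
    if rtype == "pheno_ann":
        # disease, phenotype term, frequency, evidence
        if len(cells) < 3:
            return None
        attrs = {}
        if len(cells) > 3 and cells[3]:
            attrs["frequency"] = cells[3]
        if len(cells) > 4 and cells[4]:
            attrs["evidence"] = cells[4]
        return RelationRow(
            _local_ref("hpo", cells[1]), "has_phenotype", EndpointRef("hp", cells[2]), attrs
        )
    if rtype == "gene_ann":
        if len(cells) < 3:
            return None
        return RelationRow(_local_ref("hpo", cells[1]), "causes_condition", _local_ref("hpo", cells[2]))
    # generic: link/ann subject predicate object [attr]
    if len(cells) < 4:
        return None
    predicate = cells[2]
    if predicate not in allowed:
        return None
    attrs = {}
    attr_name = _TSV_LINK_ATTR.get(source)
    if attr_name and len(cells) > 4 and cells[4]:
        attrs[attr_name] = cells[4]
    return RelationRow(_local_ref(source, cells[1]), predicate, _local_ref(source, cells[3]), attrs)


def _read_hpo(annotations: Path, ontology: Path | None) -> ExtractResult:
    result = _read_rowtyped_tsv(annotations, "hpo")
    if ontology is not None:
        graph = obonet.read_obo(str(ontology))
        for term_id, data in sorted(graph.nodes(data=True)):
            xrefs = {normalize_xref("hp", term_id)}
            for xr in data.get("xref", []):
                ns, sep, ident = xr.partition(":")
                if sep and ident:
                    xrefs.add(normalize_xref(ns, ident))
            result.records.append(
                SourceRecord("hpo", term_id, NodeKind.PHENOTYPE, data.get("name", ""), frozenset(xrefs))
            )
    # phenotype endpoints are term IDs; attach the hp namespace so the binder
    # can resolve pheno_ann objects through the term records
    return result


def read_pivot(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a pivot mapping file: one ``concept<TAB>namespace<TAB>identifier``
    mapping per line."""
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ValueError(f"{path}:{lineno}: pivot rows have 3 columns")
            rows.append((cells[0], cells[1], cells[2]))
    return rows


def extract(paths: Mapping[str, Path] | Path, source: str) -> ExtractResult:
    """Run one source's wrapper over its dump file(s).

    ``paths`` is the dump path, or for the phenotype source a mapping with
    ``annotations`` and optional ``ontology`` entries.  Malformed records are
    logged and counted in the result's ``skipped`` counter; an unreadable
    file raises.
    """
    if source == "drugbank":
        return _read_drugbank(Path(paths))
    if source == "uniprot":
        return _read_uniprot(Path(paths))
    if source == "hpo":
        if isinstance(paths, Mapping):
            return _read_hpo(Path(paths["annotations"]), Path(paths["ontology"]) if paths.get("ontology") else None)
        return _read_hpo(Path(paths), None)
    if source in _TSV_ENTITY_KINDS:
        return _read_rowtyped_tsv(Path(paths), source)
    raise ValueError(f"unknown source: {source!r}")
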
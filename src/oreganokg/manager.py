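"""Triple rewriting, serialization, and the end-to-end build pipeline.

The manager replaces source-local endpoints in wrapper-emitted relation rows
by the global identifiers recorded in the mapping table, drops rows with an
unresolvable endpoint (a node is not integrated if no linkage can be made for
it), deduplicates, and serializes the graph: a 3-column TSV edge list, a
Turtle document carrying names and cross-references, and per-kind
cross-reference tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from urllib.parse import quote

from rdflib import Graph as RDFGraph
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import RDFS

from .binder import MappingTable, SourceRecord, normalize_xref
from .schema import (
    GraphID,
    KnowledgeGraph,
    NodeKind,
    Predicate,
    Triple,
    default_registry,
)
from .wrappers import (
    EndpointRef,
    RelationRow,
    extract,
    filter_atc_codes,
    filter_hpo_links,
    filter_npass_human,
    filter_pharmgkb_evidence,
    filter_uniprot,
    read_pivot,
    restrict_omim_via_umls,
)

log = logging.getLogger(__name__)

#: Default source integration order: the drug source seeds the hub, the
#: protein source comes last because its links are restricted to nodes
#: already present in the graph.
DEFAULT_ORDER = ("drugbank", "sider", "pharmgkb", "npass", "hpo", "reactome", "uniprot")

NS = Namespace("http://oreganokg.example.org/")

#: Cross-reference table file names, one per node kind (irregular plurals are
#: part of the released-artifact layout).  ACTIVITY/EFFECT are name lists.
XREF_FILE_NAMES: dict[NodeKind, str] = {
    NodeKind.TARGET: "TARGET.tsv",
    NodeKind.PHENOTYPE: "PHENOTYPES.tsv",
    NodeKind.DISEASE: "DISEASES.tsv",
    NodeKind.PATHWAY: "PATHWAYS.tsv",
    NodeKind.GENE: "GENES.tsv",
    NodeKind.COMPOUND: "COMPOUND.tsv",
    NodeKind.INDICATION: "INDICATIONS.tsv",
    NodeKind.SIDE_EFFECT: "SIDE_EFFECT.tsv",
}
NAME_LIST_FILE_NAMES: dict[NodeKind, str] = {
    NodeKind.ACTIVITY: "ACTIVITY.tsv",
    NodeKind.EFFECT: "EFFECT.tsv",
}


# --------------------------------------------------------------------------
# rewriting
# --------------------------------------------------------------------------


def _resolve_endpoint(
    ref: EndpointRef, expected_kind: NodeKind, table: MappingTable
) -> GraphID | None:
    if ref.namespace == "atc":
        return GraphID(NodeKind.ATC, ref.identifier) if expected_kind is NodeKind.ATC else None
    if ref.namespace.endswith("-local"):
        oid = table.lookup_local(ref.namespace[: -len("-local")], ref.identifier)
    else:
        oid = table.lookup_xref(expected_kind, normalize_xref(ref.namespace, ref.identifier))
    if oid is not None and oid.kind is not expected_kind:
        return None
    return oid


def rewrite_triples(
    local_triples: Sequence[RelationRow],
    table: MappingTable,
    registry: Mapping[str, Predicate] | None = None,
) -> tuple[list[Triple], Counter]:
    """Rewrite local-ID relation rows into global-ID triples.

    Rows whose subject or object cannot be resolved are dropped and counted
    by reason; the output is deduplicated preserving first occurrence.
    """
    registry = registry or default_registry()
    dropped: Counter = Counter()
    out: list[Triple] = []
    seen: set[Triple] = set()
    for row in local_triples:
        pred = registry.get(row.predicate)
        if pred is None:
            dropped["unknown_predicate"] += 1
            continue
        subj = _resolve_endpoint(row.subject, pred.subject_kind, table)
        if subj is None:
            dropped["unmapped_subject"] += 1
            continue
        obj = _resolve_endpoint(row.object, pred.object_kind, table)
        if obj is None:
            dropped["unmapped_object"] += 1
            continue
        t = Triple(str(subj), row.predicate, str(obj))
        if t in seen:
            dropped["duplicate"] += 1
            continue
        seen.add(t)
        out.append(t)
    return out, dropped


# --------------------------------------------------------------------------
# TSV triples
# --------------------------------------------------------------------------


def write_triples_tsv(
    g: KnowledgeGraph,
    path: str | Path,
    kind_alias: Mapping[NodeKind, str] | None = None,
    header: bool = False,
) -> None:
    """Write the edge list as 3 tab-separated columns, one triple per line,
    sorted lexicographically by (subject, predicate, object)."""
    alias = {k.value: v for k, v in (kind_alias or {}).items()}

    def render(endpoint: str) -> str:
        head, sep, local = endpoint.partition(":")
        return f"{alias[head]}:{local}" if head in alias else endpoint

    lines = sorted((t.subject, t.predicate, t.object) for t in g)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write("Subject\tPredicate\tObject\n")
        for s, p, o in lines:
            fh.write(f"{render(s)}\t{p}\t{render(o)}\n")


def read_triples_tsv(
    path: str | Path,
    kind_alias: Mapping[str, NodeKind] | None = None,
    header: bool = False,
) -> KnowledgeGraph:
    """Read a 3-column TSV edge list back into a graph; malformed lines are a
    hard error with the line number."""
    alias = {name: kind for name, kind in (kind_alias or {}).items()}
    g = KnowledgeGraph()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if header and lineno == 1:
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            s, p, o = cells
            try:
                subj = GraphID.parse(s, alias)
                obj = GraphID.parse(o, alias)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            g.add(Triple(str(subj), p, str(obj)))
    return g


# --------------------------------------------------------------------------
# Turtle
# --------------------------------------------------------------------------


def _node_iri(endpoint: str) -> URIRef:
    kind, _, local = endpoint.partition(":")
    return URIRef(str(NS) + quote(f"{kind}_{local}", safe=""))


def _iri_to_endpoint(iri: URIRef) -> str | None:
    text = str(iri)
    if not text.startswith(str(NS)):
        return None
    local = text[len(str(NS)):]
    for kind in sorted((k.value for k in NodeKind), key=len, reverse=True):
        if local.startswith(kind + "_"):
            from urllib.parse import unquote

            return f"{kind}:{unquote(local[len(kind) + 1:])}"
    return None


def write_turtle(g: KnowledgeGraph, table: MappingTable | None, path: str | Path) -> None:
    """Serialize the graph as Turtle with entity names and cross-references.

    Each graph edge becomes one statement under a project-namespace property;
    each node additionally carries an ``rdfs:label`` (display name) and one
    ``xref`` statement per cross-reference from the mapping table."""
    rg = RDFGraph()
    rg.bind("oregano", NS)
    rg.bind("rdfs", RDFS)
    xref_prop = NS["xref"]
    for t in g:
        rg.add((_node_iri(t.subject), NS[t.predicate], _node_iri(t.object)))
    rows = table.rows if table is not None else {}
    for node in g.nodes:
        iri = _node_iri(node)
        kind, _, local = node.partition(":")
        row = rows.get(GraphID(NodeKind(kind), local))
        label = row.display_name if row and row.display_name else node
        rg.add((iri, RDFS.label, Literal(label)))
        if row:
            for xref in sorted(row.xrefs):
                rg.add((iri, xref_prop, Literal(f"{xref.namespace}:{xref.identifier}")))
    Path(path).write_bytes(rg.serialize(format="turtle", encoding="utf-8"))


def read_turtle_edges(path: str | Path) -> set[Triple]:
    """Recover the edge set from a Turtle file written by :func:`write_turtle`
    (label/xref annotation statements are ignored)."""
    rg = RDFGraph()
    rg.parse(str(path), format="turtle")
    edges: set[Triple] = set()
    annotation = {RDFS.label, NS["xref"]}
    for s, p, o in rg:
        if p in annotation or not isinstance(o, URIRef):
            continue
        subj, obj = _iri_to_endpoint(s), _iri_to_endpoint(o)
        if subj is None or obj is None or not str(p).startswith(str(NS)):
            continue
        edges.add(Triple(subj, str(p)[len(str(NS)):], obj))
    return edges


# --------------------------------------------------------------------------
# cross-reference tables
# --------------------------------------------------------------------------


def write_xref_tables(table: MappingTable, outdir: str | Path, order: Sequence[str] = DEFAULT_ORDER) -> list[Path]:
    """Write one cross-reference TSV per node kind.

    The first header cell is the key ``ID_OREGANO:<n>`` where ``n`` is the
    number of entries in the file; the remaining header cells name the
    sources.  Each data row starts with the entity display name, then the
    global identifier, then the source-local identifiers (``;``-separated
    when one source contributed several).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for kind, fname in XREF_FILE_NAMES.items():
        rows = sorted(table.rows_of_kind(kind), key=lambda r: int(r.oid.local))
        path = outdir / fname
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join([f"ID_OREGANO:{len(rows)}", "OREGANO_ID", *order]) + "\n")
            for row in rows:
                cells = [row.display_name, str(row.oid)]
                cells += [";".join(row.local_ids.get(src, [])) for src in order]
                fh.write("\t".join(cells) + "\n")
        written.append(path)
    for kind, fname in NAME_LIST_FILE_NAMES.items():
        rows = sorted(table.rows_of_kind(kind), key=lambda r: int(r.oid.local))
        path = outdir / fname
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"ID_OREGANO:{len(rows)}\n")
            for row in rows:
                fh.write((row.display_name or str(row.oid)) + "\n")
        written.append(path)
    return written


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


@dataclass
class BuildResult:
    graph: KnowledgeGraph
    table: MappingTable
    extracted: dict[str, int] = field(default_factory=dict)
    filtered_out: dict[str, int] = field(default_factory=dict)
    dropped: Counter = field(default_factory=Counter)


def _augment_disease_xrefs(
    records: list[SourceRecord],
    umls_pivot: list[tuple[str, str, str]],
    orphanet_pivot: list[tuple[str, str, str]],
) -> list[SourceRecord]:
    """Attach pivot-mediated cross-references (UMLS concepts, the OMIM codes
    reachable through them, Orphanet identifiers) to phenotype-source disease
    records."""
    disease_ids = {r.local_id for r in records if r.kind is NodeKind.DISEASE and r.source == "hpo"}
    all_omim = {ident for _, ns, ident in umls_pivot if ns.lower() == "omim"}
    kept_omim = restrict_omim_via_umls(all_omim, disease_ids, umls_pivot)

    extra: dict[str, set] = {d: set() for d in disease_ids}
    by_concept: dict[str, dict[str, set[str]]] = {}
    for concept, ns, ident in umls_pivot:
        by_concept.setdefault(concept, {}).setdefault(ns.lower(), set()).add(ident)
    for concept, maps in by_concept.items():
        for d in maps.get("hpo_disease", set()) & disease_ids:
            extra[d].add(normalize_xref("umls", concept))
            for omim in maps.get("omim", set()) & kept_omim:
                extra[d].add(normalize_xref("omim", omim))
    for orpha, ns, ident in orphanet_pivot:
        if ns.lower() == "hpo_disease" and ident in disease_ids:
            extra[ident].add(normalize_xref("orphanet", orpha))

    out: list[SourceRecord] = []
    for rec in records:
        if rec.source == "hpo" and rec.kind is NodeKind.DISEASE and extra.get(rec.local_id):
            out.append(
                SourceRecord(
                    rec.source,
                    rec.local_id,
                    rec.kind,
                    rec.display_name,
                    frozenset(rec.xrefs) | extra[rec.local_id],
                    rec.attributes,
                )
            )
        else:
            out.append(rec)
    return out


def _strip_class_atc_xrefs(records: list[SourceRecord]) -> list[SourceRecord]:
    """Drop non-substance (shorter than 7 characters) ATC codes from
    pharmacogenomic compound cross-references."""
    out = []
    for rec in records:
        if rec.kind is NodeKind.COMPOUND:
            atc = [x.identifier for x in rec.xrefs if x.namespace == "atc"]
            keep = set(filter_atc_codes(atc))
            xrefs = frozenset(x for x in rec.xrefs if x.namespace != "atc" or x.identifier in keep)
            out.append(
                SourceRecord(rec.source, rec.local_id, rec.kind, rec.display_name, xrefs, rec.attributes)
            )
        else:
            out.append(rec)
    return out


def build_graph(
    manifest: Mapping[str, object],
    order: Sequence[str] = DEFAULT_ORDER,
    registry: Mapping[str, Predicate] | None = None,
    min_overlap: int = 1,
) -> BuildResult:
    """Run the full wrapper -> binder -> manager pipeline over a source suite.

    ``manifest`` maps source names to dump paths (the phenotype source maps
    to ``{"annotations": ..., "ontology": ...}``) and the pivot names
    ``umls``/``orphanet`` to pivot files.
    """
    registry = registry or default_registry()
    result = BuildResult(KnowledgeGraph(), MappingTable(min_overlap=min_overlap))
    table = result.table
    umls_pivot = read_pivot(Path(manifest["umls"])) if "umls" in manifest else []
    orphanet_pivot = read_pivot(Path(manifest["orphanet"])) if "orphanet" in manifest else []

    all_relations: list[RelationRow] = []
    for source in order:
        if source not in manifest:
            continue
        res = extract(manifest[source], source)
        relations, records = res.relations, res.records
        n_raw = len(relations)
        if source == "npass":
            ht = filter_npass_human([r for r in relations if r.predicate == "has_target"])
            relations = ht + [r for r in relations if r.predicate != "has_target"]
        elif source == "pharmgkb":
            relations = filter_pharmgkb_evidence(relations)
            records = _strip_class_atc_xrefs(records)
        elif source == "hpo":
            hp = filter_hpo_links([r for r in relations if r.predicate == "has_phenotype"])
            relations = hp + [r for r in relations if r.predicate != "has_phenotype"]
            records = _augment_disease_xrefs(records, umls_pivot, orphanet_pivot)
        elif source == "uniprot":
            records, relations = filter_uniprot(records, relations, table.known_keys())

        require_match = source == "uniprot"
        bound = skipped = 0
        for rec in records:
            oid, _ = table.resolve(rec, require_match=require_match)
            if oid is None:
                skipped += 1
            else:
                bound += 1
        result.extracted[source] = n_raw
        result.filtered_out[source] = n_raw - len(relations)
        log.info(
            "%s: %d relation rows (%d filtered out), %d records bound, %d skipped",
            source, n_raw, n_raw - len(relations), bound, skipped,
        )
        all_relations.extend(relations)

    triples, dropped = rewrite_triples(all_relations, table, registry)
    result.dropped = dropped
    for t in triples:
        result.graph.add(t)
    log.info("graph: %d triples, %d nodes; dropped %s", len(result.graph), len(result.graph.nodes), dict(dropped))
    return result
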
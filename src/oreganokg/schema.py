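"""Graph schema: node kinds, the predicate vocabulary, identifiers, validation.

The graph is a directed labelled multigraph of (subject, predicate, object)
triples over eleven kinds of typed entities (compounds, targets, genes,
diseases, ATC codes, phenotypes, pathways, effects, activities, indications
and side effects).  The predicate vocabulary is a closed set of 19 labelled
relations, each with a fixed domain (subject kind) and range (object kind);
it is loaded from a plain-text table so the schema is data, not code.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class NodeKind(str, enum.Enum):
    """The eleven entity categories of the graph."""

    COMPOUND = "COMPOUND"
    TARGET = "TARGET"
    GENE = "GENE"
    DISEASE = "DISEASE"
    ATC = "ATC"
    PHENOTYPE = "PHENOTYPE"
    PATHWAY = "PATHWAY"
    EFFECT = "EFFECT"
    ACTIVITY = "ACTIVITY"
    INDICATION = "INDICATION"
    SIDE_EFFECT = "SIDE_EFFECT"

    def __str__(self) -> str:  # render as bare name in IDs
        return self.value


#: Kinds for which global serial identifiers are minted.  ATC codes are
#: self-identifying: the 7-character classification code is both the local
#: and the global identifier, so no serial is ever assigned.
MINTED_KINDS = frozenset(k for k in NodeKind if k is not NodeKind.ATC)


@dataclass(frozen=True, order=True)
class GraphID:
    """A global node identifier, rendered as ``KIND:local``.

    For minted kinds ``local`` is the decimal serial (e.g. ``COMPOUND:10025``);
    for ATC it is the classification code itself (e.g. ``ATC:A10BA02``).
    """

    kind: NodeKind
    local: str

    def render(self, alias: Mapping[NodeKind, str] | None = None) -> str:
        name = (alias or {}).get(self.kind, self.kind.value)
        return f"{name}:{self.local}"

    def __str__(self) -> str:
        return self.render()

    @property
    def serial(self) -> int | None:
        return int(self.local) if self.kind in MINTED_KINDS else None

    @classmethod
    def parse(cls, text: str, alias: Mapping[str, NodeKind] | None = None) -> "GraphID":
        """Parse a rendered identifier; ``alias`` maps alternate kind names
        (e.g. ``PROTEIN`` -> TARGET) back to canonical kinds."""
        head, sep, local = text.partition(":")
        if not sep or not local:
            raise ValueError(f"not a graph identifier: {text!r}")
        if alias and head in alias:
            return cls(alias[head], local)
        try:
            return cls(NodeKind(head), local)
        except ValueError:
            raise ValueError(f"unknown node kind in identifier: {text!r}") from None


@dataclass(frozen=True)
class Predicate:
    label: str
    subject_kind: NodeKind
    object_kind: NodeKind


# Default predicate table: label <TAB> subject kind <TAB> object kind.
# One row per relation in the vocabulary; loadable from a file of the same
# layout via load_predicates().
DEFAULT_PREDICATE_TABLE = """\
has_code\tCOMPOUND\tATC
subclass_of\tATC\tATC
has_target\tCOMPOUND\tTARGET
has_activity\tCOMPOUND\tACTIVITY
decreases_activity\tCOMPOUND\tACTIVITY
increases_activity\tCOMPOUND\tACTIVITY
has_effect\tCOMPOUND\tEFFECT
decreases_effect\tCOMPOUND\tEFFECT
increases_effect\tCOMPOUND\tEFFECT
increases_efficacy\tCOMPOUND\tCOMPOUND
decreases_efficacy\tCOMPOUND\tCOMPOUND
causes_condition\tGENE\tDISEASE
has_phenotype\tDISEASE\tPHENOTYPE
is_affecting\tCOMPOUND\tGENE
is_substance_that_treats\tCOMPOUND\tDISEASE
acts_within\tGENE\tPATHWAY
has_indication\tCOMPOUND\tINDICATION
has_side_effect\tCOMPOUND\tSIDE_EFFECT
gene_product_of\tTARGET\tGENE
"""


def load_predicates(source: str | Path) -> dict[str, Predicate]:
    """Load a predicate registry from a TSV table (text or path).

    Each non-empty, non-comment line is ``label<TAB>subject_kind<TAB>object_kind``.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    else:
        text = source
        p = Path(source)
        try:
            if "\t" not in source and p.is_file():
                text = p.read_text(encoding="utf-8")
        except OSError:
            pass
    registry: dict[str, Predicate] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"predicate table line {lineno}: expected 3 columns")
        label, skind, okind = (p.strip() for p in parts)
        if label in registry:
            raise ValueError(f"duplicate predicate label {label!r}")
        registry[label] = Predicate(label, NodeKind(skind), NodeKind(okind))
    return registry


def default_registry() -> dict[str, Predicate]:
    return load_predicates(DEFAULT_PREDICATE_TABLE)


@dataclass(frozen=True)
class Triple:
    """A directed (subject, predicate, object) edge over rendered identifiers."""

    subject: str
    predicate: str
    object: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


def _endpoint_kind(endpoint: str) -> NodeKind | None:
    head = endpoint.partition(":")[0]
    try:
        return NodeKind(head)
    except ValueError:
        return None


def validate_triple(t: Triple, registry: Mapping[str, Predicate]) -> list[str]:
    """Return schema violations for one triple (empty list = valid).

    An unknown predicate or a domain/range mismatch is reported as a
    violation entry, never raised.
    """
    violations: list[str] = []
    pred = registry.get(t.predicate)
    if pred is None:
        return [f"unknown predicate: {t.predicate!r}"]
    skind = _endpoint_kind(t.subject)
    okind = _endpoint_kind(t.object)
    if skind is not pred.subject_kind:
        violations.append(
            f"domain violation: {t.predicate} expects subject kind "
            f"{pred.subject_kind.value}, got {t.subject!r}"
        )
    if okind is not pred.object_kind:
        violations.append(
            f"range violation: {t.predicate} expects object kind "
            f"{pred.object_kind.value}, got {t.object!r}"
        )
    return violations


class KnowledgeGraph:
    """A deduplicated set of triples plus a node-kind index.

    Insertion order of first occurrence is preserved; every endpoint of every
    triple is registered in the node index.
    """

    def __init__(self) -> None:
        self._triples: dict[Triple, None] = {}
        self.nodes: dict[str, NodeKind] = {}

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __iter__(self):
        return iter(self._triples)

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples)

    def add_node(self, node: str, kind: NodeKind | None = None) -> None:
        if kind is None:
            kind = _endpoint_kind(node)
            if kind is None:
                raise ValueError(f"cannot infer node kind for {node!r}")
        existing = self.nodes.get(node)
        if existing is not None and existing is not kind:
            raise ValueError(f"node {node!r} already registered as {existing.value}")
        self.nodes[node] = kind

    def add(self, t: Triple) -> bool:
        """Insert a triple; returns False if it was already present."""
        if t in self._triples:
            return False
        self.add_node(t.subject)
        self.add_node(t.object)
        self._triples[t] = None
        return True

    @classmethod
    def from_triples(cls, triples: Iterable[Triple]) -> "KnowledgeGraph":
        g = cls()
        for t in triples:
            g.add(t)
        return g

    def entities(self) -> list[str]:
        return sorted(self.nodes)

    def relations(self) -> list[str]:
        return sorted({t.predicate for t in self._triples})


@dataclass
class GraphStats:
    node_counts: "pd.Series"
    predicate_counts: "pd.Series"
    n_nodes: int = field(init=False)
    n_triples: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_nodes = int(self.node_counts.sum())
        self.n_triples = int(self.predicate_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [("node", k, int(v)) for k, v in self.node_counts.items()]
        rows += [("predicate", k, int(v)) for k, v in self.predicate_counts.items()]
        return pd.DataFrame(rows, columns=["level", "name", "count"])


def graph_stats(g: KnowledgeGraph) -> GraphStats:
    """Occurrence counts per node kind and per predicate."""
    node_counter = Counter(kind.value for kind in g.nodes.values())
    pred_counter = Counter(t.predicate for t in g)
    kinds = [k.value for k in NodeKind]
    node_counts = pd.Series({k: node_counter.get(k, 0) for k in kinds}, dtype=int)
    predicate_counts = pd.Series(dict(sorted(pred_counter.items())), dtype=int)
    return GraphStats(node_counts, predicate_counts)
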
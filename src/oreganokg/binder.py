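"""Entity fusion by cross-reference overlap.

Source-local records are resolved one at a time against a global mapping
table.  A record merges into the existing row of the same node kind with
which it shares the most normalized cross-references (ties broken toward the
oldest row, i.e. the lowest serial); a record sharing no cross-reference with
any row mints a fresh identifier.  Fusion is strictly cross-reference based:
display names never participate in matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .schema import MINTED_KINDS, GraphID, NodeKind

log = logging.getLogger(__name__)


class XRefKey(NamedTuple):
    """A normalized (namespace, identifier) cross-reference key."""

    namespace: str
    identifier: str


def normalize_xref(namespace: str, identifier: str) -> XRefKey:
    """Deterministic normalization: trim, case-fold the namespace, and strip a
    redundant ``namespace:`` prefix from the identifier if present."""
    ns = namespace.strip().lower()
    ident = identifier.strip()
    prefix = ns + ":"
    if ident.lower().startswith(prefix):
        ident = ident[len(prefix):]
    return XRefKey(ns, ident)


@dataclass(frozen=True)
class SourceRecord:
    """One source-local entity: its identifier, kind, name, cross-references
    and free-form attributes (organism, evidence level, ...)."""

    source: str
    local_id: str
    kind: NodeKind
    display_name: str = ""
    xrefs: frozenset[XRefKey] = frozenset()
    attributes: Mapping[str, str] = field(default_factory=dict)

    def normalized_xrefs(self) -> frozenset[XRefKey]:
        return frozenset(normalize_xref(ns, ident) for ns, ident in self.xrefs)


@dataclass
class Row:
    oid: GraphID
    kind: NodeKind
    display_name: str
    local_ids: dict[str, list[str]]  # source -> local IDs (several allowed)
    xrefs: set[XRefKey]


class MappingTable:
    """The global ledger of fused nodes: one row per node, one OREGANO-style
    identifier per row, per-kind serial counters that are never reused."""

    def __init__(self, min_overlap: int = 1) -> None:
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        self.min_overlap = min_overlap
        self.rows: dict[GraphID, Row] = {}
        self._counters: dict[NodeKind, int] = {k: 0 for k in MINTED_KINDS}
        # (kind, xref) -> GraphID; a key never maps to two rows of one kind
        self._xref_index: dict[tuple[NodeKind, XRefKey], GraphID] = {}
        self._xref_kinds: dict[XRefKey, set[NodeKind]] = {}
        self._local_index: dict[tuple[str, str], GraphID] = {}
        self.conflicts: list[str] = []
        self.bridges: list[str] = []

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.rows)

    def lookup_local(self, source: str, local_id: str) -> GraphID | None:
        return self._local_index.get((source, local_id))

    def lookup_xref(self, kind: NodeKind, xref: XRefKey) -> GraphID | None:
        return self._xref_index.get((kind, xref))

    def known_keys(self) -> set[XRefKey]:
        """All cross-reference keys currently attached to any row."""
        return {x for (_, x) in self._xref_index}

    def rows_of_kind(self, kind: NodeKind) -> list[Row]:
        return [r for r in self.rows.values() if r.kind is kind]

    # -- resolution ------------------------------------------------------

    def candidate_matches(
        self, rec: SourceRecord, kind: NodeKind | None = None
    ) -> list[tuple[GraphID, int]]:
        """Existing rows of the record's kind sharing >= 1 cross-reference,
        as (identifier, overlap count), sorted by overlap descending then by
        serial ascending (oldest row first)."""
        kind = kind or rec.kind
        overlaps: dict[GraphID, int] = {}
        for xref in rec.normalized_xrefs():
            oid = self._xref_index.get((kind, xref))
            if oid is not None:
                overlaps[oid] = overlaps.get(oid, 0) + 1
        return sorted(overlaps.items(), key=lambda kv: (-kv[1], _oid_sort_key(kv[0])))

    def _mint(self, kind: NodeKind, local_hint: str) -> GraphID:
        if kind in MINTED_KINDS:
            serial = self._counters[kind]
            self._counters[kind] = serial + 1
            return GraphID(kind, str(serial))
        # ATC-like self-identifying kinds: the code is the identifier
        return GraphID(kind, local_hint)

    def _attach(self, oid: GraphID, rec: SourceRecord) -> None:
        row = self.rows[oid]
        ids = row.local_ids.setdefault(rec.source, [])
        if rec.local_id not in ids:
            ids.append(rec.local_id)
        self._local_index.setdefault((rec.source, rec.local_id), oid)
        for xref in rec.normalized_xrefs():
            kinds = self._xref_kinds.setdefault(xref, set())
            if kinds and row.kind not in kinds:
                # same key seen under another kind: matching stays per-kind,
                # so this record keeps its own row; record the conflict
                self.conflicts.append(
                    f"xref {xref} spans kinds {sorted(k.value for k in kinds)} "
                    f"and {row.kind.value} ({rec.source}:{rec.local_id})"
                )
                log.warning("cross-kind xref collision: %s", self.conflicts[-1])
            kinds.add(row.kind)
            key = (row.kind, xref)
            owner = self._xref_index.get(key)
            if owner is None:
                self._xref_index[key] = oid
                row.xrefs.add(xref)
            elif owner != oid:
                # A later record bridges two existing rows; fusion stays
                # greedy-sequential, so the event is logged, not applied.
                self.bridges.append(
                    f"{rec.source}:{rec.local_id} bridges {owner} and {oid} via {xref}"
                )
        if not row.display_name and rec.display_name:
            row.display_name = rec.display_name

    def resolve(self, rec: SourceRecord, require_match: bool = False) -> tuple[GraphID | None, bool]:
        """Resolve one record: merge into the best candidate row, else mint.

        Returns ``(identifier, merged)``.  With ``require_match=True`` a
        record with no candidate is skipped (returns ``(None, False)``)
        instead of minting — used for sources restricted to nodes already in
        the graph.
        """
        existing = self._local_index.get((rec.source, rec.local_id))
        if existing is not None:
            self._attach(existing, rec)
            return existing, True
        candidates = [
            (oid, n) for oid, n in self.candidate_matches(rec) if n >= self.min_overlap
        ]
        if candidates:
            oid = candidates[0][0]
            self._attach(oid, rec)
            return oid, True
        if require_match:
            return None, False
        if rec.kind not in MINTED_KINDS:
            # self-identifying kind: reuse the code if already present
            oid = GraphID(rec.kind, rec.local_id)
            merged = oid in self.rows
            if not merged:
                self.rows[oid] = Row(oid, rec.kind, rec.display_name, {}, set())
            self._attach(oid, rec)
            return oid, merged
        oid = self._mint(rec.kind, rec.local_id)
        self.rows[oid] = Row(oid, rec.kind, rec.display_name, {}, set())
        self._attach(oid, rec)
        return oid, False

    def partition(self) -> dict[GraphID, set[tuple[str, str]]]:
        """The induced partition of (source, local_id) keys into rows."""
        out: dict[GraphID, set[tuple[str, str]]] = {}
        for (source, local_id), oid in self._local_index.items():
            out.setdefault(oid, set()).add((source, local_id))
        return out


def _oid_sort_key(oid: GraphID) -> tuple[int, int, str]:
    """Candidate tie-break ordering: serials compare numerically (oldest row
    first); self-identifying codes sort lexically after all serials."""
    s = oid.serial
    return (0, s, "") if s is not None else (1, 0, oid.local)


def candidate_matches(
    rec: SourceRecord, table: MappingTable, kind: NodeKind | None = None
) -> list[tuple[GraphID, int]]:
    return table.candidate_matches(rec, kind)


def resolve(
    rec: SourceRecord, table: MappingTable, require_match: bool = False
) -> tuple[GraphID | None, bool]:
    return table.resolve(rec, require_match=require_match)


def build_mapping_table(
    xref_streams: Sequence[Iterable[SourceRecord]],
    min_overlap: int = 1,
    require_match_sources: frozenset[str] | set[str] = frozenset(),
) -> MappingTable:
    """Fuse ordered record streams into a mapping table.

    Streams are processed sequentially, records within a stream in input
    order, so the result is deterministic for identical input.
    """
    table = MappingTable(min_overlap=min_overlap)
    for stream in xref_streams:
        for rec in stream:
            table.resolve(rec, require_match=rec.source in require_match_sources)
    return table
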
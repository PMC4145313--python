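"""jplace parsing and conversion of placements into root-to-query branch lengths."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .tree_model import ReferenceTree, TreeError, read_newick

__all__ = [
    "PlacementRecord",
    "PlacementSet",
    "PlacementError",
    "read_jplace",
    "best_placement",
    "query_tip_length",
]

REQUIRED_FIELDS = ("edge_num", "distal_length", "pendant_length", "like_weight_ratio")


class PlacementError(ValueError):
    """Raised for malformed or inconsistent placement data."""


@dataclass(frozen=True)
class PlacementRecord:
    """One candidate attachment of a marker fragment to the reference tree.

    ``offset`` is always stored in the internal proximal convention: distance
    from the root-facing (proximal) node of the edge toward the distal node.
    """

    query_id: str
    marker_id: str
    edge_num: int
    offset: float
    pendant: float
    weight: float
    phylum: Optional[str] = None

    def __post_init__(self):
        if self.pendant < 0:
            raise PlacementError(f"negative pendant length for {self.query_id}")
        if not (0.0 <= self.weight <= 1.0 + 1e-6):
            raise PlacementError(f"weight out of [0,1] for {self.query_id}")


@dataclass
class PlacementSet:
    sample_id: str
    tree_checksum: str
    records: List[PlacementRecord] = field(default_factory=list)

    def queries(self) -> Dict[str, List[PlacementRecord]]:
        out: Dict[str, List[PlacementRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.query_id, []).append(rec)
        return out

    def best_per_query(self) -> List[PlacementRecord]:
        return [best_placement(recs) for recs in self.queries().values()]


def read_jplace(
    doc,
    tree: ReferenceTree,
    sample_id: str = "",
    offset_from: str = "proximal",
    manifest: Optional[Dict[str, Dict[str, str]]] = None,
) -> PlacementSet:
    """Parse a jplace (v1-v3) document against a loaded reference tree.

    Parameters
    ----------
    doc : str | dict
        jplace JSON text or an already-decoded document.
    tree : ReferenceTree
        Tree whose edge numbers the placements refer to.
    offset_from : {"proximal", "distal"}
        Producer dialect for ``distal_length``: measured from the proximal
        (root-facing, the jplace default here) or the distal node of the
        edge.  Internally everything is normalized to proximal offsets.
    manifest : optional
        ``query_id -> {"marker_id": ..., "phylum": ...}`` side table; values
        override anything encoded in the query name.
    """
    if offset_from not in ("proximal", "distal"):
        raise PlacementError("offset_from must be 'proximal' or 'distal'")
    if isinstance(doc, (str, bytes)):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise PlacementError(f"malformed jplace JSON: {exc}") from exc
    if "placements" not in doc or "fields" not in doc:
        raise PlacementError("not a jplace document (missing placements/fields)")

    fields = [f.replace("edge_number", "edge_num") for f in doc["fields"]]
    missing = [f for f in REQUIRED_FIELDS if f not in fields]
    if missing:
        raise PlacementError(
            f"jplace fields missing {missing}; found {doc['fields']}"
        )
    idx = {f: i for i, f in enumerate(fields)}

    if "tree" in doc:
        embedded = read_newick(doc["tree"])
        if set(embedded.edge_nums.values()) != set(tree.edge_nums.values()):
            raise PlacementError(
                "embedded jplace tree edge numbers do not match reference tree"
            )

    edge_map = tree.edge_by_number()
    records: List[PlacementRecord] = []
    for pq in doc["placements"]:
        names = pq.get("n") or [nm[0] for nm in pq.get("nm", [])]
        if not names:
            raise PlacementError("placement without query name")
        for name in names:
            meta = (manifest or {}).get(name, {})
            marker = meta.get("marker_id", _marker_from_name(name))
            phylum = meta.get("phylum")
            for p in pq["p"]:
                edge_num = int(p[idx["edge_num"]])
                if edge_num not in edge_map:
                    raise PlacementError(
                        f"query {name}: edge {edge_num} absent from tree"
                    )
                child = edge_map[edge_num]
                edge_len = tree.lengths[child]
                off = float(p[idx["distal_length"]])
                if offset_from == "distal":
                    off = edge_len - off
                if off < -1e-9 or off > edge_len + 1e-9:
                    raise PlacementError(
                        f"query {name}: offset {off:.6g} outside edge "
                        f"{edge_num} (length {edge_len:.6g})"
                    )
                records.append(
                    PlacementRecord(
                        query_id=name,
                        marker_id=marker,
                        edge_num=edge_num,
                        offset=min(max(off, 0.0), edge_len),
                        pendant=float(p[idx["pendant_length"]]),
                        weight=float(p[idx["like_weight_ratio"]]),
                        phylum=phylum,
                    )
                )
    ps = PlacementSet(sample_id=sample_id, tree_checksum=tree.checksum(), records=records)
    for query, recs in ps.queries().items():
        total = sum(r.weight for r in recs)
        if total > 1.0 + 1e-6:
            raise PlacementError(
                f"query {query}: like-weight ratios sum to {total:.6g} > 1"
            )
    return ps


def _marker_from_name(name: str) -> str:
    # convention: query ids like "<marker>|<fragment>"; fall back to the name
    return name.split("|", 1)[0] if "|" in name else name


def best_placement(records: Sequence[PlacementRecord]) -> PlacementRecord:
    """Highest like-weight-ratio record; ties go to the smaller edge number."""
    if not records:
        raise PlacementError("no placement records for query")
    return min(records, key=lambda r: (-r.weight, r.edge_num))


def query_tip_length(tree: ReferenceTree, rec: PlacementRecord) -> float:
    """Root-to-query branch length implied by a placement.

    distance(root -> proximal node of the edge) + offset + pendant length.
    """
    if not tree.rooted:
        raise TreeError("tree is unrooted; apply midpoint_root first")
    edge_map = tree.edge_by_number()
    if rec.edge_num not in edge_map:
        raise PlacementError(f"edge {rec.edge_num} absent from tree")
    child = edge_map[rec.edge_num]
    edge_len = tree.lengths[child]
    if rec.offset > edge_len + 1e-9:
        raise PlacementError(
            f"offset {rec.offset:.6g} exceeds edge length {edge_len:.6g}"
        )
    depth_child = tree.depths()[child]
    return (depth_child - edge_len) + rec.offset + rec.pendant


def weighted_tip_length(tree: ReferenceTree, records: Sequence[PlacementRecord]) -> float:
    """Like-weight-averaged tip length over a query's candidate placements.

    Sensitivity-analysis alternative to :func:`best_placement`.
    """
    if not records:
        raise PlacementError("no placement records for query")
    total = sum(r.weight for r in records)
    if total <= 0:
        raise PlacementError("all placement weights are zero")
    return sum(r.weight * query_tip_length(tree, r) for r in records) / total
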
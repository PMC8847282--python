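"""Greedy centroid-based OTU clustering at a similarity threshold.

Emulates the classic greedy strategy of centroid clustering tools: process
sequences in a deterministic order (length descending, ties broken by id),
compare each query to all existing centroids by global-alignment identity,
join the best-matching centroid at or above the threshold, otherwise found a
new centroid. Centroids are static seeds; there is no re-election.
"""

from __future__ import annotations

from .distances import IdentityScoring, pairwise_identity
from .partition import Partition
from .seqio import SequenceRecord

ORDER_POLICIES = ("length_desc", "input")


def cluster_order(records: list[SequenceRecord], order_policy: str = "length_desc") -> list[SequenceRecord]:
    """Deterministic processing order for greedy clustering."""
    if order_policy == "length_desc":
        return sorted(records, key=lambda r: (-len(r.residues), r.id))
    if order_policy == "input":
        return list(records)
    raise ValueError(f"unknown order policy {order_policy!r}")


def greedy_cluster(records: list[SequenceRecord], threshold: float,
                   order_policy: str = "length_desc",
                   scoring: IdentityScoring | None = None,
                   method_id: str | None = None) -> Partition:
    """Cluster sequences greedily at a pairwise-identity threshold.

    Each query joins the centroid of *highest* identity provided that identity
    is >= threshold (ties go to the earliest-created centroid); otherwise it
    founds a new cluster. ``threshold`` in (0, 1]; 0 is allowed for degenerate
    testing (everything joins the first centroid).
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    method_id = method_id or f"OTU-{threshold:g}"
    ordered = cluster_order(records, order_policy)
    centroids: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    members: dict[str, str] = {}  # sequence id -> centroid id
    for rec in ordered:
        best_idx = -1
        best_identity = -1.0
        for idx, cen in enumerate(centroids):
            identity = pairwise_identity(rec.residues, cen.residues, scoring)
            if identity > best_identity:
                best_identity = identity
                best_idx = idx
        if best_idx >= 0 and best_identity >= threshold:
            members[rec.id] = centroids[best_idx].id
        else:
            centroids.append(rec)
            members[rec.id] = rec.id
    # Stable cluster labels in order of centroid creation.
    labels = {cen.id: f"{method_id}_{i}" for i, cen in enumerate(centroids, start=1)}
    assignment = {seq_id: labels[cen_id] for seq_id, cen_id in members.items()}
    return Partition(method_id, assignment,
                     metadata={"threshold": threshold,
                               "order_policy": order_policy,
                               "centroids": [c.id for c in centroids]})
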
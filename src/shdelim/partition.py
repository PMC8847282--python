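"""Species-hypothesis partitions: one method's assignment of sequences to clusters.

A :class:`Partition` is the common currency of every delimitation method in this
package: greedy OTU clustering, ASAP, GMYC, PTP, and externally supplied
species-hypothesis (SH) tables all reduce to a map ``sequence_id -> cluster_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Partition:
    """Assignment of every sequence to exactly one species-hypothesis cluster.

    Parameters
    ----------
    method_id:
        Identifier of the method that produced the partition (e.g. ``"OTU-97"``).
    assignment:
        Map from sequence id to cluster id. Every sequence appears exactly once.
    metadata:
        Free-form per-run annotations (seeds, thresholds, centroid ids, support).
    """

    method_id: str
    assignment: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("Partition must assign at least one sequence")

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def clusters(self) -> dict[str, frozenset[str]]:
        """Derived map cluster_id -> member set. No cluster is empty by construction."""
        out: dict[str, set[str]] = {}
        for seq_id, cl in self.assignment.items():
            out.setdefault(cl, set()).add(seq_id)
        return {cl: frozenset(members) for cl, members in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def cluster_sets(self) -> set[frozenset[str]]:
        """The partition as a set of member sets (label-free)."""
        return set(self.clusters.values())

    def equivalent(self, other: "Partition") -> bool:
        """True if both partitions induce the same grouping, ignoring cluster labels."""
        return self.cluster_sets() == other.cluster_sets()

    def renamed(self, method_id: str) -> "Partition":
        return Partition(method_id, dict(self.assignment), dict(self.metadata))


def from_cluster_sets(method_id: str, clusters, prefix: str | None = None,
                      metadata: dict | None = None) -> Partition:
    """Build a Partition from an iterable of member-id collections.

    Cluster labels are ``<prefix>_1 .. <prefix>_k`` in order of each cluster's
    lexicographically smallest member, so labels are deterministic.
    """
    prefix = prefix or method_id
    sets = [sorted(c) for c in clusters]
    if any(not s for s in sets):
        raise ValueError("empty cluster in partition")
    sets.sort(key=lambda s: s[0])
    assignment: dict[str, str] = {}
    for i, members in enumerate(sets, start=1):
        label = f"{prefix}_{i}"
        for m in members:
            if m in assignment:
                raise ValueError(f"sequence {m!r} assigned to more than one cluster")
            assignment[m] = label
    return Partition(method_id, assignment, metadata or {})


def write_partition_tsv(partitions: list[Partition], path) -> None:
    """Write one or more partitions over the same id set as a TSV table.

    Header: ``sequence_id<TAB><method1><TAB>...``; rows sorted by sequence id.
    """
    if not partitions:
        raise ValueError("no partitions to write")
    ids = sorted(partitions[0].assignment)
    for p in partitions[1:]:
        if sorted(p.assignment) != ids:
            raise ValueError(f"partition {p.method_id!r} covers a different id set")
    with open(path, "w") as fh:
        fh.write("sequence_id\t" + "\t".join(p.method_id for p in partitions) + "\n")
        for seq_id in ids:
            fh.write(seq_id + "\t" + "\t".join(p.assignment[seq_id] for p in partitions) + "\n")
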
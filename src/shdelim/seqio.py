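"""Sequence, alignment and SH-table input/output, plus alignment site statistics.

FASTA parsing is delegated to Biopython; this module adds the package's domain
types (:class:`SequenceRecord`, :class:`Alignment`, :class:`SiteStats`), the
column-region bookkeeping used for partitioned barcode matrices (ITS1/5.8S/ITS2),
and readers for externally computed species-hypothesis tables.

Coordinates are 0-based, half-open everywhere; :func:`region_from_one_based`
converts the 1-based inclusive intervals that printed tables use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .partition import Partition

# IUPAC nucleotide alphabet plus gap.  'U' is mapped to 'T' on read.
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUITY = frozenset("RYSWKMBDHVN")
ALPHABET = UNAMBIGUOUS | AMBIGUITY | {"-"}


@dataclass
class SequenceRecord:
    """A single barcode sequence: unique id, free-text label, IUPAC residues."""

    id: str
    label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length sequence records with an optional named column-region map.

    ``region_map`` maps region names (e.g. ``"ITS1"``) to 0-based half-open
    column intervals ``(start, end)``; intervals must be non-overlapping and
    lie within the alignment.
    """

    records: list[SequenceRecord]
    region_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        length = len(self.records[0])
        ragged = [r.id for r in self.records if len(r) != length]
        if ragged:
            raise ValueError(f"unequal sequence lengths for ids: {ragged}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        _validate_region_map(self.region_map, length)

    @property
    def columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def region(self, name: str) -> "Alignment":
        """Sub-alignment of one named region."""
        start, end = self.region_map[name]
        recs = [SequenceRecord(r.id, r.label, r.residues[start:end]) for r in self.records]
        return Alignment(recs, {name: (0, end - start)})


@dataclass
class SiteStats:
    """Per-alignment site counts (variable, parsimony-informative, constant)."""

    length: int
    variable_sites: int
    parsimony_informative: int
    constant_sites: int

    def __post_init__(self) -> None:
        if not (self.parsimony_informative <= self.variable_sites <= self.length):
            raise ValueError("inconsistent site statistics")
        if self.constant_sites + self.variable_sites > self.length:
            raise ValueError("constant + variable sites exceed alignment length")


def _validate_region_map(region_map: dict[str, tuple[int, int]], length: int) -> None:
    taken: list[tuple[int, int]] = []
    for name, (start, end) in region_map.items():
        if not (0 <= start < end <= length):
            raise ValueError(
                f"region {name!r} [{start}, {end}) outside alignment of {length} columns")
        for s, e in taken:
            if start < e and s < end:
                raise ValueError(f"region {name!r} overlaps another region")
        taken.append((start, end))


def region_from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval (as printed in tables) to 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval {start}-{end}")
    return start - 1, end


def _normalise(residues: str) -> str:
    return residues.upper().replace("U", "T")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The header line is split at the first whitespace: first token -> id, the
    remainder -> label. Residues are upper-cased and 'U' is mapped to 'T'.
    Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        label = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, label, _normalise(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description=r.label) for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path, region_map: dict[str, tuple[int, int]] | None = None) -> Alignment:
    """Read an aligned FASTA file; all sequences must have equal length."""
    return Alignment(read_fasta(path), dict(region_map or {}))


def read_region_map(path) -> dict[str, tuple[int, int]]:
    """Load a region map from JSON: ``{"ITS1": [0, 162], ...}`` (0-based half-open)."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: (int(iv[0]), int(iv[1])) for name, iv in raw.items()}


def site_stats(alignment: Alignment, treat_ambiguous: str = "ignore") -> SiteStats:
    """Count variable, parsimony-informative and constant columns.

    A column is *variable* if it shows >= 2 distinct counted states, and
    *parsimony-informative* if >= 2 states each occur in >= 2 sequences.

    treat_ambiguous:
        ``"ignore"`` (default) — ambiguity codes, 'N' and '-' are excluded when
        classifying a column; ``"gap_as_state"`` — '-' counts as a fifth state
        (ambiguity codes and 'N' are still excluded).
    """
    if treat_ambiguous not in ("ignore", "gap_as_state"):
        raise ValueError(f"unknown treat_ambiguous policy {treat_ambiguous!r}")
    counted = set(UNAMBIGUOUS) | ({"-"} if treat_ambiguous == "gap_as_state" else set())
    variable = informative = constant = 0
    cols = zip(*(r.residues for r in alignment.records))
    for col in cols:
        counts: dict[str, int] = {}
        for ch in col:
            if ch in counted:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                informative += 1
        elif len(counts) == 1:
            constant += 1
    return SiteStats(alignment.columns, variable, informative, constant)


def read_partition_table(path, known_ids: set[str] | None = None) -> list[Partition]:
    """Read externally computed SH assignments from a TSV table.

    Expected header: ``sequence_id<TAB><method1><TAB>...``. Returns one
    Partition per method column. A missing assignment is an error; ids absent
    from ``known_ids`` (when given) raise a warning but are kept.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty partition table {path}")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "sequence_id":
        raise ValueError(
            f"partition table {path} must start with a 'sequence_id' header column")
    methods = header[1:]
    assignments: list[dict[str, str]] = [{} for _ in methods]
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"row {fields[0]!r} has {len(fields)} fields, expected {len(header)}")
        seq_id = fields[0]
        if known_ids is not None and seq_id not in known_ids:
            warnings.warn(f"partition table id {seq_id!r} not in dataset", stacklevel=2)
        for i, code in enumerate(fields[1:]):
            if not code:
                raise ValueError(f"missing assignment for id {seq_id!r}, method {methods[i]!r}")
            if seq_id in assignments[i]:
                raise ValueError(f"id {seq_id!r} assigned twice under method {methods[i]!r}")
            assignments[i][seq_id] = code
    return [Partition(m, a) for m, a in zip(methods, assignments)]
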
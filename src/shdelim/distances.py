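"""Pairwise distances and identities for barcode sequences.

Two distance models are exposed: raw p-distance (fraction of differing
compared sites) and its Jukes–Cantor (JC69) correction
``d = -(3/4) ln(1 - 4p/3)``, the substitution model used for the hierarchical
(ASAP-style) partitioning. Gapped/ambiguous sites are excluded pairwise by
default. For threshold-based OTU clustering of *unaligned* sequences,
:func:`pairwise_identity` performs a global pairwise alignment (Biopython's
``PairwiseAligner``) and scores identity over non-terminal-gap columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align
from skbio import DistanceMatrix

from .seqio import Alignment, UNAMBIGUOUS

GAP_POLICIES = ("pairwise", "complete")


@dataclass(frozen=True)
class IdentityScoring:
    """Alignment scoring for identity computation (penalties are positive)."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 1.0


def _comparable(a: str, b: str) -> bool:
    return a in UNAMBIGUOUS and b in UNAMBIGUOUS


def p_distance(a: str, b: str, gap_policy: str = "pairwise") -> float:
    """Fraction of mismatches over compared sites of two equal-length strings.

    Under ``pairwise`` deletion a site is compared iff both residues are
    unambiguous bases; ``complete`` deletion additionally requires the call
    site to pre-mask columns (handled by :func:`pairwise_matrix`).
    """
    if len(a) != len(b):
        raise ValueError("p_distance requires equal-length aligned sequences")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    compared = mismatches = 0
    for x, y in zip(a, b):
        if _comparable(x, y):
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return mismatches / compared


def jc69(p: float) -> float:
    """Jukes–Cantor distance for an observed proportion of differing sites.

    Valid for 0 <= p < 0.75; at p >= 0.75 the correction diverges (saturation)
    and an error is raised rather than capping silently.
    """
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        raise ValueError(f"p = {p} is at or beyond JC69 saturation (p >= 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _encode(alignment: Alignment) -> np.ndarray:
    """Integer-encode an alignment: A,C,G,T -> 0..3, everything else -> -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    rows = [lut[np.frombuffer(r.residues.encode(), dtype=np.uint8)]
            for r in alignment.records]
    return np.vstack(rows)


def pairwise_matrix(alignment: Alignment, model: str = "jc69",
                    gap_policy: str = "pairwise") -> DistanceMatrix:
    """Full symmetric distance matrix for an alignment.

    model: ``"p"`` or ``"jc69"``. Under ``complete`` deletion, columns with any
    non-ACGT residue are removed before any pair is compared.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown distance model {model!r}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    enc = _encode(alignment)
    if gap_policy == "complete":
        keep = (enc >= 0).all(axis=0)
        enc = enc[:, keep]
    n = len(alignment.records)
    ids = alignment.ids
    d = np.zeros((n, n))
    valid = enc >= 0
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
        p = int((enc[i][both] != enc[j][both]).sum()) / compared
        d[i, j] = d[j, i] = jc69(p) if model == "jc69" else p
    return DistanceMatrix(d, ids)


def _aligner(scoring: IdentityScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def pairwise_identity(a: str, b: str, scoring: IdentityScoring | None = None) -> float:
    """Global-alignment identity of two unaligned sequences in [0, 1].

    Identity = matching columns / alignment columns, where columns consisting
    of a terminal gap are excluded; internal gap columns count against
    identity. With the default scoring this approximates the accept-best
    behaviour of greedy centroid clustering tools.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    scoring = scoring or IdentityScoring()
    alignment = _aligner(scoring).align(a, b)[0]
    ga, gb = _gapped_rows(alignment)
    ncol = len(ga)
    # Terminal-gap columns: gap columns contiguous with either alignment end.
    start = 0
    while start < ncol and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = ncol
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    compared = end - start
    if compared == 0:
        return 0.0
    matches = sum(1 for k in range(start, end) if ga[k] == gb[k] and ga[k] != "-")
    return matches / compared


def _gapped_rows(alignment) -> tuple[str, str]:
    """Gapped target/query strings from a Bio.Align alignment object."""
    coords = alignment.coordinates
    a, b = alignment.sequences
    ga: list[str] = []
    gb: list[str] = []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:
            ga.append(a[a0:a1])
            gb.append(b[b0:b1])
        elif a1 > a0:
            ga.append(a[a0:a1])
            gb.append("-" * (a1 - a0))
        else:
            ga.append("-" * (b1 - b0))
            gb.append(b[b0:b1])
    return "".join(ga), "".join(gb)


def write_phylip(dmat: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{dmat.shape[0]}\n")
        for i, name in enumerate(dmat.ids):
            row = " ".join(f"{x:.6f}" for x in dmat.data[i])
            fh.write(f"{name:<12s}{row}\n")


def write_long_tsv(dmat: DistanceMatrix, path) -> None:
    """Write the upper triangle as long-format TSV: id_a, id_b, distance."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tdistance\n")
        ids = list(dmat.ids)
        for i, j in combinations(range(len(ids)), 2):
            fh.write(f"{ids[i]}\t{ids[j]}\t{dmat.data[i, j]:.8f}\n")
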
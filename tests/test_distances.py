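import math

import numpy as np
import pytest

from shdelim import distances
from shdelim.distances import (IdentityScoring, jc69, p_distance, pairwise_identity,
                               pairwise_matrix)
from shdelim.seqio import Alignment, SequenceRecord


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGA", 0.25),
        ("AC-T", "ACGT", 0.0),     # pairwise deletion: 3 compared sites, 0 mismatches
        ("AAAA", "TTTT", 1.0),
        ("ACNT", "ACGT", 0.0),     # ambiguous site excluded
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("--NN", "AC--")

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")


class TestJC69:
    def test_zero(self):
        assert jc69(0.0) == 0.0

    def test_closed_form_at_p01(self):
        # -(3/4) ln(1 - 4*0.1/3) evaluated by hand to 6 d.p.
        assert round(jc69(0.1), 6) == 0.107326

    def test_saturation_is_error(self):
        with pytest.raises(ValueError, match="saturation"):
            jc69(0.75)

    def test_monotone_and_dominates_p(self):
        grid = np.linspace(0.0, 0.74, 200)
        vals = [jc69(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v >= p for v, p in zip(vals, grid))


class TestPairwiseMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = Alignment([SequenceRecord(f"s{i}", "", "ACGTACGT") for i in range(4)])
        dm = pairwise_matrix(aln)
        assert np.allclose(dm.data, 0.0)

    def test_matches_per_pair_calls(self):
        recs = [SequenceRecord("a", "", "ACGTACGTAA"),
                SequenceRecord("b", "", "ACGTACTTAA"),
                SequenceRecord("c", "", "ACCTACTTAT")]
        aln = Alignment(recs)
        dm = pairwise_matrix(aln, model="jc69")
        for i, ri in enumerate(recs):
            for j, rj in enumerate(recs):
                if i != j:
                    expected = jc69(p_distance(ri.residues, rj.residues))
                    assert dm.data[i, j] == pytest.approx(expected)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        recs = [SequenceRecord(f"s{i}", "", "".join(rng.choice(list("ACGT"), 30)))
                for i in range(5)]
        dm = pairwise_matrix(Alignment(recs), model="p")
        perm = [3, 1, 4, 0, 2]
        dm2 = pairwise_matrix(Alignment([recs[i] for i in perm]), model="p")
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert dm2.data[a, b] == pytest.approx(dm.data[i, j])

    def test_incomparable_pair_named(self):
        recs = [SequenceRecord("ok", "", "ACGT"),
                SequenceRecord("gappy", "", "----")]
        with pytest.raises(ValueError, match="gappy"):
            pairwise_matrix(Alignment(recs))


def gotoh_oracle(a: str, b: str, scoring: IdentityScoring):
    """Independent affine-gap global aligner (Gotoh), returning score and one
    optimal gapped alignment. Gap of length L costs open + (L-1)*extend."""
    n, m = len(a), len(b)
    NEG = -1e18
    op, ex = -scoring.gap_open, -scoring.gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = op + (i - 1) * ex
    for j in range(1, m + 1):
        Y[0][j] = op + (j - 1) * ex
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + op, X[i - 1][j] + ex, Y[i - 1][j] + op)
            Y[i][j] = max(M[i][j - 1] + op, Y[i][j - 1] + ex, X[i][j - 1] + op)
    score = max(M[n][m], X[n][m], Y[n][m])
    # one optimal traceback
    ga, gb = [], []
    state = max(((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")))[1]
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            prev = M[i][j] - s
            ga.append(a[i - 1]); gb.append(b[j - 1])
            i, j = i - 1, j - 1
            state = "M" if abs(M[i][j] - prev) < 1e-9 else \
                    ("X" if abs(X[i][j] - prev) < 1e-9 else "Y")
        elif state == "X":
            cur = X[i][j]
            ga.append(a[i - 1]); gb.append("-")
            if i > 1 or j > 0:
                if abs(X[i - 1][j] + ex - cur) < 1e-9:
                    state = "X"
                elif abs(M[i - 1][j] + op - cur) < 1e-9:
                    state = "M"
                else:
                    state = "Y"
            i -= 1
        else:
            cur = Y[i][j]
            ga.append("-"); gb.append(b[j - 1])
            if j > 1 or i > 0:
                if abs(Y[i][j - 1] + ex - cur) < 1e-9:
                    state = "Y"
                elif abs(M[i][j - 1] + op - cur) < 1e-9:
                    state = "M"
                else:
                    state = "X"
            j -= 1
    return score, "".join(reversed(ga)), "".join(reversed(gb))


def identity_of(ga: str, gb: str) -> float:
    ncol = len(ga)
    start = 0
    while start < ncol and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = ncol
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(ga[k] == gb[k] and ga[k] != "-" for k in range(start, end))
    return matches / (end - start)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_mutated_pairs(self):
        rng = np.random.default_rng(5)
        scoring = IdentityScoring()
        for _ in range(25):
            base = "".join(rng.choice(list("ACGT"), 80))
            seq = list(base)
            for pos in rng.choice(80, size=3, replace=False):
                seq[pos] = rng.choice([c for c in "ACGT" if c != seq[pos]])
            cut = int(rng.integers(10, 60))
            mutated = "".join(seq[:cut] + seq[cut + 2:])  # 2-nt deletion
            score, ga, gb = gotoh_oracle(base, mutated, scoring)
            got = pairwise_identity(base, mutated, scoring)
            assert got == pytest.approx(identity_of(ga, gb))
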
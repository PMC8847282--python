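import numpy as np
import pytest

from shdelim import distances, seqio, simulate, trees
from shdelim.seqio import Alignment, SequenceRecord


@pytest.fixture
def toy_tree():
    """3-tip ultrametric tree: ((A:1,B:1):1,C:2);"""
    return trees.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    """4-tip ultrametric caterpillar with node heights 3, 2, 1."""
    return trees.tree_from_string("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def small_alignment():
    recs = [
        SequenceRecord("s1", "", "ACGTACGTAC"),
        SequenceRecord("s2", "", "ACGTACGTAC"),
        SequenceRecord("s3", "", "ACTTACGAAC"),
    ]
    return Alignment(recs, {"A": (0, 4), "B": (4, 10)})


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int,
                     with_ambiguity: bool = True) -> Alignment:
    alphabet = list("ACGT") + (["N", "-", "R", "Y"] if with_ambiguity else [])
    probs = None
    if with_ambiguity:
        probs = [0.22, 0.22, 0.22, 0.22, 0.03, 0.03, 0.03, 0.03]
    recs = []
    for i in range(n_seqs):
        residues = "".join(rng.choice(alphabet, size=n_cols, p=probs))
        recs.append(SequenceRecord(f"t{i}", "", residues))
    return Alignment(recs)


@pytest.fixture(scope="session")
def strong_gap_dataset():
    """One strong-gap dataset shared by fast tests (seed fixed)."""
    cfg = simulate.strong_gap_config(seed=11)
    records, truth = simulate.make_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def strong_gap_distances(strong_gap_dataset):
    _, records, _ = strong_gap_dataset
    return distances.pairwise_matrix(seqio.Alignment(records))
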
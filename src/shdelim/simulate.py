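"""Synthetic barcode datasets with known species structure.

The generator chains three stages, each seeded from independent sub-streams of
one master seed:

1. a pure-birth (Yule) species tree — exponential waiting times with rate
   ``birth_rate x lineages``, including the final interval after the n-th
   lineage appears, so E[root height] = sum_{k=2..n} 1/(lambda k);
2. a multispecies-coalescent gene tree via msprime: each species is a
   population of coalescent scale ``theta`` (pairwise within-species TMRCA has
   mean theta), with population splits at the species-tree node times;
3. Jukes–Cantor sequence evolution along the gene tree with ``mu`` expected
   substitutions per site per unit time, using the exact JC69 transition
   probabilities.

The ``strong_gap`` preset produces datasets with a pronounced barcode gap
(within-species identity ≈ 0.997, between-species identity <= ~0.95): the
species tree is conditioned on a minimum divergence depth by seeded rejection
sampling, since rate choices alone cannot bound the most recent split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import msprime
import numpy as np

from .partition import Partition, from_cluster_sets
from .seqio import SequenceRecord
from .trees import tree_from_string

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic barcode dataset."""

    n_species: int = 5
    tips_per_species: int = 8
    birth_rate: float = 1.0        # speciation rate of the Yule species tree
    theta: float = 0.005           # within-species coalescent scale (time units)
    seq_length: int = 500          # bp
    mu: float = 0.05               # substitutions/site per unit branch length
    seed: int = 1
    min_species_depth: float | None = None  # reject species trees with shallower splits

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.tips_per_species < 1:
            raise ValueError("n_species and tips_per_species must be >= 1")
        if min(self.birth_rate, self.theta, self.mu) <= 0 or self.seq_length < 1:
            raise ValueError("rates and sequence length must be positive")


def strong_gap_config(seed: int = 1, **overrides) -> SimConfig:
    """The default well-separated study design: 5 species x 8 tips.

    Minimum species divergence depth 0.6 with mu = 0.05 bounds the smallest
    between-species JC distance at ~0.06 (identity <= ~0.95). theta = 0.005
    keeps even the deepest within-species coalescences shallow enough that
    essentially every within-species pair stays above 0.995 identity — the
    identity bound must hold per pair, so it is the tail of the TMRCA
    distribution, not its mean, that is constrained.
    """
    cfg = SimConfig(n_species=5, tips_per_species=8, birth_rate=1.0, theta=0.005,
                    seq_length=500, mu=0.05, seed=seed, min_species_depth=0.6)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated dataset."""

    true_partition: Partition
    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree    # ultrametric, time units
    phylogram: dendropy.Tree    # gene tree with lengths scaled by mu


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit sub-seeds derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) + 1 for s in ss.generate_state(n, dtype=np.uint32)]


def simulate_species_tree(n_species: int, birth_rate: float, seed: int,
                          min_depth: float | None = None) -> dendropy.Tree:
    """Yule species tree with tips sp1..spN.

    Forward construction: start from one lineage; while fewer than n lineages,
    wait Exp(birth_rate * k) then split a uniformly chosen lineage; after the
    n-th lineage appears, wait a final Exp(birth_rate * n) before the present.
    With ``min_depth`` set, trees whose shallowest divergence is younger than
    the floor are rejected and redrawn (seeded, hence reproducible).
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    if n_species == 1:
        return tree_from_string("sp1:0.0;")
    while True:
        newick, shallowest = _yule_forward(n_species, birth_rate, rng)
        if min_depth is None or shallowest >= min_depth:
            return tree_from_string(newick)


class _SimNode:
    __slots__ = ("height", "children")

    def __init__(self, height: float):
        self.height = height
        self.children: list["_SimNode"] = []


def _yule_forward(n: int, birth_rate: float, rng: np.random.Generator) -> tuple[str, float]:
    """One Yule draw -> (rooted newick string, shallowest split height)."""
    # Split times measured forward from the first split at time 0.
    split_times = [0.0]
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / (birth_rate * k))
        split_times.append(t)
    present = t + rng.exponential(1.0 / (birth_rate * n))
    heights = [present - s for s in split_times]  # descending, root first

    root = _SimNode(heights[0])
    active = [_SimNode(0.0), _SimNode(0.0)]  # heights set at their own split / tip time
    root.children = list(active)
    for h in heights[1:]:
        i = int(rng.integers(len(active)))
        node = active[i]
        node.height = h
        node.children = [_SimNode(0.0), _SimNode(0.0)]
        active[i] = node.children[0]
        active.append(node.children[1])

    label = iter(range(1, n + 1))

    def render(node: _SimNode, parent_height: float) -> str:
        stem = parent_height - node.height
        if node.children:
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{stem:.10f}"
        return f"sp{next(label)}:{stem:.10f}"

    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});", heights[-1]


def _species_heights(species_tree: dendropy.Tree) -> dict:
    from .trees import node_heights
    return node_heights(species_tree)


def _demography(species_tree: dendropy.Tree, theta: float) -> msprime.Demography:
    """Each species is a population of coalescent scale theta; ancestral
    populations appear at the species-tree split times."""
    heights = _species_heights(species_tree)
    dem = msprime.Demography()
    names: dict = {}
    counter = iter(range(1, 10**6))
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            names[node] = node.taxon.label
        else:
            names[node] = f"anc{next(counter)}"
        dem.add_population(name=names[node], initial_size=theta)
    internals = sorted((n for n in names if not n.is_leaf()), key=lambda n: heights[n])
    for node in internals:
        dem.add_population_split(time=heights[node],
                                 derived=[names[c] for c in node.child_nodes()],
                                 ancestral=names[node])
    return dem


def simulate_gene_tree(species_tree: dendropy.Tree, tips_per_species: int,
                       theta: float, seed: int) -> dendropy.Tree:
    """Multispecies-coalescent gene tree: Kingman coalescent of scale theta
    within each species, with lineages merging at the species split times.
    Tips are labelled ``<species>_<k>``; the output is ultrametric."""
    if tips_per_species < 1:
        raise ValueError("tips_per_species must be >= 1")
    dem = _demography(species_tree, theta)
    species = [leaf.taxon.label for leaf in species_tree.leaf_node_iter()]
    samples = [msprime.SampleSet(tips_per_species, population=sp, ploidy=1)
               for sp in species]
    ts = msprime.sim_ancestry(samples=samples, demography=dem, ploidy=1,
                              random_seed=int(seed) % (2**31 - 1) + 1)
    tree = ts.first()
    labels = {}
    tab = ts.tables
    per_species_count: dict = {}
    for sample in ts.samples():
        pop = ts.population(tab.nodes[sample].population).metadata["name"]
        per_species_count[pop] = per_species_count.get(pop, 0) + 1
        labels[sample] = f"{pop}_{per_species_count[pop]}"
    newick = tree.as_newick(node_labels=labels)
    return tree_from_string(newick)


def evolve_sequences(tree: dendropy.Tree, seq_length: int, mu: float,
                     seed: int) -> list[SequenceRecord]:
    """Evolve sequences along a tree under JC69.

    The root sequence is uniform over {A,C,G,T}; along an edge of length L the
    per-site substitution probability is the exact JC69 value
    ``(3/4)(1 - exp(-4*mu*L/3))`` and a substituted site picks uniformly among
    the three other bases. ``mu`` scales branch lengths to substitutions/site
    (pass mu=1 for a phylogram).
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(seed)
    seqs: dict = {}
    root = tree.seed_node
    seqs[root] = rng.integers(4, size=seq_length)
    records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            d = mu * (node.edge.length or 0.0)
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            parent_seq = seqs[node.parent_node]
            child = parent_seq.copy()
            mask = rng.random(seq_length) < p_change
            n_sub = int(mask.sum())
            if n_sub:
                child[mask] = (child[mask] + rng.integers(1, 4, size=n_sub)) % 4
            seqs[node] = child
        if node.is_leaf():
            residues = "".join(_BASES[seqs[node]])
            records.append(SequenceRecord(node.taxon.label, "", residues))
    records.sort(key=lambda r: r.id)
    return records


def _scaled(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return clone


def true_partition(records: list[SequenceRecord]) -> Partition:
    """Ground-truth partition from ``<species>_<k>`` tip names."""
    groups: dict = {}
    for rec in records:
        sp = rec.id.rsplit("_", 1)[0]
        groups.setdefault(sp, set()).add(rec.id)
    return from_cluster_sets("TRUTH", groups.values(), prefix="SP")


def make_dataset(config: SimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """Simulate a full dataset (sequences + truth bundle) from one seed.

    Sub-seeds for the three stages are derived independently from
    ``config.seed``, so e.g. enlarging ``seq_length`` does not perturb the
    trees.
    """
    s_tree, s_gene, s_seq = _sub_seeds(config.seed, 3)
    species_tree = simulate_species_tree(config.n_species, config.birth_rate,
                                         s_tree, config.min_species_depth)
    gene_tree = simulate_gene_tree(species_tree, config.tips_per_species,
                                   config.theta, s_gene)
    phylogram = _scaled(gene_tree, config.mu)
    records = evolve_sequences(gene_tree, config.seq_length, config.mu, s_seq)
    truth = SimTruth(true_partition=records and true_partition(records),
                     species_tree=species_tree, gene_tree=gene_tree,
                     phylogram=phylogram)
    return records, truth


def distance_sh_partition(dmat, threshold: float, method_id: str) -> Partition:
    """Synthetic stand-in for an externally computed SH assignment table.

    Reference SH systems cluster barcode sequences at fixed distance
    thresholds (e.g. 3% and 1.5%); this emulates that rule by single-linkage
    clustering of a distance matrix at ``threshold``, so synthetic studies can
    exercise the external-table ingestion path without any download.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if threshold <= 0:
        raise ValueError("distance threshold must be positive")
    Z = linkage(squareform(dmat.data, checks=False), method="single")
    labels = fcluster(Z, t=threshold, criterion="distance")
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(dmat.ids[i])
    return from_cluster_sets(method_id, groups.values(), prefix=method_id)
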
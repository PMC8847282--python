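"""PTP (Poisson tree processes) species delimitation on a phylogram.

PTP models branch lengths (expected substitutions per site) as draws from two
exponential distributions: between-species (speciation) branches and
within-species (coalescent) branches. A delimitation is an *antichain* of
species-root nodes whose subtrees tile the tips; edges strictly inside a
species subtree are the coalescent class, all other edges (the root edge is
excluded) the speciation class. Per-class rate MLEs are analytic
(count / length sum), so the likelihood of any delimitation is closed-form and
the search is purely combinatorial: a greedy node-toggling hill climb with
random restarts for the ML fit, and a Metropolis–Hastings sampler over
antichains for Bayesian per-species support.

Following the study design this package mirrors, when ML and Bayesian runs
disagree the result with fewer species hypotheses is adopted
(:func:`select_fewer`) to avoid excessive species division.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

import dendropy

from .partition import Partition, from_cluster_sets


@dataclass
class PtpFit:
    """One PTP delimitation: species roots, partition, rates, likelihood."""

    species_roots: frozenset
    partition: Partition
    lambda_spec: float | None
    lambda_coal: float | None
    logL: float
    mode: str                       # "ML" or "Bayesian"
    support: dict = field(default_factory=dict)   # cluster_id -> posterior frequency
    seed: int | None = None


class _Indexed:
    """Integer-indexed view of a rooted tree for fast antichain arithmetic."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = [self.index[id(n.parent_node)] if n.parent_node else -1
                       for n in self.nodes]
        self.children = [[self.index[id(c)] for c in n.child_nodes()] for n in self.nodes]
        self.lengths = np.array([(n.edge.length or 0.0) for n in self.nodes])
        self.is_leaf = [not c for c in self.children]
        self.tip_labels = [n.taxon.label if n.is_leaf() else None for n in self.nodes]
        # tips under each node, as sorted tuples (preorder suffix property)
        self.tips_below: list[tuple[str, ...]] = [()] * len(self.nodes)
        for i in range(len(self.nodes) - 1, -1, -1):
            if self.is_leaf[i]:
                self.tips_below[i] = (self.tip_labels[i],)
            else:
                acc: list[str] = []
                for c in self.children[i]:
                    acc.extend(self.tips_below[c])
                self.tips_below[i] = tuple(sorted(acc))

    @property
    def n(self) -> int:
        return len(self.nodes)


def _class_loglik(count: int, total: float) -> tuple[float, float | None]:
    """Log-likelihood contribution and rate MLE of one exponential class."""
    if count == 0:
        return 0.0, None
    if total <= 0:
        raise ValueError("zero-length branch class with nonzero edge count")
    lam = count / total
    return count * math.log(lam) - count, lam


def _antichain_loglik(idx: _Indexed, roots: frozenset[int]) -> tuple[float, float | None, float | None]:
    """logL and per-class rate MLEs for a species-root antichain (node indices)."""
    # Edge i (into node i) is coalescent iff its parent lies inside a species
    # subtree, i.e. the parent is a species root or a descendant of one.
    inside = np.zeros(idx.n, dtype=bool)   # node is strictly inside-or-root of a species
    for i in range(idx.n):
        p = idx.parent[i]
        inside[i] = (i in roots) or (p >= 0 and inside[p])
    coal_count = coal_sum = spec_count = spec_sum = 0.0
    for i in range(idx.n):
        p = idx.parent[i]
        if p < 0:
            continue  # root edge excluded from both classes
        if inside[p]:
            coal_count += 1
            coal_sum += idx.lengths[i]
        else:
            spec_count += 1
            spec_sum += idx.lengths[i]
    ll_spec, lam_spec = _class_loglik(int(spec_count), spec_sum)
    ll_coal, lam_coal = _class_loglik(int(coal_count), coal_sum)
    return ll_spec + ll_coal, lam_spec, lam_coal


def _validate_tree(tree: dendropy.Tree) -> _Indexed:
    root = tree.seed_node
    if len(root.child_nodes()) == 0:
        raise ValueError("tree has no structure")
    if tree.is_rooted is False and len(root.child_nodes()) > 2:
        raise ValueError("PTP requires a rooted tree; please root the input first")
    return _Indexed(tree)


def _roots_to_partition(idx: _Indexed, roots: frozenset[int], method_id: str) -> Partition:
    return from_cluster_sets(method_id, [set(idx.tips_below[r]) for r in roots],
                             prefix=method_id)


def ptp_loglik(tree: dendropy.Tree, species_roots) -> tuple[float, float | None, float | None]:
    """Two-class exponential log-likelihood of a delimitation.

    ``species_roots`` is an iterable of dendropy nodes forming an antichain
    that covers all tips. Returns (logL, lambda_spec, lambda_coal); a class
    with no edges contributes 0 and has rate None.
    """
    idx = _Indexed(tree)
    roots = frozenset(idx.index[id(n)] for n in species_roots)
    _check_antichain(idx, roots)
    return _antichain_loglik(idx, roots)


def _check_antichain(idx: _Indexed, roots: frozenset[int]) -> None:
    covered: list[str] = []
    for r in roots:
        covered.extend(idx.tips_below[r])
    all_tips = idx.tips_below[0]
    if sorted(covered) != list(all_tips):
        raise ValueError("species roots must form an antichain covering every tip exactly once")


def _neighbor_moves(idx: _Indexed, roots: frozenset[int]) -> list[frozenset[int]]:
    """Antichains one move away: split a species root, or merge a full sibling set."""
    out = []
    for r in roots:
        if not idx.is_leaf[r]:
            out.append(roots - {r} | frozenset(idx.children[r]))
    parents = {idx.parent[r] for r in roots if idx.parent[r] >= 0}
    for p in parents:
        kids = idx.children[p]
        if all(k in roots for k in kids):
            out.append(roots - frozenset(kids) | {p})
    return out


def _random_antichain(idx: _Indexed, rng: np.random.Generator) -> frozenset[int]:
    """Uniform-ish random antichain by recursive coin-flip cutting from the root."""
    roots: list[int] = []
    stack = [0]
    while stack:
        i = stack.pop()
        if idx.is_leaf[i] or rng.random() < 0.5:
            roots.append(i)
        else:
            stack.extend(idx.children[i])
    return frozenset(roots)


def enumerate_antichains(idx_or_tree) -> list[frozenset[int]]:
    """All antichains covering the tips (exhaustive; for small trees/tests)."""
    idx = idx_or_tree if isinstance(idx_or_tree, _Indexed) else _Indexed(idx_or_tree)

    def rec(i: int) -> list[list[int]]:
        options = [[i]]
        if not idx.is_leaf[i]:
            sub = [rec(c) for c in idx.children[i]]
            combos = [[]]
            for choices in sub:
                combos = [acc + choice for acc in combos for choice in choices]
            options.extend(combos)
        return options

    return [frozenset(o) for o in rec(0)]


def ptp_ml(tree: dendropy.Tree, n_starts: int = 25, max_iter: int = 1000,
           seed: int = 0, method_id: str = "PTP-ML") -> PtpFit:
    """Maximum-likelihood PTP delimitation by greedy hill climbing.

    ``n_starts`` restarts: the single-species and all-singleton extremes plus
    seeded random antichains. Deterministic for a fixed seed.
    """
    idx = _validate_tree(tree)
    if len(idx.tips_below[0]) < 4:
        raise ValueError("PTP requires at least 4 tips")
    rng = np.random.default_rng(seed)
    singletons = frozenset(i for i in range(idx.n) if idx.is_leaf[i])
    starts = [frozenset({0}), singletons]
    while len(starts) < max(n_starts, 2):
        starts.append(_random_antichain(idx, rng))
    best_roots, best_ll = None, -np.inf
    for start in starts:
        roots, ll = start, _antichain_loglik(idx, start)[0]
        for _ in range(max_iter):
            improved = False
            for cand in _neighbor_moves(idx, roots):
                cll = _antichain_loglik(idx, cand)[0]
                if cll > ll + 1e-12:
                    roots, ll, improved = cand, cll, True
            if not improved:
                break
        if ll > best_ll:
            best_roots, best_ll = roots, ll
    ll, lam_spec, lam_coal = _antichain_loglik(idx, best_roots)
    part = _roots_to_partition(idx, best_roots, method_id)
    return PtpFit(species_roots=best_roots, partition=part, lambda_spec=lam_spec,
                  lambda_coal=lam_coal, logL=ll, mode="ML", seed=seed)


def ptp_bayes(tree: dendropy.Tree, generations: int = 100_000, burnin_frac: float = 0.1,
              seed: int = 0, method_id: str = "PTP-Bayes") -> PtpFit:
    """Bayesian PTP: Metropolis–Hastings over antichains with a uniform prior.

    Single-move proposals (split one species / merge one sibling group) with a
    Hastings correction for the changing move count. Post-burn-in samples give
    per-species support (frequency of the exact tip set) and the reported
    partition is the most frequently sampled delimitation.
    """
    if generations < 1000:
        raise ValueError("use at least 1,000 MCMC generations")
    if not (0.0 <= burnin_frac < 1.0):
        raise ValueError("burnin_frac must lie in [0, 1)")
    idx = _validate_tree(tree)
    rng = np.random.default_rng(seed)
    roots = frozenset(i for i in range(idx.n) if idx.is_leaf[i])
    ll = _antichain_loglik(idx, roots)[0]
    burnin = int(generations * burnin_frac)
    delim_counts: Counter = Counter()
    species_counts: Counter = Counter()
    n_samples = 0
    for gen in range(generations):
        moves = _neighbor_moves(idx, roots)
        if moves:
            prop = moves[rng.integers(len(moves))]
            prop_ll = _antichain_loglik(idx, prop)[0]
            hastings = len(moves) / len(_neighbor_moves(idx, prop))
            if math.log(rng.random()) < (prop_ll - ll) + math.log(hastings):
                roots, ll = prop, prop_ll
        if gen >= burnin:
            key = frozenset(idx.tips_below[r] for r in roots)
            delim_counts[key] += 1
            for r in roots:
                species_counts[idx.tips_below[r]] += 1
            n_samples += 1
    best_key = max(delim_counts.items(), key=lambda kv: (kv[1], -len(kv[0])))[0]
    # Map the sampled tip sets back to nodes, shallowest first, so unifurcation
    # chains cannot contribute two nodes with the same subtree.
    chosen: list[int] = []
    selected = np.zeros(idx.n, dtype=bool)
    for i in range(idx.n):  # preorder
        p = idx.parent[i]
        if p >= 0 and selected[p]:
            selected[i] = True  # under an already-chosen species root
            continue
        if idx.tips_below[i] in best_key:
            chosen.append(i)
            selected[i] = True
    best_roots = frozenset(chosen)
    ll, lam_spec, lam_coal = _antichain_loglik(idx, best_roots)
    part = _roots_to_partition(idx, best_roots, method_id)
    support = {}
    for cluster_id, members in part.clusters.items():
        support[cluster_id] = species_counts[tuple(sorted(members))] / n_samples
    part.metadata.update({"seed": seed, "generations": generations,
                          "burnin_frac": burnin_frac, "support": support})
    return PtpFit(species_roots=best_roots, partition=part, lambda_spec=lam_spec,
                  lambda_coal=lam_coal, logL=ll, mode="Bayesian",
                  support=support, seed=seed)


def select_fewer(fit_ml: PtpFit, fit_bayes: PtpFit) -> Partition:
    """Adopt the PTP result with fewer species hypotheses (ties -> Bayesian).

    Mirrors the consensus-study rule of preferring the coarser of the ML and
    Bayesian delimitations to avoid excessive species division.
    """
    ids_ml = set(fit_ml.partition.assignment)
    ids_bayes = set(fit_bayes.partition.assignment)
    if ids_ml != ids_bayes:
        raise ValueError("ML and Bayesian fits cover different tip sets")
    if fit_ml.partition.n_clusters < fit_bayes.partition.n_clusters:
        return fit_ml.partition.renamed("PTP")
    return fit_bayes.partition.renamed("PTP")
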
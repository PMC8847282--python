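import math
from itertools import product

import numpy as np
import pytest

from shdelim.ptp import (PtpFit, ptp_bayes, ptp_loglik, ptp_ml, select_fewer)
from shdelim.trees import tree_from_string


def tip_nodes(tree, labels):
    wanted = set(labels)
    return [leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label in wanted]


def independent_loglik(tree, species_tip_sets):
    """Edge classification + two-exponential likelihood recomputed from
    scratch, without the package's antichain machinery."""
    species = [frozenset(s) for s in species_tip_sets]

    def leaves_below(node):
        return frozenset(l.taxon.label for l in node.leaf_iter())

    coal, spec = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_leaves = leaves_below(node.parent_node)
        inside = any(parent_leaves <= sp for sp in species)
        (coal if inside else spec).append(node.edge.length or 0.0)
    ll = 0.0
    for lengths in (coal, spec):
        m, s = len(lengths), sum(lengths)
        if m:
            ll += m * math.log(m / s) - m
    return ll


def enumerate_partitions(tree):
    """All antichain delimitations as sets of tip-label frozensets."""
    def rec(node):
        own = frozenset(l.taxon.label for l in node.leaf_iter())
        options = [frozenset([own])]
        kids = node.child_nodes()
        if kids:
            sub = [rec(c) for c in kids]
            for combo in product(*sub):
                options.append(frozenset().union(*combo))
        return options

    return rec(tree.seed_node)


def random_phylogram(rng, n_tips):
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{l}:{rng.exponential(0.1) + 1e-4:.6f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.1) + 1e-4:.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return tree_from_string(f"({nodes[0]},{nodes[1]});")


FOUR_TIP = "((A:0.01,B:0.02):0.5,(C:0.03,D:0.015):0.4);"


class TestLoglik:
    def test_all_singletons_is_one_class(self):
        tree = tree_from_string(FOUR_TIP)
        roots = tip_nodes(tree, "ABCD")
        ll, lam_spec, lam_coal = ptp_loglik(tree, roots)
        lengths = [0.01, 0.02, 0.5, 0.03, 0.015, 0.4]
        m, s = len(lengths), sum(lengths)
        assert ll == pytest.approx(m * math.log(m / s) - m)
        assert lam_spec == pytest.approx(m / s)
        assert lam_coal is None

    def test_two_species_split_hand_computed(self):
        tree = tree_from_string(FOUR_TIP)
        root = tree.seed_node
        ll, lam_spec, lam_coal = ptp_loglik(tree, root.child_nodes())
        coal = [0.01, 0.02, 0.03, 0.015]
        spec = [0.5, 0.4]
        hand = (4 * math.log(4 / sum(coal)) - 4) + (2 * math.log(2 / sum(spec)) - 2)
        assert ll == pytest.approx(hand)
        assert lam_coal == pytest.approx(4 / sum(coal))
        assert lam_spec == pytest.approx(2 / sum(spec))

    def test_rates_are_maximizers(self):
        """Perturbing either rate away from the reported MLE lowers the
        two-class log-likelihood."""
        tree = tree_from_string(FOUR_TIP)
        _, lam_spec, lam_coal = ptp_loglik(tree, tree.seed_node.child_nodes())
        coal = [0.01, 0.02, 0.03, 0.015]
        spec = [0.5, 0.4]

        def ll(ls, lc):
            return (sum(math.log(lc) - lc * b for b in coal)
                    + sum(math.log(ls) - ls * b for b in spec))

        base = ll(lam_spec, lam_coal)
        for eps in (0.9, 1.1):
            assert ll(lam_spec * eps, lam_coal) < base
            assert ll(lam_spec, lam_coal * eps) < base

    def test_invalid_antichain_rejected(self):
        tree = tree_from_string(FOUR_TIP)
        with pytest.raises(ValueError, match="antichain"):
            ptp_loglik(tree, tip_nodes(tree, "AB"))

    def test_invariant_to_tip_relabeling(self):
        rng = np.random.default_rng(1)
        t1 = random_phylogram(rng, 6)
        text = t1.as_string(schema="newick")
        for i in range(6):
            text = text.replace(f"t{i}:", f"x{i}:")
        t2 = tree_from_string(text)
        ll1 = ptp_loglik(t1, t1.seed_node.child_nodes())[0]
        ll2 = ptp_loglik(t2, t2.seed_node.child_nodes())[0]
        assert ll1 == pytest.approx(ll2)


class TestML:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for rep in range(50):
            tree = random_phylogram(rng, int(rng.integers(4, 7)))
            best_ll = max(independent_loglik(tree, part)
                          for part in enumerate_partitions(tree))
            fit = ptp_ml(tree, seed=rep)
            assert fit.logL == pytest.approx(best_ll, abs=1e-9)

    def test_beats_trivial_extremes(self):
        rng = np.random.default_rng(3)
        tree = random_phylogram(rng, 8)
        fit = ptp_ml(tree, seed=0)
        tips = [frozenset([l.taxon.label]) for l in tree.leaf_node_iter()]
        singletons = independent_loglik(tree, tips)
        one_species = independent_loglik(
            tree, [frozenset(l.taxon.label for l in tree.leaf_node_iter())])
        assert fit.logL >= singletons - 1e-9
        assert fit.logL >= one_species - 1e-9

    def test_two_class_simulation_recovery(self):
        """Branch lengths drawn from the model's own two exponential classes
        (means 0.2 and 0.002): the true 5-species partition is the ML
        delimitation in >= 90% of replicates."""
        rng = np.random.default_rng(8)
        ok = 0
        reps = 30
        for _ in range(reps):
            species = []
            for s in range(5):
                labels = [f"sp{s}x{t}" for t in range(6)]
                nodes = [f"{l}:{rng.exponential(0.002) + 1e-6:.8f}" for l in labels]
                while len(nodes) > 1:
                    i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                    merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.002) + 1e-6:.8f}"
                    nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
                base = nodes[0].rsplit(":", 1)[0]
                species.append(f"{base}:{rng.exponential(0.2) + 1e-6:.8f}")
            while len(species) > 2:
                i, j = sorted(rng.choice(len(species), 2, replace=False))
                merged = f"({species[i]},{species[j]}):{rng.exponential(0.2) + 1e-6:.8f}"
                species = [n for k, n in enumerate(species) if k not in (i, j)] + [merged]
            tree = tree_from_string(f"({species[0]},{species[1]});")
            truth = {frozenset(f"sp{s}x{t}" for t in range(6)) for s in range(5)}
            got = set(frozenset(m) for m in ptp_ml(tree, seed=1).partition.clusters.values())
            ok += got == truth
        assert ok >= 0.9 * reps


class TestBayes:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        tree = random_phylogram(rng, 6)
        f1 = ptp_bayes(tree, generations=2000, seed=5)
        f2 = ptp_bayes(tree, generations=2000, seed=5)
        assert f1.partition.assignment == f2.partition.assignment
        assert f1.support == f2.support

    def test_burnin_validation(self):
        rng = np.random.default_rng(2)
        tree = random_phylogram(rng, 5)
        with pytest.raises(ValueError):
            ptp_bayes(tree, generations=2000, burnin_frac=1.0)
        with pytest.raises(ValueError):
            ptp_bayes(tree, generations=10)

    def test_chain_reaches_ml_optimum_on_small_trees(self):
        rng = np.random.default_rng(4)
        for rep in range(5):
            tree = random_phylogram(rng, 6)
            best_ll = max(independent_loglik(tree, part)
                          for part in enumerate_partitions(tree))
            fit = ptp_bayes(tree, generations=5000, seed=rep)
            # the sampled modal delimitation is scored by its exact logL
            assert fit.logL <= best_ll + 1e-9
            assert fit.logL >= best_ll - 2.0  # within posterior reach of the optimum

    def test_strong_two_class_support(self):
        """Well-separated two-species tree: both true species sampled with
        support >= 0.95."""
        nwk = ("((a1:0.001,(a2:0.001,a3:0.002):0.001):0.6,"
               "(b1:0.002,(b2:0.001,b3:0.001):0.002):0.5);")
        tree = tree_from_string(nwk)
        fit = ptp_bayes(tree, generations=20000, seed=3)
        truth = {frozenset(["a1", "a2", "a3"]), frozenset(["b1", "b2", "b3"])}
        got = {frozenset(m) for m in fit.partition.clusters.values()}
        assert got == truth
        assert all(s >= 0.95 for s in fit.support.values())


class TestSelectFewer:
    def _fit(self, part, mode):
        return PtpFit(species_roots=frozenset(), partition=part,
                      lambda_spec=1.0, lambda_coal=1.0, logL=0.0, mode=mode)

    def test_fewer_wins(self):
        from shdelim.partition import from_cluster_sets
        ml = from_cluster_sets("PTP-ML", [{"a"}, {"b"}, {"c"}])
        bayes = from_cluster_sets("PTP-Bayes", [{"a", "b"}, {"c"}])
        chosen = select_fewer(self._fit(ml, "ML"), self._fit(bayes, "Bayesian"))
        assert chosen.n_clusters == 2 and chosen.method_id == "PTP"

    def test_tie_goes_to_bayesian(self):
        from shdelim.partition import from_cluster_sets
        ml = from_cluster_sets("PTP-ML", [{"a", "b"}, {"c"}])
        bayes = from_cluster_sets("PTP-Bayes", [{"a"}, {"b", "c"}])
        chosen = select_fewer(self._fit(ml, "ML"), self._fit(bayes, "Bayesian"))
        assert chosen.cluster_sets() == bayes.cluster_sets()

    def test_mismatched_tip_sets_rejected(self):
        from shdelim.partition import from_cluster_sets
        ml = from_cluster_sets("PTP-ML", [{"a"}, {"b"}])
        bayes = from_cluster_sets("PTP-Bayes", [{"a"}, {"z"}])
        with pytest.raises(ValueError):
            select_fewer(self._fit(ml, "ML"), self._fit(bayes, "Bayesian"))
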
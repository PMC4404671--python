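"""Jost's D_est, Weir–Cockerham theta, permutation tests and NJ trees."""

import numpy as np
import pandas as pd
import pytest

from tomatopop.differentiation import (bootstrap_tree, differentiation_matrix,
                                       jost_dest, neighbor_joining,
                                       pairwise_differentiation,
                                       permutation_test, wc_fst)
from tomatopop.distances import DistanceMatrix
from tomatopop.simulate import (SimulationConfig, simulate_dataset,
                                two_population_config)

from conftest import make_matrix
from oracles import (jost_dest_bruteforce, tree_path_lengths,
                     wc_theta_bruteforce)


def two_fixed_groups(n=6, loci=4):
    calls = np.vstack([np.full((n, loci), 2), np.full((n, loci), 0)]) \
        .astype(np.int8)
    m = make_matrix(calls)
    groups = {"g1": m.accessions[:n], "g2": m.accessions[n:]}
    return m, groups


def random_matrix_with_groups(seed, n_per=8, loci=30, n_groups=3, ps=None):
    rng = np.random.default_rng(seed)
    blocks, groups = [], {}
    for k in range(n_groups):
        p = ps[k] if ps else rng.uniform(0.2, 0.8, size=loci)
        blocks.append(rng.binomial(2, p, size=(n_per, loci)))
    calls = np.vstack(blocks).astype(np.int8)
    m = make_matrix(calls)
    for k in range(n_groups):
        groups[f"g{k}"] = m.accessions[k * n_per:(k + 1) * n_per]
    return m, groups


class TestJostD:
    def test_identical_frequencies_zero_uncorrected(self):
        calls = np.array([[2, 0], [1, 1], [0, 2], [2, 0], [1, 1], [0, 2]],
                         dtype=np.int8)
        m = make_matrix(calls)
        groups = {"a": m.accessions[:3], "b": m.accessions[3:]}
        assert jost_dest(m, groups, corrected=False) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_alleles_gives_one(self):
        m, groups = two_fixed_groups()
        assert jost_dest(m, groups) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle_three_groups(self):
        m, groups = random_matrix_with_groups(seed=13, loci=5)
        rows = [[m.accessions.index(a) for a in groups[k]]
                for k in sorted(groups)]
        assert jost_dest(m, groups) == pytest.approx(
            jost_dest_bruteforce(m.calls, rows), abs=1e-9)

    def test_invariant_to_relabeling_and_group_order(self):
        m, groups = random_matrix_with_groups(seed=14)
        flipped = make_matrix((2 - m.calls).astype(np.int8))
        assert jost_dest(m, groups) == pytest.approx(
            jost_dest(flipped, groups), abs=1e-12)
        reordered = dict(reversed(list(groups.items())))
        assert jost_dest(m, groups) == pytest.approx(
            jost_dest(m, reordered), abs=1e-12)


class TestWcFst:
    def test_fixed_opposite_alleles_equal_sizes_theta_one(self):
        m, groups = two_fixed_groups()
        assert wc_fst(m, groups) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle_three_groups(self):
        m, groups = random_matrix_with_groups(seed=15, loci=5)
        rows = [[m.accessions.index(a) for a in groups[k]]
                for k in sorted(groups)]
        assert wc_fst(m, groups) == pytest.approx(
            wc_theta_bruteforce(m.calls, rows), abs=1e-9)

    def test_panmictic_groups_near_zero(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0.2, 0.8, size=500)
        calls = rng.binomial(2, p, size=(80, 500)).astype(np.int8)
        m = make_matrix(calls, positions=np.arange(500.0))
        groups = {"a": m.accessions[:40], "b": m.accessions[40:]}
        assert abs(wc_fst(m, groups)) < 0.01

    def test_balding_nichols_parameter_recovery(self):
        ds = simulate_dataset(two_population_config(f=0.15, seed=42))
        theta = wc_fst(ds.matrix, ds.truth.groups_at("species"))
        assert 0.13 <= theta <= 0.17


class TestPermutation:
    def test_observed_below_all_permutations_p_one(self):
        # constant statistic: every permutation ties the observed -> p = 1
        m, groups = random_matrix_with_groups(seed=17)
        res = permutation_test(lambda mm, gg: 0.0, m, groups, n_perm=19, seed=1)
        assert res.p_value == 1.0

    def test_strong_signal_minimal_p(self):
        ds = simulate_dataset(two_population_config(
            f=0.5, n_per_group=30, n_markers=200, seed=18))
        groups = ds.truth.groups_at("species")
        res = permutation_test(jost_dest, ds.matrix, groups,
                               n_perm=99, seed=2)
        assert res.p_value == pytest.approx(1 / 100)

    def test_seeded_reproducibility(self):
        m, groups = random_matrix_with_groups(seed=19)
        r1 = permutation_test(wc_fst, m, groups, n_perm=49, seed=7)
        r2 = permutation_test(wc_fst, m, groups, n_perm=49, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 50


class TestNeighborJoining:
    def test_recovers_additive_four_leaf_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        paths = tree_path_lengths(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels[i + 1:], start=i + 1):
                assert paths[frozenset((a, b))] == pytest.approx(d[i, j])

    def test_three_leaves_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["x", "y", "z"], d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})

    def test_negative_branches_clamped_and_counted(self):
        d = np.array([[0, 1, 10, 10],
                      [1, 0, 10, 10],
                      [10, 10, 0, 0.1],
                      [10, 10, 0.1, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
        all_lengths = []
        def walk(n):
            all_lengths.append(n.length)
            for c in n.children:
                walk(c)
        walk(tree.root)
        assert min(all_lengths) >= 0.0

    def test_missing_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(list("abc"), d))

    def test_matches_skbio_topology_on_random_matrix(self):
        # independent oracle: scikit-bio's NJ on the same matrix
        import io
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(20)
        x = rng.uniform(0.5, 2.0, size=(6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(6)]
        ours = neighbor_joining(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        their_splits = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = frozenset(labels) - side
            if 1 < len(side) < len(labels) - 1:
                small = side if (len(side), sorted(side)) <= \
                    (len(other), sorted(other)) else other
                their_splits.add(small)
        assert ours.bipartitions() <= their_splits | \
            {frozenset(labels) - s for s in their_splits}


class TestBootstrap:
    def test_single_replicate_supports_zero_or_hundred(self):
        m, groups = random_matrix_with_groups(seed=21, n_groups=4, loci=40)
        tree, support = bootstrap_tree(m, groups, n_boot=1, seed=3)
        assert set(support["support"]) <= {0.0, 100.0}

    def test_long_internal_branch_high_support(self):
        # 4 groups: two pairs of near-identical frequency profiles, the pairs
        # far apart -> the internal edge separating the pairs is certain
        rng = np.random.default_rng(22)
        base1 = np.clip(rng.uniform(0.05, 0.25, 60), 0.01, 0.99)
        base2 = np.clip(rng.uniform(0.75, 0.95, 60), 0.01, 0.99)
        ps = [base1, np.clip(base1 + 0.05, 0, 1),
              base2, np.clip(base2 - 0.05, 0, 1)]
        m, groups = random_matrix_with_groups(seed=23, n_per=10, loci=60,
                                              n_groups=4, ps=ps)
        tree, support = bootstrap_tree(m, groups, n_boot=100, seed=4)
        split = frozenset({"g0", "g1"})
        row = support[support["bipartition"] == "g0|g1"]
        assert not row.empty and row["support"].iloc[0] >= 95

    def test_star_like_no_internal_signal(self):
        m, groups = random_matrix_with_groups(seed=24, n_per=10, loci=60,
                                              n_groups=4)
        # groups drawn from one shared frequency vector -> no signal
        rng = np.random.default_rng(25)
        p = rng.uniform(0.3, 0.7, 60)
        calls = rng.binomial(2, p, size=(40, 60)).astype(np.int8)
        m = make_matrix(calls)
        groups = {f"g{k}": m.accessions[k * 10:(k + 1) * 10] for k in range(4)}
        _tree, support = bootstrap_tree(m, groups, n_boot=100, seed=5)
        assert (support["support"] < 95).all()


class TestPairwise:
    def test_matrix_symmetric_with_clamping(self):
        m, groups = random_matrix_with_groups(seed=26)
        pairs = pairwise_differentiation(m, groups, "dest")
        dm = differentiation_matrix(pairs)
        assert (dm.values >= 0).all()
        assert np.allclose(dm.values, dm.values.T)
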
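"""Standardized PCA and hierarchical classification with mixture detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tomatopop.pca import (HierarchicalConfig, LevelConfig,
                           classify_hierarchical, standardized_pca)
from tomatopop.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


def two_pop_fixed(n=10, loci=20, noise_rng=None):
    calls = np.vstack([np.full((n, loci), 2), np.full((n, loci), 0)])
    if noise_rng is not None:
        flip = noise_rng.random(calls.shape) < 0.02
        calls = np.where(flip, 1, calls)
    return make_matrix(calls.astype(np.int8))


class TestPca:
    def test_two_fixed_populations_rank_one(self):
        m = two_pop_fixed()
        res = standardized_pca(m, n_components=3)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)
        pc1 = res.scores[:, 0]
        assert np.ptp(pc1[:10]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(pc1[10:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[0] - pc1[-1]) > 0

    def test_duplicating_accessions_preserves_structure(self):
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        m = make_matrix(calls)
        doubled = make_matrix(np.vstack([calls, calls]),
                              accessions=[f"a{i}" for i in range(16)])
        r1 = standardized_pca(m, 2)
        r2 = standardized_pca(doubled, 2)
        # duplicated accessions land exactly on their originals
        assert np.allclose(np.abs(r2.scores[:8]), np.abs(r2.scores[8:]),
                           atol=1e-9)
        # and the inter-accession geometry matches the original up to scale
        d1 = np.linalg.norm(r1.scores[:, :1] - r1.scores[:, :1].T)
        assert d1 > 0

    def test_admixed_individual_scores_at_midpoint(self):
        rng = np.random.default_rng(32)
        n, loci = 30, 400
        pa = np.full(loci, 0.05)
        pb = np.full(loci, 0.95)
        calls_a = rng.binomial(2, pa, size=(n, loci))
        calls_b = rng.binomial(2, pb, size=(n, loci))
        admixed = rng.binomial(2, (pa + pb) / 2, size=(1, loci))
        m = make_matrix(np.vstack([calls_a, calls_b, admixed]).astype(np.int8),
                        positions=np.arange(float(loci)))
        res = standardized_pca(m, 2)
        pc1 = res.scores[:, 0]
        mid = (pc1[:n].mean() + pc1[n:2 * n].mean()) / 2
        spread = abs(pc1[:n].mean() - pc1[n:2 * n].mean())
        assert abs(pc1[-1] - mid) < 0.15 * spread

    def test_marker_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(33)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        m = make_matrix(calls)
        perm = rng.permutation(30)
        m2 = make_matrix(calls[:, perm])
        r1 = standardized_pca(m, 3)
        r2 = standardized_pca(m2, 3)
        assert np.allclose(np.abs(r1.scores), np.abs(r2.scores), atol=1e-8)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            standardized_pca(make_matrix([[2, 2], [2, 2]]))


class TestHierarchicalClassification:
    def test_recovers_simulated_three_species_structure(self):
        ds = simulate_dataset(SimulationConfig(seed=41, n_markers=1000))
        cfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=3), LevelConfig(n_clusters=3),
                    LevelConfig(n_clusters=2)], seed=1)
        classes = classify_hierarchical(ds.matrix, cfg)
        truth = ds.truth.table.set_index("accession_id")
        pred = classes.table.set_index("accession_id")
        keep = truth.index[(~truth["is_mixture"])
                           & (~pred.loc[truth.index, "is_mixture"])]
        ari = adjusted_rand_score(truth.loc[keep, "species"],
                                  pred.loc[keep, "species"])
        assert ari >= 0.9

    def test_strong_admixture_labelled_mixture(self):
        rng = np.random.default_rng(42)
        n, loci = 25, 300
        calls_a = rng.binomial(2, 0.05, size=(n, loci))
        calls_b = rng.binomial(2, 0.95, size=(n, loci))
        admixed = rng.binomial(2, 0.5, size=(2, loci))
        m = make_matrix(np.vstack([calls_a, calls_b, admixed]).astype(np.int8),
                        positions=np.arange(float(loci)))
        cfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=2), LevelConfig(n_clusters=1),
                    LevelConfig(n_clusters=1)], seed=2)
        classes = classify_hierarchical(m, cfg)
        t = classes.table.set_index("accession_id")
        assert t.loc["a50", "is_mixture"] or t.loc["a51", "is_mixture"]
        # pure individuals overwhelmingly retain non-mixture labels
        assert t.iloc[:50]["is_mixture"].mean() < 0.2

    def test_nesting_is_strict(self):
        ds = simulate_dataset(SimulationConfig(seed=43, n_markers=600))
        cfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=3), LevelConfig(n_clusters=2),
                    LevelConfig(n_clusters=2)], seed=3)
        classes = classify_hierarchical(ds.matrix, cfg)
        t = classes.table[~classes.table["is_mixture"]]
        nest = t[t["subgroup"] != ""].groupby("subgroup")["group"].nunique()
        assert (nest == 1).all()
        nest2 = t[t["group"] != ""].groupby("group")["species"].nunique()
        assert (nest2 == 1).all()

    def test_fixed_seed_is_reproducible(self):
        ds = simulate_dataset(SimulationConfig(seed=44, n_markers=400))
        cfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=3), LevelConfig(n_clusters=2),
                    LevelConfig(n_clusters=2)], seed=4)
        c1 = classify_hierarchical(ds.matrix, cfg)
        c2 = classify_hierarchical(ds.matrix, cfg)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_homogeneous_population_single_cluster(self):
        rng = np.random.default_rng(45)
        p = rng.uniform(0.3, 0.7, 200)
        calls = rng.binomial(2, p, size=(30, 200)).astype(np.int8)
        m = make_matrix(calls, positions=np.arange(200.0))
        cfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=1), LevelConfig(n_clusters=1),
                    LevelConfig(n_clusters=1)], seed=5)
        classes = classify_hierarchical(m, cfg)
        labels = classes.table["species"].unique()
        assert len(labels) == 1
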
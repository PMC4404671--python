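"""Haversine geography, climate PCA distances and Mantel tests."""

import numpy as np
import pandas as pd
import pytest

from tomatopop.distances import DistanceMatrix
from tomatopop.ibd import (EARTH_RADIUS_KM, climate_distance,
                           distance_density_export, haversine_km,
                           haversine_matrix, mantel_test)


def points(rows):
    return pd.DataFrame(rows, columns=["accession_id", "latitude", "longitude"])


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(10, 20, 10, 20) == 0.0

    def test_antipodal_equator_is_pi_r(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(
            np.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_one_degree_arc(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            2 * np.pi * EARTH_RADIUS_KM / 360, abs=0.1)

    def test_matrix_excludes_missing_coordinates(self):
        pts = points([("a", 0.0, 0.0), ("b", 0.0, 1.0), ("c", np.nan, 5.0)])
        d = haversine_matrix(pts)
        assert d.labels == ["a", "b"]
        assert d.excluded == ["c"]
        assert d.values[0, 1] == pytest.approx(111.19, abs=0.1)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(70)
        for _ in range(25):
            lats = rng.uniform(-80, 80, 3)
            lons = rng.uniform(-179, 179, 3)
            d01 = haversine_km(lats[0], lons[0], lats[1], lons[1])
            d12 = haversine_km(lats[1], lons[1], lats[2], lons[2])
            d02 = haversine_km(lats[0], lons[0], lats[2], lons[2])
            assert d02 <= d01 + d12 + 1e-6
            assert d01 >= 0


class TestClimateDistance:
    def test_identical_rows_distance_zero(self):
        clim = pd.DataFrame({"accession_id": ["a", "b", "c"],
                             "t": [1.0, 1.0, 4.0], "p": [2.0, 2.0, 7.0]})
        d = climate_distance(clim)
        assert d.values[d.labels.index("a"), d.labels.index("b")] == \
            pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance_equals_standardized_euclidean(self):
        rng = np.random.default_rng(71)
        clim = pd.DataFrame(rng.normal(size=(12, 5)),
                            columns=[f"v{i}" for i in range(5)])
        clim.insert(0, "accession_id", [f"a{i}" for i in range(12)])
        d = climate_distance(clim)
        x = clim.drop(columns="accession_id").to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        from scipy.spatial.distance import pdist, squareform
        expected = squareform(pdist(z))
        assert np.allclose(d.values, expected, atol=1e-9)

    def test_one_sd_shift_distance_one(self):
        # a0 and a1 differ by exactly one population SD in v1 and agree in v2
        h = np.sqrt(1.75)  # makes v1's population SD exactly 1
        clim = pd.DataFrame({"accession_id": [f"a{i}" for i in range(4)],
                             "v1": [0.0, 1.0, 0.5 + h, 0.5 - h],
                             "v2": [5.0, 5.0, 6.0, 7.0]})
        d = climate_distance(clim)
        got = d.values[d.labels.index("a0"), d.labels.index("a1")]
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_rows_excluded(self):
        clim = pd.DataFrame({"accession_id": ["a", "b", "c"],
                             "v1": [0.0, 1.0, np.nan], "v2": [0.0, 2.0, 1.0]})
        d = climate_distance(clim)
        assert d.labels == ["a", "b"] and d.excluded == ["c"]


class TestMantel:
    def test_scaled_matrix_perfect_correlation(self):
        rng = np.random.default_rng(72)
        x = rng.uniform(size=(6, 2))
        base = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        labels = [f"a{i}" for i in range(6)]
        d1 = DistanceMatrix(labels, base)
        d2 = DistanceMatrix(labels, 2.0 * base)
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(73)
        x = rng.uniform(size=(7, 2))
        y = rng.uniform(size=(7, 2))
        base1 = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        base2 = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
        labels = [f"a{i}" for i in range(7)]
        r1 = mantel_test(DistanceMatrix(labels, base1),
                         DistanceMatrix(labels, base2),
                         n_perm=9, seed=1).r
        r2 = mantel_test(DistanceMatrix(labels, base1),
                         DistanceMatrix(labels, 5.0 * base2 ),
                         n_perm=9, seed=1).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_skbio_mantel_statistic(self):
        # independent oracle for the correlation statistic
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(74)
        x = rng.uniform(size=(8, 2))
        y = x + rng.normal(0, 0.2, size=(8, 2))
        base1 = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        base2 = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
        labels = [f"a{i}" for i in range(8)]
        ours = mantel_test(DistanceMatrix(labels, base1),
                           DistanceMatrix(labels, base2), n_perm=999, seed=2)
        theirs_r, theirs_p, _ = skbio_mantel(
            SkbioDM(base1, ids=labels), SkbioDM(base2, ids=labels),
            method="pearson", permutations=999, alternative="greater")
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-9)
        assert ours.p_value == pytest.approx(float(theirs_p), abs=0.03)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(75)
        x = rng.uniform(size=(6, 2))
        y = rng.uniform(size=(6, 2))
        b1 = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        b2 = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
        labels = [f"a{i}" for i in range(6)]
        p1 = mantel_test(DistanceMatrix(labels, b1), DistanceMatrix(labels, b2),
                         n_perm=99, seed=5).p_value
        p2 = mantel_test(DistanceMatrix(labels, b1), DistanceMatrix(labels, b2),
                         n_perm=99, seed=5).p_value
        assert p1 == p2

    def test_zero_variance_triangle_rejected(self):
        labels = ["a", "b", "c", "d"]
        ones = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            mantel_test(DistanceMatrix(labels, ones),
                        DistanceMatrix(labels, ones), n_perm=9)

    def test_density_export_pairs_triangles(self):
        labels = ["a", "b", "c"]
        m1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        out = distance_density_export(DistanceMatrix(labels, m1),
                                      DistanceMatrix(labels, 2 * m1),
                                      labels=("gen", "geo"))
        assert out["gen"].tolist() == [1, 2, 3]
        assert out["geo"].tolist() == [2, 4, 6]
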
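"""Isolation by distance: geographic and climatic distances and Mantel tests.

Geographic distances use the haversine great-circle formula with Earth
radius R = 6371 km. Climatic distances standardize each climate variable,
rotate to principal components and take Euclidean distances on the full
score space (which equals the Euclidean distance on the standardized
variables — the rotation is orthogonal; the PCA step mirrors common
practice and allows truncation). Association between distance matrices is
tested with the Mantel permutation test; the default is one-sided for a
positive correlation, matching the directional isolation-by-distance
hypothesis, with a two-sided alternative available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .distances import DistanceMatrix

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def haversine_matrix(points: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) for rows with valid coordinates.

    ``points`` needs columns accession_id, latitude, longitude; rows with
    missing coordinates are excluded (their ids are recorded in
    ``attrs['excluded']`` of the returned matrix values frame is not kept —
    exclusion list is attached to the DistanceMatrix as ``excluded``).
    """
    ok = points["latitude"].notna() & points["longitude"].notna()
    excluded = points.loc[~ok, "accession_id"].tolist()
    pts = points.loc[ok]
    lat = np.radians(pts["latitude"].to_numpy(dtype=float))
    lon = np.radians(pts["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(pts["accession_id"].tolist(), (d + d.T) / 2)
    dm.excluded = excluded  # type: ignore[attr-defined]
    return dm


def climate_distance(climate: pd.DataFrame,
                     n_components: int | None = None) -> DistanceMatrix:
    """Euclidean distances on standardized-climate principal-component scores.

    ``climate`` is indexed/keyed by ``accession_id`` with one column per
    climate variable. Incomplete rows are excluded; zero-variance variables
    are dropped with a record in ``dropped_variables``.
    """
    if "accession_id" in climate.columns:
        climate = climate.set_index("accession_id")
    if climate.shape[1] < 2:
        raise ValueError("need at least two climate variables")
    complete = climate.dropna()
    x = complete.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(complete.columns, keep) if not k]
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    k = n_components if n_components is not None else x.shape[1]
    scores = PCA(n_components=min(k, *x.shape)).fit_transform(x)
    d = squareform(pdist(scores))
    dm = DistanceMatrix([str(i) for i in complete.index], d)
    dm.dropped_variables = dropped  # type: ignore[attr-defined]
    dm.excluded = [str(i) for i in climate.index.difference(complete.index)]  # type: ignore[attr-defined]
    return dm


@dataclass
class MantelResult:
    r: float
    p_value: float
    n: int          # matrix dimension used
    n_perm: int
    alternative: str = "greater"


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix,
                n_perm: int = 1000, seed: int | None = None,
                alternative: str = "greater") -> MantelResult:
    """Mantel correlation between two distance matrices over shared labels.

    r is the Pearson correlation of the upper triangles; the null permutes
    the rows and columns of the second matrix simultaneously. The add-one
    estimator gives p = (1 + #{extreme}) / (n_perm + 1); "greater" counts
    permuted r >= observed, "two-sided" counts |permuted| >= |observed|.
    """
    common = [l for l in d1.labels if l in set(d2.labels)]
    if len(common) < 4:
        raise ValueError("need at least 4 shared labels")
    m1 = d1.submatrix(common).values
    m2 = d2.submatrix(common).values
    n = len(common)
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if v1.std() == 0 or m2[iu].std() == 0:
        raise ValueError("zero-variance distance triangle; r undefined")
    obs = float(np.corrcoef(v1, m2[iu])[0, 1])
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mp = m2[np.ix_(perm, perm)]
        r = np.corrcoef(v1, mp[iu])[0, 1]
        if alternative == "greater":
            extreme = r >= obs
        elif alternative == "two-sided":
            extreme = abs(r) >= abs(obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        if extreme:
            n_extreme += 1
    p = (1.0 + n_extreme) / (n_perm + 1.0)
    return MantelResult(obs, p, n, n_perm, alternative)


def distance_density_export(d1: DistanceMatrix, d2: DistanceMatrix,
                            labels: tuple[str, str] = ("d1", "d2")) -> pd.DataFrame:
    """Long-format paired upper-triangle distances for 2-D density plotting."""
    common = [l for l in d1.labels if l in set(d2.labels)]
    iu = np.triu_indices(len(common), k=1)
    return pd.DataFrame({
        labels[0]: d1.submatrix(common).values[iu],
        labels[1]: d2.submatrix(common).values[iu],
    })
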
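"""smartPCA-style standardized genotype PCA and hierarchical classification.

Each marker column is centred on its mean dosage mu and divided by
sqrt(p(1-p)) with p = mu/2, the expected binomial standard deviation under
drift — the normalization of Patterson-style eigenanalysis. Missing entries
are set to zero after centring (the column mean), monomorphic markers are
dropped, and the accession covariance is eigendecomposed.

The three-level classification runs a PCA on all accessions, clusters the
leading components with k-means, then recurses into each cluster for group
and subgroup levels. An accession whose nearest-to-second-nearest centroid
distance ratio exceeds the mixture threshold lies between clusters and is
flagged as a mixture at that level; mixtures are excluded from deeper levels.
Externally supplied label files may replace the clustering at any level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genotypes import MISSING, Classification, GenotypeMatrix


@dataclass
class PcaResult:
    scores: np.ndarray          # accessions x components
    eigenvalues: np.ndarray     # non-increasing, non-negative
    variance_fraction: np.ndarray
    accessions: list[str]
    n_markers_used: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.accessions, columns=cols)


def standardized_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Eigendecomposition of drift-standardized dosages."""
    if matrix.n_accessions < 2:
        raise ValueError("need at least two accessions")
    x = matrix.calls.astype(float)
    x[matrix.calls == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    p = mu / 2.0
    sd = np.sqrt(p * (1.0 - p))
    poly = sd > 0
    if not poly.any():
        raise ValueError("all markers monomorphic")
    x = (x[:, poly] - mu[poly]) / sd[poly]
    x[np.isnan(x)] = 0.0
    n = x.shape[0]
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, n)
    scores = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    total = evals.sum()
    varfrac = evals[:k] / total if total > 0 else np.zeros(k)
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PcaResult(scores, evals[:k], varfrac, list(matrix.accessions),
                     int(poly.sum()))


@dataclass
class LevelConfig:
    """One level of the hierarchical classification.

    ``n_clusters`` may be an int applied to every parent cluster or a mapping
    parent-label -> int; ``labels`` (accession_id -> label) bypasses
    clustering entirely, so a published classification can be injected.
    """

    n_clusters: int | dict[str, int] = 2
    n_pcs: int = 2
    labels: dict[str, str] | None = None


@dataclass
class HierarchicalConfig:
    levels: list[LevelConfig]
    mixture_threshold: float = 0.8
    min_cluster_size: int = 5
    seed: int = 0


def _cluster_level(matrix: GenotypeMatrix, members: list[str], k: int,
                   n_pcs: int, mixture_threshold: float, seed: int):
    """K-means on leading PCs; returns (labels array of int, mixture mask)."""
    sub = matrix.subset(accession_ids=members)
    pca = standardized_pca(sub, n_components=n_pcs)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(pca.scores)
    centroids = km.cluster_centers_
    dist = np.linalg.norm(pca.scores[:, None, :] - centroids[None, :, :], axis=2)
    part = np.partition(dist, 1, axis=1)
    nearest, second = part[:, 0], part[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        margin = np.where(second > 0, nearest / second, 0.0)
    mixture = margin > mixture_threshold
    return assign, mixture


def classify_hierarchical(matrix: GenotypeMatrix,
                          config: HierarchicalConfig) -> Classification:
    """Three-level nested classification with mixture detection.

    Nesting is strict: each level re-runs PCA + k-means inside every parent
    cluster of sufficient size; accessions flagged as mixtures at a level
    keep their labels above it and none below.
    """
    if len(config.levels) != 3:
        raise ValueError("expected exactly three levels (species, group, subgroup)")
    acc = list(matrix.accessions)
    table = pd.DataFrame({"accession_id": acc, "species": "", "group": "",
                          "subgroup": "", "is_mixture": False})
    table = table.set_index("accession_id")

    level_names = list(Classification.LEVELS)
    # parents: list of (parent_label_path, member ids)
    parents: list[tuple[str, list[str]]] = [("", acc)]
    for depth, (level_cfg, level_name) in enumerate(zip(config.levels, level_names)):
        next_parents: list[tuple[str, list[str]]] = []
        for parent_label, members in parents:
            members = [m for m in members if not table.loc[m, "is_mixture"]]
            if len(members) < max(config.min_cluster_size, 2):
                # too small to subdivide: inherit the parent label downward
                for m in members:
                    table.loc[m, level_name] = parent_label
                if parent_label:
                    next_parents.append((parent_label, members))
                continue
            if level_cfg.labels is not None:
                lab = {m: level_cfg.labels.get(m, "") for m in members}
                for m, l in lab.items():
                    table.loc[m, level_name] = l
                    if l == "":
                        table.loc[m, "is_mixture"] = True
                for l in sorted(set(lab.values()) - {""}):
                    next_parents.append((l, [m for m in members if lab[m] == l]))
                continue
            k = level_cfg.n_clusters
            if isinstance(k, dict):
                k = k.get(parent_label, 1)
            k = min(k, len(members))
            if k <= 1:
                label = parent_label if parent_label else "all"
                for m in members:
                    table.loc[m, level_name] = label
                next_parents.append((label, members))
                continue
            assign, mixture = _cluster_level(
                matrix, members, k, level_cfg.n_pcs,
                config.mixture_threshold, config.seed + depth)
            # stable cluster naming: order clusters by their smallest member index
            order = {}
            for ci in range(k):
                idx = [i for i, a in enumerate(assign) if a == ci]
                order[ci] = min(idx) if idx else len(members)
            rank = {ci: r for r, ci in
                    enumerate(sorted(order, key=lambda c: order[c]))}
            prefix = f"{parent_label}." if parent_label else ""
            for m, a, mix in zip(members, assign, mixture):
                if mix:
                    table.loc[m, "is_mixture"] = True
                else:
                    table.loc[m, level_name] = f"{prefix}{rank[a] + 1}"
            for ci in range(k):
                label = f"{prefix}{rank[ci] + 1}"
                sub_members = [m for m, a, mix in zip(members, assign, mixture)
                               if a == ci and not mix]
                if sub_members:
                    next_parents.append((label, sub_members))
        parents = next_parents

    table = table.reset_index()
    # mixture accessions carry no labels below their flag level
    mix = table["is_mixture"].astype(bool)
    table.loc[mix, "subgroup"] = ""
    return Classification(table)
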
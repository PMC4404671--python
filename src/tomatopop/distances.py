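"""Kosman–Leonard allele-sharing distances between diploid genotypes.

For two diploid biallelic genotypes coded as reference-allele dosage the
per-locus dissimilarity is one minus the fraction of shared alleles,

    d(x, y) = |x - y| / 2,

so identical homozygotes or identical heterozygotes score 0, a homozygote vs
the opposite homozygote scores 1, and any pair one allele apart scores 0.5.
The pairwise distance is the mean over loci where both calls are observed
(pairwise-complete loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, Classification, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(self.values)), initial=0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("negative distances")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels) \
            .to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def kosman_leonard_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """Kosman–Leonard distance between two dosage vectors over shared
    non-missing loci; NaN when no locus is informative."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must cover the same markers")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        return float("nan")
    return float(np.abs(g1[ok] - g2[ok]).mean() / 2.0)


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """All pairwise Kosman–Leonard distances.

    Uses dosage-indicator matrix products so the cost is a handful of BLAS
    calls rather than a Python loop over accession pairs. Pairs with no
    shared informative locus come out NaN.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least two accessions")
    x = matrix.calls
    obs = (x != MISSING)
    ind = [(x == d).astype(np.float32) for d in (0, 1, 2)]
    # sum over loci of |xi - xj|: |0-1|=|1-2|=1, |0-2|=2
    cross = lambda a, b: ind[a] @ ind[b].T
    num = (cross(0, 1) + cross(1, 0) + cross(1, 2) + cross(2, 1)
           + 2.0 * (cross(0, 2) + cross(2, 0)))
    counts = obs.astype(np.float32) @ obs.astype(np.float32).T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(counts > 0, num / counts / 2.0, np.nan)
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # kill float32 rounding asymmetry
    return DistanceMatrix(list(matrix.accessions), d)


def _within_class_distances(dist: DistanceMatrix,
                            classes: dict[str, list[str]]) -> np.ndarray:
    pools = []
    index = {l: i for i, l in enumerate(dist.labels)}
    for members in classes.values():
        idx = [index[m] for m in members if m in index]
        if len(idx) < 2:
            continue
        sub = dist.values[np.ix_(idx, idx)]
        pools.append(sub[np.triu_indices(len(idx), k=1)])
    if not pools:
        return np.array([])
    pooled = np.concatenate(pools)
    return pooled[~np.isnan(pooled)]


def hierarchy_distance_summary(
    dist: DistanceMatrix,
    classes: Classification,
    replicate_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pooled within-class distance distributions per hierarchy level.

    Returns one row per level (species, group, subgroup and, when replicate
    groups are supplied, replicate) with n pairs, median and quartiles. The
    expected nesting pattern — medians non-increasing from species down to
    replicates — is attached as the boolean column ``ordering_ok`` on every
    row.
    """
    rows = []
    level_specs: list[tuple[str, dict[str, list[str]]]] = [
        (level, classes.groups_at(level)) for level in Classification.LEVELS
    ]
    if replicate_groups:
        level_specs.append(("replicate", dict(replicate_groups)))
    medians = []
    for level, groups in level_specs:
        pooled = _within_class_distances(dist, groups)
        if pooled.size == 0:
            rows.append({"level": level, "n_pairs": 0, "q25": np.nan,
                         "median": np.nan, "q75": np.nan})
            medians.append(np.nan)
            continue
        q25, med, q75 = np.percentile(pooled, [25, 50, 75])
        rows.append({"level": level, "n_pairs": pooled.size,
                     "q25": q25, "median": med, "q75": q75})
        medians.append(med)
    valid = [m for m in medians if not np.isnan(m)]
    ordering_ok = all(a >= b - 1e-12 for a, b in zip(valid, valid[1:]))
    out = pd.DataFrame(rows)
    out["ordering_ok"] = ordering_ok
    return out


def within_class_pool(dist: DistanceMatrix,
                      classes: dict[str, list[str]]) -> np.ndarray:
    """Long-format pooled within-class distances (for violin-style exports)."""
    return _within_class_distances(dist, classes)
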
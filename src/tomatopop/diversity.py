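"""Per-group diversity statistics: observed/expected heterozygosity and P95.

For a biallelic locus with reference-allele frequency p estimated from the
non-missing calls of a group, expected heterozygosity is H_e = 2p(1-p) and
observed heterozygosity is the fraction of non-missing genotypes that are
heterozygous (dosage 1). Group values are unweighted means over loci with at
least one non-missing call. P95 is the fraction of those loci whose
major-allele frequency within the group is below 0.95 — a within-group
polymorphism rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, Classification, GenotypeMatrix


@dataclass
class LocusDiversity:
    """Per-locus p, H_e, H_o arrays for one group (NaN where no data)."""

    p: np.ndarray
    he: np.ndarray
    ho: np.ndarray
    n_obs: np.ndarray


def locus_diversity(calls: np.ndarray, unbiased: bool = False) -> LocusDiversity:
    """Allele frequency, H_e and H_o per locus over the rows of ``calls``.

    ``unbiased`` applies the small-sample correction 2N/(2N-1) to H_e.
    """
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    dose = np.where(obs, calls, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose.sum(axis=0) / (2 * n), np.nan)
        he = 2.0 * p * (1.0 - p)
        if unbiased:
            he = np.where(n > 0, he * (2 * n) / np.maximum(2 * n - 1, 1), np.nan)
        ho = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    return LocusDiversity(p=p, he=he, ho=ho, n_obs=n.astype(int))


def group_diversity(matrix: GenotypeMatrix,
                    groups: dict[str, list[str]] | Classification,
                    level: str = "group",
                    min_group_size: int = 5,
                    p95_threshold: float = 0.95,
                    unbiased: bool = False) -> pd.DataFrame:
    """Table-2-style summary: one row per group with N, H_o, H_e and P95.

    ``groups`` is either a mapping label -> accession ids or a
    :class:`Classification`, in which case labels at ``level`` are used and
    mixture accessions/groups are excluded. Groups smaller than
    ``min_group_size`` are omitted. A group with zero informative loci is
    reported with NaN statistics.
    """
    if isinstance(groups, Classification):
        groups = groups.groups_at(level)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        if len(members) < min_group_size:
            continue
        sub = matrix.subset(accession_ids=members)
        ld = locus_diversity(sub.calls, unbiased=unbiased)
        informative = ld.n_obs > 0
        if not informative.any():
            rows.append({"group": label, "N": len(members), "H_o": np.nan,
                         "H_e": np.nan, "P95": np.nan, "n_loci": 0})
            continue
        major = np.maximum(ld.p[informative], 1 - ld.p[informative])
        rows.append({
            "group": label,
            "N": len(members),
            "H_o": float(np.mean(ld.ho[informative])),
            "H_e": float(np.mean(ld.he[informative])),
            "P95": float(np.mean(major < p95_threshold)),
            "n_loci": int(informative.sum()),
        })
    return pd.DataFrame(rows, columns=["group", "N", "H_o", "H_e", "P95", "n_loci"])


def write_diversity_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
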
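"""Three-stage marker selection: missingness, major-allele frequency, cM thinning.

The cascade mirrors the order in which array QC is usually narrated: first
drop markers with poor call rates (more than ``max_missing_fraction`` missing,
strict inequality), then near-monomorphic markers (major-allele frequency
strictly above ``max_major_freq``), then thin by genetic-map distance so no
two retained markers on a chromosome sit closer than ``min_cm``. Thinning is
a deterministic greedy left-to-right scan per chromosome; ties at identical
positions keep the first marker in input order.

Two marker sets are first-class outputs of :func:`select_markers`: the fully
thinned set (default for structure/diversity/distance analyses) and the
all-polymorphic set (missingness + MAF only), which rarefaction and LD use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

REASON_RETAINED = "retained"
REASON_MISSING = "missingness"
REASON_MAF = "major-allele-frequency"
REASON_THIN = "thinned"
REASON_NO_DATA = "no data"
REASON_UNMAPPED = "unmapped"


@dataclass
class FilterReport:
    """Accounting of a filter stage (or cascade); totals reconcile exactly."""

    n_input: int
    reasons: pd.DataFrame  # columns: marker, reason

    @property
    def n_retained(self) -> int:
        return int((self.reasons["reason"] == REASON_RETAINED).sum())

    def n_removed(self, reason: str) -> int:
        return int((self.reasons["reason"] == reason).sum())

    @property
    def counts(self) -> dict[str, int]:
        c = self.reasons["reason"].value_counts().to_dict()
        c["n_input"] = self.n_input
        return c

    def to_tsv(self, path: str | Path) -> None:
        self.reasons.to_csv(path, sep="\t", index=False)


def _report(matrix: GenotypeMatrix, removed: dict[str, str]) -> FilterReport:
    reasons = pd.DataFrame({
        "marker": matrix.marker_ids,
        "reason": [removed.get(m, REASON_RETAINED) for m in matrix.marker_ids],
    })
    return FilterReport(matrix.n_markers, reasons)


def filter_missingness(matrix: GenotypeMatrix,
                       max_missing_fraction: float = 0.10
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers whose missing fraction is strictly above the threshold."""
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    if matrix.n_markers == 0 or matrix.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    frac = matrix.missing_fraction_per_marker()
    drop = frac > max_missing_fraction
    removed = {m: REASON_MISSING for m, d in zip(matrix.marker_ids, drop) if d}
    return matrix.subset(marker_mask=~drop), _report(matrix, removed)


def filter_major_allele(matrix: GenotypeMatrix,
                        max_major_freq: float = 0.95
                        ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers whose major-allele frequency is strictly above the
    threshold; markers with no data at all are removed with reason "no data".
    """
    p = matrix.allele_frequencies()
    no_data = np.isnan(p)
    with np.errstate(invalid="ignore"):
        major = np.maximum(p, 1.0 - p)
        drop = major > max_major_freq
    removed = {}
    for m, nd, d in zip(matrix.marker_ids, no_data, drop):
        if nd:
            removed[m] = REASON_NO_DATA
        elif d:
            removed[m] = REASON_MAF
    keep = ~(no_data | np.where(np.isnan(major), False, drop))
    return matrix.subset(marker_mask=keep), _report(matrix, removed)


def thin_by_map(matrix: GenotypeMatrix, min_cm: float = 0.1
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy per-chromosome thinning: scanning markers in map order, keep a
    marker iff it lies at least ``min_cm`` from the last kept marker.

    Markers lacking a map position are excluded with reason "unmapped".
    With ``min_cm = 0`` thinning is the identity on mapped markers.
    """
    if min_cm < 0:
        raise ValueError("min_cm must be non-negative")
    pos = matrix.markers["position_cm"].to_numpy(dtype=float)
    chrom = matrix.markers["chromosome"].to_numpy(dtype=object)
    unmapped = np.isnan(pos) | (chrom == "")
    keep = np.zeros(matrix.n_markers, dtype=bool)
    for c in pd.unique(chrom[~unmapped]):
        idx = np.flatnonzero((chrom == c) & ~unmapped)
        order = idx[np.argsort(pos[idx], kind="stable")]  # stable = input-order ties
        last = -np.inf
        for j in order:
            if pos[j] - last >= min_cm:
                keep[j] = True
                last = pos[j]
    removed = {}
    for m, um, k in zip(matrix.marker_ids, unmapped, keep):
        if um:
            removed[m] = REASON_UNMAPPED
        elif not k:
            removed[m] = REASON_THIN
    return matrix.subset(marker_mask=keep), _report(matrix, removed)


@dataclass
class MarkerSets:
    """The two marker sets the analyses run on."""

    thinned: GenotypeMatrix
    all_polymorphic: GenotypeMatrix
    cascade: pd.DataFrame  # stage, n_input, n_removed, n_retained


def select_markers(matrix: GenotypeMatrix,
                   max_missing_fraction: float = 0.10,
                   max_major_freq: float = 0.95,
                   min_cm: float = 0.1) -> MarkerSets:
    """Run the full cascade and return both marker sets with stage accounting."""
    m1, r1 = filter_missingness(matrix, max_missing_fraction)
    m2, r2 = filter_major_allele(m1, max_major_freq)
    m3, r3 = thin_by_map(m2, min_cm)
    cascade = pd.DataFrame([
        {"stage": "missingness", "n_input": r1.n_input,
         "n_removed": r1.n_input - r1.n_retained, "n_retained": r1.n_retained},
        {"stage": "major-allele", "n_input": r2.n_input,
         "n_removed": r2.n_input - r2.n_retained, "n_retained": r2.n_retained},
        {"stage": "thinning", "n_input": r3.n_input,
         "n_removed": r3.n_input - r3.n_retained, "n_retained": r3.n_retained},
    ])
    return MarkerSets(thinned=m3, all_polymorphic=m2, cascade=cascade)
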
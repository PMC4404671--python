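"""Cross-laboratory strand harmonization, dataset merging and replicate QC.

Illumina arrays report calls relative to different strand conventions
(reference, design or TOP). Merging datasets therefore requires detecting,
per shared marker, whether one laboratory's allele pair is the reverse
complement of another's and relabelling accordingly. Dosages are never
altered by a pure strand flip — only allele labels change; a swapped allele
order additionally recodes dosage d -> 2 - d so every dataset counts copies
of the same physical allele.

A/T and C/G markers equal their own complement, so labels alone cannot orient
them. For those we run a frequency-concordance test: the orientation whose
reference-allele frequency is closer to the anchor dataset's frequency wins,
and if the two orientations are nearly equally plausible (margin below
``ambiguous_margin``) the marker is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import kosman_leonard_pair
from .genotypes import (MISSING, GenotypeMatrix, complement_alleles,
                        is_strand_ambiguous)

ACTION_KEPT = "kept"
ACTION_FLIPPED = "flipped"
ACTION_AMBIGUOUS = "ambiguous-resolved"
ACTION_DROPPED = "dropped"


@dataclass
class MergeReport:
    actions: pd.DataFrame  # columns: marker, action, detail

    def count(self, action: str) -> int:
        return int((self.actions["action"] == action).sum())


def _orient_against(anchor: tuple[str, str], other: tuple[str, str]):
    """Classify ``other`` relative to ``anchor``.

    Returns (new_pair, flip_dosage, action) or None when incompatible.
    """
    if other == anchor:
        return anchor, False, ACTION_KEPT
    if other == anchor[::-1]:
        return anchor, True, ACTION_FLIPPED
    comp = complement_alleles(other)
    if comp == anchor:
        return anchor, False, ACTION_FLIPPED
    if comp == anchor[::-1]:
        return anchor, True, ACTION_FLIPPED
    return None


def harmonize_and_merge(
    datasets: list[GenotypeMatrix],
    ambiguous_margin: float = 0.2,
) -> tuple[GenotypeMatrix, MergeReport]:
    """Merge genotype datasets onto a common strand orientation.

    The first dataset containing a marker anchors its orientation. Markers
    whose allele pairs are neither identical nor (reverse-)complementary to
    the anchor are dropped. Accessions appearing in more than one dataset
    keep one row per (accession, dataset), tagged ``id@dsK``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to merge")
    marker_ids: list[str] = []
    seen = set()
    for ds in datasets:
        for mid in ds.marker_ids:
            if mid not in seen:
                seen.add(mid)
                marker_ids.append(mid)
    shared = set.intersection(*(set(ds.marker_ids) for ds in datasets))
    if not shared:
        raise ValueError("datasets share no marker ids")

    anchor_rows: dict[str, pd.Series] = {}
    anchor_ds: dict[str, int] = {}
    for k, ds in enumerate(datasets):
        for _, row in ds.markers.iterrows():
            if row["id"] not in anchor_rows:
                anchor_rows[row["id"]] = row
                anchor_ds[row["id"]] = k

    acc_count: dict[str, int] = {}
    for ds in datasets:
        for a in ds.accessions:
            acc_count[a] = acc_count.get(a, 0) + 1

    actions: list[dict] = []
    dropped: set[str] = set()
    oriented: list[np.ndarray] = []
    row_labels: list[str] = []

    # per-dataset orientation decision for every marker it carries
    per_ds_cols: list[dict[str, np.ndarray]] = []
    for k, ds in enumerate(datasets):
        cols: dict[str, np.ndarray] = {}
        freqs = ds.allele_frequencies()
        for j, (_, row) in enumerate(ds.markers.iterrows()):
            mid = row["id"]
            anchor = anchor_rows[mid]
            a_pair = (anchor["allele_a"], anchor["allele_b"])
            o_pair = (row["allele_a"], row["allele_b"])
            col = ds.calls[:, j]
            if mid in dropped:
                continue
            if is_strand_ambiguous(a_pair):
                if o_pair not in (a_pair, a_pair[::-1]):
                    dropped.add(mid)
                    actions.append({"marker": mid, "action": ACTION_DROPPED,
                                    "detail": "allele pairs incompatible"})
                    continue
                if k == anchor_ds[mid]:  # anchor dataset: as-is
                    cols[mid] = col
                    continue
                # frequency-concordance test against the anchor dataset
                ads = datasets[anchor_ds[mid]]
                p_anchor = ads.allele_frequencies()[ads.marker_ids.index(mid)]
                p_here = freqs[j]
                if np.isnan(p_anchor) or np.isnan(p_here):
                    dropped.add(mid)
                    actions.append({"marker": mid, "action": ACTION_DROPPED,
                                    "detail": "strand-ambiguous, no frequency data"})
                    continue
                as_is = abs(p_here - p_anchor)
                flip = abs((1.0 - p_here) - p_anchor)
                margin = abs(as_is - flip)
                if margin < ambiguous_margin:
                    dropped.add(mid)
                    actions.append({"marker": mid, "action": ACTION_DROPPED,
                                    "detail": f"strand-ambiguous, margin {margin:.3f}"})
                    continue
                if flip < as_is:
                    col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
                actions.append({"marker": mid, "action": ACTION_AMBIGUOUS,
                                "detail": f"margin {margin:.3f}"})
                cols[mid] = col
                continue
            res = _orient_against(a_pair, o_pair)
            if res is None:
                dropped.add(mid)
                actions.append({"marker": mid, "action": ACTION_DROPPED,
                                "detail": f"{o_pair} incompatible with {a_pair}"})
                continue
            _, flip_dosage, action = res
            if flip_dosage:
                col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
            if action != ACTION_KEPT or flip_dosage:
                actions.append({"marker": mid, "action": ACTION_FLIPPED,
                                "detail": f"{o_pair} -> {a_pair}"})
            cols[mid] = col
        per_ds_cols.append(cols)

    kept_ids = [m for m in marker_ids if m not in dropped]
    acted = {a["marker"] for a in actions}
    for mid in kept_ids:
        if mid not in acted:
            actions.append({"marker": mid, "action": ACTION_KEPT, "detail": ""})

    for k, ds in enumerate(datasets):
        n = ds.n_accessions
        block = np.full((n, len(kept_ids)), MISSING, dtype=np.int8)
        for c, mid in enumerate(kept_ids):
            if mid in per_ds_cols[k]:
                block[:, c] = per_ds_cols[k][mid]
        oriented.append(block)
        for a in ds.accessions:
            row_labels.append(f"{a}@ds{k}" if acc_count[a] > 1 else a)

    if kept_ids:
        markers = pd.DataFrame([anchor_rows[m] for m in kept_ids]) \
            .reset_index(drop=True)
    else:
        markers = pd.DataFrame(columns=["id", "chromosome", "position_cm",
                                        "allele_a", "allele_b"])
    merged = GenotypeMatrix(np.vstack(oriented), row_labels, markers)
    report = MergeReport(pd.DataFrame(actions, columns=["marker", "action", "detail"])
                         .sort_values("marker").reset_index(drop=True))
    return merged, report


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

@dataclass
class ReplicateReport:
    """Per replicate group: mean pairwise distance, flag, chosen representative."""

    summary: pd.DataFrame
    flagged: list[str] = field(default_factory=list)
    representatives: dict[str, str] = field(default_factory=dict)


def replicate_concordance(
    matrix: GenotypeMatrix,
    replicate_groups: dict[str, list[str]],
    threshold: float = 0.05,
    seed: int | None = None,
) -> ReplicateReport:
    """Check genotyping reproducibility across repeated samples.

    For each group of samples of the same uniquely named accession, computes
    the mean pairwise Kosman–Leonard distance; groups whose mean exceeds
    ``threshold`` are flagged as inconsistent (candidates for removal). For
    downstream analysis one representative per group is drawn with the seeded
    RNG. Singleton groups have an undefined distance (NaN) and trivially keep
    their only member.
    """
    rng = np.random.default_rng(seed)
    rows = []
    flagged: list[str] = []
    reps: dict[str, str] = {}
    lookup = {a: i for i, a in enumerate(matrix.accessions)}
    for name, members in replicate_groups.items():
        unknown = [m for m in members if m not in lookup]
        if unknown:
            raise ValueError(f"replicate group {name!r}: unknown accessions {unknown}")
        reps[name] = members[int(rng.integers(len(members)))]
        if len(members) < 2:
            rows.append({"group": name, "n": len(members),
                         "mean_distance": np.nan, "flagged": False,
                         "note": "singleton; distance undefined"})
            continue
        dists = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                dists.append(kosman_leonard_pair(
                    matrix.calls[lookup[members[i]]],
                    matrix.calls[lookup[members[j]]]))
        mean_d = float(np.nanmean(dists)) if dists else float("nan")
        flag = bool(mean_d > threshold)
        if flag:
            flagged.append(name)
        rows.append({"group": name, "n": len(members),
                     "mean_distance": mean_d, "flagged": flag, "note": ""})
    summary = pd.DataFrame(rows, columns=["group", "n", "mean_distance",
                                          "flagged", "note"])
    return ReplicateReport(summary, flagged, reps)


def deduplicate(matrix: GenotypeMatrix,
                replicate_groups: dict[str, list[str]],
                seed: int | None = None,
                drop_flagged: bool = True,
                threshold: float = 0.05) -> tuple[GenotypeMatrix, ReplicateReport]:
    """Retain one seeded-random representative per uniquely named accession,
    dropping flagged (inconsistent) groups entirely when ``drop_flagged``."""
    report = replicate_concordance(matrix, replicate_groups, threshold, seed)
    in_groups = {m for members in replicate_groups.values() for m in members}
    keep: list[str] = [a for a in matrix.accessions if a not in in_groups]
    for name, rep in report.representatives.items():
        if drop_flagged and name in report.flagged:
            continue
        keep.append(rep)
    keep_order = [a for a in matrix.accessions if a in set(keep)]
    return matrix.subset(accession_ids=keep_order), report
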
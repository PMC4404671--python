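"""Linkage-disequilibrium decay: within-chromosome pairwise r² and LOESS fits.

r² is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete accessions (the composite / Rogers–Huff convention —
what TASSEL computes on unphased genotypes). Distances come from the genetic
map in cM by default; a physical-position mode is available when the marker
table carries a ``position_bp`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genotypes import MISSING, GenotypeMatrix


def pairwise_r2(matrix: GenotypeMatrix,
                accession_ids: list[str] | None = None,
                min_obs: int = 4,
                position: str = "position_cm",
                max_pairs_per_chrom: int | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """All within-chromosome marker-pair r² values for an accession subset.

    Pairs with fewer than ``min_obs`` pairwise-complete calls or with either
    marker monomorphic in the subset are skipped (counted in ``attrs``).
    ``max_pairs_per_chrom`` subsamples pairs (seeded) to bound output size.
    """
    sub = matrix if accession_ids is None else matrix.subset(accession_ids)
    pos = sub.markers[position].to_numpy(dtype=float)
    chrom = sub.markers["chromosome"].to_numpy(dtype=object)
    ids = np.array(sub.marker_ids, dtype=object)
    mapped = ~np.isnan(pos) & (chrom != "")
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    for c in pd.unique(chrom[mapped]):
        idx = np.flatnonzero((chrom == c) & mapped)
        if len(idx) < 2:
            continue
        pairs = [(i, j) for a, i in enumerate(idx) for j in idx[a + 1:]]
        if max_pairs_per_chrom is not None and len(pairs) > max_pairs_per_chrom:
            chosen = rng.choice(len(pairs), size=max_pairs_per_chrom,
                                replace=False)
            pairs = [pairs[k] for k in sorted(chosen)]
        for i, j in pairs:
            gi = sub.calls[:, i]
            gj = sub.calls[:, j]
            ok = (gi != MISSING) & (gj != MISSING)
            if ok.sum() < min_obs:
                n_skipped += 1
                continue
            x = gi[ok].astype(float)
            y = gj[ok].astype(float)
            if x.std() == 0 or y.std() == 0:
                n_skipped += 1
                continue
            r = np.corrcoef(x, y)[0, 1]
            rows.append({"marker1": ids[i], "marker2": ids[j],
                         "chromosome": c,
                         "distance_cm": abs(pos[i] - pos[j]),
                         "r2": float(r * r),
                         "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["marker1", "marker2", "chromosome",
                                      "distance_cm", "r2", "n"])
    out.attrs["n_skipped"] = n_skipped
    return out


def loess_decay(points: pd.DataFrame, span: float = 0.3,
                grid: np.ndarray | None = None) -> pd.DataFrame:
    """Tricube-weighted local linear fit of r² against distance.

    Returns fitted values on ``grid`` (default: 50 points spanning the
    observed distances), clipped to [0, 1]. Input order does not affect the
    fit.
    """
    if len(points) < 10:
        raise ValueError("need at least 10 LD points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = points["distance_cm"].to_numpy(dtype=float)
    y = points["r2"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all distances identical; cannot fit a decay curve")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, dtype=float)
    fitted = lowess(y, x, frac=span, it=0, xvals=grid)
    return pd.DataFrame({"distance_cm": grid,
                         "r2_fit": np.clip(fitted, 0.0, 1.0),
                         "span": span})


def ld_decay_by_group(matrix: GenotypeMatrix,
                      groups: dict[str, list[str]],
                      span: float = 0.3,
                      max_pairs_per_chrom: int | None = 2000,
                      seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group LD points and fitted decay curves on a shared grid."""
    all_points = []
    curves = []
    rng = np.random.default_rng(seed)
    for label in sorted(groups):
        pts = pairwise_r2(matrix, groups[label],
                          max_pairs_per_chrom=max_pairs_per_chrom,
                          seed=int(rng.integers(2 ** 31)))
        if pts.empty:
            continue
        pts = pts.assign(group=label)
        all_points.append(pts)
        if len(pts) >= 10 and np.ptp(pts["distance_cm"].to_numpy()) > 0:
            curve = loess_decay(pts, span=span)
            curves.append(curve.assign(group=label))
    points_df = pd.concat(all_points, ignore_index=True) if all_points \
        else pd.DataFrame()
    curves_df = pd.concat(curves, ignore_index=True) if curves \
        else pd.DataFrame()
    return points_df, curves_df
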
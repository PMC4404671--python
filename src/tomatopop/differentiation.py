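"""Group differentiation: Jost's D_est, Weir–Cockerham theta, permutation
significance, and neighbor-joining trees with locus-bootstrap support.

Jost's D per locus is

    D = [(H_T - H_S) / (1 - H_S)] * [n / (n - 1)],

with H_S and H_T estimated by the Nei–Chesser small-sample estimators built
on the harmonic-mean group size ñ and the observed heterozygosity:

    H_S = ñ/(ñ-1) * (h_s - H_o/(2ñ)),          h_s = mean_k 2 p_k q_k
    H_T = h_t + H_S/(ñ n) - H_o/(2 ñ n),       h_t = 2 p̄ q̄, p̄ = mean_k p_k

The multi-locus D_est is the arithmetic mean of per-locus D over loci that
are polymorphic in the pooled sample (a harmonic-mean aggregate is available
behind a flag). F_st uses the Weir–Cockerham variance components a (among
groups), b (among individuals within groups) and c (within individuals),
aggregated as the ratio of sums theta = sum(a) / sum(a+b+c).

Negative estimates are reported as computed; they are clamped at zero only
when a differentiation matrix feeds the neighbor-joining tree, which needs
non-negative distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Per-group locus statistics
# ---------------------------------------------------------------------------

def _group_locus_stats(matrix: GenotypeMatrix, groups: dict[str, list[str]]):
    """Per group x locus: non-missing sample size n, ref-allele freq p and
    observed heterozygosity h (fraction of hets)."""
    labels = sorted(groups)
    ns, ps, hs = [], [], []
    for lab in labels:
        sub = matrix.calls[matrix.accession_index(groups[lab])]
        obs = sub != MISSING
        n = obs.sum(axis=0).astype(float)
        dose = np.where(obs, sub, 0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, dose.sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return labels, np.array(ns), np.array(ps), np.array(hs)


def _included_loci(n: np.ndarray, p: np.ndarray, min_n: int = 2) -> np.ndarray:
    """Loci with >= min_n genotypes in every group and polymorphic pooled."""
    enough = (n >= min_n).all(axis=0)
    with np.errstate(invalid="ignore"):
        pooled_p = np.nansum(n * p, axis=0) / np.maximum(np.nansum(n, axis=0), 1)
    poly = (pooled_p > 0) & (pooled_p < 1)
    return enough & poly


def jost_dest_per_locus(matrix: GenotypeMatrix, groups: dict[str, list[str]],
                        corrected: bool = True) -> np.ndarray:
    """Per-locus Jost D over included loci (NaN elsewhere)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _, n, p, h = _group_locus_stats(matrix, groups)
    r = len(groups)
    ok = _included_loci(n, p)
    q = 1.0 - p
    hs_u = np.mean(2.0 * p * q, axis=0)
    pbar = np.mean(p, axis=0)
    ht_u = 2.0 * pbar * (1.0 - pbar)
    if corrected:
        with np.errstate(invalid="ignore", divide="ignore"):
            n_harm = r / np.sum(1.0 / n, axis=0)
            ho = np.mean(h, axis=0)
            hs = n_harm / (n_harm - 1.0) * (hs_u - ho / (2.0 * n_harm))
            ht = ht_u + hs / (n_harm * r) - ho / (2.0 * n_harm * r)
    else:
        hs, ht = hs_u, ht_u
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (ht - hs) / (1.0 - hs) * (r / (r - 1.0))
    d = np.where(ok & (np.abs(1.0 - hs) > 1e-12), d, np.nan)
    return d


def jost_dest(matrix: GenotypeMatrix, groups: dict[str, list[str]],
              corrected: bool = True, aggregate: str = "mean") -> float:
    """Multi-locus Jost D_est; NaN when no locus qualifies.

    ``aggregate``: "mean" (arithmetic mean of per-locus D, default) or
    "harmonic" (harmonic mean over loci with positive D).
    """
    d = jost_dest_per_locus(matrix, groups, corrected=corrected)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    if aggregate == "mean":
        return float(d.mean())
    if aggregate == "harmonic":
        pos = d[d > 0]
        if pos.size == 0:
            return 0.0
        return float(pos.size / np.sum(1.0 / pos))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def wc_fst_components(matrix: GenotypeMatrix, groups: dict[str, list[str]]):
    """Weir–Cockerham per-locus variance components (a, b, c).

    Monomorphic pooled loci and loci missing a group contribute NaN and are
    excluded from the ratio of sums.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _, n, p, h = _group_locus_stats(matrix, groups)
    r = float(len(groups))
    ok = _included_loci(n, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad = ~ok | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_fst(matrix: GenotypeMatrix, groups: dict[str, list[str]]) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of sums over loci)."""
    a, b, c = wc_fst_components(matrix, groups)
    ok = ~np.isnan(a)
    if not ok.any():
        return float("nan")
    denom = np.sum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return float("nan")
    return float(np.sum(a[ok]) / denom)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    n_redrawn: int = 0


def permutation_test(statistic: Callable[[GenotypeMatrix, dict], float],
                     matrix: GenotypeMatrix,
                     groups: dict[str, list[str]],
                     n_perm: int = 1000,
                     seed: int | None = None,
                     max_redraw: int = 100) -> PermutationResult:
    """Label-permutation null for a group statistic.

    Accession-to-group labels are shuffled holding group sizes fixed; the
    add-one p-value p = (1 + #{perm >= obs}) / (n_perm + 1) avoids zero.
    Permutations on which the statistic is undefined are redrawn (counted).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = statistic(matrix, groups)
    if np.isnan(observed):
        raise ValueError("statistic undefined on the observed grouping")
    rng = np.random.default_rng(seed)
    labels = sorted(groups)
    pool = np.concatenate([np.asarray(groups[l], dtype=object) for l in labels])
    sizes = [len(groups[l]) for l in labels]
    edges = np.cumsum([0] + sizes)
    n_ge = 0
    n_redrawn = 0
    for _ in range(n_perm):
        for _attempt in range(max_redraw + 1):
            perm = rng.permutation(pool)
            shuffled = {l: list(perm[edges[i]:edges[i + 1]])
                        for i, l in enumerate(labels)}
            stat = statistic(matrix, shuffled)
            if not np.isnan(stat):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("statistic undefined on too many permutations")
        if stat >= observed:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perm + 1.0)
    return PermutationResult(float(observed), p, n_perm, n_redrawn)


# ---------------------------------------------------------------------------
# Pairwise differentiation matrices
# ---------------------------------------------------------------------------

def pairwise_differentiation(matrix: GenotypeMatrix,
                             groups: dict[str, list[str]],
                             stat: str = "dest",
                             n_perm: int = 0,
                             seed: int | None = None) -> pd.DataFrame:
    """Long-format pairwise D_est or theta (optionally with permutation p)."""
    fn = {"dest": jost_dest, "fst": wc_fst}[stat]
    labels = sorted(groups)
    rng = np.random.default_rng(seed)
    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            pair = {gi: groups[gi], gj: groups[gj]}
            value = fn(matrix, pair)
            row = {"group1": gi, "group2": gj, "statistic": stat, "value": value}
            if n_perm > 0:
                res = permutation_test(fn, matrix, pair, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
                row["p_value"] = res.p_value
                row["n_perm"] = n_perm
            rows.append(row)
    return pd.DataFrame(rows)


def differentiation_matrix(pairwise: pd.DataFrame,
                           clamp_negative: bool = True) -> DistanceMatrix:
    """Square matrix from long-format pairwise values (for tree building)."""
    labels = sorted(set(pairwise["group1"]) | set(pairwise["group2"]))
    idx = {l: i for i, l in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for _, r in pairwise.iterrows():
        v = r["value"]
        if clamp_negative and v < 0:
            v = 0.0
        m[idx[r["group1"]], idx[r["group2"]]] = v
        m[idx[r["group2"]], idx[r["group1"]]] = v
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Minimal unrooted-tree node for NJ output and bootstrap annotation."""

    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])
        return frozenset().union(*(c.leaves() for c in self.children))

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk(ws) for c in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PopulationTree:
    root: TreeNode
    negative_branches_clamped: int = 0

    def newick(self, with_support: bool = False) -> str:
        # root itself carries no meaningful length
        inner = ",".join(c._nwk(with_support) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to its smaller side
        (ties broken lexicographically)."""
        all_leaves = self.root.leaves()
        splits: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for c in node.children:
                walk(c)
            if node.children and node is not self.root:
                side = node.leaves()
                other = all_leaves - side
                if 1 < len(side) < len(all_leaves) - 1:
                    splits.add(_canonical_split(side, other))
        walk(self.root)
        return splits

    def internal_nodes(self):
        out = []
        def walk(node: TreeNode) -> None:
            for c in node.children:
                walk(c)
            if node.children and node is not self.root:
                out.append(node)
        walk(self.root)
        return out


def _canonical_split(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return a if tuple(sorted(a)) < tuple(sorted(b)) else b


def neighbor_joining(dist: DistanceMatrix) -> PopulationTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lowest-index pair; negative branch lengths
    are clamped to zero and counted on the returned tree.
    """
    n0 = len(dist.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dist.values).all():
        raise ValueError("distance matrix has missing entries")
    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dist.labels]
    clamped = 0

    def set_len(node: TreeNode, v: float) -> None:
        nonlocal clamped
        if v < 0:
            clamped += 1
            v = 0.0
        node.length = v

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin over row-major order
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final 3-node star from the three pairwise equations
    v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=list(nodes))
    for node, v in zip(nodes, (v0, v1, v2)):
        set_len(node, v)
    return PopulationTree(root, negative_branches_clamped=clamped)


def bootstrap_tree(matrix: GenotypeMatrix,
                   groups: dict[str, list[str]],
                   n_boot: int = 1000,
                   seed: int | None = None,
                   stat: str = "dest",
                   max_redraw: int = 100) -> tuple[PopulationTree, pd.DataFrame]:
    """NJ point-estimate tree with locus-bootstrap bipartition support.

    Loci are resampled with replacement; the pairwise differentiation matrix
    and NJ tree are recomputed per replicate; support for each internal edge
    of the point-estimate tree is the percentage of replicates containing its
    bipartition. Replicates with an undefined pairwise value are redrawn.
    """
    point_pairs = pairwise_differentiation(matrix, groups, stat=stat)
    tree = neighbor_joining(differentiation_matrix(point_pairs))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    n_redrawn = 0
    for _ in range(n_boot):
        for _attempt in range(max_redraw + 1):
            idx = rng.integers(matrix.n_markers, size=matrix.n_markers)
            boot = matrix.subset(marker_mask=None)
            boot = GenotypeMatrix(matrix.calls[:, idx],
                                  matrix.accessions,
                                  matrix.markers.iloc[idx].assign(
                                      id=[f"b{t}" for t in range(len(idx))]))
            pairs = pairwise_differentiation(boot, groups, stat=stat)
            if pairs["value"].isna().any():
                n_redrawn += 1
                continue
            rep = neighbor_joining(differentiation_matrix(pairs))
            break
        else:
            raise RuntimeError("too many degenerate bootstrap replicates")
        rep_splits = rep.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    for node in tree.internal_nodes():
        side = node.leaves()
        other = tree.root.leaves() - side
        if 1 < len(side) < len(tree.root.leaves()) - 1:
            key = _canonical_split(side, other)
            node.support = 100.0 * counts[key] / n_boot
    support = pd.DataFrame(
        [{"bipartition": "|".join(sorted(s)), "support": 100.0 * c / n_boot}
         for s, c in sorted(counts.items(), key=lambda kv: sorted(kv[0]))])
    support.attrs["n_redrawn"] = n_redrawn
    return tree, support
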
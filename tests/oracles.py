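"""Independent brute-force oracles used to derive expected test values.

Everything here is deliberately naive — explicit loops over genotypes,
exhaustive enumeration of subsets — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


# -- Kosman–Leonard: exhaustive per-locus allele sharing ---------------------

def kl_pair_bruteforce(g1, g2) -> float:
    """Distance = 1 - shared alleles / 2 per locus, from explicit allele
    multisets, averaged over loci observed in both genotypes."""
    per_locus = []
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        set_a = ["R"] * a + ["A"] * (2 - a)
        set_b = ["R"] * b + ["A"] * (2 - b)
        shared = 0
        pool = list(set_b)
        for allele in set_a:
            if allele in pool:
                pool.remove(allele)
                shared += 1
        per_locus.append(1.0 - shared / 2.0)
    return float(np.mean(per_locus)) if per_locus else float("nan")


# -- Heterozygosity from explicit genotype counts ----------------------------

def diversity_bruteforce(column) -> tuple[float, float]:
    """(H_e, H_o) for one locus from a list of dosages with missing."""
    obs = [g for g in column if g != MISSING]
    n = len(obs)
    p = sum(obs) / (2.0 * n)
    he = 2.0 * p * (1.0 - p)
    ho = sum(1 for g in obs if g == 1) / n
    return he, ho


# -- Jost D and WC theta from per-group allele counts ------------------------

def _locus_group_counts(calls, group_rows):
    """Per group: (n genotypes, ref-allele count, het count) at one locus."""
    out = []
    for rows in group_rows:
        obs = [calls[i] for i in rows if calls[i] != MISSING]
        out.append((len(obs), sum(obs), sum(1 for g in obs if g == 1)))
    return out


def jost_d_locus_bruteforce(counts, corrected=True):
    """Jost D at one locus from [(n_k, ref_copies_k, het_k), ...]."""
    r = len(counts)
    ns = [n for n, _, _ in counts]
    if any(n < 2 for n in ns):
        return float("nan")
    ps = [ref / (2.0 * n) for n, ref, _ in counts]
    pooled = sum(ref for _, ref, _ in counts) / (2.0 * sum(ns))
    if pooled <= 0 or pooled >= 1:
        return float("nan")
    hs_u = sum(2 * p * (1 - p) for p in ps) / r
    pbar = sum(ps) / r
    ht_u = 2 * pbar * (1 - pbar)
    if corrected:
        n_harm = r / sum(1.0 / n for n in ns)
        ho = sum(het / n for n, _, het in counts) / r
        hs = n_harm / (n_harm - 1.0) * (hs_u - ho / (2 * n_harm))
        ht = ht_u + hs / (n_harm * r) - ho / (2 * n_harm * r)
    else:
        hs, ht = hs_u, ht_u
    if abs(1.0 - hs) < 1e-12:
        return float("nan")
    return (ht - hs) / (1.0 - hs) * r / (r - 1.0)


def jost_dest_bruteforce(matrix_calls, group_rows, corrected=True) -> float:
    values = []
    for j in range(matrix_calls.shape[1]):
        counts = _locus_group_counts(matrix_calls[:, j], group_rows)
        d = jost_d_locus_bruteforce(counts, corrected)
        if not math.isnan(d):
            values.append(d)
    return float(np.mean(values)) if values else float("nan")


def wc_theta_bruteforce(matrix_calls, group_rows) -> float:
    """Weir–Cockerham theta, ratio of summed per-locus components, all loops."""
    sum_a = sum_abc = 0.0
    r = len(group_rows)
    for j in range(matrix_calls.shape[1]):
        counts = _locus_group_counts(matrix_calls[:, j], group_rows)
        ns = [n for n, _, _ in counts]
        if any(n < 2 for n in ns):
            continue
        ps = [ref / (2.0 * n) for n, ref, _ in counts]
        hs = [het / n for n, _, het in counts]
        pooled = sum(ref for _, ref, _ in counts) / (2.0 * sum(ns))
        if pooled <= 0 or pooled >= 1:
            continue
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1.0)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc != 0 else float("nan")


# -- Rarefaction by exhaustive subset enumeration ----------------------------

def rarefied_alleles_exhaustive(locus_counts: dict[str, int], g: int) -> float:
    """E[# distinct alleles in g copies] by enumerating every C(N, g) subset."""
    copies = [a for a, n in sorted(locus_counts.items()) for _ in range(n)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    total = sum(len({copies[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


def rarefied_private_exhaustive(pop_counts: dict[str, dict[str, int]],
                                focal: str, g: int) -> float:
    """E[# alleles private to focal in simultaneous g-draws], by enumerating
    the full product space of subsets across populations."""
    pools = {}
    for pop, counts in pop_counts.items():
        copies = [a for a, n in sorted(counts.items()) for _ in range(n)]
        pools[pop] = [frozenset(copies[i] for i in sub)
                      for sub in itertools.combinations(range(len(copies)), g)]
    others = [p for p in pop_counts if p != focal]
    total = 0.0
    n_joint = 0
    for joint in itertools.product(*(pools[p] for p in [focal] + others)):
        focal_set, other_sets = joint[0], joint[1:]
        private = sum(1 for a in focal_set
                      if all(a not in s for s in other_sets))
        total += private
        n_joint += 1
    return total / n_joint


# -- Tree distances (for NJ exactness on additive matrices) ------------------

def tree_path_lengths(tree) -> dict[frozenset, float]:
    """Leaf-pair path lengths of a PopulationTree, by explicit traversal."""
    dists = {}

    def leaf_depths(node, depth):
        if not node.children:
            return {node.name: depth + node.length}
        out = {}
        for c in node.children:
            out.update(leaf_depths(c, depth + node.length))
        return out

    def walk(node):
        subtrees = [leaf_depths(c, 0.0) for c in node.children]
        for i in range(len(subtrees)):
            for j in range(i + 1, len(subtrees)):
                for la, da in subtrees[i].items():
                    for lb, db in subtrees[j].items():
                        dists[frozenset((la, lb))] = da + db
        for c in node.children:
            if c.children:
                walk(c)

    walk(tree.root)
    return dists
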
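"""Rarefaction of allelic richness and private allelic richness.

For a locus where a population carries N allele copies, N_i of allele i, the
expected number of distinct alleles in a standardized draw of g copies
(sampling without replacement) is

    E[K(g)] = sum_i [ 1 - C(N - N_i, g) / C(N, g) ],

the hypergeometric probability that allele i appears at least once. Private
allelic richness multiplies, per allele, its presence probability in the
focal population's g-draw by its absence probability in every other
population's g-draw. Both statistics average over loci. g is expressed in
allele copies (two per diploid genotype); loci where any population has
fewer than g copies are dropped listwise so curves stay comparable across
populations. Hypergeometric absence probabilities are evaluated in exact
integer/rational arithmetic (binomial coefficients never overflow as Python
integers), so closed-form identities — E[K(1)] = 1, E[K(N)] = the observed
allele count — hold exactly rather than to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class AlleleCountTable:
    """Allele-copy counts: populations x loci x alleles.

    ``counts[pop][locus]`` is a dict allele -> copy count. For biallelic
    dosage data the alleles are "A" (reference) and "B".
    """

    counts: dict[str, list[dict[str, int]]]
    locus_ids: list[str]

    def totals(self, pop: str) -> np.ndarray:
        return np.array([sum(l.values()) for l in self.counts[pop]], dtype=int)

    @property
    def populations(self) -> list[str]:
        return sorted(self.counts)

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix,
                    groups: dict[str, list[str]]) -> "AlleleCountTable":
        counts: dict[str, list[dict[str, int]]] = {}
        for pop, members in groups.items():
            sub = matrix.calls[matrix.accession_index(members)]
            obs = sub != MISSING
            n = obs.sum(axis=0)
            ref = np.where(obs, sub, 0).sum(axis=0)
            counts[pop] = [{"A": int(r), "B": int(2 * m - r)}
                           for r, m in zip(ref, n)]
        return cls(counts, list(matrix.marker_ids))


@lru_cache(maxsize=65536)
def _absence_prob(n_total: int, n_allele: int, g: int) -> Fraction:
    """P(allele absent from a g-draw) = C(N - N_i, g) / C(N, g), exact."""
    if n_allele == 0:
        return Fraction(1)
    if n_total - n_allele < g:
        return Fraction(0)
    return Fraction(comb(n_total - n_allele, g), comb(n_total, g))


def _admissible_loci(table: AlleleCountTable, g: int,
                     populations: list[str]) -> np.ndarray:
    """Loci where every listed population has at least g copies (listwise)."""
    ok = np.ones(len(table.locus_ids), dtype=bool)
    for pop in populations:
        ok &= table.totals(pop) >= g
    return ok


def rarefied_richness(table: AlleleCountTable, population: str, g: int,
                      across: list[str] | None = None) -> float:
    """Mean expected number of distinct alleles per locus at sample size g.

    ``across`` lists the populations used for listwise locus admissibility
    (defaults to all populations in the table, the ADZE convention).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    pops = across if across is not None else table.populations
    ok = _admissible_loci(table, g, pops)
    if not ok.any():
        raise ValueError(f"no locus admits g={g} in all populations")
    values = []
    for locus, keep in zip(table.counts[population], ok):
        if not keep:
            continue
        n_total = sum(locus.values())
        values.append(float(sum((1 - _absence_prob(n_total, ni, g)
                                 for ni in locus.values() if ni > 0),
                                start=Fraction(0))))
    return float(np.mean(values))


def rarefied_private_richness(table: AlleleCountTable, focal: str, g: int,
                              across: list[str] | None = None) -> float:
    """Mean expected number of alleles per locus private to ``focal`` in a
    simultaneous g-draw from every population."""
    pops = across if across is not None else table.populations
    others = [p for p in pops if p != focal]
    if not others:
        raise ValueError("private richness needs at least two populations")
    ok = _admissible_loci(table, g, pops)
    if not ok.any():
        raise ValueError(f"no locus admits g={g} in all populations")
    values = []
    for li, keep in enumerate(ok):
        if not keep:
            continue
        focal_locus = table.counts[focal][li]
        n_focal = sum(focal_locus.values())
        total = Fraction(0)
        for allele, ni in focal_locus.items():
            if ni == 0:
                continue
            present = 1 - _absence_prob(n_focal, ni, g)
            absent_elsewhere = Fraction(1)
            for other in others:
                other_locus = table.counts[other][li]
                absent_elsewhere *= _absence_prob(
                    sum(other_locus.values()), other_locus.get(allele, 0), g)
            total += present * absent_elsewhere
        values.append(float(total))
    return float(np.mean(values))


def rarefaction_curve(table: AlleleCountTable,
                      populations: list[str] | None = None,
                      g_grid: list[int] | None = None) -> pd.DataFrame:
    """Long-format rarefaction curves for both statistics.

    ``g_grid`` defaults to 2..min over populations of the smallest locus
    total. The ``monotone_ok`` column diagnoses that each population's
    richness curve is non-decreasing in g.
    """
    pops = populations if populations is not None else table.populations
    if g_grid is None:
        gmax = min(int(table.totals(p).min()) for p in pops)
        g_grid = list(range(2, max(gmax, 2) + 1))
    rows = []
    for pop in pops:
        for g in g_grid:
            rows.append({
                "population": pop, "g": g,
                "richness": rarefied_richness(table, pop, g, across=pops),
                "private_richness": rarefied_private_richness(
                    table, pop, g, across=pops) if len(pops) > 1 else np.nan,
            })
    df = pd.DataFrame(rows)
    mono = True
    for pop in pops:
        r = df.loc[df["population"] == pop].sort_values("g")["richness"].to_numpy()
        if np.any(np.diff(r) < -1e-9):
            mono = False
    df["monotone_ok"] = mono
    return df
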
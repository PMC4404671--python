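"""Fruit weight/shape locus allele frequencies per genetic group.

Six cloned loci — fw2.2, fw3.2 (fruit weight) and lc, fas, ovate, sun
(fruit shape) — segregate an ancestral (wild-type) and a derived
(mutation-bearing) allele. Per genetic group we report, over informative
(non-missing) calls, both the carrier frequency of the derived allele
(heterozygotes count as carriers) and the allele-count frequency
(heterozygotes contribute 1/2), each with an exact Clopper–Pearson 95%
binomial confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta

from .genotypes import Classification

TRAIT_LOCI = ("fw2.2", "fw3.2", "lc", "fas", "ovate", "sun")
CALLS = ("ancestral", "derived", "heterozygous", "missing")


def validate_trait_calls(calls: pd.DataFrame) -> pd.DataFrame:
    required = {"accession_id", "locus", "call"}
    if not required <= set(calls.columns):
        raise ValueError(f"trait-call table needs columns {sorted(required)}")
    bad_locus = set(calls["locus"]) - set(TRAIT_LOCI)
    if bad_locus:
        raise ValueError(f"unknown trait loci {sorted(bad_locus)}")
    bad_call = set(calls["call"]) - set(CALLS)
    if bad_call:
        raise ValueError(f"unknown call values {sorted(bad_call)}")
    if calls.duplicated(["accession_id", "locus"]).any():
        raise ValueError("duplicate (accession, locus) calls")
    return calls


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles.

    Boundaries are exact: k = 0 gives low = 0 and k = n gives high = 1.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid k={k}, n={n}")
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def group_allele_frequencies(calls: pd.DataFrame,
                             classes: Classification,
                             level: str = "group",
                             min_group_size: int = 5,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Derived-allele frequency estimates per group and locus.

    Columns: carrier_freq (het counts as derived carrier) with its exact CI,
    and allele_freq (het contributes 1/2). Group-locus cells with no
    informative call, and groups below ``min_group_size`` informative
    accessions, are omitted.
    """
    calls = validate_trait_calls(calls)
    labels = classes.labels(level)
    rows = []
    merged = calls.merge(labels.rename("group_label"), left_on="accession_id",
                         right_index=True, how="inner")
    merged = merged[merged["group_label"] != ""]
    for (group, locus), sub in merged.groupby(["group_label", "locus"]):
        informative = sub[sub["call"] != "missing"]
        n = len(informative)
        if n < min_group_size:
            continue
        n_het = int((informative["call"] == "heterozygous").sum())
        n_derived = int((informative["call"] == "derived").sum())
        carriers = n_derived + n_het
        lo, hi = clopper_pearson(carriers, n, alpha)
        rows.append({
            "group": group, "locus": locus, "n": n,
            "carrier_freq": carriers / n,
            "carrier_ci_low": lo, "carrier_ci_high": hi,
            "allele_freq": (n_derived + 0.5 * n_het) / n,
        })
    return pd.DataFrame(rows, columns=["group", "locus", "n", "carrier_freq",
                                       "carrier_ci_low", "carrier_ci_high",
                                       "allele_freq"])
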
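"""Synthetic SNP-array datasets with the structure the analyses assume.

Allele frequencies drift down a three-level hierarchy (species -> group ->
subgroup) under the Balding–Nichols model: a descendant's frequency is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the parent frequency p and
whose variance is F·p(1-p). Diploid genotypes are binomial draws from the
subgroup frequency, so every downstream estimator (H_e, WC theta, D_est) has
a known expectation in the generating F values. Admixed individuals draw
each locus's parental subgroup according to their mixing proportions, which
places them between their parents in PCA space in expectation.

Geography gives each group a centroid with normally dispersed members, so
genetic and geographic distances co-vary at the group level (a positive
isolation-by-distance control); climate variables are linear in latitude and
longitude plus noise, inheriting that correlation. Trait-locus calls follow
per-species derived-allele frequencies under Hardy–Weinberg.

The default configuration emulates the scale of a tomato germplasm panel:
~860 accessions (wild SP ~112, intermediate SLC ~221, cultivated SLL ~492,
plus ~5% admixed), 7,700 biallelic SNPs on 12 chromosomes of ~100 cM, 3%
missing calls, and species-level differentiation increasing from wild to
cultivated so that simulated diversity orders SP > SLC > SLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (MISSING, Classification, GenotypeMatrix,
                        PassportTable)
from .traits import TRAIT_LOCI


@dataclass
class SubgroupSpec:
    name: str
    size: int
    f: float = 0.05  # drift from the group frequency


@dataclass
class GroupSpec:
    name: str
    f: float  # drift from the species frequency
    subgroups: list[SubgroupSpec]
    centroid: tuple[float, float] = (0.0, 0.0)  # (lat, lon)
    dispersal_sd: float = 1.0                   # degrees


@dataclass
class SpeciesSpec:
    name: str
    f: float  # drift from the ancestral frequency
    groups: list[GroupSpec]
    trait_derived_freq: float = 0.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_markers: int = 7700
    n_chromosomes: int = 12
    chromosome_cm: float = 100.0
    species: list[SpeciesSpec] = field(default_factory=lambda: default_hierarchy())
    admixture_fraction: float = 0.05
    mixing_proportions: tuple[float, float] = (0.5, 0.5)
    missingness: float = 0.03
    missingness_dispersion: float = 35.0  # Beta concentration of per-marker rates
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    climate_n_vars: int = 4
    climate_noise_sd: float = 0.5
    trait_missing_rate: float = 0.02

    def validate(self) -> None:
        for sp in self.species:
            if not 0 <= sp.f < 1:
                raise ValueError(f"species {sp.name}: F out of [0,1)")
            for g in sp.groups:
                if not 0 <= g.f < 1:
                    raise ValueError(f"group {g.name}: F out of [0,1)")
                for s in g.subgroups:
                    if s.size < 1:
                        raise ValueError(f"subgroup {s.name}: size < 1")
                    if not 0 <= s.f < 1:
                        raise ValueError(f"subgroup {s.name}: F out of [0,1)")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness out of [0,1)")
        if not 0 <= self.admixture_fraction < 1:
            raise ValueError("admixture_fraction out of [0,1)")


def default_hierarchy() -> list[SpeciesSpec]:
    """Wild / intermediate / cultivated species with nested Andean geography.

    F grows from wild (weak drift, high diversity) to cultivated (strong
    domestication bottleneck), reproducing the qualitative diversity chain
    wild > intermediate > cultivated.
    """
    def sg(prefix, sizes, f=0.05):
        return [SubgroupSpec(f"{prefix}.{i+1}", n, f) for i, n in enumerate(sizes)]

    sp = SpeciesSpec("SP", f=0.10, trait_derived_freq=0.02, groups=[
        GroupSpec("SP.Peru", 0.05, sg("SP.Peru", [40, 25, 18]),
                  centroid=(-9.0, -78.5), dispersal_sd=1.5),
        GroupSpec("SP.Ecuador", 0.10, sg("SP.Ecuador", [10, 7]),
                  centroid=(-0.5, -79.5), dispersal_sd=0.8),
        GroupSpec("SP.Montane", 0.08, sg("SP.Montane", [7, 5]),
                  centroid=(-3.5, -79.0), dispersal_sd=0.8),
    ])
    slc = SpeciesSpec("SLC", f=0.20, trait_derived_freq=0.35, groups=[
        GroupSpec("SLC.Andean", 0.06, sg("SLC.Andean", [45, 30, 15]),
                  centroid=(-1.5, -78.0), dispersal_sd=1.8),
        GroupSpec("SLC.nonAndean", 0.10, sg("SLC.nonAndean", [60, 40, 21]),
                  centroid=(15.0, -90.0), dispersal_sd=6.0),
        GroupSpec("SLC.vintage", 0.12, sg("SLC.vintage", [10]),
                  centroid=(40.0, -4.0), dispersal_sd=4.0),
    ])
    sll = SpeciesSpec("SLL", f=0.30, trait_derived_freq=0.90, groups=[
        GroupSpec("SLL.vintage", 0.08, sg("SLL.vintage", [120, 52]),
                  centroid=(42.0, 12.0), dispersal_sd=5.0),
        GroupSpec("SLL.contemporary", 0.10,
                  sg("SLL.contemporary", [128, 124, 68]),
                  centroid=(40.0, -95.0), dispersal_sd=6.0),
    ])
    return [sp, slc, sll]


def balding_nichols(rng: np.random.Generator, p: np.ndarray,
                    f: float) -> np.ndarray:
    """Draw descendant frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f == 0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12),
                    np.maximum((1.0 - p) * scale, 1e-12))


@dataclass
class SimulatedDataset:
    matrix: GenotypeMatrix
    passport: PassportTable
    truth: Classification
    trait_calls: pd.DataFrame
    subgroup_freqs: dict[str, np.ndarray]  # generating frequencies (truth)


def _marker_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom = np.repeat(np.arange(cfg.n_chromosomes),
                      int(np.ceil(cfg.n_markers / cfg.n_chromosomes)))[: cfg.n_markers]
    pos = np.empty(cfg.n_markers)
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.sort(rng.uniform(0, cfg.chromosome_cm, size=len(idx)))
    pairs = np.array([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")],
                     dtype=object)
    chosen = pairs[rng.integers(len(pairs), size=cfg.n_markers)]
    return pd.DataFrame({
        "id": [f"snp{i:05d}" for i in range(cfg.n_markers)],
        "chromosome": [f"chr{c + 1:02d}" for c in chrom],
        "position_cm": pos,
        "allele_a": chosen[:, 0],
        "allele_b": chosen[:, 1],
    })


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full dataset: genotypes + map, passports with GPS/climate,
    the true classification, and trait-locus calls."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_table(cfg, rng)
    m = cfg.n_markers
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=m)

    subgroup_freqs: dict[str, np.ndarray] = {}
    sub_meta: dict[str, tuple[str, str, GroupSpec, SpeciesSpec]] = {}
    for sp in cfg.species:
        p_sp = balding_nichols(rng, p0, sp.f)
        for g in sp.groups:
            p_g = balding_nichols(rng, p_sp, g.f)
            for s in g.subgroups:
                subgroup_freqs[s.name] = balding_nichols(rng, p_g, s.f)
                sub_meta[s.name] = (sp.name, g.name, g, sp)

    calls_rows, acc_ids = [], []
    class_rows, passport_rows, trait_rows = [], [], []
    counter = 0

    def trait_call(q: float) -> str:
        if rng.random() < cfg.trait_missing_rate:
            return "missing"
        n_derived = rng.binomial(2, q)
        return ("ancestral", "heterozygous", "derived")[n_derived]

    for sub_name, (sp_name, g_name, g_spec, sp_spec) in sub_meta.items():
        size = next(s.size for s in g_spec.subgroups if s.name == sub_name)
        freqs = subgroup_freqs[sub_name]
        geno = rng.binomial(2, freqs, size=(size, m)).astype(np.int8)
        for i in range(size):
            aid = f"ACC{counter:04d}"
            counter += 1
            acc_ids.append(aid)
            calls_rows.append(geno[i])
            class_rows.append({"accession_id": aid, "species": sp_name,
                               "group": g_name, "subgroup": sub_name,
                               "is_mixture": False})
            lat = g_spec.centroid[0] + rng.normal(0, g_spec.dispersal_sd)
            lon = g_spec.centroid[1] + rng.normal(0, g_spec.dispersal_sd)
            passport_rows.append({"accession_id": aid,
                                  "passport_class": sp_name,
                                  "latitude": float(np.clip(lat, -89, 89)),
                                  "longitude": float(np.clip(lon, -179, 179))})
            for locus in TRAIT_LOCI:
                trait_rows.append({"accession_id": aid, "locus": locus,
                                   "call": trait_call(sp_spec.trait_derived_freq)})

    # admixed individuals between two random distinct subgroups
    n_base = counter
    n_admix = int(round(cfg.admixture_fraction * n_base))
    sub_names = list(subgroup_freqs)
    w = np.asarray(cfg.mixing_proportions, dtype=float)
    w = w / w.sum()
    for _ in range(n_admix):
        a, b = rng.choice(len(sub_names), size=2, replace=False)
        pa, pb = subgroup_freqs[sub_names[a]], subgroup_freqs[sub_names[b]]
        pick_a = rng.random(m) < w[0]
        p_mix = np.where(pick_a, pa, pb)
        geno = rng.binomial(2, p_mix).astype(np.int8)
        aid = f"ACC{counter:04d}"
        counter += 1
        acc_ids.append(aid)
        calls_rows.append(geno)
        class_rows.append({"accession_id": aid, "species": "", "group": "",
                           "subgroup": "", "is_mixture": True})
        g_spec = sub_meta[sub_names[a]][2]
        passport_rows.append({"accession_id": aid, "passport_class": "mixture",
                              "latitude": float(np.clip(
                                  g_spec.centroid[0] + rng.normal(0, 3), -89, 89)),
                              "longitude": float(np.clip(
                                  g_spec.centroid[1] + rng.normal(0, 3), -179, 179))})
        for locus in TRAIT_LOCI:
            trait_rows.append({"accession_id": aid, "locus": locus,
                               "call": trait_call(0.5)})

    calls = np.vstack(calls_rows)
    if cfg.missingness > 0:
        # per-marker missing rates: Beta around the mean rate, so a realistic
        # tail of badly called markers exceeds the 10% QC threshold
        k = cfg.missingness_dispersion
        rates = rng.beta(cfg.missingness * k, (1 - cfg.missingness) * k,
                         size=calls.shape[1])
        mask = rng.random(calls.shape) < rates[None, :]
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    passport = pd.DataFrame(passport_rows)
    for j in range(cfg.climate_n_vars):
        a, b = rng.normal(0, 1, size=2)
        passport[f"clim{j + 1}"] = (
            a * passport["latitude"] / 10.0 + b * passport["longitude"] / 10.0
            + rng.normal(0, cfg.climate_noise_sd, size=len(passport)))

    matrix = GenotypeMatrix(calls, acc_ids, markers)
    return SimulatedDataset(
        matrix=matrix,
        passport=PassportTable(passport),
        truth=Classification(pd.DataFrame(class_rows)),
        trait_calls=pd.DataFrame(trait_rows),
        subgroup_freqs=subgroup_freqs,
    )


def two_population_config(f: float, n_per_group: int = 100,
                          n_markers: int = 2000, seed: int = 0,
                          missingness: float = 0.0) -> SimulationConfig:
    """Minimal two-population Balding–Nichols config for parameter-recovery
    experiments: two species, one group and one subgroup each, drift F at the
    species level only."""
    def species(name, lat):
        return SpeciesSpec(name, f=f, groups=[
            GroupSpec(f"{name}.g", 0.0,
                      [SubgroupSpec(f"{name}.g.1", n_per_group, 0.0)],
                      centroid=(lat, -78.0), dispersal_sd=1.0)])
    return SimulationConfig(
        seed=seed, n_markers=n_markers, n_chromosomes=4,
        species=[species("P1", -5.0), species("P2", 5.0)],
        admixture_fraction=0.0, missingness=missingness)


def worked_toy() -> SimulatedDataset:
    """A tiny deterministic dataset (12 accessions x 20 markers, 3 groups)
    whose diversity, distance, differentiation and rarefaction values are
    small enough to verify by hand or exhaustive enumeration."""
    cfg = SimulationConfig(
        seed=12020, n_markers=20, n_chromosomes=2, chromosome_cm=10.0,
        species=[
            SpeciesSpec("S1", 0.30, groups=[GroupSpec(
                "S1.g", 0.0, [SubgroupSpec("S1.g.1", 4, 0.0)],
                centroid=(-5.0, -78.0))]),
            SpeciesSpec("S2", 0.30, groups=[GroupSpec(
                "S2.g", 0.0, [SubgroupSpec("S2.g.1", 4, 0.0)],
                centroid=(0.0, -79.0))]),
            SpeciesSpec("S3", 0.30, groups=[GroupSpec(
                "S3.g", 0.0, [SubgroupSpec("S3.g.1", 4, 0.0)],
                centroid=(5.0, -80.0))]),
        ],
        admixture_fraction=0.0, missingness=0.05, climate_n_vars=2)
    return simulate_dataset(cfg)
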
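"""End-to-end orchestration: filters -> classification -> diversity ->
differentiation -> trees -> PCA -> rarefaction -> LD -> IBD -> trait loci.

Every stage writes its table under the output directory; a JSON manifest
records parameters, seeds and the SHA-256 of every artifact so a rerun with
the same inputs and seed is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differentiation import (bootstrap_tree, pairwise_differentiation)
from .distances import distance_matrix, hierarchy_distance_summary
from .diversity import group_diversity
from .filters import select_markers
from .genotypes import Classification, GenotypeMatrix, PassportTable
from .ibd import climate_distance, haversine_matrix, mantel_test
from .ld import ld_decay_by_group
from .pca import HierarchicalConfig, LevelConfig, classify_hierarchical, standardized_pca
from .rarefaction import AlleleCountTable, rarefaction_curve
from .simulate import SimulatedDataset
from .traits import group_allele_frequencies


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    max_missing_fraction: float = 0.10
    max_major_freq: float = 0.95
    min_cm: float = 0.1
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    min_group_size: int = 5
    level: str = "group"              # hierarchy level for group analyses
    n_clusters: tuple[int, int, int] = (3, 3, 2)
    mixture_threshold: float = 0.8
    ld_max_pairs: int = 2000
    rarefaction_g: tuple[int, ...] = (2, 4, 8, 16)
    use_truth_classification: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(dataset: SimulatedDataset | tuple,
                 config: PipelineConfig | None = None) -> dict:
    """Run the full analysis and return the manifest dict.

    ``dataset`` bundles the genotype matrix, passport table, a classification
    (used directly when ``use_truth_classification``, otherwise re-derived by
    hierarchical PCA) and trait-locus calls.
    """
    cfg = config or PipelineConfig()
    if isinstance(dataset, tuple):
        matrix, passport, truth, trait_calls = dataset
    else:
        matrix, passport, truth, trait_calls = (
            dataset.matrix, dataset.passport, dataset.truth, dataset.trait_calls)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {"version": __version__,
                      "parameters": asdict(cfg), "stages": {}, "artifacts": {}}

    # 1. marker selection
    sets = select_markers(matrix, cfg.max_missing_fraction,
                          cfg.max_major_freq, cfg.min_cm)
    _write(sets.cascade, out / "filter_cascade.tsv")
    manifest["stages"]["filters"] = sets.cascade.to_dict("records")
    thinned, allpoly = sets.thinned, sets.all_polymorphic

    # 2. classification (hierarchical PCA unless the supplied one is reused)
    if cfg.use_truth_classification and truth is not None:
        classes = truth
    else:
        hcfg = HierarchicalConfig(
            levels=[LevelConfig(n_clusters=k) for k in cfg.n_clusters],
            mixture_threshold=cfg.mixture_threshold,
            seed=int(rng.integers(2 ** 31)))
        classes = classify_hierarchical(thinned, hcfg)
    classes.table.to_csv(out / "classification.tsv", sep="\t", index=False)
    groups = classes.groups_at(cfg.level)
    groups = {k: v for k, v in groups.items() if len(v) >= cfg.min_group_size}
    manifest["stages"]["classification"] = {
        "level": cfg.level, "n_groups": len(groups),
        "n_mixture": int(classes.table["is_mixture"].sum())}

    # 3. PCA scores on the thinned set
    pca = standardized_pca(thinned, n_components=10)
    scores = pca.scores_frame().reset_index(names="accession_id")
    _write(scores, out / "pca_scores.tsv")
    manifest["stages"]["pca"] = {
        "variance_fraction": [float(v) for v in pca.variance_fraction[:5]]}

    # 4. diversity per group
    div = group_diversity(thinned, groups, min_group_size=cfg.min_group_size)
    _write(div, out / "diversity.tsv")

    # 5. distances + hierarchy summary
    dist = distance_matrix(thinned)
    dist.to_tsv(out / "distances.tsv")
    _write(hierarchy_distance_summary(dist, classes),
           out / "distance_hierarchy.tsv")

    # 6. differentiation + tree
    if len(groups) >= 2:
        dest = pairwise_differentiation(thinned, groups, "dest",
                                        n_perm=cfg.n_perm,
                                        seed=int(rng.integers(2 ** 31)))
        fst = pairwise_differentiation(thinned, groups, "fst",
                                       n_perm=cfg.n_perm,
                                       seed=int(rng.integers(2 ** 31)))
        _write(dest, out / "dest_pairwise.tsv")
        _write(fst, out / "fst_pairwise.tsv")
        if len(groups) >= 3:
            tree, support = bootstrap_tree(thinned, groups, n_boot=cfg.n_boot,
                                           seed=int(rng.integers(2 ** 31)))
            (out / "nj_tree.nwk").write_text(tree.newick(with_support=True) + "\n")
            _write(support, out / "nj_support.tsv")

    # 7. rarefaction on the all-polymorphic set
    act = AlleleCountTable.from_matrix(allpoly, groups)
    g_max = min(int(act.totals(p).min()) for p in act.populations) \
        if act.populations else 0
    g_grid = [g for g in cfg.rarefaction_g if 2 <= g <= g_max]
    if g_grid and len(groups) >= 2:
        _write(rarefaction_curve(act, g_grid=g_grid), out / "rarefaction.tsv")

    # 8. LD decay on the all-polymorphic set
    pts, curves = ld_decay_by_group(allpoly, groups,
                                    max_pairs_per_chrom=cfg.ld_max_pairs,
                                    seed=int(rng.integers(2 ** 31)))
    if not curves.empty:
        _write(curves, out / "ld_curves.tsv")
    manifest["stages"]["ld"] = {"n_points": int(len(pts))}

    # 9. isolation by distance per group
    mantel_rows = []
    ptab = passport.table if isinstance(passport, PassportTable) else passport
    climate_cols = [c for c in ptab.columns if c.startswith("clim")]
    for label, members in sorted(groups.items()):
        sub = ptab[ptab["accession_id"].isin(members)]
        if len(sub) < 4 or sub["latitude"].isna().all():
            continue
        geo = haversine_matrix(sub)
        gen = dist.submatrix([a for a in geo.labels])
        try:
            res = mantel_test(gen, geo, n_perm=cfg.n_perm,
                              seed=int(rng.integers(2 ** 31)))
            mantel_rows.append({"group": label, "pair": "genetic~geographic",
                                "r": res.r, "p_value": res.p_value, "n": res.n})
        except ValueError:
            pass
        if climate_cols:
            clim = climate_distance(sub[["accession_id"] + climate_cols])
            try:
                res = mantel_test(gen.submatrix(
                    [l for l in gen.labels if l in set(clim.labels)]), clim,
                    n_perm=cfg.n_perm, seed=int(rng.integers(2 ** 31)))
                mantel_rows.append({"group": label, "pair": "genetic~climatic",
                                    "r": res.r, "p_value": res.p_value,
                                    "n": res.n})
            except ValueError:
                pass
    if mantel_rows:
        _write(pd.DataFrame(mantel_rows), out / "mantel.tsv")

    # 10. trait loci
    if trait_calls is not None and len(trait_calls):
        freq = group_allele_frequencies(trait_calls, classes, level="species"
                                        if cfg.use_truth_classification
                                        else cfg.level,
                                        min_group_size=cfg.min_group_size)
        if not freq.empty:
            _write(freq, out / "trait_frequencies.tsv")

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def reproduce_from_files(genotype_tsv: str | Path,
                         genetic_map_tsv: str | Path,
                         classification_tsv: str | Path,
                         out_dir: str | Path,
                         max_missing_fraction: float = 0.10,
                         max_major_freq: float = 0.95,
                         min_cm: float = 0.1,
                         level: str = "group") -> dict:
    """Recompute the filter cascade and per-group diversity summary from
    user-supplied files (e.g. a published array genotype matrix with its map
    and classification), without any simulation.

    Returns {"cascade": DataFrame, "diversity": DataFrame} and writes both
    under ``out_dir``.
    """
    from .genotypes import (attach_map, read_classification_tsv,
                            read_genetic_map, read_genotype_tsv)
    matrix = attach_map(read_genotype_tsv(genotype_tsv),
                        read_genetic_map(genetic_map_tsv))
    classes = read_classification_tsv(classification_tsv)
    sets = select_markers(matrix, max_missing_fraction, max_major_freq, min_cm)
    div = group_diversity(sets.thinned, classes, level=level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write(sets.cascade, out / "filter_cascade.tsv")
    _write(div, out / "diversity.tsv")
    return {"cascade": sets.cascade, "diversity": div}
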
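#!/usr/bin/env python
"""Per-group diversity (H_o, H_e, P95), Kosman–Leonard distance structure,
pairwise D_est / F_st with permutation significance, and the NJ tree with
locus-bootstrap support.
"""

from pathlib import Path

from tomatopop.differentiation import bootstrap_tree, pairwise_differentiation
from tomatopop.distances import distance_matrix, hierarchy_distance_summary
from tomatopop.diversity import group_diversity
from tomatopop.genotypes import (attach_map, read_classification_tsv,
                                 read_genetic_map, read_genotype_tsv)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 12
N_PERM = 199
N_BOOT = 199


def main() -> None:
    matrix = attach_map(
        read_genotype_tsv(ROOT / "markers" / "genotypes_thinned.tsv"),
        read_genetic_map(ROOT / "markers" / "map_thinned.tsv"))
    classes = read_classification_tsv(ROOT / "structure" / "classification.tsv")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    for level in ("species", "group"):
        table = group_diversity(matrix, classes, level=level)
        table.to_csv(out / f"diversity_{level}.tsv", sep="\t", index=False,
                     float_format="%.4f")
        if level == "species":
            ordered = table.sort_values("H_e", ascending=False)
            chain = " > ".join(ordered["group"])
            print(f"species H_e ordering: {chain}")

    dist = distance_matrix(matrix)
    dist.to_tsv(out / "kosman_leonard_distances.tsv")
    summary = hierarchy_distance_summary(dist, classes)
    summary.to_csv(out / "distance_hierarchy.tsv", sep="\t", index=False)
    print("within-class distance medians decrease down the hierarchy:",
          bool(summary["ordering_ok"].iloc[0]))

    groups = {k: v for k, v in classes.groups_at("species").items()
              if len(v) >= 5}
    dest = pairwise_differentiation(matrix, groups, "dest", n_perm=N_PERM,
                                    seed=SEED)
    fst = pairwise_differentiation(matrix, groups, "fst", n_perm=N_PERM,
                                   seed=SEED + 1)
    dest.to_csv(out / "dest_pairwise.tsv", sep="\t", index=False)
    fst.to_csv(out / "fst_pairwise.tsv", sep="\t", index=False)
    sig = (dest["p_value"] <= 0.05).all() and (fst["p_value"] <= 0.05).all()
    print(f"all pairwise species differentiation significant at 0.05: {sig}")

    ggroups = {k: v for k, v in classes.groups_at("group").items()
               if len(v) >= 5}
    if len(ggroups) >= 3:
        tree, support = bootstrap_tree(matrix, ggroups, n_boot=N_BOOT,
                                       seed=SEED + 2)
        (out / "nj_tree.nwk").write_text(tree.newick(with_support=True) + "\n")
        support.to_csv(out / "nj_support.tsv", sep="\t", index=False)
        print(f"NJ tree over {len(ggroups)} groups; median bootstrap support "
              f"{support['support'].median():.0f}%")


if __name__ == "__main__":
    main()
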
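#!/usr/bin/env python
"""Isolation by distance and by climate: Mantel tests of genetic vs
haversine-geographic and climate-PCA distances within each genetic group.
"""

from pathlib import Path

import pandas as pd

from tomatopop.distances import distance_matrix
from tomatopop.genotypes import (attach_map, read_classification_tsv,
                                 read_genetic_map, read_genotype_tsv,
                                 read_passport_tsv)
from tomatopop.ibd import (climate_distance, distance_density_export,
                           haversine_matrix, mantel_test)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 14
N_PERM = 999


def main() -> None:
    matrix = attach_map(
        read_genotype_tsv(ROOT / "markers" / "genotypes_thinned.tsv"),
        read_genetic_map(ROOT / "markers" / "map_thinned.tsv"))
    classes = read_classification_tsv(ROOT / "structure" / "classification.tsv")
    passports = read_passport_tsv(ROOT / "data" / "passports.tsv").table
    out = ROOT / "ibd"
    out.mkdir(parents=True, exist_ok=True)

    gen_all = distance_matrix(matrix)
    clim_cols = [c for c in passports.columns if c.startswith("clim")]
    rows = []
    for label, members in sorted(classes.groups_at("species").items()):
        sub = passports[passports["accession_id"].isin(members)]
        if len(sub) < 4:
            continue
        geo = haversine_matrix(sub)
        res = mantel_test(gen_all, geo, n_perm=N_PERM, seed=SEED)
        rows.append({"group": label, "pair": "genetic~geographic",
                     "r": res.r, "p_value": res.p_value, "n": res.n})
        clim = climate_distance(sub[["accession_id"] + clim_cols])
        res_c = mantel_test(gen_all, clim, n_perm=N_PERM, seed=SEED + 1)
        rows.append({"group": label, "pair": "genetic~climatic",
                     "r": res_c.r, "p_value": res_c.p_value, "n": res_c.n})
        density = distance_density_export(
            gen_all.submatrix([l for l in geo.labels]), geo,
            labels=("genetic", "geographic_km"))
        density.to_csv(out / f"density_{label}.tsv", sep="\t", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(out / "mantel_results.tsv", sep="\t", index=False)
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
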
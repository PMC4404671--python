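#!/usr/bin/env python
"""Marker selection: missingness (>10%), major-allele frequency (>0.95) and
0.1 cM thinning.

Produces the two marker sets the analyses run on — the thinned set (default)
and the all-polymorphic set (rarefaction, LD) — and reports the cascade
accounting.
"""

from pathlib import Path

from tomatopop.filters import select_markers
from tomatopop.genotypes import attach_map, read_genetic_map, read_genotype_tsv
from tomatopop.genotypes import write_genotype_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = attach_map(read_genotype_tsv(ROOT / "data" / "genotypes.tsv"),
                        read_genetic_map(ROOT / "data" / "genetic_map.tsv"))
    sets = select_markers(matrix)
    out = ROOT / "markers"
    out.mkdir(parents=True, exist_ok=True)
    sets.cascade.to_csv(out / "filter_cascade.tsv", sep="\t", index=False)
    write_genotype_tsv(sets.thinned, out / "genotypes_thinned.tsv")
    sets.thinned.markers.to_csv(out / "map_thinned.tsv", sep="\t", index=False)
    write_genotype_tsv(sets.all_polymorphic, out / "genotypes_polymorphic.tsv")
    sets.all_polymorphic.markers.to_csv(out / "map_polymorphic.tsv",
                                        sep="\t", index=False)
    print(sets.cascade.to_string(index=False))
    print(f"thinned set: {sets.thinned.n_markers} markers; "
          f"all-polymorphic set: {sets.all_polymorphic.n_markers} markers")


if __name__ == "__main__":
    main()
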
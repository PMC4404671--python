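#!/usr/bin/env python
"""Generate the study-scale synthetic dataset all later steps analyse.

Writes genotypes, genetic map, passports (GPS + climate), the true
classification and trait-locus calls under results/data/. The configuration
emulates a three-species tomato germplasm panel: ~866 accessions x 7,700
SNPs on 12 chromosomes, drift increasing from wild (SP) to cultivated (SLL),
~5% admixed individuals and ~3% missing calls.
"""

from pathlib import Path

from tomatopop.genotypes import write_classification_tsv, write_genotype_tsv
from tomatopop.simulate import SimulationConfig, simulate_dataset

SEED = 20140601
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(SimulationConfig(seed=SEED))
    write_genotype_tsv(ds.matrix, OUT / "genotypes.tsv")
    ds.matrix.markers.to_csv(OUT / "genetic_map.tsv", sep="\t", index=False)
    ds.passport.table.to_csv(OUT / "passports.tsv", sep="\t", index=False)
    write_classification_tsv(ds.truth, OUT / "classification_truth.tsv")
    ds.trait_calls.to_csv(OUT / "trait_calls.tsv", sep="\t", index=False)
    n_mix = int(ds.truth.table["is_mixture"].sum())
    print(f"simulated {ds.matrix.n_accessions} accessions "
          f"({n_mix} admixed) x {ds.matrix.n_markers} markers -> {OUT}")


if __name__ == "__main__":
    main()
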
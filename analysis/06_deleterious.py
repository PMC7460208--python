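#!/usr/bin/env python
"""Deleterious-variant summaries: SIFT classification, pooled frequency
spectrum, and per-population presence intersections (UpSet-style).

Runs on the call-rate tier (no MAF filter): deleterious alleles are
predominantly rare and a MAF cut would empty the spectrum's first bins.
"""

from pathlib import Path

from popkit.deleterious import (
    classify_deleterious,
    frequency_spectrum,
    intersection_sets,
    read_annotations,
)
from popkit.variant_io import read_population_map, read_vcf

REPO = Path(__file__).resolve().parent.parent
SCRATCH = REPO / "scratch" / "demo"
RESULTS = REPO / "results"


def main() -> None:
    gm = read_vcf(SCRATCH / "sites.vcf")
    popmap = read_population_map(SCRATCH / "populations.tsv", outgroup="wild")
    table = classify_deleterious(read_annotations(SCRATCH / "annotations.tsv"))
    spectrum = frequency_spectrum(table, gm, popmap)
    spectrum.to_csv(RESULTS / "06_sift_spectrum.tsv", sep="\t", index=False)
    subsets, per_pop = intersection_sets(table, gm, popmap)
    subsets.head(40).to_csv(RESULTS / "06_sift_intersections.tsv", sep="\t", index=False)
    per_pop.to_csv(RESULTS / "06_sift_per_population.tsv", sep="\t")

    n_del = int(table["deleterious"].sum())
    first_bin = int(spectrum["all"].iloc[0])
    total = int(spectrum["all"].sum())
    shared_all = subsets[subsets["size"] == len(per_pop)]["count"]
    print(f"deleterious variants: {n_del}")
    print(f"in the 0-0.05 pooled-frequency bin: {first_bin}/{total} "
          f"({100 * first_bin / max(total, 1):.1f}%)")
    print(f"present in every study population: "
          f"{int(shared_all.iloc[0]) if len(shared_all) else 0}")
    print("\nper-population totals and population-specific counts:")
    print(per_pop.to_string())


if __name__ == "__main__":
    main()
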
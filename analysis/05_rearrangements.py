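#!/usr/bin/env python
"""tRNA gene-order rearrangements relative to the ancestral arrangement.

Derives each taxon's signed gene order, classifies deviations from the
putative ancestral insect arrangement (shuffle / translocation / remote
translocation / inversion) and computes the pairwise breakpoint-distance
matrix.

Reads results/study/genomes.gb; writes results/rearrangements.tsv and
results/breakpoints.tsv.
"""

import argparse
from pathlib import Path

from mitocompare.genome_io import parse_genbank
from mitocompare.pipeline import breakpoint_matrix, rearrangement_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    genomes = parse_genbank(args.study / "genomes.gb")
    events = rearrangement_table(genomes)
    args.out.mkdir(parents=True, exist_ok=True)
    events.to_csv(args.out / "rearrangements.tsv", sep="\t", index=False)
    mat = breakpoint_matrix(genomes)
    mat.to_csv(args.out / "breakpoints.tsv", sep="\t")
    if events.empty:
        print("no rearrangements detected")
    else:
        print(events.to_string(index=False))
    print("\nbreakpoint distances:")
    print(mat.to_string())
    print(f"wrote {args.out}/rearrangements.tsv and breakpoints.tsv")


if __name__ == "__main__":
    main()
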
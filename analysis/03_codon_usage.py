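#!/usr/bin/env python
"""Relative synonymous codon usage of the study taxa.

Tallies codons of all PCGs under the invertebrate mitochondrial code
(stop codons excluded) and reports RSCU per codon with the L1/L2 and
S1/S2 family split; prints each taxon's most heavily used codon family.

Reads results/study/genomes.gb; writes results/rscu.tsv.
"""

import argparse
from pathlib import Path

from mitocompare.genome_io import parse_genbank
from mitocompare.pipeline import rscu_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results/rscu.tsv"))
    args = ap.parse_args()

    genomes = parse_genbank(args.study / "genomes.gb")
    table = rscu_table(genomes)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    for species, grp in table.groupby("species", sort=False):
        by_fam = grp.groupby("family")["count"].sum()
        top = by_fam.idxmax()
        print(f"{species}: {int(grp['count'].sum())} codons; "
              f"most used family {top} ({int(by_fam.max())} codons)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
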
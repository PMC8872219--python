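#!/usr/bin/env python
"""Export the phylogenetic supermatrix ingredients.

One unaligned FASTA per protein-coding gene (taxa carrying the gene) plus
a partition manifest, ready for external alignment and tree inference;
alignment and phylogenetics themselves are outside this pipeline.

Reads results/study/genomes.gb; writes results/supermatrix/.
"""

import argparse
from pathlib import Path

from mitocompare.genome_io import parse_genbank, write_supermatrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results/supermatrix"))
    args = ap.parse_args()

    genomes = parse_genbank(args.study / "genomes.gb")
    out = write_supermatrix(genomes, args.out)
    fastas = sorted(out.glob("*.fasta"))
    print(f"{len(fastas)} per-gene FASTA files under {out}")
    manifest = (out / "partitions.tsv").read_text().splitlines()[1:]
    short = [row for row in manifest if int(row.split("\t")[1]) < len(genomes)]
    for row in short:
        gene, n, taxa = row.split("\t")
        print(f"  note: {gene} present in only {n} taxa ({taxa})")


if __name__ == "__main__":
    main()
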
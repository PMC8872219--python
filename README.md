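# mitocompare

Comparative analysis of insect mitochondrial genomes, built around the
questions one asks of newly sequenced hymenopteran mitogenomes: how biased
is the base composition of the protein-coding complement, which codons are
over-used, how fast is each gene evolving, and how has the tRNA gene order
been rearranged relative to the ancestral insect arrangement?

The package is aimed at people assembling and annotating insect (typically
wasp) mitogenomes who want the standard comparative statistics computed
reproducibly from annotated records — GenBank flat files or FASTA plus a
feature table — without a chain of GUI tools, plus a synthetic-mitogenome
generator so every stage of the pipeline can be exercised and
cross-validated without touching public databases.

## What it computes

**Strand-asymmetry statistics** over the 13 protein-coding genes (PCGs),
concatenated in coding orientation:

    AT-skew = (A% − T%) / (A% + T%)        GC-skew = (G% − C%) / (G% + C%)

**Relative synonymous codon usage** (RSCU) under the invertebrate
mitochondrial code (translation table 5: UGA=Trp, AGA/AGG=Ser, AUA=Met),
with leucine split into L1 (CUN) / L2 (UUR) and serine into S1 (AGN) /
S2 (UCN) families:

    RSCU(c) = n_c · |family| / Σ_{c' ∈ family} n_{c'}

**Pairwise Ka/Ks by Nei–Gojobori counting.** Each codon contributes
fractional synonymous (S) and nonsynonymous (N) sites from its nine
single-base changes; differing codon pairs contribute difference counts
(Sd, Nd) averaged over all minimal mutational pathways, excluding pathways
through stop codons. The proportions pS = Sd/S and pN = Nd/N (reported as
Ks and Ka) are corrected for multiple hits with the Jukes–Cantor formula

    d = −(3/4) · ln(1 − (4/3) p)

giving the corrected series JKs, JKa and the ratios Ka/Ks and JKa/JKs.

**Gene-order rearrangements.** Signed gene orders are compared against the
putative ancestral insect arrangement and each deviation is classified as
a *shuffle* (local reordering within a tRNA cluster), *translocation*
(move into an adjacent cluster, crossing one protein-coding/rRNA anchor
gene), *remote translocation* (crossing two or more anchors), *inversion*
(strand switch in place) or *inverted translocation*; orientation-aware
breakpoint distances summarise overall divergence in gene order.

**Supermatrix export.** Per-gene unaligned FASTA plus a partition manifest
for external alignment and tree inference (phylogenetics itself is out of
scope).

## Worked example

Generate a four-taxon synthetic study (an ancestral-arrangement reference
plus three derived taxa carrying wasp-style tRNA rearrangements and
partial assemblies), then run the analyses:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_composition_profile.py
python analysis/05_rearrangements.py
```

The composition step prints:

```
species  sequence_length_bp at_percent at_skew gc_skew  pcg_length_bp
 taxon0               14673      81.20 -0.1579 -0.0789          11121
 taxon1               13761      76.01 -0.1532 -0.0375          11121
 taxon2               14673      75.81 -0.1515 -0.0736          11121
 taxon3               14607      75.38 -0.1509 -0.0679          11121
```

taxon0 reproduces the generator's preset (A+T ≈ 81–82% of PCG bases,
negative AT-skew — the profile typical of ichneumonid coding strands);
the derived taxa are AT-poorer because divergence erodes the bias.  The
rearrangement step prints the classified events:

```
genome gene          kind ancestral_context observed_context  displacement
taxon1 trnC       shuffle         trnW|trnY        nad2|trnW             1
taxon2 trnM       shuffle         trnQ|nad2        trnI|trnQ             1
taxon3 trnQ translocation            .|trnM        nad2|trnW             2
taxon3 trnY       shuffle         trnC|cox1        trnW|trnC             1
```

— taxon1's trnW-trnC-trnY cluster is shuffled to trnW-trnY-trnC, taxon2's
trnI-trnQ-trnM cluster is locally reordered, and in taxon3 trnQ has
translocated across nad2 into that cluster with a shuffle of trnY,
producing the block trnQ-trnY-trnW-trnC.  `04_evolutionary_rates.py`
writes the per-gene Ka/Ks table and names the fastest and slowest genes;
`06_supermatrix_export.py` writes the 13 per-gene FASTA files.

The same operations are available on any annotated GenBank input through
the CLI:

```bash
mitocompare profile results/study/genomes.gb
mitocompare kaks results/study/genomes.gb --out kaks.tsv
mitocompare rearrange results/study/genomes.gb
mitocompare run-all results/study/genomes.gb --out report/
```

## Layout

- `src/mitocompare/` — the library: `genome_io`, `composition`,
  `codon_evolution`, `gene_order`, `simulate`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance tests (the acceptance tests
  that recompute published statistics from deposited GenBank records
  require network access to NCBI; everything else runs offline).
- `docs/methods.md` — models, conventions and limitations.
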
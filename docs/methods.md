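# Methods

This note records the models, conventions and numerical choices behind
mitocompare, the reasoning where a design was genuinely open, and what the
synthetic-data cross-validation does and does not demonstrate.

## Coordinates, names and the ancestral arrangement

Internally every feature is 0-based, half-open on the annotated sequence;
GenBank I/O converts from/to the flat file's 1-based inclusive convention.
Features spanning the origin of a circular genome are stored as two joined
segments under one feature identity. When a gene carries both a bare
`gene` feature and a typed `CDS`/`tRNA`/`rRNA` feature, the typed
coordinates win (the GenBank convention). Names are resolved through an
alias table (case- and punctuation-insensitive) to the canonical 37-gene
vocabulary; `tRNA-Leu`/`tRNA-Ser` without a codon-family qualifier are
disambiguated by anticodon (UAG→trnL1, UAA→trnL2, GCU/UCU→trnS1,
UGA→trnS2). A name that cannot be resolved is kept, flagged `unresolved`,
and excluded from analysis — never guessed and never silently dropped.
"Complete" means all 37 genes plus a control region are annotated;
anything less is treated as a partial assembly.

The ancestral insect arrangement used as the rearrangement reference is
the Drosophila-like gene order, stored as a signed circular constant
(minority-strand genes carry a minus sign). It is never mutated.

## Composition and RSCU

Composition is computed over the concatenation of all annotated PCGs,
each taken in coding orientation and ordered by ancestral gene order.
Computing on coding-orientation extractions (rather than one raw genome
strand) is deliberate: it matches how gene sequences are exported by
annotation tools, makes the statistic invariant to which strand a record
happens to be submitted on, and is the scope in which published
ichneumonid tables are reported. Ambiguity bases (N) count toward lengths
but are excluded from all numerators and denominators; skews are null
when their denominator is zero. Full precision is kept internally;
reports round percentages to 2 d.p., skews to 4 d.p. and rates to 5 d.p.

RSCU uses translation table 5. The L1/L2/S1/S2 family split is the
default because it is how insect-mitogenome codon-usage figures are
conventionally drawn; a merged-family mode (all six Leu or Ser codons in
one family) is available as a switch. Stop codons (TAA/TAG), codons
containing N, and incomplete terminal triplets are excluded from tallies.
Entirely unused families report RSCU 0 for all members.

## Ka/Ks

Counting follows the classic Nei–Gojobori scheme. Site counts: each of a
codon's nine single-base changes is classified under table 5; changes
creating stops count as nonsynonymous, so s + n = 3 for every codon.
Difference counts: averaged over all minimal mutational pathways between
two codons, excluding pathways whose *intermediate* codons are stops; if
every pathway is poisoned, all pathways are used and the pair is flagged.
In a pairwise comparison, potential sites are averaged between the two
sequences and summed over columns; columns with a gap, an N, or a stop
codon in either sequence are skipped, and incomplete terminal codons are
trimmed before analysis.

The uncorrected proportions pS = Sd/S and pN = Nd/N are what counting
methods conventionally report as Ks and Ka; the Jukes–Cantor correction
d = −(3/4)ln(1 − 4p/3) inflates both (reported as JKs/JKa), returning
null at saturation (p ≥ 0.75). Both series are always emitted, as is the
uncorrected and corrected ratio.

Pairwise alignment is protein-level global Needleman–Wunsch (match +1,
mismatch −1, gap −2; ties resolved preferring the diagonal move, then the
vertical) back-translated to codons so gaps occur in whole-codon units.
The aligner is written in-package because the deterministic tie-break
order is part of the reproducibility contract; externally pre-aligned
sequences can be supplied instead. Multi-taxon gene summaries average
over all unordered pairs; the headline ratio is the ratio of mean
components (mean Ka over mean Ks), with the mean of per-pair ratios as a
secondary column, because the two disagree whenever rates vary across
pairs and the component version is the stabler summary.

No likelihood-based estimators (GY94/YN00) are provided; that is a
deliberate non-goal.

## Rearrangement classification

Observed and ancestral orders are restricted to their shared genes before
comparison, so partial assemblies cannot create spurious events; the
control region is excluded from event calling (it is routinely
unassembled). Circular orders are compared under the rotation that
explains the observed order with the fewest moved genes; rotations
aligning one of several well-spaced anchor genes (cox1, cob, nad4, nad2,
rrnL) are tried first and an exhaustive rotation scan is the fallback, so
the classification is invariant under rotation of the input.

Moved genes are the complement of a longest common subsequence of the two
restricted orders. The LCS backtrack tie-break is fixed (prefer skipping
the current observed element), which makes the attribution of an
adjacent-gene swap deterministic: the ancestrally later gene of the pair
is reported as moved. Co-moving genes — adjacent in both orders, in the
same relative order, with the same strand status — are merged into a
single block event.

Event kinds are decided by the *anchor genes* (PCGs and rRNAs) a move
crosses rather than by rank displacement alone: a tRNA hopping within its
cluster and one hopping out of it can have identical rank displacements
while being biologically different events. A move crossing no anchor (or
an adjacent-neighbour swap, displacement 1) is a **shuffle**; crossing
exactly one anchor is a **translocation** (the gene joined an adjacent
cluster); crossing two or more is a **remote translocation**. A strand
flip without movement is an **inversion**; a moved gene whose strand also
flipped is an **inverted translocation**. The rank-displacement window
(default w = 3) is retained as a reported diagnostic field and a
configurable knob, but it does not decide the kind: a displacement
threshold cannot separate the within-cluster swap from the one-anchor hop,
whereas anchor crossing reproduces the labels used in the comparative
literature for the classic wasp cases (trnW-trnC-trnY → trnW-trnY-trnC as
a shuffle; trnQ joining that cluster as a translocation with a shuffle of
trnY; a far-moved trnK as a remote translocation).

Breakpoint distance counts signed, orientation-aware adjacencies present
in one order but absent in the other after restriction to shared genes;
an adjacency equals its reverse complement. The wrap-around adjacency
participates only when both orders are circular and free of assembly
gaps. No rearrangement *mechanism* inference (tandem duplication /
random loss, DCJ optimisation) is attempted.

## Synthetic-data generator

The generator emulates the statistical structure of a small comparative
mitogenomics study so the estimators can be validated against known
truth. Its defaults are the study conditions, chosen once:

- **Base composition** (coding strand): A 0.3608, T 0.4592, G 0.0855,
  C 0.0945 — A+T = 0.82, AT-skew = −0.12, GC-skew = −0.05, the middle of
  the range reported for ichneumonid PCGs.
- **PCG lengths**: a realistic per-gene table totalling 11,121 bp
  (cox1 1536 … atp8 162), all multiples of 3; tRNAs 66 bp, rrnL 1320 bp,
  rrnS 780 bp, control region 420 bp (droppable, since real short-read
  assemblies usually lack it).
- **Divergence targets**: pS = 0.20, pN = 0.10 per derived taxon relative
  to taxon 0.
- **Randomness**: one root seed; every (taxon, gene) pair draws from its
  own substream, so adding a taxon or gene never perturbs the others.

PCGs are built from an ATN start, internal codons drawn from the
product-of-base-probabilities distribution restricted to sense codons
(optionally reweighted per codon), and a TAA/TAG stop. Because excluding
the AT-rich stops shifts the realised composition slightly, the spec
exposes the exact analytic expectation of the PCG base counts; recovery
tests compare against that expectation at multinomial-sampling accuracy
rather than against the nominal probabilities.

Divergence is injected codon-by-codon: at most one substitution per codon
(so the estimator's pathway counting classifies each difference
unambiguously), with per-alternative acceptance probabilities tuned so
the expected realised (pS, pN) equal the targets; stops are never
introduced and start/stop codons are preserved. Substitutions shift the
mutated sequence's potential-site totals, and since the estimator divides
by sites averaged over both sequences this would bias recovery by a few
percent; the generator therefore rescales its rates by the analytically
expected site shift. At divergences too high for one event per codon to
carry the target rate, it falls back to independent per-position events,
which reintroduces a little pathway-averaging noise. Non-coding genes are
mutated at the PCG-average per-site rate.

Rearrangement events are *realized*: the generator tries candidate
placements of the moved gene and accepts the first the classifier reads
back as exactly the requested (gene, kind), preferring the most local
realization (fewest anchors crossed, then smallest displacement). This
closes the loop between the generative vocabulary and the classifier by
construction — which is precisely what the round-trip property tests
rely on — at the cost that the generator cannot produce an event the
classifier would mislabel.

What the generator does **not** emulate: codon-usage correlation along a
gene, among-site rate variation, composition drift constrained by
selection (derived taxa drift toward base-uniform composition, so their
A+T% falls below the preset), indels within PCGs, duplicated genes,
tree-structured relationships among more than two taxa (taxa are i.i.d.
derivations of taxon 0), or a replication-origin mutational gradient.
Passing recovery tests therefore demonstrates the correctness of the
counting, correction and classification machinery — not that real
mitogenomes satisfy these models.

## Reporting conventions

Reports order species by input order; TSVs carry fixed formats (2 d.p.
percentages, 4 d.p. skews, 5 d.p. rates), never comments; run metadata
goes to a sidecar JSON. Re-running with the same inputs and configuration
produces byte-identical outputs. Every number in a report comes from one
library operation; the report layer only rounds.

## Known limitations

- Moves that cross the chosen linearization cut of a circular order can
  be classified more "remotely" than their circular geometry warrants;
  the rotation search minimises how often this matters, and none of the
  documented wasp cases are affected.
- The anchor-crossing definition of shuffle vs. translocation is a
  formalisation of vocabulary the comparative literature uses informally;
  other formalisations (displacement windows, common intervals) exist and
  give different labels in edge cases.
- DnaSP-style multi-sequence Ka/Ks behaviour is not specified publicly;
  the all-pairs mean used here is one defensible choice, and exact
  decimal agreement with figures produced by other alignment/averaging
  toolchains should not be expected.
- Reported Ks/Ka are difference proportions, not rate estimates under a
  codon model; at high divergence they saturate and the Jukes–Cantor
  correction returns null beyond p ≥ 0.75.
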
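"""Base composition, strand-skew and codon-usage statistics.

Skews quantify strand asymmetry of the coding strand:

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

Relative synonymous codon usage (RSCU) is a codon's observed count divided
by its expected count under uniform usage within its synonymous family;
families follow the invertebrate mitochondrial code (translation table 5)
with leucine split into L1 (CUN) and L2 (UUR) and serine into S1 (AGN)
and S2 (UCN), the categories conventional for insect mitogenome reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .catalog import ANCESTRAL_ORDER, PCGS

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: sense codons of the invertebrate mitochondrial code (DNA alphabet)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE5.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)


def codon_family(codon: str, split: bool = True) -> str:
    """Synonymous-family label of a sense codon.

    With ``split=True`` (default) the six leucine codons form two families
    L1 (CUN) / L2 (UUR) and the six serine codons S1 (AGN) / S2 (UCN);
    otherwise families are plain amino acids.
    """
    aa = _TABLE5.forward_table[codon]
    if not split:
        return aa
    if aa == "L":
        return "L1" if codon.startswith("CT") else "L2"
    if aa == "S":
        return "S1" if codon.startswith("AG") else "S2"
    return aa


#: family -> codons, under the split convention
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(codon_family(_c), ())
    FAMILIES[codon_family(_c)] += (_c,)


@dataclass
class CompositionProfile:
    """Base counts and derived skew statistics for a sequence set.

    ``total_length`` includes ambiguity bases (N), which are excluded from
    the A/T/G/C counts and hence from every percentage and skew.
    """

    a: int
    t: int
    g: int
    c: int
    total_length: int
    scope: str = ""

    @property
    def counted(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def at_percent(self) -> float | None:
        if self.counted == 0:
            return None
        return 100.0 * (self.a + self.t) / self.counted

    @property
    def at_skew(self) -> float | None:
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float | None:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)


def base_counts(seqs: list[str], scope: str = "") -> CompositionProfile:
    """Summed A/T/G/C counts over a list of sequences (N excluded from the
    counts, included in total length)."""
    a = t = g = c = total = 0
    for si, seq in enumerate(seqs):
        seq = seq.upper()
        for pos, ch in enumerate(seq):
            if ch == "A":
                a += 1
            elif ch == "T":
                t += 1
            elif ch == "G":
                g += 1
            elif ch == "C":
                c += 1
            elif ch != "N":
                raise ValueError(
                    f"non-IUPAC character {ch!r} at sequence {si}, position {pos}")
        total += len(seq)
    return CompositionProfile(a=a, t=t, g=g, c=c, total_length=total, scope=scope)


def skews(profile: CompositionProfile) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew); a skew is None when its denominator is zero."""
    return profile.at_skew, profile.gc_skew


def pcg_composition(genome) -> CompositionProfile:
    """Composition profile over the concatenated protein-coding genes.

    Each PCG is taken in coding orientation and genes are concatenated in
    ancestral gene order; partial genomes contribute the PCGs they carry.
    Values are kept at full precision — rounding (two decimals for
    percentages, four for skews) happens only in reports.
    """
    from .genome_io import extract_gene_sequence

    anc_rank = {g: i for i, (g, _) in enumerate(ANCESTRAL_ORDER)}
    present = [g for g in sorted(PCGS, key=anc_rank.__getitem__)
               if genome.has_gene(g)]
    if not present:
        raise ValueError(f"genome {genome.id!r} has no protein-coding genes")
    seqs = [extract_gene_sequence(genome, g) for g in present]
    return base_counts(seqs, scope=f"PCGs concatenated ({genome.id})")


def rscu(coding_seqs: list[str], split_families: bool = True) -> pd.DataFrame:
    """RSCU table from in-frame coding sequences.

    Codons are tallied under translation table 5; stop codons, codons
    containing N and incomplete terminal triplets are excluded.  Returns a
    DataFrame with columns codon (RNA alphabet), family, count, rscu; the
    attribute ``genetic_code`` records the table id.

    RSCU(codon) = count * family_size / family_total; zero for unused
    codons of used families, and 0 by convention for entirely unused
    families.
    """
    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for seq in coding_seqs:
        seq = seq.upper()
        if len(seq) < 3:
            import logging
            logging.getLogger(__name__).warning(
                "rscu: sequence shorter than one codon skipped")
            continue
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if codon in counts:
                counts[codon] += 1
            # stop codons, N-containing codons: excluded

    rows = []
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fams.setdefault(codon_family(codon, split_families), []).append(codon)
    for fam, codons in sorted(fams.items()):
        total = sum(counts[c] for c in codons)
        size = len(codons)
        for c in sorted(codons):
            val = counts[c] * size / total if total else 0.0
            rows.append({"codon": c.replace("T", "U"), "family": fam,
                         "count": counts[c], "rscu": val})
    df = pd.DataFrame(rows)
    df.attrs["genetic_code"] = 5
    df.attrs["split_families"] = split_families
    return df
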
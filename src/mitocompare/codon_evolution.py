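"""Pairwise Ka/Ks by Nei–Gojobori counting with Jukes–Cantor correction.

The estimator follows the classic counting approach: every codon
contributes fractional synonymous (S) and nonsynonymous (N) *sites*
according to the effect of its nine possible single-base changes under the
invertebrate mitochondrial code, and every differing codon pair
contributes synonymous/nonsynonymous *differences* averaged over all
minimal mutational pathways between the codons, excluding pathways through
stop codons.  The observed proportions pS = Sd/S and pN = Nd/N are then
corrected for multiple hits with the Jukes–Cantor formula

    d = -(3/4) ln(1 - (4/3) p)

yielding the corrected rates (reported as JKs / JKa alongside the
uncorrected pS / pN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_FORWARD = dict(_TABLE5.forward_table)
_STOPS = frozenset(_TABLE5.stop_codons)
_BASES = "ACGT"

GAP_CODON = "---"


def _aa(codon: str) -> str:
    return _FORWARD.get(codon, "*")


def translate(codon_seq: str) -> str:
    """Translate under the invertebrate mitochondrial code (table 5:
    UGA=Trp, AGA/AGG=Ser, AUA=Met).  A trailing incomplete codon is
    dropped with a warning; internal stops translate to ``*``."""
    seq = codon_seq.upper().replace("U", "T")
    if len(seq) % 3:
        logger.warning("translate: trailing %d-base remainder dropped",
                       len(seq) % 3)
        seq = seq[: len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        out.append(_aa(codon) if set(codon) <= set(_BASES) else "X")
    return "".join(out)


# ---------------------------------------------------------------------------
# pairwise protein alignment, back-translated to codons

@dataclass
class CodonAlignment:
    """Two gap-aligned in-frame codon sequences (gaps in whole codons)."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon lists differ in length")

    def __len__(self) -> int:
        return len(self.codons_a)

    def columns(self):
        for ca, cb in zip(self.codons_a, self.codons_b):
            yield ca, cb, (ca != GAP_CODON and cb != GAP_CODON)


def _nw_protein(a: str, b: str,
                match: int = 1, mismatch: int = -1, gap: int = -2
                ) -> tuple[str, str]:
    """Global Needleman–Wunsch with deterministic tie-breaking: diagonal
    preferred, then the vertical (gap-in-b) move."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0=diag 1=up 2=left
    for i in range(1, n + 1):
        score[i][0] = i * gap
        move[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * gap
        move[0][j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1][j] + gap
            l = score[i][j - 1] + gap
            best = max(d, u, l)
            score[i][j] = best
            move[i][j] = 0 if d == best else (1 if u == best else 2)
    out_a, out_b = [], []
    i, j = n, m
    while i or j:
        mv = move[i][j]
        if mv == 0:
            out_a.append(i - 1)
            out_b.append(j - 1)
            i -= 1
            j -= 1
        elif mv == 1:
            out_a.append(i - 1)
            out_b.append(None)
            i -= 1
        else:
            out_a.append(None)
            out_b.append(j - 1)
            j -= 1
    return out_a[::-1], out_b[::-1]


def codon_align(seq_a: str, seq_b: str) -> CodonAlignment:
    """Codon-aware pairwise alignment.

    The two coding sequences are translated (table 5), globally aligned at
    the protein level, and the alignment is back-translated to codons so
    gaps occur only in whole-codon units.
    """
    if not seq_a or not seq_b:
        raise ValueError("codon_align requires two non-empty sequences")
    sa = seq_a.upper().replace("U", "T")
    sb = seq_b.upper().replace("U", "T")
    sa = sa[: len(sa) - len(sa) % 3]
    sb = sb[: len(sb) - len(sb) % 3]
    pa, pb = translate(sa), translate(sb)
    idx_a, idx_b = _nw_protein(pa, pb)
    cod_a = [GAP_CODON if i is None else sa[3 * i: 3 * i + 3] for i in idx_a]
    cod_b = [GAP_CODON if j is None else sb[3 * j: 3 * j + 3] for j in idx_b]
    return CodonAlignment(cod_a, cod_b)


# ---------------------------------------------------------------------------
# Nei–Gojobori counting

def ng_sites(codon: str) -> tuple[float, float]:
    """Potential synonymous and nonsynonymous sites of one codon.

    Each of the nine single-base changes is classified under table 5;
    changes creating stop codons count as nonsynonymous.  Returns
    (s, n) with s + n = 3.
    """
    codon = codon.upper().replace("U", "T")
    if set(codon) - set(_BASES):
        raise ValueError(f"ambiguous codon {codon!r}")
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == aa0:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Counts are averaged over all minimal mutational pathways; pathways
    passing through a stop codon are excluded.  When every pathway hits a
    stop, all pathways are used instead and the third return value flags
    the fallback.
    """
    a = codon_a.upper().replace("U", "T")
    b = codon_b.upper().replace("U", "T")
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0, False

    def walk(order):
        # a path is poisoned when an *intermediate* codon (not the given
        # endpoints) is a stop
        sd = nd = 0.0
        cur = a
        poisoned = False
        for k, p in enumerate(order):
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if cur not in _STOPS and nxt not in _STOPS and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            if nxt in _STOPS and k < len(order) - 1:
                poisoned = True
            cur = nxt
        return sd, nd, poisoned

    paths = [walk(order) for order in permutations(diff)]
    clean = [(sd, nd) for sd, nd, poisoned in paths if not poisoned]
    fallback = not clean
    use = clean if clean else [(sd, nd) for sd, nd, _ in paths]
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(y for _, y in use) / len(use)
    return sd, nd, fallback


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); None at
    saturation (p >= 0.75)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        logger.warning("jukes_cantor: p=%.4f saturated", p)
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# per-pair and per-gene summaries

@dataclass
class KaKsResult:
    """Site and difference counts with uncorrected and corrected rates.

    ``ps``/``pn`` are the uncorrected proportions Sd/S and Nd/N (the
    quantities usually reported as Ks and Ka by counting methods);
    ``jks``/``jka`` are their Jukes–Cantor corrections.  Ratios are None
    when their denominator is zero or a correction saturated.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int

    @property
    def ps(self) -> float:
        return self.sd / self.s_sites if self.s_sites else float("nan")

    @property
    def pn(self) -> float:
        return self.nd / self.n_sites if self.n_sites else float("nan")

    @property
    def jks(self) -> float | None:
        return jukes_cantor(self.ps) if self.s_sites else None

    @property
    def jka(self) -> float | None:
        return jukes_cantor(self.pn) if self.n_sites else None

    @property
    def ratio(self) -> float | None:
        """pN/pS (the uncorrected Ka/Ks)."""
        if not self.s_sites or self.ps == 0:
            return None
        return self.pn / self.ps

    @property
    def jratio(self) -> float | None:
        """JKa/JKs."""
        jks, jka = self.jks, self.jka
        if jks is None or jka is None or jks == 0:
            return None
        return jka / jks


def kaks_pair(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori counts over one pairwise codon alignment.

    Columns with a gap, an ambiguity base, or a stop codon in either
    sequence are skipped.  Potential sites are averaged between the two
    sequences and summed over columns.
    """
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb, both in aln.columns():
        if not both:
            continue
        if set(ca + cb) - set(_BASES):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        sa, na = ng_sites(ca)
        sb, nb = ng_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd, _ = ng_differences(ca, cb)
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise ValueError("no usable codon columns in alignment")
    return KaKsResult(s_sites=S, n_sites=N, sd=Sd, nd=Nd, n_codons=used)


@dataclass
class GeneKaKsSummary:
    """Mean pairwise rates for one gene across a genome set.

    Headline ratios are computed from the mean components (mean pN over
    mean pS); the mean of the per-pair ratios is kept as a secondary
    statistic since the two disagree whenever rates vary across pairs.
    """

    gene: str
    n_pairs: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ks: float            # mean pairwise pS
    ka: float            # mean pairwise pN
    jks: float | None
    jka: float | None
    ka_ks: float | None          # mean ka / mean ks
    jka_jks: float | None
    mean_ratio: float | None     # mean of per-pair pN/pS
    pairs: list[KaKsResult]


def gene_kaks_summary(genomes: list, gene: str) -> GeneKaKsSummary:
    """All-pairs Ka/Ks summary for one protein-coding gene."""
    from .genome_io import extract_gene_sequence

    carriers = [g for g in genomes if g.has_gene(gene)]
    if len(carriers) < 2:
        raise ValueError(f"gene {gene!r} present in fewer than 2 genomes")
    results: list[KaKsResult] = []
    for ga, gb in combinations(carriers, 2):
        aln = codon_align(extract_gene_sequence(ga, gene),
                          extract_gene_sequence(gb, gene))
        results.append(kaks_pair(aln))

    def mean(vals):
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    ks = mean([r.ps for r in results])
    ka = mean([r.pn for r in results])
    jks = mean([r.jks for r in results])
    jka = mean([r.jka for r in results])
    ratios = [r.ratio for r in results if r.ratio is not None]
    return GeneKaKsSummary(
        gene=gene,
        n_pairs=len(results),
        s_sites=mean([r.s_sites for r in results]),
        n_sites=mean([r.n_sites for r in results]),
        sd=mean([r.sd for r in results]),
        nd=mean([r.nd for r in results]),
        ks=ks, ka=ka, jks=jks, jka=jka,
        ka_ks=(ka / ks) if ks else None,
        jka_jks=(jka / jks) if jks else None,
        mean_ratio=mean(ratios),
        pairs=results,
    )
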
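"""Synthetic annotated mitogenomes with controlled statistical structure.

The generator emulates the inputs of an insect comparative-mitogenomics
study: 37-gene circular genomes in the ancestral arrangement with a
prescribed coding-strand base composition, pairwise synonymous /
nonsynonymous divergence, injected rearrangement events, and optionally
missing genes or an unassembled control region — so that every pipeline
stage (composition, RSCU, Ka/Ks, rearrangement classification) can be
exercised and cross-validated offline.

Randomness contract: one root seed; each (taxon, gene) pair draws from its
own substream, so adding a taxon or gene never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio.Seq import Seq

from .catalog import ANCESTRAL_ORDER, CR, PCGS, category_of
from .codon_evolution import _FORWARD, _STOPS, _aa
from .composition import CompositionProfile
from .gene_order import GeneOrder, detect_events
from .genome_io import GeneFeature, MitoGenome

_BASES = "ACGT"

#: realistic per-gene coding lengths (bp, divisible by 3; total 11,121 —
#: the scale typical for an ichneumonid PCG complement)
DEFAULT_PCG_LENGTHS: dict[str, int] = {
    "cox1": 1536, "cox2": 678, "cox3": 786, "cob": 1140, "nad1": 936,
    "nad2": 1002, "nad3": 351, "nad4": 1338, "nad4l": 288, "nad5": 1704,
    "nad6": 522, "atp6": 678, "atp8": 162,
}

#: ichneumonid-like coding-strand base probabilities: A+T = 0.82,
#: AT-skew = -0.12, GC-skew = -0.05
DEFAULT_BASE_PROBS: dict[str, float] = {
    "A": 0.3608, "T": 0.4592, "G": 0.0855, "C": 0.0945,
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    ``target_ps``/``target_pn`` are the synonymous/nonsynonymous
    difference proportions each derived taxon carries relative to taxon 0.
    ``events`` and ``missing_genes`` are keyed by taxon index.
    """

    seed: int = 0
    n_taxa: int = 4
    base_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_PROBS))
    codon_weights: dict[str, float] | None = None
    target_ps: float = 0.20
    target_pn: float = 0.10
    events: dict[int, list[tuple[str, str]]] = field(default_factory=dict)
    missing_genes: dict[int, list[str]] = field(default_factory=dict)
    pcg_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    trna_length: int = 66
    rrnl_length: int = 1320
    rrns_length: int = 780
    cr_length: int = 420
    include_cr: bool = True

    def __post_init__(self) -> None:
        tot = sum(self.base_probs.get(b, 0.0) for b in _BASES)
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"base probabilities sum to {tot}, not 1")
        if not (0 <= self.target_ps <= 0.74 and 0 <= self.target_pn <= 0.74):
            raise ValueError("divergence targets must lie in [0, 0.74]")
        for g, L in self.pcg_lengths.items():
            if L % 3 or L < 9:
                raise ValueError(f"PCG length for {g} must be a multiple of 3 >= 9")
        if all(self.base_probs.get(b, 0.0) == 0.0 for b in _BASES):
            raise ValueError("infeasible spec: zero-probability composition")

    # -- codon model ------------------------------------------------------

    def codon_distribution(self) -> tuple[list[str], np.ndarray]:
        """Sense-codon sampling distribution: product of base probabilities,
        optionally reweighted per codon, with stop codons removed."""
        codons, probs = [], []
        for c in ("".join(t) for t in product(_BASES, repeat=3)):
            if c in _STOPS:
                continue
            p = np.prod([self.base_probs[b] for b in c])
            if self.codon_weights:
                p *= self.codon_weights.get(c, 1.0)
            codons.append(c)
            probs.append(p)
        probs = np.asarray(probs, dtype=float)
        if probs.sum() <= 0:
            raise ValueError("infeasible spec: no codon has positive probability")
        return codons, probs / probs.sum()

    def expected_pcg_composition(self) -> CompositionProfile:
        """Analytic expectation of the PCG-concatenation base counts.

        Accounts for the fixed start (ATN) and stop (TAA/TAG) codons and
        the stop-exclusion renormalisation of internal codons, so recovered
        statistics can be compared at multinomial-sampling accuracy.
        """
        codons, probs = self.codon_distribution()
        e_codon = {b: 0.0 for b in _BASES}  # expected bases per internal codon
        for cod, p in zip(codons, probs):
            for b in cod:
                e_codon[b] += p
        # start ATN: one A, one T, third base from the base model
        e_start = {b: self.base_probs[b] for b in _BASES}
        e_start["A"] += 1.0
        e_start["T"] += 1.0
        # stop TA + (A or G), G chosen with the model's A/G odds
        pg = self.base_probs["G"] / (self.base_probs["A"] + self.base_probs["G"])
        e_stop = {"A": 1.0 + (1.0 - pg), "T": 1.0, "G": pg, "C": 0.0}
        total = {b: 0.0 for b in _BASES}
        for L in self.pcg_lengths.values():
            for b in _BASES:
                total[b] += (L // 3 - 2) * e_codon[b] + e_start[b] + e_stop[b]
        n = int(round(sum(total.values())))
        return CompositionProfile(a=total["A"], t=total["T"], g=total["G"],
                                  c=total["C"], total_length=n,
                                  scope="analytic expectation")


def _rng(spec: SimulationSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), *stream])


_GENE_INDEX = {g: i for i, (g, _) in enumerate(ANCESTRAL_ORDER)}


def _gene_length(spec: SimulationSpec, gene: str) -> int:
    cat = category_of(gene)
    if cat == "PCG":
        return spec.pcg_lengths[gene]
    if cat == "tRNA":
        return spec.trna_length
    if cat == "rRNA":
        return spec.rrnl_length if gene == "rrnL" else spec.rrns_length
    return spec.cr_length


def _draw_pcg(spec: SimulationSpec, rng: np.random.Generator, length: int) -> str:
    codons, probs = spec.codon_distribution()
    n_internal = length // 3 - 2
    start = "AT" + rng.choice(list(_BASES), p=[spec.base_probs[b] for b in _BASES])
    pg = spec.base_probs["G"] / (spec.base_probs["A"] + spec.base_probs["G"])
    stop = "TA" + ("G" if rng.random() < pg else "A")
    internal = rng.choice(len(codons), size=n_internal, p=probs)
    return start + "".join(codons[i] for i in internal) + stop


def simulate_genome(spec: SimulationSpec, taxon_index: int) -> MitoGenome:
    """One 37-gene annotated genome in the ancestral arrangement.

    Deterministic under (spec.seed, taxon_index).  Event injection,
    divergence and gene dropping are separate steps (:func:`apply_events`,
    :func:`evolve_pair`, :func:`drop_genes`).
    """
    features: list[GeneFeature] = []
    chunks: list[str] = []
    pos = 0
    for gene, sign in ANCESTRAL_ORDER:
        if gene == CR and (not spec.include_cr or spec.cr_length == 0):
            continue
        rng = _rng(spec, taxon_index, _GENE_INDEX[gene])
        length = _gene_length(spec, gene)
        if category_of(gene) == "PCG":
            coding = _draw_pcg(spec, rng, length)
        else:
            coding = "".join(rng.choice(list(_BASES), size=length,
                                        p=[spec.base_probs[b] for b in _BASES]))
        genomic = coding if sign > 0 else str(Seq(coding).reverse_complement())
        features.append(GeneFeature(
            canonical_name=gene, category=category_of(gene), strand=sign,
            segments=[(pos, pos + length)]))
        chunks.append(genomic)
        pos += length
    genome = MitoGenome(id=f"taxon{taxon_index}", sequence="".join(chunks),
                        circular=True, features=features)
    genome.complete = genome.infer_complete()
    return genome


# ---------------------------------------------------------------------------
# divergence

from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_alternatives(codon: str):
    """Single-base alternatives of a codon: (synonymous non-stop,
    nonsynonymous non-stop, count of nonsynonymous incl. stop-creating)."""
    syn: list[str] = []
    non: list[str] = []
    n_non_total = 0
    aa0 = _aa(codon)
    for p in range(3):
        for b in _BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt in _STOPS:
                n_non_total += 1
            elif _aa(alt) == aa0:
                syn.append(alt)
            else:
                non.append(alt)
                n_non_total += 1
    return syn, non, n_non_total


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    from .codon_evolution import ng_sites
    return ng_sites(codon)


def _site_corrected_targets(codons: list[str], ps: float, pn: float
                            ) -> tuple[float, float]:
    """Scale the divergence targets so the *estimated* proportions hit them.

    The counting estimator divides the observed differences by sites
    averaged over the two sequences; substitutions shift the mutated
    sequence's site totals (high-bias codons tend to mutate toward codons
    of different degeneracy), which would otherwise bias the recovered
    proportions by a few percent.  The expected post-mutation site totals
    are computed analytically and the applied rates rescaled accordingly.
    """
    S0 = N0 = S1 = N1 = 0.0
    for c in codons:
        if set(c) - set(_BASES) or c in _STOPS:
            continue
        syn, non, n_non_total = _codon_alternatives(c)
        s_c, n_c = _codon_sites(c)
        p_syn = ps / 3.0
        p_non = (pn * n_non_total / 3.0) / len(non) if non else 0.0
        es, en = s_c, n_c
        for alt in syn:
            ds = _codon_sites(alt)[0] - s_c
            es += p_syn * ds / 2.0
            en -= p_syn * ds / 2.0
        for alt in non:
            ds = _codon_sites(alt)[0] - s_c
            es += p_non * ds / 2.0
            en -= p_non * ds / 2.0
        S0 += s_c; N0 += n_c; S1 += es; N1 += en
    ps_eff = ps * S1 / S0 if S0 else ps
    pn_eff = pn * N1 / N0 if N0 else pn
    return ps_eff, pn_eff


def _mutate_codon(codon: str, rng: np.random.Generator,
                  ps: float, pn: float) -> str:
    """One substitution event per codon at most, with acceptance
    probabilities tuned so that the expected realized synonymous /
    nonsynonymous difference proportions equal the targets exactly under
    pathway counting (a single difference is classified unambiguously).
    Stops are never introduced.  At divergences where one event per codon
    cannot carry the target rate, up to one substitution per *position* is
    allowed instead (pathway averaging then adds a little noise)."""
    syn, non, n_non_total = _codon_alternatives(codon)
    # per-alternative probabilities: E[sd] = ps * total_syn/3 = ps * S_codon,
    # E[nd] = pn * n_non_total/3 = pn * N_codon
    p_syn = ps / 3.0
    p_non = (pn * n_non_total / 3.0) / len(non) if non else 0.0
    total = p_syn * len(syn) + p_non * len(non)
    if total <= 0.95:
        u = rng.random()
        for alt in syn:
            u -= p_syn
            if u < 0:
                return alt
        for alt in non:
            u -= p_non
            if u < 0:
                return alt
        return codon
    # high-divergence fallback: independent events per position
    out = codon
    for p in range(3):
        syn_p = [a for a in syn if a[p] != codon[p]]
        non_p = [a for a in non if a[p] != codon[p]]
        a_p = min(ps * len(syn_p) / 3.0, 1.0)
        b_p = (pn * n_non_total / 3.0) * (len(non_p) / len(non)) if non else 0.0
        u = rng.random()
        if u < a_p and syn_p:
            alt = syn_p[rng.integers(len(syn_p))]
            out = out[:p] + alt[p] + out[p + 1:]
        elif u < a_p + b_p and non_p:
            alt = non_p[rng.integers(len(non_p))]
            out = out[:p] + alt[p] + out[p + 1:]
    return out


def evolve_pair(genome: MitoGenome, target_ps: float, target_pn: float,
                seed: int) -> MitoGenome:
    """Derived genome with PCGs mutated codon-by-codon toward target
    (pS, pN) relative to the input; start/stop codons are preserved and
    stop codons are never created.  Non-coding genes are mutated at the
    PCG-average per-site rate."""
    if not (0 <= target_ps < 0.75 and 0 <= target_pn < 0.75):
        raise ValueError("targets must lie in [0, 0.75)")
    from .genome_io import extract_gene_sequence

    seq = list(genome.sequence)
    # average per-site substitution proportion: S:N site split is roughly
    # 1:3 for these codes
    avg_rate = 0.25 * target_ps + 0.75 * target_pn
    internal: list[str] = []
    for f in genome.features:
        if f.category == "PCG" and not f.unresolved:
            coding = extract_gene_sequence(genome, f.canonical_name)
            internal.extend(coding[i:i + 3]
                            for i in range(3, len(coding) - len(coding) % 3 - 3, 3))
    ps_eff, pn_eff = _site_corrected_targets(internal, target_ps, target_pn)
    for f in sorted(genome.features, key=lambda f: f.start):
        if f.unresolved or f.category == "CR":
            continue
        rng = np.random.default_rng(
            [seed % (2**31), _GENE_INDEX.get(f.canonical_name, 99)])
        coding = extract_gene_sequence(genome, f.canonical_name)
        if f.category == "PCG":
            codons = [coding[i:i + 3] for i in range(0, len(coding) - len(coding) % 3, 3)]
            new = [codons[0]]
            for c in codons[1:-1]:
                if set(c) <= set(_BASES) and c not in _STOPS:
                    new.append(_mutate_codon(c, rng, ps_eff, pn_eff))
                else:
                    new.append(c)
            new.append(codons[-1])
            mutated = "".join(new) + coding[len(codons) * 3:]
        else:
            bases = list(coding)
            hits = rng.random(len(bases)) < avg_rate
            for i in np.flatnonzero(hits):
                alts = [b for b in _BASES if b != bases[i]]
                bases[i] = alts[rng.integers(3)]
            mutated = "".join(bases)
        genomic = mutated if f.strand > 0 else str(Seq(mutated).reverse_complement())
        cursor = 0
        for s, e in f.segments:
            seq[s:e] = genomic[cursor:cursor + (e - s)]
            cursor += e - s
    out = MitoGenome(id=f"{genome.id}_derived", sequence="".join(seq),
                     circular=genome.circular,
                     features=[GeneFeature(f.canonical_name, f.category,
                                           f.strand, list(f.segments),
                                           f.anticodon, f.raw_name, f.unresolved)
                               for f in genome.features])
    out.complete = genome.complete
    return out


def simulate_taxa(spec: SimulationSpec) -> list[MitoGenome]:
    """Full study set: taxon 0 plus derived taxa at the spec's divergence
    targets, with per-taxon events injected and genes dropped."""
    base = simulate_genome(spec, 0)
    genomes = [base]
    for i in range(1, spec.n_taxa):
        g = evolve_pair(base, spec.target_ps, spec.target_pn,
                        seed=spec.seed * 1000 + i)
        g.id = f"taxon{i}"
        genomes.append(g)
    out = []
    for i, g in enumerate(genomes):
        if spec.events.get(i):
            g = apply_events(g, spec.events[i], seed=spec.seed)
            g.id = f"taxon{i}"
        if spec.missing_genes.get(i):
            g = drop_genes(g, spec.missing_genes[i])
            g.id = f"taxon{i}"
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# rearrangement injection

def _order_of(blocks: list[tuple[GeneFeature, str]]) -> GeneOrder:
    return GeneOrder(genes=[(f.canonical_name, f.strand) for f, _ in blocks],
                     circular=True)


def apply_events(genome: MitoGenome, events: list[tuple[str, str]],
                 seed: int = 0) -> MitoGenome:
    """Inject rearrangement events, keeping sequence and annotation
    consistent.

    Each event (gene, kind) is *realized* by searching candidate
    placements (nearest insertion gaps first) and accepting the first one
    that the classifier reads back as exactly the requested event; pure
    inversions simply flip the strand in place.  This guarantees the
    generative vocabulary and the classifier agree by construction.
    """
    genes_seen = [g for g, _ in events]
    if len(genes_seen) != len(set(genes_seen)):
        raise ValueError("conflicting events: a gene may appear only once")

    from .genome_io import extract_gene_sequence

    blocks: list[tuple[GeneFeature, str]] = []
    for f in sorted(genome.features, key=lambda f: f.start):
        coding = extract_gene_sequence(genome, f.canonical_name) \
            if not f.unresolved else genome.sequence[f.start:f.end]
        # copy: the input genome must never be mutated
        blocks.append((GeneFeature(f.canonical_name, f.category, f.strand,
                                   list(f.segments), f.anticodon, f.raw_name,
                                   f.unresolved), coding))

    applied: list[tuple[str, str]] = []
    for gene, kind in events:
        idx = next((i for i, (f, _) in enumerate(blocks)
                    if f.canonical_name == gene), None)
        if idx is None:
            raise ValueError(f"cannot apply event to absent gene {gene!r}")
        if kind == "inversion":
            f, s = blocks[idx]
            f.strand = -f.strand
            applied.append((gene, kind))
            continue
        want_flip = kind == "inverted_translocation"
        feat, coding = blocks[idx]
        rest = blocks[:idx] + blocks[idx + 1:]
        # try every insertion gap; among placements the classifier reads
        # back as exactly the requested event, prefer the one crossing the
        # fewest anchors, then the smallest displacement (the most local
        # realization of the event)
        expected = sorted(applied + [(gene, kind)])
        matches = []
        for j in range(len(rest) + 1):
            trial_feat = GeneFeature(feat.canonical_name, feat.category,
                                     -feat.strand if want_flip else feat.strand,
                                     list(feat.segments), feat.anticodon)
            trial = rest[:j] + [(trial_feat, coding)] + rest[j:]
            evts = detect_events(_order_of(trial))
            if sorted((e.gene, e.kind) for e in evts) == expected:
                this = next(e for e in evts if e.gene == gene)
                matches.append(((this.anchors_crossed,
                                 this.displacement, j), trial))
        if not matches:
            raise ValueError(f"no placement realizes {kind} for {gene!r}")
        blocks = min(matches, key=lambda m: m[0])[1]
        applied.append((gene, kind))

    # rebuild sequence and coordinates
    chunks: list[str] = []
    pos = 0
    new_feats: list[GeneFeature] = []
    for f, coding in blocks:
        genomic = coding if f.strand > 0 else str(Seq(coding).reverse_complement())
        length = len(coding)
        new_feats.append(GeneFeature(f.canonical_name, f.category, f.strand,
                                     [(pos, pos + length)], f.anticodon,
                                     f.raw_name, f.unresolved))
        chunks.append(genomic)
        pos += length
    out = MitoGenome(id=genome.id, sequence="".join(chunks),
                     circular=genome.circular, features=new_feats)
    out.complete = genome.complete
    return out


def drop_genes(genome: MitoGenome, names: list[str],
               excise: bool = True) -> MitoGenome:
    """Remove genes (emulating unassembled/absent genes).  With ``excise``
    the underlying sequence is removed too; otherwise only the annotation
    is dropped."""
    drop = set(names)
    kept = [f for f in genome.features if f.canonical_name not in drop]
    if not excise:
        out = MitoGenome(id=genome.id, sequence=genome.sequence,
                         circular=genome.circular,
                         features=[GeneFeature(f.canonical_name, f.category,
                                               f.strand, list(f.segments),
                                               f.anticodon, f.raw_name,
                                               f.unresolved) for f in kept])
        out.complete = out.infer_complete()
        return out
    keep_mask = np.ones(len(genome.sequence), dtype=bool)
    for f in genome.features:
        if f.canonical_name in drop:
            for s, e in f.segments:
                keep_mask[s:e] = False
    # removed_before[x] = number of excised bases in [0, x)
    removed_before = np.concatenate([[0], np.cumsum(~keep_mask)])
    new_feats = []
    for f in kept:
        segs = [(s - int(removed_before[s]), e - int(removed_before[e]))
                for s, e in f.segments]
        new_feats.append(GeneFeature(f.canonical_name, f.category, f.strand,
                                     segs, f.anticodon, f.raw_name, f.unresolved))
    new_seq = "".join(ch for ch, k in zip(genome.sequence, keep_mask) if k)
    out = MitoGenome(id=genome.id, sequence=new_seq,
                     circular=genome.circular, features=new_feats)
    out.complete = out.infer_complete()
    return out
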
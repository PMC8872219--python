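"""Nei–Gojobori counting, Jukes–Cantor correction and codon alignment,
checked against independent exhaustive-enumeration oracles."""

import itertools
import random

import pytest
from Bio.Seq import Seq

from mitocompare.codon_evolution import (CodonAlignment, GAP_CODON,
                                         codon_align, gene_kaks_summary,
                                         jukes_cantor, kaks_pair,
                                         ng_differences, ng_sites, translate)

BASES = "ACGT"
STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code
SENSE = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
         if c not in STOPS]


def _aa(codon: str) -> str:
    """Independent translation via Biopython's Seq machinery."""
    return "*" if codon in STOPS else str(Seq(codon).translate(table=5))


def oracle_sites(codon: str):
    """Brute-force site counts: classify all nine single-base changes."""
    syn = 0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if alt not in STOPS and _aa(alt) == _aa(codon):
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_differences(a: str, b: str):
    """Brute-force pathway enumeration, excluding stop-traversing paths."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    results, fallback_results = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, poisoned = a, 0, 0, False
        for k, p in enumerate(order):
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if cur not in STOPS and nxt not in STOPS and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            if nxt in STOPS and k < len(order) - 1:
                poisoned = True
            cur = nxt
        fallback_results.append((sd, nd))
        if not poisoned:
            results.append((sd, nd))
    use = results or fallback_results
    return (sum(x for x, _ in use) / len(use),
            sum(y for _, y in use) / len(use))


class TestTranslate:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGTGA", "MW"),       # UGA is tryptophan in this code
        ("AGA", "S"),           # AGA is serine, not arginine/stop
        ("ATA", "M"),           # AUA is methionine
        ("", ""),
        ("TAA", "*"),
        ("ATGCC", "M"),         # trailing remainder dropped
    ])
    def test_table5_translation(self, seq, expected):
        assert translate(seq) == expected


class TestNgSites:
    def test_phenylalanine_third_position(self):
        s, n = ng_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    @pytest.mark.parametrize("codon", SENSE)
    def test_matches_enumeration_oracle_on_all_sense_codons(self, codon):
        s, n = ng_sites(codon)
        es, en = oracle_sites(codon)
        assert s == pytest.approx(es)
        assert n == pytest.approx(en)
        assert s + n == pytest.approx(3.0)


class TestNgDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),       # Phe -> Leu, nonsynonymous
        ("TTA", "CTG", (2.0, 0.0)),       # both 2-step paths Leu throughout
    ])
    def test_frozen_examples(self, a, b, expected):
        sd, nd, _ = ng_differences(a, b)
        assert (sd, nd) == pytest.approx(expected)

    def test_matches_pathway_oracle_on_random_pairs(self):
        rng = random.Random(20240917)
        for _ in range(500):
            a, b = rng.choice(SENSE), rng.choice(SENSE)
            sd, nd, _ = ng_differences(a, b)
            esd, end = oracle_differences(a, b)
            assert sd == pytest.approx(esd), (a, b)
            assert nd == pytest.approx(end), (a, b)

    def test_symmetry(self):
        rng = random.Random(5)
        for _ in range(100):
            a, b = rng.choice(SENSE), rng.choice(SENSE)
            assert ng_differences(a, b)[:2] == pytest.approx(
                ng_differences(b, a)[:2])


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=5e-5)

    def test_monotone_and_inflating(self):
        assert jukes_cantor(0.2) < jukes_cantor(0.3)
        for p in (0.01, 0.1, 0.3, 0.5, 0.7):
            assert jukes_cantor(p) > p

    def test_saturation_returns_none(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)


class TestCodonAlign:
    def test_identical_sequences_align_without_gaps(self):
        seq = "ATGTTTGGGAAA"
        aln = codon_align(seq, seq)
        assert all(both for _, _, both in aln.columns())
        assert aln.codons_a == aln.codons_b

    def test_internal_codon_deletion_yields_one_gap(self):
        a = "ATGTTTGGGTGTAAA"
        b = "ATGTTTTGTAAA"     # GGG deleted
        aln = codon_align(a, b)
        assert aln.codons_b.count(GAP_CODON) == 1
        assert aln.codons_a[aln.codons_b.index(GAP_CODON)] == "GGG"
        assert aln.codons_a.count(GAP_CODON) == 0

    def test_aligned_length_at_least_max_input(self):
        a, b = "ATGAAATTTCCCGGG", "TGTCATGATCAGGAA"
        aln = codon_align(a, b)
        assert len(aln) >= 5


class TestKaKsPair:
    def test_identical_genes_have_zero_rates_and_null_ratio(self):
        aln = codon_align("ATGTTTGGG", "ATGTTTGGG")
        r = kaks_pair(aln)
        assert r.ps == 0 and r.pn == 0
        assert r.ratio is None

    def test_two_codon_toy_alignment_hand_enumerated(self):
        # TTT/TTA: sites (1/3+2/3)/2, one nonsyn difference;
        # GGG/GGA: sites (1+1)/2, one syn difference
        r = kaks_pair(CodonAlignment(["TTT", "GGG"], ["TTA", "GGA"]))
        assert r.s_sites == pytest.approx(1.5)
        assert r.n_sites == pytest.approx(4.5)
        assert (r.sd, r.nd) == (1.0, 1.0)
        assert r.ps == pytest.approx(2 / 3)
        assert r.pn == pytest.approx(2 / 9)

    def test_sites_conservation(self):
        rng = random.Random(3)
        codons_a = [rng.choice(SENSE) for _ in range(60)]
        codons_b = [rng.choice(SENSE) for _ in range(60)]
        r = kaks_pair(CodonAlignment(codons_a, codons_b))
        assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons)

    def test_gap_and_stop_columns_skipped(self):
        aln = CodonAlignment(["TTT", GAP_CODON, "TAA", "GGG"],
                             ["TTT", "AAA", "TTA", "GGG"])
        assert kaks_pair(aln).n_codons == 2

    def test_all_columns_unusable_is_an_error(self):
        with pytest.raises(ValueError):
            kaks_pair(CodonAlignment([GAP_CODON], ["AAA"]))


class TestGeneSummary:
    def test_identical_genomes_give_zero_summary(self, mini_genome):
        import copy
        g2 = copy.deepcopy(mini_genome)
        g2.id = "copy"
        s = gene_kaks_summary([mini_genome, g2], "cox1")
        assert s.ks == 0 and s.ka == 0 and s.ka_ks is None

    def test_mean_equals_brute_force_average_over_pairs(self, default_spec):
        from itertools import combinations
        from mitocompare.genome_io import extract_gene_sequence
        from mitocompare.simulate import evolve_pair, simulate_genome
        base = simulate_genome(default_spec, 0)
        taxa = [base,
                evolve_pair(base, 0.10, 0.05, seed=21),
                evolve_pair(base, 0.20, 0.10, seed=22)]
        s = gene_kaks_summary(taxa, "nad3")
        assert s.n_pairs == 3
        expected_ks = []
        for ga, gb in combinations(taxa, 2):
            aln = codon_align(extract_gene_sequence(ga, "nad3"),
                              extract_gene_sequence(gb, "nad3"))
            expected_ks.append(kaks_pair(aln).ps)
        assert s.ks == pytest.approx(sum(expected_ks) / 3)

    def test_requires_two_carriers(self, mini_genome):
        with pytest.raises(ValueError):
            gene_kaks_summary([mini_genome], "cox1")
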
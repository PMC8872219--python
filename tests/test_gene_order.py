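"""Gene-order representation, rearrangement classification and
breakpoint distances."""

import itertools
import random

import pytest

from mitocompare.catalog import ANCESTRAL_ORDER, CR
from mitocompare.gene_order import (GeneOrder, ancestral_order,
                                    breakpoint_distance, detect_events,
                                    linearize, read_gene_orders,
                                    write_gene_orders)

ANC = [(g, s) for g, s in ANCESTRAL_ORDER if g != CR]
TOKENS = [g for g, _ in ANC]


def circ(genes) -> GeneOrder:
    return GeneOrder(genes=list(genes), circular=True)


class TestGeneOrderType:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneOrder(genes=[("trnI", 1), ("trnI", 1)])

    def test_missing_disjoint_from_present(self):
        o = GeneOrder(genes=[("trnI", 1)], missing={"trnI", "trnQ"})
        assert o.missing == {"trnQ"}


class TestLinearize:
    def test_rotation_of_ancestral_recovers_canonical_form(self):
        rotated = circ(ANC[5:] + ANC[:5])
        assert linearize(rotated) == ANC

    def test_anchor_falls_back_to_earliest_present_pcg(self):
        no_cox1 = [(g, s) for g, s in ANC if g != "cox1"]
        rotated = circ(no_cox1[7:] + no_cox1[:7])
        assert linearize(rotated) == no_cox1

    def test_empty_and_linear_orders_pass_through(self):
        assert linearize(GeneOrder(genes=[], circular=True)) == []
        linear = GeneOrder(genes=ANC[:5], circular=False)
        assert linearize(linear) == ANC[:5]


class TestDetectEvents:
    def test_ancestral_order_has_no_events(self):
        assert detect_events(ancestral_order()) == []

    def test_rotation_invariance(self):
        for r in (1, 10, 25):
            assert detect_events(circ(ANC[r:] + ANC[:r])) == []

    def test_partial_ancestral_genome_creates_no_spurious_events(self):
        drop = {"trnK", "trnV", "rrnS", "nad2"}
        partial = circ([(g, s) for g, s in ANC if g not in drop])
        assert detect_events(partial) == []

    def test_pure_inversion_detected_by_sign_alone(self):
        flipped = [(g, -s if g == "trnQ" else s) for g, s in ANC]
        evts = detect_events(circ(flipped))
        assert [(e.gene, e.kind, e.displacement) for e in evts] == \
            [("trnQ", "inversion", 0)]

    def test_wcy_cluster_swap_is_a_single_shuffle(self):
        # trnW-trnC-trnY observed as trnW-trnY-trnC (annotated strands kept)
        i = TOKENS.index("trnC")
        obs = circ(ANC[:i] + [ANC[i + 1], ANC[i]] + ANC[i + 2:])
        evts = detect_events(obs)
        assert len(evts) == 1
        assert evts[0].kind == "shuffle"
        assert evts[0].gene in ("trnC", "trnY")

    def test_iqm_cluster_rearrangement_is_a_shuffle(self):
        # trnI-trnQ-trnM observed as trnM-trnI-trnQ
        obs = circ([ANC[2], ANC[0], ANC[1]] + ANC[3:])
        evts = detect_events(obs)
        assert len(evts) == 1 and evts[0].kind == "shuffle"

    def test_trnq_transfer_into_wcy_cluster(self):
        # observed trnI trnM nad2 trnQ trnY trnW trnC cox1...:
        # trnQ crosses nad2 into the adjacent cluster (translocation) and
        # trnY shuffles within it
        obs = circ([ANC[0], ANC[2], ANC[3], ANC[1], ANC[6], ANC[4], ANC[5]]
                   + ANC[7:])
        kinds = {(e.gene, e.kind) for e in detect_events(obs)}
        assert kinds == {("trnQ", "translocation"), ("trnY", "shuffle")}

    def test_distant_move_is_remote_translocation(self):
        # trnK moved between trnA and trnR, far from its trnD neighborhood
        k = TOKENS.index("trnK")
        a = TOKENS.index("trnA")
        without = ANC[:k] + ANC[k + 1:]
        target = without.index(("trnA", 1))
        obs = circ(without[:target + 1] + [ANC[k]] + without[target + 1:])
        evts = detect_events(obs)
        assert [(e.gene, e.kind) for e in evts] == \
            [("trnK", "remote_translocation")]
        assert evts[0].anchors_crossed >= 2

    def test_comoving_block_reported_as_one_event(self):
        # move the adjacent pair trnK-trnD together to a distant site
        k = TOKENS.index("trnK")
        block = ANC[k:k + 2]
        without = ANC[:k] + ANC[k + 2:]
        target = [g for g, _ in without].index("trnT")
        obs = circ(without[:target + 1] + block + without[target + 1:])
        evts = detect_events(obs)
        assert len(evts) == 1
        assert evts[0].gene == "trnK+trnD"


class TestEventRecovery:
    def test_single_event_recovery_for_every_gene_and_kind(self, mini_genome):
        """Injecting any single event on the ancestral arrangement and
        re-classifying recovers exactly that event, for all 37 genes and
        all five kinds."""
        from mitocompare.gene_order import EVENT_KINDS
        from mitocompare.genome_io import to_gene_order
        from mitocompare.simulate import apply_events
        for gene in TOKENS:
            for kind in EVENT_KINDS:
                mutated = apply_events(mini_genome, [(gene, kind)])
                evts = detect_events(to_gene_order(mutated))
                assert [(e.gene, e.kind) for e in evts] == [(gene, kind)], \
                    (gene, kind, [(e.gene, e.kind) for e in evts])


# --- breakpoint distance ----------------------------------------------------

def oracle_breakpoints(a: GeneOrder, b: GeneOrder) -> int:
    """Naive adjacency enumerator, written from the definition."""
    shared = set(a.tokens()) & set(b.tokens())

    def adjacencies(order):
        lin = [(g, s) for g, s in linearize(order) if g in shared]
        out = set()
        pairs = list(zip(lin, lin[1:]))
        if order.circular and not order.breakpoints and len(lin) > 1:
            pairs.append((lin[-1], lin[0]))
        for (x, sx), (y, sy) in pairs:
            out.add(min(((x, sx), (y, sy)), ((y, -sy), (x, -sx))))
        return out

    return len(adjacencies(a) - adjacencies(b))


class TestBreakpointDistance:
    def test_identical_orders_have_distance_zero(self):
        assert breakpoint_distance(ancestral_order(), ancestral_order()) == 0

    def test_adjacent_transposition_on_toy_order(self):
        genes = [(f"g{i}", 1) for i in range(6)]
        moved = [genes[0], genes[2], genes[1]] + genes[3:]
        a = GeneOrder(genes=genes)
        b = GeneOrder(genes=moved)
        assert breakpoint_distance(a, b) == oracle_breakpoints(a, b) == 3

    def test_symmetry_on_random_signed_orders(self):
        # symmetric whenever both orders contribute equally many
        # adjacencies, i.e. share topology
        rng = random.Random(8)
        names = [f"g{i}" for i in range(6)]
        for _ in range(200):
            topo = rng.random() < 0.5
            n = rng.randint(2, 6)

            def rand_order():
                toks = rng.sample(names, n)
                return GeneOrder(
                    genes=[(t, rng.choice([1, -1])) for t in toks],
                    circular=topo)

            a, b = rand_order(), rand_order()
            if set(a.tokens()) != set(b.tokens()):
                continue
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)

    def test_matches_bruteforce_on_all_signed_three_gene_orders(self):
        perms = []
        for p in itertools.permutations("xyz"):
            for signs in itertools.product([1, -1], repeat=3):
                perms.append(GeneOrder(genes=list(zip(p, signs))))
        ref = perms[0]
        for other in perms:
            assert breakpoint_distance(ref, other) == \
                oracle_breakpoints(ref, other)

    def test_fewer_than_two_shared_genes_is_an_error(self):
        a = GeneOrder(genes=[("x", 1), ("y", 1)])
        b = GeneOrder(genes=[("y", 1), ("z", 1)])
        with pytest.raises(ValueError):
            breakpoint_distance(a, b)


class TestGeneOrderText:
    def test_round_trip(self, tmp_path):
        orders = {"t1": GeneOrder(genes=ANC[:6], circular=False),
                  "t2": GeneOrder(genes=[("trnQ", -1), ("trnM", 1)])}
        path = tmp_path / "orders.txt"
        write_gene_orders(orders, path)
        back = read_gene_orders(path)
        assert back["t1"].genes == ANC[:6]
        assert back["t2"].genes == [("trnQ", -1), ("trnM", 1)]
        assert "trnW" in back["t2"].missing
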
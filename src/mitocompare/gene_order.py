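"""Mitochondrial gene orders and rearrangement classification.

A gene order is a signed arrangement of the canonical mitochondrial genes
(sign = strand).  Observed orders are compared against the putative
ancestral insect arrangement and each deviation is classified into the
field's event vocabulary: *shuffle* (local reordering within a tRNA
cluster), *translocation* (move into an adjacent cluster, crossing one
protein-coding/rRNA "anchor" gene), *remote translocation* (crossing two
or more anchors), *inversion* (strand switch in place) and *inverted
translocation* (move plus strand switch).

The shuffle/translocation boundary is defined by the anchor genes a move
crosses rather than by rank displacement alone: a tRNA hopping over a
single neighbour within its cluster moves as far, in ranks, as one that
leaves its cluster, yet the two are biologically distinct events.  An
adjacent-neighbour swap (rank displacement 1) always counts as a shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import ANCESTRAL_ORDER, CR, PCGS, RRNAS, ALL_TOKENS

#: non-tRNA genes act as cluster anchors for event classification
ANCHOR_GENES = frozenset(PCGS) | frozenset(RRNAS)

EVENT_KINDS = ("shuffle", "translocation", "remote_translocation",
               "inversion", "inverted_translocation")


@dataclass
class GeneOrder:
    """Signed, possibly partial, possibly circular gene arrangement."""

    genes: list[tuple[str, int]]
    circular: bool = False
    missing: set[str] = field(default_factory=set)
    breakpoints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        toks = [g for g, _ in self.genes]
        if len(toks) != len(set(toks)):
            dup = sorted({t for t in toks if toks.count(t) > 1})
            raise ValueError(f"duplicate genes in order: {dup}")
        self.missing = set(self.missing) - set(toks)

    def tokens(self) -> list[str]:
        return [g for g, _ in self.genes]

    def sign_of(self, token: str) -> int:
        for g, s in self.genes:
            if g == token:
                return s
        raise KeyError(token)

    def __contains__(self, token: str) -> bool:
        return any(g == token for g, _ in self.genes)


def ancestral_order() -> GeneOrder:
    """The ancestral insect arrangement as a circular GeneOrder."""
    return GeneOrder(genes=list(ANCESTRAL_ORDER), circular=True)


@dataclass
class RearrangementEvent:
    """One classified deviation from the ancestral arrangement."""

    gene: str                      # token, or "a+b+..." for a co-moving block
    kind: str                      # one of EVENT_KINDS
    ancestral_context: tuple[str | None, str | None]
    observed_context: tuple[str | None, str | None]
    displacement: int              # gene ranks moved (0 for pure inversions)
    anchors_crossed: int = 0

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.gene.split("+"))


_ANC_TOKENS = [g for g, _ in ANCESTRAL_ORDER]
_ANC_RANK = {g: i for i, g in enumerate(_ANC_TOKENS)}


def linearize(order: GeneOrder) -> list[tuple[str, int]]:
    """Deterministic linearization of a (circular) order.

    Circular orders are rotated so the anchor gene (cox1, falling back to
    the present PCG earliest in the ancestral order, then to the first
    gene) occupies the rank it has in the ancestral arrangement restricted
    to the genes present.  Linear orders are returned unchanged.
    """
    genes = list(order.genes)
    if not order.circular or not genes:
        return genes
    present = {g for g, _ in genes}
    anchor = None
    if "cox1" in present:
        anchor = "cox1"
    else:
        for g in _ANC_TOKENS:
            if g in PCGS and g in present:
                anchor = g
                break
    if anchor is None:
        anchor = genes[0][0]
    anc_restricted = [g for g in _ANC_TOKENS if g in present]
    target = anc_restricted.index(anchor) if anchor in _ANC_RANK else 0
    cur = next(i for i, (g, _) in enumerate(genes) if g == anchor)
    shift = (cur - target) % len(genes)
    return genes[shift:] + genes[:shift]


# ---------------------------------------------------------------------------
# longest common subsequence (deterministic backtrack)

def _lcs_table(a: list[str], b: list[str]) -> list[list[int]]:
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = 1 + dp[i + 1][j + 1]
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    return dp


def _lcs_keep(a: list[str], b: list[str]) -> set[str]:
    """Tokens kept by a longest common subsequence of two duplicate-free
    token lists.  Ties are broken by preferring to skip the current
    *observed* element, so an adjacent transposition attributes the move to
    the ancestrally later gene of the pair — a deterministic convention."""
    dp = _lcs_table(a, b)
    keep: set[str] = set()
    i = j = 0
    n, m = len(a), len(b)
    while i < n and j < m:
        if a[i] == b[j]:
            keep.add(a[i])
            i += 1
            j += 1
        elif dp[i][j + 1] >= dp[i + 1][j]:
            j += 1
        else:
            i += 1
    return keep


def _neighbors(tokens: list[str], idx: int) -> tuple[str | None, str | None]:
    left = tokens[idx - 1] if idx > 0 else None
    right = tokens[idx + 1] if idx < len(tokens) - 1 else None
    return left, right


def detect_events(observed: GeneOrder,
                  ancestral: GeneOrder | None = None,
                  window: int = 3) -> list[RearrangementEvent]:
    """Classify the observed order's deviations from the ancestral one.

    Both orders are restricted to their shared genes (the control region is
    excluded), so partial genomes never produce spurious events.  Moved
    genes are identified as the complement of a longest common subsequence;
    co-moving adjacent genes are merged into a single block event.

    ``window`` is the rank-displacement window used in the reported
    ``displacement`` field; classification itself is anchor-based (see
    module docstring).
    """
    anc = ancestral if ancestral is not None else ancestral_order()
    anc_lin = [(g, s) for g, s in linearize(anc) if g != CR]
    obs_lin = [(g, s) for g, s in linearize(observed) if g != CR]
    shared = {g for g, _ in anc_lin} & {g for g, _ in obs_lin}
    A = [(g, s) for g, s in anc_lin if g in shared]
    O = [(g, s) for g, s in obs_lin if g in shared]
    if observed.circular and len(O) > 1:
        # a circular order has no intrinsic start; compare under the
        # rotation that explains the order with the fewest moved genes.
        # Rotations aligning one of several well-spaced anchor genes to its
        # ancestral rank are tried first (almost always one of them is
        # unmoved); the exhaustive rotation scan is a rare fallback.  The
        # choice depends only on the circular arrangement, so the result is
        # rotation-invariant.
        a_tok_full = [g for g, _ in A]
        a_pos = {g: i for i, g in enumerate(a_tok_full)}
        o_pos = {g: i for i, (g, _) in enumerate(O)}

        def rotated(shift):
            return O[shift:] + O[:shift]

        candidates = [0]
        for anchor in ("cox1", "cob", "nad4", "nad2", "rrnL"):
            if anchor in a_pos and anchor in o_pos:
                candidates.append((o_pos[anchor] - a_pos[anchor]) % len(O))
        best, best_len = O, -1
        seen = set()
        for shift in candidates:
            if shift in seen:
                continue
            seen.add(shift)
            rot = rotated(shift)
            length = _lcs_table(a_tok_full, [g for g, _ in rot])[0][0]
            if length > best_len:
                best, best_len = rot, length
            if best_len >= len(O) - 1:
                break
        if len(O) - best_len > max(3, len(O) // 6):
            for shift in range(len(O)):
                if shift in seen:
                    continue
                rot = rotated(shift)
                length = _lcs_table(a_tok_full, [g for g, _ in rot])[0][0]
                if length > best_len:
                    best, best_len = rot, length
        O = best
    a_tok = [g for g, _ in A]
    o_tok = [g for g, _ in O]
    a_rank = {g: i for i, g in enumerate(a_tok)}
    o_rank = {g: i for i, g in enumerate(o_tok)}
    a_sign = dict(A)
    o_sign = dict(O)
    flipped = {g for g in shared if a_sign[g] != o_sign[g]}

    keep = _lcs_keep(a_tok, o_tok)
    moved = [g for g in o_tok if g not in keep]

    events: list[RearrangementEvent] = []

    # pure inversions: strand flip without movement
    for g in o_tok:
        if g in flipped and g not in moved:
            events.append(RearrangementEvent(
                gene=g, kind="inversion",
                ancestral_context=_neighbors(a_tok, a_rank[g]),
                observed_context=_neighbors(o_tok, o_rank[g]),
                displacement=0))

    # merge co-moving blocks: moved genes adjacent in both orders, same
    # relative order (maximal common signed substrings of the restricted
    # orders)
    blocks: list[list[str]] = []
    for g in moved:
        if blocks:
            prev = blocks[-1][-1]
            if (o_rank[g] == o_rank[prev] + 1
                    and a_rank.get(g, -99) == a_rank.get(prev, 99) + 1
                    and (g in flipped) == (prev in flipped)):
                blocks[-1].append(g)
                continue
        blocks.append([g])

    for block in blocks:
        g0 = block[0]
        i0 = min(a_rank[g] for g in block)
        i1 = max(a_rank[g] for g in block)
        j0 = o_rank[g0]
        j1 = o_rank[block[-1]]
        # nearest unmoved flanks in the observed order
        left_anchor_rank = None
        for j in range(j0 - 1, -1, -1):
            if o_tok[j] in keep:
                left_anchor_rank = a_rank[o_tok[j]]
                break
        right_anchor_rank = None
        for j in range(j1 + 1, len(o_tok)):
            if o_tok[j] in keep:
                right_anchor_rank = a_rank[o_tok[j]]
                break
        # kept genes jumped over, in ancestral coordinates
        if left_anchor_rank is not None and left_anchor_rank > i1:
            crossed = [g for g in keep
                       if i1 < a_rank[g] <= left_anchor_rank]
        elif right_anchor_rank is not None and right_anchor_rank < i0:
            crossed = [g for g in keep
                       if right_anchor_rank <= a_rank[g] < i0]
        else:
            crossed = []
        n_anchors = sum(1 for g in crossed if g in ANCHOR_GENES)
        displacement = abs(a_rank[g0] - o_rank[g0])

        if any(g in flipped for g in block):
            kind = "inverted_translocation" if crossed else "inversion"
            if not crossed and displacement > 0:
                kind = "inverted_translocation"
        elif displacement <= 1 or n_anchors == 0:
            kind = "shuffle"
        elif n_anchors == 1:
            kind = "translocation"
        else:
            kind = "remote_translocation"

        events.append(RearrangementEvent(
            gene="+".join(block), kind=kind,
            ancestral_context=_neighbors(a_tok, a_rank[g0]),
            observed_context=_neighbors(o_tok, o_rank[g0]),
            displacement=displacement,
            anchors_crossed=n_anchors))

    events.sort(key=lambda e: o_rank.get(e.genes[0], 0))
    return events


# ---------------------------------------------------------------------------
# breakpoint distance

def _adjacencies(order: GeneOrder, shared: set[str]) -> set[tuple]:
    lin = [(g, s) for g, s in linearize(order) if g in shared]
    adjs = set()
    pairs = list(zip(lin, lin[1:]))
    if order.circular and not order.breakpoints and len(lin) > 1:
        pairs.append((lin[-1], lin[0]))
    for (x, sx), (y, sy) in pairs:
        fwd = ((x, sx), (y, sy))
        rev = ((y, -sy), (x, -sx))
        adjs.add(min(fwd, rev))
    return adjs


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Signed, orientation-aware adjacencies present in ``a`` but not ``b``.

    Both orders are restricted to their shared genes first; the wrap-around
    adjacency participates only when both orders are circular and free of
    assembly gaps.
    """
    shared = set(a.tokens()) & set(b.tokens())
    if len(shared) < 2:
        raise ValueError("breakpoint distance needs >= 2 shared genes")
    return len(_adjacencies(a, shared) - _adjacencies(b, shared))


# ---------------------------------------------------------------------------
# plain-text gene-order format

def write_gene_orders(orders: dict[str, GeneOrder], path) -> None:
    """One genome per entry: ``>id`` then whitespace-separated signed
    tokens, ``-`` prefix marking the minority strand."""
    with open(path, "w") as fh:
        for gid, order in orders.items():
            fh.write(f">{gid}\n")
            fh.write(" ".join(f"-{g}" if s < 0 else g
                              for g, s in order.genes) + "\n")


def read_gene_orders(path, circular: bool = False) -> dict[str, GeneOrder]:
    orders: dict[str, GeneOrder] = {}
    gid = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                gid = line[1:].strip()
                continue
            if gid is None:
                raise ValueError("gene-order file must start with a '>id' line")
            genes = []
            for tok in line.split():
                sign = -1 if tok.startswith("-") else 1
                genes.append((tok.lstrip("-"), sign))
            missing = set(ALL_TOKENS) - {g for g, _ in genes}
            orders[gid] = GeneOrder(genes=genes, circular=circular,
                                    missing=missing)
            gid = None
    return orders
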
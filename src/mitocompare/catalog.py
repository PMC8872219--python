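"""Canonical vocabulary for the 37 metazoan mitochondrial genes.

Insect mitogenomes carry 13 protein-coding genes (PCGs), 22 tRNAs, two
rRNAs and an A+T-rich control region (CR).  Annotations in public records
use wildly inconsistent names (``ND2`` / ``nad2`` / ``NADH dehydrogenase
subunit 2``; ``COI`` / ``COX1``; ``tRNA-Leu`` with or without the
codon-family qualifier), so everything entering the pipeline is mapped to
one canonical token.  The two leucine and two serine tRNAs are kept as
separate tokens (``trnL1``/``trnL2``, ``trnS1``/``trnS2``) because they are
distinct genes recognising distinct codon families.
"""

from __future__ import annotations

import re

#: the 13 protein-coding genes
PCGS: tuple[str, ...] = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

#: the 22 tRNA genes (L1 = CUN leucine, L2 = UUR leucine,
#: S1 = AGN serine, S2 = UCN serine)
TRNAS: tuple[str, ...] = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

CR = "CR"

#: all 37 genes plus the control region
ALL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS
ALL_TOKENS: tuple[str, ...] = ALL_GENES + (CR,)

UNRESOLVED = "unresolved"

#: Putative ancestral insect mitochondrial arrangement (Drosophila-like),
#: as a signed circular order; -1 marks the minority (N) strand.
ANCESTRAL_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1), ("trnW", 1),
    ("trnC", -1), ("trnY", -1), ("cox1", 1), ("trnL2", 1), ("cox2", 1),
    ("trnK", 1), ("trnD", 1), ("atp8", 1), ("atp6", 1), ("cox3", 1),
    ("trnG", 1), ("nad3", 1), ("trnA", 1), ("trnR", 1), ("trnN", 1),
    ("trnS1", 1), ("trnE", 1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4l", -1), ("trnT", 1), ("trnP", -1), ("nad6", 1),
    ("cob", 1), ("trnS2", 1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1), (CR, 1),
)


def category_of(token: str) -> str:
    """Gene category of a canonical token: PCG, tRNA, rRNA or CR."""
    if token in PCGS:
        return "PCG"
    if token in TRNAS:
        return "tRNA"
    if token in RRNAS:
        return "rRNA"
    if token == CR:
        return "CR"
    raise ValueError(f"not a canonical token: {token!r}")


# one-letter amino-acid code -> unambiguous tRNA token (Leu/Ser need the
# anticodon or an explicit 1/2 suffix and are absent here)
_AA_TO_TRNA = {
    "I": "trnI", "Q": "trnQ", "M": "trnM", "W": "trnW", "C": "trnC",
    "Y": "trnY", "K": "trnK", "D": "trnD", "G": "trnG", "A": "trnA",
    "R": "trnR", "N": "trnN", "E": "trnE", "F": "trnF", "H": "trnH",
    "T": "trnT", "P": "trnP", "V": "trnV",
}

_AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: anticodon -> leucine/serine tRNA token.  UAG reads CUN codons (trnL1),
#: UAA reads UUR (trnL2), GCU/UCU read AGN (trnS1), UGA reads UCN (trnS2).
ANTICODON_TO_TRNA = {
    "TAG": "trnL1", "TAA": "trnL2", "GCT": "trnS1", "TCT": "trnS1",
    "TGA": "trnS2",
}

# fixed aliases, keyed by the squeezed (alnum-only, upper-case) raw name
_ALIASES: dict[str, str] = {}


def _add(canon: str, *names: str) -> None:
    for n in names:
        _ALIASES[re.sub(r"[^A-Z0-9]", "", n.upper())] = canon


for _i in range(1, 7):
    _add(f"nad{_i}", f"nad{_i}", f"ND{_i}", f"NADH{_i}",
         f"NADH dehydrogenase subunit {_i}", f"NADH-ubiquinone oxidoreductase chain {_i}")
_add("nad4l", "nad4l", "ND4L", "NADH4L", "NADH dehydrogenase subunit 4L")
for _i, _rom in ((1, "I"), (2, "II"), (3, "III")):
    _add(f"cox{_i}", f"cox{_i}", f"COX{_i}", f"CO{_i}", f"CO{_rom}", f"COX{_rom}",
         f"cytochrome c oxidase subunit {_i}", f"cytochrome oxidase subunit {_rom}")
_add("cob", "cob", "COB", "CYTB", "CYB", "cytochrome b", "cytb")
_add("atp6", "atp6", "ATPase6", "ATP synthase F0 subunit 6", "ATPase subunit 6")
_add("atp8", "atp8", "ATPase8", "ATP synthase F0 subunit 8", "ATPase subunit 8")
_add("rrnL", "rrnL", "16S", "16S rRNA", "l-rRNA", "lrRNA", "large subunit ribosomal RNA",
     "16S ribosomal RNA", "rrn16")
_add("rrnS", "rrnS", "12S", "12S rRNA", "s-rRNA", "srRNA", "small subunit ribosomal RNA",
     "12S ribosomal RNA", "rrn12")
_add(CR, "CR", "D-loop", "control region", "A+T rich region", "AT rich region",
     "putative control region")
_add("trnL1", "trnL1", "tRNA-Leu(CUN)", "tRNA-Leu(tag)", "trnL-tag", "tRNA-Leu1", "trnL CUN")
_add("trnL2", "trnL2", "tRNA-Leu(UUR)", "tRNA-Leu(taa)", "trnL-taa", "tRNA-Leu2", "trnL UUR")
_add("trnS1", "trnS1", "tRNA-Ser(AGN)", "tRNA-Ser(gct)", "trnS-gct", "tRNA-Ser1", "trnS AGN",
     "tRNA-Ser(tct)")
_add("trnS2", "trnS2", "tRNA-Ser(UCN)", "tRNA-Ser(tga)", "trnS-tga", "tRNA-Ser2", "trnS UCN")
for _aa1, _tok in _AA_TO_TRNA.items():
    _aa3 = {v: k for k, v in _AA3_TO_AA1.items()}[_aa1]
    _add(_tok, _tok, f"trn{_aa1}", f"tRNA-{_aa3.capitalize()}", f"tRNA {_aa3.capitalize()}")


def canonicalize_gene_name(raw_name: str, anticodon: str | None = None) -> str:
    """Resolve a raw annotation label to a canonical token.

    Resolution is case- and punctuation-insensitive.  ``tRNA-Leu`` /
    ``tRNA-Ser`` without a codon-family suffix are disambiguated by the
    anticodon; with neither, the ``UNRESOLVED`` sentinel is returned —
    never a guess.
    """
    squeezed = re.sub(r"[^A-Z0-9]", "", raw_name.upper())
    if squeezed in _ALIASES:
        return _ALIASES[squeezed]

    # generic tRNA forms: trnX, tRNA-Xxx, possibly with an embedded anticodon
    m = re.match(r"^TRNA?([A-Z]{1,3})([ACGTU]{3})?$", squeezed)
    if m:
        aa, embedded = m.groups()
        if len(aa) == 3 and aa in _AA3_TO_AA1:
            aa = _AA3_TO_AA1[aa]
        if aa in _AA_TO_TRNA:
            return _AA_TO_TRNA[aa]
        if aa in ("L", "LEU", "S", "SER"):
            ac = embedded or (anticodon or "")
            ac = ac.upper().replace("U", "T")
            if ac in ANTICODON_TO_TRNA:
                tok = ANTICODON_TO_TRNA[ac]
                if (aa.startswith("L") and tok.startswith("trnL")) or (
                    aa.startswith("S") and tok.startswith("trnS")
                ):
                    return tok
    if anticodon:
        ac = anticodon.upper().replace("U", "T")
        if ac in ANTICODON_TO_TRNA:
            return ANTICODON_TO_TRNA[ac]
    return UNRESOLVED
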
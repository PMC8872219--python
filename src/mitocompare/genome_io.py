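"""Annotated mitogenome I/O.

Reads and writes GenBank flat files (via Biopython) and a FASTA + TSV
feature-table fallback, canonicalizes gene names, extracts strand-correct
gene sequences and derives signed gene orders.

Internal coordinates are 0-based half-open on the annotated sequence;
GenBank I/O converts from/to the 1-based inclusive convention of the flat
file.  Features spanning the origin of a circular genome are stored as two
joined segments under a single feature identity.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import catalog
from .catalog import ALL_GENES, CR, PCGS, UNRESOLVED, canonicalize_gene_name, category_of
from .gene_order import GeneOrder

logger = logging.getLogger(__name__)


class MissingGeneError(KeyError):
    """Requested gene is not annotated in the genome."""

    def __init__(self, genome_id: str, name: str):
        super().__init__(f"gene {name!r} absent from genome {genome_id!r}")
        self.genome_id = genome_id
        self.name = name


class GenomeParseError(ValueError):
    pass


@dataclass
class GeneFeature:
    """One annotated gene.

    ``segments`` is a list of (start, end) 0-based half-open intervals in
    genomic order along the coding direction; a single interval for normal
    features, two for origin-spanning features of circular genomes.
    """

    canonical_name: str
    category: str            # PCG | tRNA | rRNA | CR
    strand: int              # +1 / -1
    segments: list[tuple[int, int]]
    anticodon: str | None = None
    raw_name: str | None = None
    unresolved: bool = False

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def __len__(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class MitoGenome:
    """An annotated (possibly partial, possibly circular) mitogenome."""

    id: str
    sequence: str
    circular: bool = False
    complete: bool = False
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeParseError(
                f"genome {self.id!r}: non-IUPAC characters {sorted(bad)}")
        for f in self.features:
            for s, e in f.segments:
                if not (0 <= s < e <= len(self.sequence)):
                    raise GenomeParseError(
                        f"genome {self.id!r}: feature {f.canonical_name} "
                        f"[{s},{e}) outside sequence bounds")
        self.features.sort(key=lambda f: f.start)

    def gene_names(self) -> list[str]:
        return [f.canonical_name for f in self.features if not f.unresolved]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.canonical_name == name and not f.unresolved:
                return f
        raise MissingGeneError(self.id, name)

    def has_gene(self, name: str) -> bool:
        return any(f.canonical_name == name and not f.unresolved
                   for f in self.features)

    def infer_complete(self) -> bool:
        present = set(self.gene_names())
        return set(ALL_GENES) <= present and CR in present


def extract_gene_sequence(genome: MitoGenome, name: str) -> str:
    """Coding-orientation nucleotide sequence of one gene.

    Minority-strand features are reverse-complemented; origin-spanning
    features are joined across their segments before orientation.
    """
    f = genome.feature(name)
    raw = "".join(genome.sequence[s:e] for s, e in f.segments)
    if f.strand < 0:
        raw = str(Seq(raw).reverse_complement())
    return raw


# ---------------------------------------------------------------------------
# GenBank parsing

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "gene", "misc_feature", "D-loop")


def _feature_name(bio_feat) -> str | None:
    q = bio_feat.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return q[key][0]
    if bio_feat.type == "D-loop":
        return "control region"
    return None


def _feature_anticodon(bio_feat) -> str | None:
    q = bio_feat.qualifiers
    if "anticodon" in q and q["anticodon"]:
        # formats like "(pos:5..7,aa:Leu,seq:taa)" or bare "taa"
        raw = q["anticodon"][0]
        if "seq:" in raw:
            raw = raw.split("seq:")[1].strip(") ")
        if len(raw.strip()) == 3:
            return raw.strip().upper().replace("U", "T")
    if "note" in q:
        import re
        m = re.search(r"anticodon[:\s]+([ACGUTacgut]{3})", q["note"][0])
        if m:
            return m.group(1).upper().replace("U", "T")
    return None


def _location_segments(loc, seq_len: int) -> list[tuple[int, int]]:
    if isinstance(loc, CompoundLocation):
        return [(int(p.start), int(p.end)) for p in loc.parts]
    return [(int(loc.start), int(loc.end))]


def parse_genbank(path: str | Path) -> list[MitoGenome]:
    """Parse a (possibly multi-record) GenBank flat file into MitoGenomes.

    Gene names are canonicalized; CDS/tRNA/rRNA annotations win over bare
    ``gene`` features for the same gene; features whose names cannot be
    resolved are retained with ``unresolved=True`` and a warning, never
    dropped silently.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise GenomeParseError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no GenBank records in {path}")
    return [_record_to_genome(r) for r in records]


def _record_to_genome(record: SeqRecord) -> MitoGenome:
    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "") == "circular"
    by_name: dict[str, GeneFeature] = {}
    unresolved_feats: list[GeneFeature] = []
    # priority: typed features overwrite bare gene features
    priority = {"gene": 0, "misc_feature": 1, "D-loop": 2,
                "CDS": 2, "tRNA": 2, "rRNA": 2}

    for bf in record.features:
        if bf.type not in _FEATURE_TYPES:
            continue
        raw = _feature_name(bf)
        if raw is None:
            continue
        anticodon = _feature_anticodon(bf)
        name = canonicalize_gene_name(raw, anticodon)
        segs = _location_segments(bf.location, len(seq))
        for s, e in segs:
            if not (0 <= s < e <= len(seq)):
                raise GenomeParseError(
                    f"record {record.id}: feature {raw!r} [{s},{e}) "
                    f"outside sequence of length {len(seq)}")
        strand = -1 if (bf.location.strand or 1) < 0 else 1
        if name == UNRESOLVED:
            logger.warning("record %s: unresolved gene name %r (kept, flagged)",
                           record.id, raw)
            unresolved_feats.append(GeneFeature(
                canonical_name=UNRESOLVED, category="unknown", strand=strand,
                segments=segs, anticodon=anticodon, raw_name=raw,
                unresolved=True))
            continue
        feat = GeneFeature(
            canonical_name=name, category=category_of(name), strand=strand,
            segments=segs, anticodon=anticodon, raw_name=raw)
        prev = by_name.get(name)
        if prev is None or priority[bf.type] >= priority.get(_prev_type(prev), 0):
            feat._src_type = bf.type  # type: ignore[attr-defined]
            by_name[name] = feat

    genome = MitoGenome(
        id=record.id or record.name,
        sequence=seq,
        circular=circular,
        features=list(by_name.values()) + unresolved_feats,
    )
    genome.complete = genome.infer_complete()
    return genome


def _prev_type(feat: GeneFeature) -> str:
    return getattr(feat, "_src_type", "gene")


# ---------------------------------------------------------------------------
# GenBank writing

_CATEGORY_TO_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def write_genbank(genomes: list[MitoGenome], path: str | Path) -> None:
    """Write genomes as a multi-record GenBank flat file (round-trippable)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16].replace(".", "_"),
                        description="synthetic mitochondrial genome")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        for f in g.features:
            parts = [SimpleLocation(s, e, strand=f.strand) for s, e in f.segments]
            loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
            ftype = _CATEGORY_TO_TYPE.get(f.category, "misc_feature")
            quals: dict[str, list[str]] = {"gene": [f.canonical_name]}
            if f.anticodon:
                quals["note"] = [f"anticodon:{f.anticodon}"]
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        records.append(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + TSV feature-table fallback

def parse_fasta_with_features(fasta_path: str | Path,
                              table_path: str | Path) -> list[MitoGenome]:
    """Annotation-free fallback: FASTA plus a TSV feature table.

    Table columns: genome, name, category, strand, start, end, anticodon
    (start/end 1-based inclusive; anticodon may be empty).
    """
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    feats: dict[str, list[GeneFeature]] = {k: [] for k in seqs}
    with open(table_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gid = row["genome"]
            if gid not in seqs:
                raise GenomeParseError(f"feature table references unknown genome {gid!r}")
            name = canonicalize_gene_name(row["name"], row.get("anticodon") or None)
            start = int(row["start"]) - 1          # 1-based inclusive -> 0-based half-open
            end = int(row["end"])
            feats[gid].append(GeneFeature(
                canonical_name=name,
                category=row["category"] if name == UNRESOLVED else category_of(name),
                strand=-1 if row["strand"] in ("-", "-1") else 1,
                segments=[(start, end)],
                anticodon=row.get("anticodon") or None,
                raw_name=row["name"],
                unresolved=name == UNRESOLVED,
            ))
    out = []
    for gid, seq in seqs.items():
        g = MitoGenome(id=gid, sequence=seq, features=feats[gid])
        g.complete = g.infer_complete()
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# Gene order derivation

def to_gene_order(genome: MitoGenome) -> GeneOrder:
    """Signed gene order in genomic order; absent genes recorded as missing."""
    genes = [(f.canonical_name, f.strand) for f in genome.features
             if not f.unresolved]
    present = {g for g, _ in genes}
    missing = set(catalog.ALL_TOKENS) - present
    return GeneOrder(genes=genes, circular=genome.circular, missing=missing)


# ---------------------------------------------------------------------------
# Supermatrix export

def write_supermatrix(genomes: list[MitoGenome], out_dir: str | Path) -> Path:
    """Export one unaligned FASTA per PCG plus a partition manifest.

    The manifest (``partitions.tsv``) lists, per gene, the taxa carrying it;
    ``partitions.txt`` is a RAxML-style partition scheme usable after
    external alignment.  Taxa missing a gene are omitted from that gene's
    FASTA and logged.
    """
    if len(genomes) < 2:
        raise ValueError("supermatrix export needs at least 2 genomes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for gene in PCGS:
        records = []
        for g in genomes:
            if g.has_gene(gene):
                records.append(SeqRecord(Seq(extract_gene_sequence(g, gene)),
                                         id=g.id, description=gene))
            else:
                logger.info("supermatrix: %s lacks %s; omitted", g.id, gene)
        SeqIO.write(records, str(out_dir / f"{gene}.fasta"), "fasta")
        manifest_rows.append((gene, len(records), ",".join(r.id for r in records)))
    with open(out_dir / "partitions.tsv", "w") as fh:
        fh.write("gene\tn_taxa\ttaxa\n")
        for gene, n, taxa in manifest_rows:
            fh.write(f"{gene}\t{n}\t{taxa}\n")
    with open(out_dir / "partitions.txt", "w") as fh:
        for gene, _, _ in manifest_rows:
            fh.write(f"DNA, {gene} = {gene}.fasta\n")
    return out_dir
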
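"""Full-analysis orchestration: parse -> composition -> RSCU -> Ka/Ks ->
rearrangements -> supermatrix export, with fixed report formatting so
re-runs are byte-identical."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import PCGS
from .codon_evolution import gene_kaks_summary
from .composition import pcg_composition, rscu
from .gene_order import detect_events, breakpoint_distance, write_gene_orders
from .genome_io import (MitoGenome, extract_gene_sequence, parse_genbank,
                        to_gene_order, write_supermatrix)

logger = logging.getLogger(__name__)

# report rounding: percentages 2 d.p., skews 4 d.p., rates 5 d.p.
_FMT_PCT = "{:.2f}"
_FMT_SKEW = "{:.4f}"
_FMT_RATE = "{:.5f}"


@dataclass
class RunConfig:
    inputs: list[str | Path]
    out_dir: str | Path = "mitocompare_out"
    aligned: bool = False
    split_rscu_families: bool = True
    window: int = 3
    seed: int = 0


def _fmt(value, fmt: str) -> str:
    return "NA" if value is None else fmt.format(value)


def composition_table(genomes: list[MitoGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        prof = pcg_composition(g)
        rows.append({
            "species": g.id,
            "sequence_length_bp": len(g.sequence),
            "at_percent": _fmt(prof.at_percent, _FMT_PCT),
            "at_skew": _fmt(prof.at_skew, _FMT_SKEW),
            "gc_skew": _fmt(prof.gc_skew, _FMT_SKEW),
            "pcg_length_bp": prof.total_length,
        })
    return pd.DataFrame(rows)


def rscu_table(genomes: list[MitoGenome], split_families: bool = True) -> pd.DataFrame:
    frames = []
    for g in genomes:
        seqs = [extract_gene_sequence(g, p) for p in PCGS if g.has_gene(p)]
        df = rscu(seqs, split_families=split_families)
        df.insert(0, "species", g.id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["rscu"] = out["rscu"].map(lambda v: f"{v:.4f}")
    return out


def kaks_table(genomes: list[MitoGenome]) -> pd.DataFrame:
    rows = []
    for gene in PCGS:
        carriers = sum(1 for g in genomes if g.has_gene(gene))
        if carriers < 2:
            logger.warning("kaks: gene %s present in %d genome(s); skipped",
                           gene, carriers)
            continue
        s = gene_kaks_summary(genomes, gene)
        rows.append({
            "gene": gene, "n_pairs": s.n_pairs,
            "S": _fmt(s.s_sites, _FMT_RATE), "N": _fmt(s.n_sites, _FMT_RATE),
            "Sd": _fmt(s.sd, _FMT_RATE), "Nd": _fmt(s.nd, _FMT_RATE),
            "Ks": _fmt(s.ks, _FMT_RATE), "Ka": _fmt(s.ka, _FMT_RATE),
            "Ka_Ks": _fmt(s.ka_ks, _FMT_RATE),
            "JKs": _fmt(s.jks, _FMT_RATE), "JKa": _fmt(s.jka, _FMT_RATE),
            "JKa_JKs": _fmt(s.jka_jks, _FMT_RATE),
            "mean_pair_ratio": _fmt(s.mean_ratio, _FMT_RATE),
        })
    return pd.DataFrame(rows)


def rearrangement_table(genomes: list[MitoGenome], window: int = 3) -> pd.DataFrame:
    rows = []
    for g in genomes:
        order = to_gene_order(g)
        for e in detect_events(order, window=window):
            rows.append({
                "genome": g.id, "gene": e.gene, "kind": e.kind,
                "ancestral_context": "|".join(x or "." for x in e.ancestral_context),
                "observed_context": "|".join(x or "." for x in e.observed_context),
                "displacement": e.displacement,
                "anchors_crossed": e.anchors_crossed,
            })
    return pd.DataFrame(rows, columns=["genome", "gene", "kind",
                                       "ancestral_context", "observed_context",
                                       "displacement", "anchors_crossed"])


def breakpoint_matrix(genomes: list[MitoGenome]) -> pd.DataFrame:
    ids = [g.id for g in genomes]
    orders = {g.id: to_gene_order(g) for g in genomes}
    mat = pd.DataFrame(0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = breakpoint_distance(orders[a], orders[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def load_genomes(inputs: list[str | Path]) -> list[MitoGenome]:
    genomes: list[MitoGenome] = []
    for path in inputs:
        genomes.extend(parse_genbank(path))
    return genomes


def run_all(config: RunConfig, genomes: list[MitoGenome] | None = None) -> dict:
    """Run every stage; independent stages still run when one fails.

    Returns a report dict (stage -> output path or error) and writes the
    five analysis outputs plus a sidecar run log under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = load_genomes(config.inputs)
    if not genomes:
        raise ValueError("run_all needs at least one input genome")
    report: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            report[name] = str(fn())
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            report[name] = f"ERROR: {exc}"
        timings[name] = round(time.perf_counter() - t0, 3)

    def _composition():
        p = out / "composition.tsv"
        composition_table(genomes).to_csv(p, sep="\t", index=False)
        return p

    def _rscu():
        p = out / "rscu.tsv"
        rscu_table(genomes, config.split_rscu_families).to_csv(p, sep="\t", index=False)
        return p

    def _kaks():
        if len(genomes) < 2:
            raise ValueError("Ka/Ks needs at least 2 genomes")
        p = out / "kaks.tsv"
        kaks_table(genomes).to_csv(p, sep="\t", index=False)
        return p

    def _rearrange():
        p = out / "rearrangements.tsv"
        rearrangement_table(genomes, config.window).to_csv(p, sep="\t", index=False)
        write_gene_orders({g.id: to_gene_order(g) for g in genomes},
                          out / "gene_orders.txt")
        if len(genomes) >= 2:
            breakpoint_matrix(genomes).to_csv(out / "breakpoints.tsv", sep="\t")
        return p

    def _supermatrix():
        if len(genomes) < 2:
            raise ValueError("supermatrix export needs at least 2 genomes")
        return write_supermatrix(genomes, out / "supermatrix")

    stage("composition", _composition)
    stage("rscu", _rscu)
    stage("kaks", _kaks)
    stage("rearrangements", _rearrange)
    stage("supermatrix", _supermatrix)

    meta = {
        "tool": "mitocompare", "version": __version__,
        "config": {k: str(v) for k, v in vars(config).items()},
        "n_genomes": len(genomes),
        "stages": report, "timings_s": timings,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    meta["failed"] = [k for k, v in report.items() if v.startswith("ERROR")]
    return meta
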
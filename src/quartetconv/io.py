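"""Readers and writers for every on-disk format of the pipeline.

Conventions: CDS in FASTA; gene coordinates in GFF3 or a 4+ column TSV;
all tabular outputs are tab-separated with a single '#'-prefixed header
line; simulation truth and mixture fits are JSON.  Coordinates are 1-based
inclusive on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CollinearBlock,
    ConversionCall,
    GeneModel,
    HomologPair,
    KsMixtureFit,
    PairStats,
    Quartet,
    SimTruth,
    SimTruthEvent,
)

logger = logging.getLogger("quartetconv")

_VALID_CDS = set("ACGTN")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with a '#'-prefixed header line."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        names = first.lstrip("#").strip().split("\t")
        return pd.read_csv(path, sep="\t", comment=None, skiprows=1, names=names,
                           dtype=str, keep_default_na=False)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene catalogs
# ---------------------------------------------------------------------------


def read_gene_catalog(
    fasta_path: str | Path,
    coords_path: str | Path,
    genome: Optional[str] = None,
) -> list[GeneModel]:
    """Join a CDS FASTA with a coordinate file into GeneModels.

    Coordinate files may be GFF3 (gene features with an ID attribute) or a
    TSV with columns gene_id, chromosome, start_bp, end_bp [, strand
    [, genome]].  Order indices are assigned per chromosome by ascending
    start; genes lacking a CDS or coordinates, or with a CDS length not
    divisible by 3, are warned about and dropped.  Duplicate gene ids are a
    hard error.
    """
    cds: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in cds:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id}")
        cds[rec.id] = str(rec.seq).upper()

    coords = _read_coords(coords_path)
    if coords["gene_id"].duplicated().any():
        dup = coords.loc[coords["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in coordinates: {dup}")

    genes: list[GeneModel] = []
    n_dropped = 0
    for row in coords.itertuples(index=False):
        seq = cds.get(row.gene_id)
        if seq is None:
            logger.warning("gene %s has coordinates but no CDS; dropped", row.gene_id)
            n_dropped += 1
            continue
        if len(seq) % 3 != 0:
            logger.warning("gene %s CDS length %d not divisible by 3; dropped",
                           row.gene_id, len(seq))
            n_dropped += 1
            continue
        bad = set(seq) - _VALID_CDS
        if bad:
            logger.warning("gene %s CDS contains %s; dropped", row.gene_id, sorted(bad))
            n_dropped += 1
            continue
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                genome=genome or getattr(row, "genome", "") or "genome",
                chromosome=row.chromosome,
                start_bp=int(row.start_bp),
                end_bp=int(row.end_bp),
                strand=getattr(row, "strand", "+") or "+",
                cds=seq,
            )
        )
    missing_coords = set(cds) - set(coords["gene_id"])
    for g in sorted(missing_coords):
        logger.warning("gene %s has CDS but no coordinates; dropped", g)
        n_dropped += 1
    if n_dropped:
        logger.warning("%d genes dropped while reading the catalog", n_dropped)
    assign_order_indices(genes)
    return genes


def _read_coords(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        head = fh.readline()
    if head.startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    df = _read_tsv(path)
    expected = ["gene_id", "chromosome", "start_bp", "end_bp"]
    if not set(expected) <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         keep_default_na=False)
        names = expected + ["strand", "genome"][: max(df.shape[1] - 4, 0)]
        df.columns = names[: df.shape[1]]
    return df


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in {"gene", "mRNA"}:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                continue
            rows.append(
                dict(gene_id=gene_id, chromosome=fields[0], start_bp=fields[3],
                     end_bp=fields[4], strand=fields[6] if fields[6] in "+-" else "+")
            )
    df = pd.DataFrame(rows)
    return df.drop_duplicates(subset="gene_id", keep="first")


def assign_order_indices(genes: Sequence[GeneModel]) -> None:
    """Assign 0-based order indices per chromosome by ascending start."""
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.genome, g.chromosome), []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start_bp, g.gene_id))
        for k, g in enumerate(members):
            g.order_index = k


def write_gene_catalog(
    genes: Sequence[GeneModel], fasta_path: str | Path, coords_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(g.cds), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    df = pd.DataFrame(
        [
            dict(gene_id=g.gene_id, chromosome=g.chromosome, start_bp=g.start_bp,
                 end_bp=g.end_bp, strand=g.strand, genome=g.genome)
            for g in genes
        ]
    )
    _write_tsv(df, coords_path)


# ---------------------------------------------------------------------------
# homolog pair tables
# ---------------------------------------------------------------------------


def read_pair_table(path: str | Path) -> list[HomologPair]:
    """Pairs from a TSV with >= 2 columns (gene_a, gene_b [, score
    [, evalue]]); canonicalized, de-duplicated, self-pairs dropped."""
    df = _read_tsv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: pair table needs at least two columns")
    pairs: dict[tuple[str, str], HomologPair] = {}
    n_self = 0
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            n_self += 1
            continue
        score = _maybe_float(row[2]) if len(cols) > 2 else None
        evalue = _maybe_float(row[3]) if len(cols) > 3 else None
        pair = HomologPair(a, b, score=score, evalue=evalue)
        pairs.setdefault(pair.key, pair)
    if n_self:
        logger.warning("%d self-pairs dropped from %s", n_self, path)
    return list(pairs.values())


def _maybe_float(v) -> Optional[float]:
    try:
        s = str(v).strip()
        return float(s) if s else None
    except (TypeError, ValueError):
        return None


def write_pair_table(pairs: Sequence[HomologPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            dict(gene_a=p.gene_a, gene_b=p.gene_b,
                 score="" if p.score is None else p.score,
                 evalue="" if p.evalue is None else p.evalue)
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "score", "evalue"],
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# pair statistics
# ---------------------------------------------------------------------------

_PAIRSTAT_COLS = ["gene_a", "gene_b", "ka", "ks", "pn", "ps", "n_sites", "s_sites",
                  "nd", "sd", "aa_identity", "gap_fraction", "saturated_flag"]


def write_pairstats_table(stats: Sequence[PairStats], path: str | Path) -> None:
    rows = []
    for s in stats:
        rows.append(dict(
            gene_a=s.gene_a, gene_b=s.gene_b,
            ka="" if s.ka is None else f"{s.ka:.6f}",
            ks="" if s.ks is None else f"{s.ks:.6f}",
            pn="" if s.pn is None else f"{s.pn:.6f}",
            ps="" if s.ps is None else f"{s.ps:.6f}",
            n_sites=f"{s.n_sites:.2f}", s_sites=f"{s.s_sites:.2f}",
            nd=f"{s.nd:.4f}", sd=f"{s.sd:.4f}",
            aa_identity="" if s.aa_identity is None else f"{s.aa_identity:.4f}",
            gap_fraction=f"{s.gap_fraction:.4f}",
            saturated_flag=int(s.saturated),
        ))
    _write_tsv(pd.DataFrame(rows, columns=_PAIRSTAT_COLS), path)


def read_pairstats_table(path: str | Path) -> list[PairStats]:
    df = _read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(PairStats(
            gene_a=row.gene_a, gene_b=row.gene_b,
            ka=_maybe_float(row.ka), ks=_maybe_float(row.ks),
            n_sites=float(row.n_sites), s_sites=float(row.s_sites),
            nd=float(row.nd), sd=float(row.sd),
            aa_identity=_maybe_float(row.aa_identity),
            gap_fraction=float(row.gap_fraction),
            saturated=bool(int(row.saturated_flag)),
        ))
    return out


# ---------------------------------------------------------------------------
# blocks, quartets, calls
# ---------------------------------------------------------------------------


def write_blocks_table(blocks: Sequence[CollinearBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        for k, (ga, gb) in enumerate(b.anchors):
            rows.append(dict(
                block_id=b.block_id, genome_a=b.genome_a, genome_b=b.genome_b,
                chrom_a=b.chrom_a, chrom_b=b.chrom_b, n_anchors=b.n_anchors,
                orientation=b.orientation,
                median_ks="" if b.median_ks is None else f"{b.median_ks:.6f}",
                event_label=b.event_label, anchor_index=k,
                gene_a=ga, gene_b=gb,
            ))
    cols = ["block_id", "genome_a", "genome_b", "chrom_a", "chrom_b", "n_anchors",
            "orientation", "median_ks", "event_label", "anchor_index", "gene_a", "gene_b"]
    _write_tsv(pd.DataFrame(rows, columns=cols), path)


def read_blocks_table(path: str | Path) -> list[CollinearBlock]:
    df = _read_tsv(path)
    blocks: dict[str, CollinearBlock] = {}
    for row in df.itertuples(index=False):
        b = blocks.get(row.block_id)
        if b is None:
            b = CollinearBlock(
                block_id=row.block_id, genome_a=row.genome_a, genome_b=row.genome_b,
                chrom_a=row.chrom_a, chrom_b=row.chrom_b, anchors=[],
                orientation=int(row.orientation),
                median_ks=_maybe_float(row.median_ks),
                event_label=row.event_label,
            )
            blocks[row.block_id] = b
        b.anchors.append((row.gene_a, row.gene_b))
    return list(blocks.values())


def write_quartet_table(quartets: Sequence[Quartet], path: str | Path) -> None:
    rows = []
    for q in quartets:
        row = dict(quartet_id=q.quartet_id, p1=q.p1, p2=q.p2, s1=q.s1, s2=q.s2,
                   genome_a=q.genome_a, genome_b=q.genome_b,
                   filter_status=q.filter_status, filter_reason=q.filter_reason)
        for label in ("P1P2", "S1S2", "P1S1", "P2S2", "P1S2", "P2S1"):
            st = q.stats.get(label)
            row[f"ks_{label}"] = "" if st is None or st.ks is None else f"{st.ks:.6f}"
            row[f"identity_{label}"] = (
                "" if st is None or st.aa_identity is None else f"{st.aa_identity:.4f}"
            )
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), path)


def read_quartet_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


_CALL_COLS = ["quartet_id", "call_type", "converted_genome", "acceptor", "donor",
              "tract_start", "tract_end", "col_start", "col_end", "score",
              "p_value", "direction_confidence"]


def write_calls_table(calls: Sequence[ConversionCall], path: str | Path) -> None:
    rows = [
        dict(quartet_id=c.quartet_id, call_type=c.call_type,
             converted_genome=c.converted_genome, acceptor=c.acceptor, donor=c.donor,
             tract_start=c.tract_start, tract_end=c.tract_end,
             col_start=c.col_start, col_end=c.col_end,
             score="" if c.score != c.score else f"{c.score:.4f}",
             p_value=f"{c.p_value:.6g}", direction_confidence=c.direction_confidence)
        for c in calls
    ]
    _write_tsv(pd.DataFrame(rows, columns=_CALL_COLS), path)


def read_calls_table(path: str | Path) -> list[ConversionCall]:
    df = _read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        score = _maybe_float(row.score)
        out.append(ConversionCall(
            quartet_id=row.quartet_id, call_type=row.call_type,
            converted_genome=row.converted_genome, acceptor=row.acceptor,
            donor=row.donor, tract_start=int(row.tract_start),
            tract_end=int(row.tract_end), col_start=int(row.col_start),
            col_end=int(row.col_end),
            score=float("nan") if score is None else score,
            p_value=float(row.p_value),
            direction_confidence=row.direction_confidence,
        ))
    return out


# ---------------------------------------------------------------------------
# JSON: simulation truth, mixture fits
# ---------------------------------------------------------------------------


def write_truth_json(truths: Sequence[SimTruth], path: str | Path) -> None:
    payload = [
        dict(quartet_id=t.quartet_id,
             events=[dataclasses.asdict(e) for e in t.events])
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> list[SimTruth]:
    payload = json.loads(Path(path).read_text())
    return [
        SimTruth(quartet_id=t["quartet_id"],
                 events=[SimTruthEvent(**e) for e in t["events"]])
        for t in payload
    ]


def write_fit_json(fit: KsMixtureFit, path: str | Path) -> None:
    payload = dict(
        bandwidth=fit.bandwidth,
        components=[list(c) for c in fit.components],
        r_squared=fit.r_squared,
        n_components=fit.n_components,
        converged=fit.converged,
        grid=list(fit.grid),
        density=list(fit.density),
    )
    Path(path).write_text(json.dumps(payload))


def read_fit_json(path: str | Path) -> KsMixtureFit:
    d = json.loads(Path(path).read_text())
    return KsMixtureFit(
        bandwidth=d["bandwidth"], grid=d["grid"], density=d["density"],
        components=[tuple(c) for c in d["components"]],
        r_squared=d["r_squared"], n_components=d["n_components"],
        converged=d["converged"],
    )


# ---------------------------------------------------------------------------
# expression and GO
# ---------------------------------------------------------------------------


def read_tpm_table(path: str | Path) -> dict[str, float]:
    df = _read_tsv(path)
    return {str(row[0]): float(row[1]) for row in df.itertuples(index=False)}


def write_tpm_table(tpm: dict[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        [dict(gene_id=g, tpm=f"{v:.4f}") for g, v in sorted(tpm.items())],
        columns=["gene_id", "tpm"],
    )
    _write_tsv(df, path)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """TSV gene_id <tab> GO terms (comma-separated, or one row per term)."""
    df = _read_tsv(path)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        gene, terms = str(row[0]), str(row[1])
        out.setdefault(gene, set()).update(t for t in terms.split(",") if t)
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    df = pd.DataFrame(
        [dict(gene_id=g, go_terms=",".join(sorted(ts)))
         for g, ts in sorted(go_map.items())],
        columns=["gene_id", "go_terms"],
    )
    _write_tsv(df, path)
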
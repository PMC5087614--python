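"""Readers and writers for the formats the pipeline touches.

Plain TSV for tabular results (diff-able), BED6+2 for TFEs, BED12/GFF3 for
gene models, FASTA for sequences, minimal MEME for motifs and JSON for truth
and manifests.  Internal coordinates are 0-based half-open everywhere;
conversion happens only at format boundaries (GFF3 is 1-based inclusive).
Spike-in rows are identified by the ``SPIKE_`` id prefix (overridable).
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import SampleSheet, SpikeTagMatrix, SPIKE_PREFIX
from .motif import MotifParseError, PWMModel, PromoterWindow
from .tfe import GeneModel, TFERecord

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# count matrix + sample sheet


def read_count_matrix(path, spike_prefix: str = SPIKE_PREFIX) -> SpikeTagMatrix:
    """TSV with a header row of sample ids and a first column of row ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.size == 0 or df.index.name is None:
        raise ParseError(f"{path}: missing header row")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
        bad = vals.index[(vals != np.floor(vals)) | vals.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-integer count at row {bad[0]!r}, column {col!r}")
        neg = vals.index[vals < 0]
        if len(neg):
            raise ParseError(f"{path}: negative count at row {neg[0]!r}, column {col!r}")
        out[col] = vals.astype(np.int64)
    matrix = SpikeTagMatrix(out, spike_prefix=spike_prefix)
    logger.info("read %d rows x %d samples (%d spike rows) from %s",
                out.shape[0], out.shape[1], matrix.spike_mask.sum(), path)
    return matrix


def write_count_matrix(matrix: SpikeTagMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path, fluorescent_control: str = "mCherry") -> SampleSheet:
    table = pd.read_csv(path, sep="\t")
    return SampleSheet(table, fluorescent_control=fluorescent_control)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TFE BED6+2 (category, gene_id)


def write_tfe_bed(tfes: Iterable[TFERecord], path) -> None:
    with open(path, "w") as fh:
        for t in tfes:
            fh.write(
                "\t".join(
                    [t.chrom, str(t.start), str(t.end), t.id, str(t.peak), t.strand,
                     t.category or ".", t.gene_id or "."]
                )
                + "\n"
            )


def read_tfe_bed(path) -> list[TFERecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{ln}: expected >= 6 BED fields")
            chrom, start, end, name, peak, strand = fields[:6]
            category = fields[6] if len(fields) > 6 and fields[6] != "." else None
            gene_id = fields[7] if len(fields) > 7 and fields[7] != "." else None
            out.append(
                TFERecord(name, chrom, int(start), int(end), strand, int(peak),
                          category=category, gene_id=gene_id)
            )
    return out


# ---------------------------------------------------------------------------
# gene models: BED12 and GFF3


def read_gene_models(path, dialect: str = "bed12") -> list[GeneModel]:
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed12(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED fields, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            if thick_start > thick_end:
                raise ParseError(f"{path}:{ln}: thickStart > thickEnd")
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(f"{path}:{ln}: blockCount mismatch")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            if exons[0][0] != start or exons[-1][1] != end:
                raise ParseError(f"{path}:{ln}: blocks do not span the BED interval")
            cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
            out.append(GeneModel(name, chrom, strand, start, end, exons, *cds))
    return out


def write_gene_models_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            thick = (g.cds_start, g.cds_end) if g.biotype == "coding" else (g.tx_start, g.tx_start)
            fh.write(
                "\t".join(
                    [g.chrom, str(g.tx_start), str(g.tx_end), g.gene_id, "0", g.strand,
                     str(thick[0]), str(thick[1]), "0", str(len(g.exons)), sizes, starts]
                )
                + "\n"
            )


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        parents = transcripts or [gene]
        exons, cds = [], []
        for parent in parents:
            exons += [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
            cds += [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
        exons = sorted(set(exons))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        out.append(
            GeneModel(gene.id, gene.seqid, gene.strand, gene.start - 1, gene.end,
                      exons, cds_start, cds_end)
        )
    return out


def write_gene_models_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tegakit\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(base + f"gene\t{g.tx_start + 1}\t{g.tx_end}" + tail
                     + f"\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(base + f"mRNA\t{g.tx_start + 1}\t{g.tx_end}" + tail
                     + f"\tID={tid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(base + f"exon\t{s + 1}\t{e}" + tail
                         + f"\tID={tid}.exon{i};Parent={tid}\n")
            if g.biotype == "coding":
                for i, (s, e) in enumerate(g.exons, 1):
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(base + f"CDS\t{cs + 1}\t{ce}" + tail
                                 + f"\tID={tid}.cds{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_promoter_fasta(windows: Iterable[PromoterWindow], path) -> None:
    write_fasta({w.id: w.sequence for w in windows}, path)


def read_promoter_fasta(path) -> list[PromoterWindow]:
    return [
        PromoterWindow(name, "na", 0, len(seq), "+", seq)
        for name, seq in read_fasta(path).items()
    ]


# ---------------------------------------------------------------------------
# minimal MEME motif format


def write_meme_motif(pwm: PWMModel, path) -> None:
    """Minimal MEME format, fixed 6-decimal formatting (round-trip stable)."""
    bg = pwm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(bg))
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} "
                 f"nsites= 20 E= 0\n")
        for row in pwm.probs:
            fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))


def read_meme_motif(path, granularity: float = 1e-3) -> PWMModel:
    name, bg, rows, width = "motif", np.full(4, 0.25), [], None
    in_matrix = False
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            try:
                bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            except (IndexError, ValueError) as exc:
                raise MotifParseError(f"{path}: malformed background line") from exc
        elif s.startswith("MOTIF"):
            name = s.split()[1] if len(s.split()) > 1 else "motif"
        elif s.startswith("letter-probability matrix"):
            in_matrix = True
            toks = s.replace(":", " ").split()
            for j, tok in enumerate(toks):
                if tok == "w=" and j + 1 < len(toks):
                    width = int(toks[j + 1])
                elif tok.startswith("w=") and len(tok) > 2:
                    width = int(tok[2:])
        elif in_matrix and s:
            vals = s.split()
            if len(vals) != 4:
                raise MotifParseError(f"{path}: expected 4 probabilities per row")
            rows.append([float(v) for v in vals])
    if not rows:
        raise MotifParseError(f"{path}: no letter-probability matrix found")
    if width is not None and len(rows) != width:
        raise MotifParseError(f"{path}: matrix width {len(rows)} != declared w={width}")
    return PWMModel(np.array(rows), background=bg, granularity=granularity, name=name)


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
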
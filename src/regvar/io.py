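"""Readers and writers for the plain-text formats the pipeline consumes.

TSV tables go through pandas (gzip handled transparently by suffix); FASTA
through Biopython; BED/BEDPE are parsed into the package's interval types.
Motif libraries are accepted in MEME minimal format and in JASPAR PFM format.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import GeneModel, GenomicInterval, SnpRecord
from .allelic_evidence import Pwm


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, label: str = "") -> list[GenomicInterval]:
    """3+ column BED into 0-based half-open intervals."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else label
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
            )
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """BEDPE-like contact table: 6 coordinates + dataset_id [+ method]."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "chrom1": f[0],
                    "start1": int(f[1]),
                    "end1": int(f[2]),
                    "chrom2": f[3],
                    "start2": int(f[4]),
                    "end2": int(f[5]),
                    "dataset_id": f[6] if len(f) > 6 else "contacts",
                    "method": f[7] if len(f) > 7 else "unknown",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1",
            "start1",
            "end1",
            "chrom2",
            "start2",
            "end2",
            "dataset_id",
            "method",
        ],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_snp_table(path: str | Path) -> dict[str, SnpRecord]:
    """SNP TSV with columns snp_id, chrom, pos, ref, alt[, risk, diseases, coding].

    ``diseases`` is a comma-separated label list; ``coding`` is 0/1.
    """
    df = read_tsv(path)
    out = {}
    for row in df.itertuples(index=False):
        diseases = set()
        raw = getattr(row, "diseases", "")
        if isinstance(raw, str) and raw:
            diseases = set(raw.split(","))
        risk = getattr(row, "risk", None)
        out[row.snp_id] = SnpRecord(
            snp_id=row.snp_id,
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            risk_allele=None if pd.isna(risk) else risk,
            diseases=diseases,
            coding_flag=bool(int(getattr(row, "coding", 0))),
        )
    return out


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Gene TSV: gene_id, symbol, chrom, strand, tss_list (comma-separated)."""
    df = read_tsv(path)
    out = {}
    for row in df.itertuples(index=False):
        tss = [int(t) for t in str(row.tss_list).split(",")]
        out[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            symbol=row.symbol,
            chrom=row.chrom,
            strand=row.strand,
            tss_list=tss,
        )
    return out


def read_meme_motifs(path: str | Path, database: str | None = None) -> list[Pwm]:
    """MEME minimal-format motif file into Pwm objects."""
    if database is None:
        database = Path(path).stem
    pwms = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(Pwm(name, database, np.array(rows)))
                parts = line.split()
                name = parts[1]
                rows = []
                in_matrix = False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line:
                vals = line.split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                else:
                    in_matrix = False
            elif in_matrix and not line:
                in_matrix = False
    if name is not None and rows:
        pwms.append(Pwm(name, database, np.array(rows)))
    return pwms


def write_meme_motifs(pwms: list[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_jaspar_pfm(path: str | Path, database: str = "jaspar") -> list[Pwm]:
    """JASPAR PFM format: one or more count matrices with > headers.

    Counts are four lines (A, C, G, T), optionally bracketed; columns are
    normalized to probabilities.
    """
    pwms = []
    name = None
    lines: list[list[float]] = []

    def _flush() -> None:
        nonlocal lines
        if name is not None and len(lines) == 4:
            counts = np.array(lines).T  # (L, 4)
            probs = counts / counts.sum(axis=1, keepdims=True)
            pwms.append(Pwm(name, database, probs))
        lines = []

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                fields = line[1:].split()
                name = fields[-1] if len(fields) > 1 else fields[0]
            else:
                cleaned = (
                    line.replace("[", " ").replace("]", " ").replace("A", " ")
                    .replace("C", " ").replace("G", " ").replace("T", " ")
                )
                lines.append([float(v) for v in cleaned.split()])
    _flush()
    return pwms
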
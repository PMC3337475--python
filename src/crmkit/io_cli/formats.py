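"""Readers and writers for the on-disk formats.

All internal coordinates are 0-based half-open; this module is the single
place where any other convention (1-based display strings, BED columns) is
converted.  FASTA goes through Biopython with extra validation; matrices
come either as a simple ``>id`` + four-column block or as TRANSFAC-style
``P0`` blocks; tables are plain TSV via pandas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ..association import AssayVector, ExpressionMatrix
from ..errors import AlphabetError, DuplicateIdError, FormatError
from ..genome_prep import HitRecord
from ..pwm_core import CountMatrix

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class IntervalRecord:
    """A BED6 row: 0-based half-open interval with name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom!r}"
            )
        if self.strand not in "+-.":
            raise FormatError(f"invalid strand {self.strand!r}")


def one_based_to_interval(chrom: str, start1: int, end1: int, **kw) -> IntervalRecord:
    """Convert a 1-based inclusive [start1, end1] span to a record."""
    return IntervalRecord(chrom=chrom, start=start1 - 1, end=end1, **kw)


def read_fasta(path) -> dict[str, str]:
    """Parse FASTA into an ordered id -> sequence mapping.

    Rejects duplicate ids, empty records, and non-IUPAC characters; case
    is preserved.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        bad = set(seq.upper()) - _IUPAC_DNA
        if bad:
            raise AlphabetError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[IntervalRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = int(float(parts[4])) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            records.append(IntervalRecord(chrom, start, end, name, score, strand))
    return records


def write_bed(records: Iterable[IntervalRecord], path) -> None:
    """BED6, sorted by (chrom, start, end)."""
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n"
            )


def hits_to_bed(hits) -> list[IntervalRecord]:
    """SiteHits as BED records with score = round(100 * site score)."""
    return [
        IntervalRecord(
            chrom=h.seq_id,
            start=h.start,
            end=h.end,
            name=h.motif_id,
            score=int(round(100 * h.score)),
            strand=h.strand,
        )
        for h in hits
    ]


def modules_to_bed(modules, max_score: int = 1000) -> list[IntervalRecord]:
    """CRM predictions as BED records with score = capped 100 * peak Z."""
    return [
        IntervalRecord(
            chrom=m.seq_id,
            start=m.start,
            end=m.end,
            name=f"module_{m.seq_id}_{m.start}",
            score=min(max_score, int(round(100 * m.peak_z))),
            strand=".",
        )
        for m in modules
    ]


def write_bedgraph(values_by_seq: Mapping[str, np.ndarray], path) -> None:
    """Per-position track (e.g. Z scores), run-length merged."""
    with open(path, "w") as fh:
        for seq_id in sorted(values_by_seq):
            vals = np.asarray(values_by_seq[seq_id], dtype=float)
            if vals.size == 0:
                continue
            run_start = 0
            for i in range(1, vals.size + 1):
                if i == vals.size or vals[i] != vals[run_start]:
                    fh.write(
                        f"{seq_id}\t{run_start}\t{i}\t{vals[run_start]:.4f}\n"
                    )
                    run_start = i


def read_matrices(path) -> list[CountMatrix]:
    """Simple matrix text: ``>motif_id`` then one tab-separated A C G T
    count row per column."""
    matrices = []
    motif_id = None
    rows: list[list[float]] = []

    def flush():
        if motif_id is not None:
            if not rows:
                raise FormatError(f"matrix {motif_id!r} has no columns")
            matrices.append(
                CountMatrix(motif_id, np.array(rows), check_length=False)
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].strip()
                if any(m.motif_id == motif_id for m in matrices):
                    raise DuplicateIdError(f"duplicate matrix id {motif_id!r}")
                rows = []
            else:
                if motif_id is None:
                    raise FormatError(f"{path}:{lineno}: counts before any header")
                parts = line.replace(",", "\t").split()
                if len(parts) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected 4 counts, got {len(parts)}"
                    )
                rows.append([float(x) for x in parts])
    flush()
    if not matrices:
        raise FormatError(f"no matrices in {path}")
    return matrices


def write_matrices(matrices: Iterable[CountMatrix], path) -> None:
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.motif_id}\n")
            for row in m.counts:
                fh.write("\t".join(f"{x:g}" for x in row) + "\n")


def read_transfac(path) -> list[CountMatrix]:
    """TRANSFAC-style blocks: ID/NA lines name the motif, ``P0`` starts the
    count table, numbered rows carry A C G T counts, ``//`` ends a block."""
    matrices = []
    motif_id = None
    rows: list[list[float]] = []
    in_table = False

    def flush():
        nonlocal motif_id, rows, in_table
        if rows:
            matrices.append(
                CountMatrix(motif_id or f"matrix{len(matrices) + 1}",
                            np.array(rows), check_length=False)
            )
        motif_id, rows, in_table = None, [], False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith("//"):
                flush()
            elif line.startswith(("ID", "NA", "AC")) and motif_id is None:
                motif_id = line.split(maxsplit=1)[1].strip() if " " in line else None
            elif line.startswith("P0"):
                in_table = True
            elif in_table and line[:2].strip().isdigit():
                parts = line.split()
                rows.append([float(x) for x in parts[1:5]])
    flush()
    if not matrices:
        raise FormatError(f"no TRANSFAC matrices in {path}")
    return matrices


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_expression(path) -> ExpressionMatrix:
    return ExpressionMatrix(read_table(path))


def read_assay(path) -> list[AssayVector]:
    df = read_table(path)
    return [AssayVector(sample_id=c, values=df[c]) for c in df.columns]


def read_gene_sets(path) -> dict[str, set]:
    """Two-column TSV (set_id, gene_id) -> id -> gene set, header optional."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[1].lower() in ("gene", "gene_id"):
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def read_edges(path) -> dict[str, set]:
    """Two-column TSV (parent, child) -> parent -> set of children."""
    return read_gene_sets(path)


def read_hit_table(path) -> list[HitRecord]:
    """BLAST outfmt-6-like TSV: query, subject, evalue, cov_query, cov_subject."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            hits.append(
                HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    evalue=float(parts[2]),
                    coverage_query=float(parts[3]),
                    coverage_subject=float(parts[4]),
                )
            )
    return hits


def read_promoter_lengths(path) -> dict[str, int]:
    """Two-column TSV (gene_id, length)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and not parts[1].isdigit():
                continue
            out[parts[0]] = int(parts[1])
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
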
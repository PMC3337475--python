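"""Ortholog calling from precomputed hit tables and promoter extraction.

Orthologs are reciprocal best hits with an E-value ceiling and a coverage
floor on at least one of the two proteins.  Promoters run from the base
immediately 5' of the translational start, truncated at the nearest
neighboring gene-span edge (any strand) and capped at 2 kb; for operonic
genes only the first gene keeps a promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import CoordinateError

E_MAX = 1e-10
COV_MIN = 0.6
PROMOTER_MAX_LEN = 2000

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation.

    ``cds_start`` is the 1-based coordinate of the A of the start codon.
    ``span_start``/``span_end`` (1-based, inclusive) delimit the gene span
    used when this gene acts as a neighbor boundary; they default to the
    cds_start position.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    span_start: int | None = None
    span_end: int | None = None
    operon_id: str | None = None
    operon_rank: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.cds_start < 1:
            raise CoordinateError("cds_start is 1-based and must be >= 1")
        if self.operon_id is not None and (
            self.operon_rank is None or self.operon_rank < 1
        ):
            raise ValueError("operonic genes need operon_rank >= 1")
        if self.span_start is None:
            object.__setattr__(self, "span_start", self.cds_start)
        if self.span_end is None:
            object.__setattr__(self, "span_end", self.cds_start)
        if self.span_end < self.span_start:
            raise CoordinateError("span_end must be >= span_start")


@dataclass(frozen=True)
class HitRecord:
    """One row of a pairwise protein-hit table with coverage fractions."""

    query_id: str
    subject_id: str
    evalue: float
    coverage_query: float
    coverage_subject: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        for c in (self.coverage_query, self.coverage_subject):
            if not 0 <= c <= 1:
                raise ValueError("coverages must be fractions in [0, 1]")


@dataclass(frozen=True)
class OrthologTriple:
    ce_id: str
    cb_id: str
    cr_id: str

    def __post_init__(self):
        if not (self.ce_id and self.cb_id and self.cr_id):
            raise ValueError("all three ortholog ids must be present")


def best_hits(hits: Sequence[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest E-value, ties by lexicographic subject."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, h.subject_id) < (cur.evalue, cur.subject_id):
            best[h.query_id] = h
    return best


def rbh_orthologs(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    e_max: float = E_MAX,
    cov_min: float = COV_MIN,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs (a_id, b_id), sorted.

    Both directions' best hits must point at each other, both E-values must
    be strictly below ``e_max``, and at least one coverage fraction across
    the two hits must reach ``cov_min`` -- conditions applied symmetrically
    so that swapping the tables mirrors the result.
    """
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a, hab in best_ab.items():
        b = hab.subject_id
        hba = best_ba.get(b)
        if hba is None or hba.subject_id != a:
            continue
        if not (hab.evalue < e_max and hba.evalue < e_max):
            continue
        covs = (
            hab.coverage_query,
            hab.coverage_subject,
            hba.coverage_query,
            hba.coverage_subject,
        )
        if max(covs) < cov_min:
            continue
        pairs.append((a, b))
    return sorted(pairs)


def extract_promoter(
    gene: GeneModel,
    genome: Mapping[str, str],
    neighbors: Sequence[GeneModel] = (),
    max_len: int = PROMOTER_MAX_LEN,
) -> str:
    """Upstream sequence 5' of the start codon, truncated and capped.

    The region runs from position -1 relative to the ATG up to the nearest
    neighbor gene-span edge (regardless of the neighbor's strand), at most
    ``max_len`` bp.  For minus-strand genes the genomic interval downstream
    of cds_start is taken and reverse-complemented so the returned string
    reads 5'->3' toward the ATG.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom]
    clen = len(chrom_seq)
    if not 1 <= gene.cds_start <= clen:
        raise CoordinateError(
            f"cds_start {gene.cds_start} outside chromosome of length {clen}"
        )
    same_chrom = [
        n for n in neighbors if n.chrom == gene.chrom and n.gene_id != gene.gene_id
    ]
    if gene.strand == "+":
        end0 = gene.cds_start - 1  # 0-based, exclusive end of promoter
        bound = 0
        for n in same_chrom:
            n_lo0, n_hi0 = n.span_start - 1, n.span_end  # 0-based half-open
            if n_lo0 < end0:  # neighbor material below the ATG
                bound = max(bound, min(n_hi0, end0))
        start0 = max(end0 - max_len, bound, 0)
        region = chrom_seq[start0:end0]
    else:
        start0 = gene.cds_start  # first base 5' of the ATG on '-' strand
        bound = clen
        for n in same_chrom:
            n_lo0, n_hi0 = n.span_start - 1, n.span_end
            if n_hi0 > start0:  # neighbor material above the ATG
                bound = min(bound, max(n_lo0, start0))
        end0 = min(start0 + max_len, bound, clen)
        region = reverse_complement(chrom_seq[start0:end0])
    if not region:
        warnings.warn(
            f"gene {gene.gene_id!r} has a zero-length promoter region",
            stacklevel=2,
        )
    return region


def operon_first_filter(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop operonic genes with rank > 1; keep everything else."""
    return [
        g for g in genes if g.operon_id is None or g.operon_rank == 1
    ]
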
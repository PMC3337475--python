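"""Matrix-to-matrix similarity and greedy consolidation of redundant PWMs.

Similarity between two count matrices is the summed per-column average
log-likelihood ratio (ALLR) over the best ungapped alignment, searched over
all offsets and both orientations.  Two matrices are redundant when the
alignment score and the overlapping fraction both clear their thresholds
(strict inequalities); consolidation then repeatedly picks the best-ranked
remaining matrix as a representative and absorbs everything redundant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateColumnError
from .pwm_core import Background, CountMatrix, smoothed_frequencies

#: redundancy thresholds (strict >): alignment score and overlap fraction
ALLR_MIN = 6.57
OLAP_MIN = 0.681

#: shortest overlap worth aligning; one-column overlaps are meaningless
MIN_OVERLAP_COLS = 5

ORIENT_SAME = "same"
ORIENT_RC = "reverse-complement"


@dataclass(frozen=True)
class MatrixAlignment:
    """Best ungapped alignment of matrix b onto matrix a.

    ``offset`` is the position of b's first column in a's coordinate frame
    (after orienting b); negative offsets hang b off a's left end.
    ``olap`` is overlap_cols / min(len_a, len_b).
    """

    id_a: str
    id_b: str
    offset: int
    orientation: str
    overlap_cols: int
    allr_total: float
    olap: float


@dataclass
class MotifCluster:
    representative_id: str
    member_ids: list[str]
    merged_counts: CountMatrix
    alignments: dict[str, MatrixAlignment] = field(default_factory=dict)


def allr_column(
    col_a: np.ndarray,
    col_b: np.ndarray,
    bg: Background | None = None,
    pseudo: float = 0.25,
) -> float:
    """Per-column ALLR of two count columns against a background.

    ALLR = [ sum_b n_b(a) ln(p_b(b)/q_b) + sum_b n_b(b) ln(p_b(a)/q_b) ]
           / (N_a + N_b)

    with frequencies smoothed by the package-wide pseudocount convention.
    Zero-count terms contribute 0 even when the matching smoothed frequency
    is 0 (pseudo=0).
    """
    if bg is None:
        bg = Background.uniform()
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    n_a, n_b = a.sum(), b.sum()
    if n_a <= 0 or n_b <= 0:
        raise DegenerateColumnError("ALLR needs positive column totals")
    p_a = smoothed_frequencies(a, bg, pseudo)[0]
    p_b = smoothed_frequencies(b, bg, pseudo)[0]
    q = bg.freqs
    with np.errstate(divide="ignore"):
        log_b = np.log(p_b / q)
        log_a = np.log(p_a / q)
    mask_a, mask_b = a > 0, b > 0
    term_ab = (a[mask_a] * log_b[mask_a]).sum()
    term_ba = (b[mask_b] * log_a[mask_b]).sum()
    return float((term_ab + term_ba) / (n_a + n_b))


def _log_ratio(counts: np.ndarray, bg: Background, pseudo: float) -> np.ndarray:
    """ln(p_hat / q) per column and base, under the shared smoothing."""
    p = smoothed_frequencies(counts, bg, pseudo)
    with np.errstate(divide="ignore"):
        return np.log(p / bg.freqs)


def _masked_cross(counts: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Per-column sum of n_b * log-ratio, with 0 * (-inf) defined as 0."""
    with np.errstate(invalid="ignore"):
        t = counts * log_ratio
    t[counts == 0] = 0.0
    return t.sum(axis=1)


def _allr_overlap(
    counts_a: np.ndarray,
    log_a: np.ndarray,
    counts_b: np.ndarray,
    log_b: np.ndarray,
    offset: int,
) -> tuple[int, float]:
    """(overlap columns, summed ALLR) for b placed at ``offset`` on a."""
    la, lb = counts_a.shape[0], counts_b.shape[0]
    a_lo, a_hi = max(0, offset), min(la, offset + lb)
    n_overlap = a_hi - a_lo
    if n_overlap < 1:
        return 0, -np.inf
    A = counts_a[a_lo:a_hi]
    B = counts_b[a_lo - offset : a_hi - offset]
    term_ab = _masked_cross(A, log_b[a_lo - offset : a_hi - offset])
    term_ba = _masked_cross(B, log_a[a_lo:a_hi])
    per_col = (term_ab + term_ba) / (A.sum(axis=1) + B.sum(axis=1))
    return n_overlap, float(per_col.sum())


def align_matrices(
    a: CountMatrix,
    b: CountMatrix,
    bg: Background | None = None,
    pseudo: float = 0.25,
    min_overlap: int = MIN_OVERLAP_COLS,
) -> MatrixAlignment:
    """Maximize summed ALLR over all offsets and both orientations.

    Ties prefer orientation "same", then smaller |offset|, then larger
    overlap.  ``min_overlap`` is clamped to the shorter matrix length.
    """
    if bg is None:
        bg = Background.uniform()
    la, lb = len(a), len(b)
    need = min(min_overlap, la, lb)
    log_a = _log_ratio(a.counts, bg, pseudo)
    b_rc = b.reverse_complement().counts
    candidates = []  # (sort key, alignment fields)
    for orientation, cb in ((ORIENT_SAME, b.counts), (ORIENT_RC, b_rc)):
        log_cb = _log_ratio(cb, bg, pseudo)
        for offset in range(-(lb - 1), la):
            n_overlap, total = _allr_overlap(a.counts, log_a, cb, log_cb, offset)
            if n_overlap < need:
                continue
            key = (
                -total,
                0 if orientation == ORIENT_SAME else 1,
                abs(offset),
                -n_overlap,
                offset,
            )
            candidates.append((key, offset, orientation, n_overlap, total))
    if not candidates:
        raise ValueError(
            f"no alignment of {a.motif_id!r} and {b.motif_id!r} reaches "
            f"{need} overlapping columns"
        )
    key, offset, orientation, n_overlap, total = min(candidates)
    return MatrixAlignment(
        id_a=a.motif_id,
        id_b=b.motif_id,
        offset=offset,
        orientation=orientation,
        overlap_cols=n_overlap,
        allr_total=total,
        olap=n_overlap / min(la, lb),
    )


def is_redundant(
    aln: MatrixAlignment,
    allr_min: float = ALLR_MIN,
    olap_min: float = OLAP_MIN,
) -> bool:
    """True iff both criteria pass with strict inequality."""
    return aln.allr_total > allr_min and aln.olap > olap_min


def consolidate_greedy(
    matrices: list[CountMatrix],
    rank_score: dict[str, float],
    bg: Background | None = None,
    allr_min: float = ALLR_MIN,
    olap_min: float = OLAP_MIN,
    pseudo: float = 0.25,
    min_overlap: int = MIN_OVERLAP_COLS,
) -> list[MotifCluster]:
    """Greedy redundancy clustering.

    Repeatedly pick the highest-ranked unconsumed matrix as representative
    (rank ties broken by lexicographic motif id), absorb every remaining
    matrix redundant to it, and recurse on the rest.  Every input matrix
    ends up in exactly one cluster.
    """
    for m in matrices:
        if m.motif_id not in rank_score:
            raise KeyError(f"no rank score for matrix {m.motif_id!r}")
    if bg is None:
        bg = Background.uniform()
    pending = sorted(matrices, key=lambda m: (-rank_score[m.motif_id], m.motif_id))
    clusters: list[MotifCluster] = []
    while pending:
        rep, rest = pending[0], pending[1:]
        cluster = MotifCluster(
            representative_id=rep.motif_id,
            member_ids=[rep.motif_id],
            merged_counts=rep,
        )
        survivors = []
        for m in rest:
            aln = align_matrices(rep, m, bg, pseudo, min_overlap)
            if is_redundant(aln, allr_min, olap_min):
                cluster.member_ids.append(m.motif_id)
                cluster.alignments[m.motif_id] = aln
            else:
                survivors.append(m)
        clusters.append(cluster)
        pending = survivors
    return clusters
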
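"""Position weight matrices: log-odds scoring, exact cutoff distributions,
and both-strand scanning.

Count matrices hold per-column base counts over {A, C, G, T}.  Converting to
a PWM applies background-proportional pseudocounts and natural-log odds.
Scanning scores every placement on both strands and keeps placements at or
above a cutoff; the default cutoff is derived from the exact background
score distribution by dynamic programming on a discretized score lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlphabetError, CoordinateError, DegenerateColumnError

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: motif length range typical of compact-promoter studies; constructors
#: enforce it unless told otherwise.
MIN_MOTIF_LEN = 5
MAX_MOTIF_LEN = 30

#: score lattice step for the cutoff dynamic program (natural-log units)
SCORE_DELTA = 0.01

#: default per-site tail probability standing in for the scanner's
#: "default cutoff"; exposed everywhere as a knob
DEFAULT_P_SITE = 1e-3

# weights are clipped at this floor before discretization so -inf log-odds
# (zero count, zero pseudocount) stay representable on the lattice
_WEIGHT_FLOOR = -46.0


@dataclass(frozen=True)
class Background:
    """Base composition used for log-odds and for the cutoff distribution."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background needs exactly 4 base frequencies")
        if np.any(f <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "Background":
        """AT/GC-split composition with P(G)+P(C) = ``gc``."""
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        at = (1 - gc) / 2
        return cls(np.array([at, gc / 2, gc / 2, at]))


@dataclass(frozen=True)
class CountMatrix:
    """Per-column base counts for a motif.

    ``counts`` has shape (n_columns, 4) in A, C, G, T order.  Column counts
    must be nonnegative.  The column count is restricted to
    [MIN_MOTIF_LEN, MAX_MOTIF_LEN] unless ``check_length=False``.
    """

    motif_id: str
    counts: np.ndarray
    n_sites: int = 0
    check_length: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise ValueError("counts must be a (n_columns, 4) array")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.check_length and not (MIN_MOTIF_LEN <= c.shape[0] <= MAX_MOTIF_LEN):
            raise ValueError(
                f"motif {self.motif_id!r} has {c.shape[0]} columns, outside "
                f"[{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}]; pass check_length=False "
                "to override"
            )
        object.__setattr__(self, "counts", c)
        if self.n_sites == 0:
            object.__setattr__(self, "n_sites", int(round(c.sum(axis=1).max())))

    def __len__(self) -> int:
        return self.counts.shape[0]

    def reverse_complement(self) -> "CountMatrix":
        rc = self.counts[::-1, _COMPLEMENT_ORDER]
        return replace(self, counts=rc.copy())


@dataclass(frozen=True)
class PWM:
    """Natural-log odds weights of shape (n_columns, 4) plus a background.

    ``cutoff`` is an optional per-site score threshold used by scanners when
    no explicit cutoff is given.
    """

    motif_id: str
    weights: np.ndarray
    background: Background
    cutoff: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must be a (n_columns, 4) array")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def reverse_complement(self) -> "PWM":
        rc = self.weights[::-1, _COMPLEMENT_ORDER]
        return replace(self, weights=rc.copy())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def with_cutoff(self, cutoff: float) -> "PWM":
        return replace(self, cutoff=cutoff)


@dataclass(frozen=True)
class SiteHit:
    """A scored motif placement on one strand of a sequence."""

    seq_id: str
    start: int
    strand: str
    score: float
    motif_id: str
    length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.start < 0:
            raise CoordinateError("hit start must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.length


def counts_to_pwm(
    counts: CountMatrix,
    bg: Background | None = None,
    pseudo: float = 0.25,
) -> PWM:
    """Convert counts to natural-log odds weights.

    Pseudocounts are split by the background: base ``b`` in a column with
    total ``N`` gets smoothed frequency ``(n_b + 4*pseudo*q_b) / (N + 4*pseudo)``,
    so the default ``pseudo=0.25`` adds one pseudo-observation per column
    distributed according to the background.  ``pseudo=0`` gives raw
    frequencies and -inf weights for absent bases.
    """
    if bg is None:
        bg = Background.uniform()
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    q = bg.freqs
    totals = counts.counts.sum(axis=1)
    if pseudo == 0 and np.any(totals == 0):
        raise DegenerateColumnError(
            f"motif {counts.motif_id!r} has a zero-total column and pseudo=0"
        )
    p_hat = (counts.counts + 4 * pseudo * q) / (totals + 4 * pseudo)[:, None]
    with np.errstate(divide="ignore"):
        weights = np.log(p_hat / q)
    return PWM(motif_id=counts.motif_id, weights=weights, background=bg)


def smoothed_frequencies(
    counts: np.ndarray, bg: Background, pseudo: float = 0.25
) -> np.ndarray:
    """Column frequencies under the package-wide pseudocount convention."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1)
    if np.any(totals + 4 * pseudo <= 0):
        raise DegenerateColumnError("zero-total column with pseudo=0")
    return (counts + 4 * pseudo * bg.freqs) / (totals + 4 * pseudo)[:, None]


def _augmented_weights(pwm: PWM) -> np.ndarray:
    """Weights with a fifth column for N: the background-expected weight."""
    n_col = (pwm.background.freqs * pwm.weights).sum(axis=1, keepdims=True)
    return np.hstack([pwm.weights, n_col])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string (ACGTN, case-insensitive) to integer codes 0..4."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("N")] = 4
    table[ord("n")] = 4
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = sorted({c for c in seq if c.upper() not in "ACGTN"})
        raise AlphabetError(f"sequence contains non-ACGTN characters: {bad}")
    return codes.astype(np.int64)


def score_site(pwm: PWM, subsequence: str) -> float:
    """Score a single placement; N contributes the background-expected weight."""
    codes = encode_sequence(subsequence)
    if codes.size != len(pwm):
        raise ValueError(
            f"site length {codes.size} != motif length {len(pwm)}"
        )
    aug = _augmented_weights(pwm)
    return float(aug[np.arange(len(pwm)), codes].sum())


def score_positions(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every placement on the forward and reverse strands.

    Returns two arrays of length ``len(seq) - len(pwm) + 1``; element i of
    the reverse array is the score of the reverse-complemented window
    starting at forward position i.  Empty arrays if the sequence is shorter
    than the motif.
    """
    codes = encode_sequence(seq)
    L = len(pwm)
    n_pos = codes.size - L + 1
    if n_pos <= 0:
        return np.empty(0), np.empty(0)
    fwd_w = _augmented_weights(pwm)
    rev_w = _augmented_weights(pwm.reverse_complement())
    fwd = np.zeros(n_pos)
    rev = np.zeros(n_pos)
    for j in range(L):
        window = codes[j : j + n_pos]
        fwd += fwd_w[j, window]
        rev += rev_w[j, window]
    return fwd, rev


def scan_sequence(
    pwm: PWM,
    seq: str,
    cutoff: float | None = None,
    seq_id: str = "",
) -> list[SiteHit]:
    """All placements on both strands scoring >= cutoff, sorted by start
    then strand ('+' before '-').

    Falls back to ``pwm.cutoff`` when ``cutoff`` is None.  A sequence
    shorter than the motif yields an empty list.
    """
    if cutoff is None:
        cutoff = pwm.cutoff
    if cutoff is None:
        raise ValueError("no cutoff given and pwm.cutoff is unset")
    fwd, rev = score_positions(pwm, seq)
    L = len(pwm)
    hits = []
    for start in range(fwd.size):
        if fwd[start] >= cutoff:
            hits.append(
                SiteHit(seq_id, start, "+", float(fwd[start]), pwm.motif_id, L)
            )
        if rev[start] >= cutoff:
            hits.append(
                SiteHit(seq_id, start, "-", float(rev[start]), pwm.motif_id, L)
            )
    return hits


def _discretize(weights: np.ndarray, delta: float) -> np.ndarray:
    clipped = np.clip(weights, _WEIGHT_FLOOR, None)
    return np.rint(clipped / delta).astype(np.int64)


def score_distribution(
    pwm: PWM,
    bg: Background | None = None,
    delta: float = SCORE_DELTA,
) -> tuple[int, np.ndarray]:
    """Exact distribution of the per-site score of a random background site,
    on a lattice of step ``delta``.

    Returns ``(lo, probs)`` where ``probs[i]`` is the probability of the
    discretized score ``(lo + i) * delta``.
    """
    if bg is None:
        bg = pwm.background
    q = bg.freqs
    bins = _discretize(pwm.weights, delta)
    lo = 0
    probs = np.array([1.0])
    for j in range(len(pwm)):
        kb = bins[j]
        k_min, k_max = int(kb.min()), int(kb.max())
        new = np.zeros(probs.size + (k_max - k_min))
        for b in range(4):
            off = int(kb[b]) - k_min
            new[off : off + probs.size] += q[b] * probs
        probs = new
        lo += k_min
    return lo, probs


def default_cutoff(
    pwm: PWM,
    bg: Background | None = None,
    p_site: float = DEFAULT_P_SITE,
    delta: float = SCORE_DELTA,
) -> float:
    """Smallest lattice score whose background tail probability is <= p_site.

    Computed by exact dynamic programming over the discretized per-column
    score distributions.  ``p_site >= 1`` returns the minimum attainable
    (discretized) score.
    """
    if not 0 < p_site:
        raise ValueError("p_site must be positive")
    lo, probs = score_distribution(pwm, bg, delta)
    tail = np.cumsum(probs[::-1])[::-1]
    idx = int(np.searchsorted(-tail, -p_site))  # first index with tail <= p_site
    if idx >= probs.size:
        # even the maximum score is more probable than p_site: cutoff just
        # above the top of the lattice, so nothing passes
        return (lo + probs.size) * delta
    # snap up to the nearest attainable score; the tail is unchanged because
    # no probability mass lies in between
    while probs[idx] == 0.0:
        idx += 1
    return (lo + idx) * delta
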
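"""Module detection from clustered binding sites.

Per promoter: count how many predicted sites cover each position, convert
the counts to per-sequence Z scores, call peak positions at Z >= 3.09
(upper-tail p = 0.001), then grow each peak in both directions while the
next positive-Z position is less than 30 bp beyond the current boundary.
Peaks swallowed by an earlier extension do not seed modules of their own;
overlapping modules are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import CoordinateError
from .pwm_core import (
    DEFAULT_P_SITE,
    PWM,
    Background,
    SiteHit,
    default_cutoff,
    scan_sequence,
)

#: peak threshold: upper-tail standard normal deviate for p = 0.001
Z_MIN = 3.09

#: extension reach in bp (the longest motif length); strictly less-than
MAX_GAP = 30


def zscore_for_pvalue(p: float) -> float:
    """Upper-tail standard normal deviate with tail probability ``p``."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(norm.isf(p))


@dataclass(frozen=True)
class DensityProfile:
    """Per-position site coverage with per-sequence mean/sd and Z scores."""

    seq_id: str
    counts: np.ndarray
    mean: float
    sd: float
    z: np.ndarray

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class CRMPrediction:
    """A predicted module: a half-open interval seeded by >= 1 peak."""

    seq_id: str
    start: int
    end: int
    peak_z: float
    seed_peaks: tuple[int, ...] = ()
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("module end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def site_density(hits: list[SiteHit], seq_len: int) -> np.ndarray:
    """Coverage counts: counts[i] = number of hits whose interval covers i."""
    counts = np.zeros(seq_len, dtype=float)
    # difference-array accumulation, O(hits + seq_len)
    diff = np.zeros(seq_len + 1)
    for h in hits:
        if h.start < 0 or h.end > seq_len:
            raise CoordinateError(
                f"hit [{h.start}, {h.end}) outside sequence of length {seq_len}"
            )
        diff[h.start] += 1
        diff[h.end] -= 1
    counts += np.cumsum(diff[:-1])
    return counts


def zscore_profile(counts: np.ndarray, seq_id: str = "") -> DensityProfile:
    """Per-sequence Z transform with the population SD.

    A flat profile (sd = 0) has all Z set to 0: no local enrichment.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty count vector")
    mean = float(c.mean())
    sd = float(c.std())  # population formula, ddof=0
    z = (c - mean) / sd if sd > 0 else np.zeros_like(c)
    return DensityProfile(seq_id=seq_id, counts=c, mean=mean, sd=sd, z=z)


def find_peaks(profile: DensityProfile, z_min: float = Z_MIN) -> list[int]:
    """All positions with z >= z_min (inclusive), ascending."""
    return [int(i) for i in np.flatnonzero(profile.z >= z_min)]


def _grow(peak: int, positive: np.ndarray, max_gap: int) -> tuple[int, int]:
    """Extend from a peak over positive-Z positions with gaps < max_gap.

    ``positive`` is the sorted array of positions with z > 0.  Returns the
    inclusive [left, right] boundaries reached.
    """
    idx = int(np.searchsorted(positive, peak))
    # rightward: jump to the next positive position while it is < max_gap
    # beyond the current boundary
    right_idx = idx
    while (
        right_idx + 1 < positive.size
        and positive[right_idx + 1] - positive[right_idx] < max_gap
    ):
        right_idx += 1
    left_idx = idx
    while left_idx - 1 >= 0 and positive[left_idx] - positive[left_idx - 1] < max_gap:
        left_idx -= 1
    return int(positive[left_idx]), int(positive[right_idx])


def extend_peaks(
    profile: DensityProfile,
    peaks: list[int],
    max_gap: int = MAX_GAP,
) -> list[CRMPrediction]:
    """Grow peaks into modules.

    Peaks are processed by descending Z (ties by ascending coordinate); a
    peak that falls inside an already-grown module is consumed and seeds
    nothing.  Overlapping modules are merged afterwards.
    """
    if not peaks:
        return []
    z = profile.z
    positive = np.flatnonzero(z > 0)
    order = sorted(peaks, key=lambda p: (-z[p], p))
    raw: list[tuple[int, int, list[int]]] = []  # inclusive [left, right], seeds
    for peak in order:
        if any(left <= peak <= right for left, right, _ in raw):
            continue
        left, right = _grow(peak, positive, max_gap)
        raw.append((left, right, [peak]))
    raw.sort()
    merged: list[list] = []
    for left, right, seeds in raw:
        if merged and left <= merged[-1][1]:  # inclusive intervals overlap
            merged[-1][1] = max(merged[-1][1], right)
            merged[-1][2].extend(seeds)
        else:
            merged.append([left, right, list(seeds)])
    out = []
    for left, right, seeds in merged:
        out.append(
            CRMPrediction(
                seq_id=profile.seq_id,
                start=left,
                end=right + 1,
                peak_z=float(z[left : right + 1].max()),
                seed_peaks=tuple(sorted(seeds)),
            )
        )
    return out


def predict_modules(
    seqs: dict[str, str],
    pwms: list[PWM],
    bg: Background | None = None,
    p_site: float = DEFAULT_P_SITE,
    z_min: float = Z_MIN,
    max_gap: int = MAX_GAP,
) -> list[CRMPrediction]:
    """Full per-sequence pipeline: scan -> density -> Z -> peaks -> extend.

    PWMs without a stored cutoff get the exact-DP default at ``p_site``.
    Output is sorted by (seq_id, start, end).
    """
    if not seqs:
        raise ValueError("no sequences given")
    resolved = []
    for pwm in pwms:
        if pwm.cutoff is None:
            pwm = pwm.with_cutoff(default_cutoff(pwm, bg, p_site))
        resolved.append(pwm)
    out: list[CRMPrediction] = []
    for seq_id in sorted(seqs):
        seq = seqs[seq_id]
        hits: list[SiteHit] = []
        for pwm in resolved:
            hits.extend(scan_sequence(pwm, seq, seq_id=seq_id))
        counts = site_density(hits, len(seq))
        profile = zscore_profile(counts, seq_id=seq_id)
        peaks = find_peaks(profile, z_min)
        modules = extend_peaks(profile, peaks, max_gap)
        for mod in modules:
            motif_ids = sorted(
                {h.motif_id for h in hits if h.start < mod.end and h.end > mod.start}
            )
            out.append(
                CRMPrediction(
                    seq_id=mod.seq_id,
                    start=mod.start,
                    end=mod.end,
                    peak_z=mod.peak_z,
                    seed_peaks=mod.seed_peaks,
                    motif_ids=tuple(motif_ids),
                )
            )
    out.sort(key=lambda m: (m.seq_id, m.start, m.end))
    return out
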
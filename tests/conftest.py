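"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results with naive Python loops and
enumeration so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from crmkit import pwm_core, synth
from crmkit.pwm_core import Background, CountMatrix, counts_to_pwm

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_score(weights, site: str, bg_freqs) -> float:
    """Plain-Python per-column scoring; N gets the background expectation."""
    total = 0.0
    for j, ch in enumerate(site):
        if ch == "N":
            total += sum(bg_freqs[b] * weights[j][b] for b in range(4))
        else:
            total += weights[j]["ACGT".index(ch)]
    return total


def naive_scan(pwm, seq: str, cutoff: float):
    """Double-loop scanner over both strands; returns (start, strand, score)."""
    L = len(pwm)
    w = pwm.weights.tolist()
    q = pwm.background.freqs.tolist()
    out = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        s_fwd = naive_score(w, window, q)
        if s_fwd >= cutoff:
            out.append((start, "+", s_fwd))
        s_rev = naive_score(w, revcomp(window), q)
        if s_rev >= cutoff:
            out.append((start, "-", s_rev))
    return out


def naive_density(intervals, seq_len: int):
    """Interval-stabbing count per position."""
    counts = [0] * seq_len
    for start, end in intervals:
        for i in range(seq_len):
            if start <= i < end:
                counts[i] += 1
    return counts


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for kk in range(k, min(K, n) + 1):
        if n - kk <= N - K:
            total += comb(K, kk) * comb(N - K, n - kk)
    return total / denom


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing point probabilities <= the observed one."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def point(aa):
        return comb(r1, aa) * comb(r2, c1 - aa) / comb(N, c1)

    p_obs = point(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point(aa)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def worm_bg():
    return Background.from_gc(0.36)


@pytest.fixture(scope="session")
def strong_pwm(worm_bg):
    cm = synth.strong_count_matrix(seed=0)
    return counts_to_pwm(cm, worm_bg)


@pytest.fixture(scope="session")
def planted_fixture(worm_bg, strong_pwm):
    """20 planted 2-kb promoters plus 60 unplanted controls, fixed seeds."""
    seqs = synth.gen_promoters(20, 2000, 0.36, seed=1)
    planted, truth = synth.plant_sites(seqs, strong_pwm, 12, (900, 1050), seed=2)
    controls = synth.gen_promoters(60, 2000, 0.36, seed=9, prefix="ctrl")
    return planted, truth, controls


def random_count_matrix(rng, length=None, max_count=20, motif_id="m"):
    if length is None:
        length = int(rng.integers(5, 9))
    counts = rng.integers(0, max_count, size=(length, 4)).astype(float) + 1.0
    return CountMatrix(motif_id, counts, check_length=False)


def random_pwm(rng, bg, length=None, motif_id="m"):
    return pwm_core.counts_to_pwm(random_count_matrix(rng, length, motif_id=motif_id), bg)


def random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
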
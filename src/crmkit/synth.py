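"""Seeded synthetic-data generators with recorded planted truth.

Every generator is a pure function of its parameters and an explicit seed,
so pipelines can be tested end to end without any external data: random
promoters with a chosen GC content, motif sites sampled from a PWM's
column distributions and planted into a window, expression matrices with
planted coherent clusters, and assay vectors with a target correlation to
an occupancy vector.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .association import AssayVector, ExpressionMatrix, OccupancyVector
from .genome_prep import reverse_complement
from .pwm_core import ALPHABET, PWM, Background

_BASES = np.array(list(ALPHABET))


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    start: int
    strand: str
    motif_id: str
    site_seq: str


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside generated fixtures."""

    sites: list[PlantedSite] = field(default_factory=list)
    windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "sites": [asdict(s) for s in self.sites],
            "windows": {k: list(v) for k, v in self.windows.items()},
            "clusters": self.clusters,
            "effects": self.effects,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        return cls(
            sites=[PlantedSite(**s) for s in payload["sites"]],
            windows={k: tuple(v) for k, v in payload["windows"].items()},
            clusters=payload["clusters"],
            effects=payload["effects"],
        )


def strong_count_matrix(
    length: int = 10,
    dominant_count: float = 37.0,
    other_count: float = 1.0,
    seed: int = 0,
    motif_id: str = "planted1",
) -> "CountMatrix":
    """A high-information count matrix with one dominant base per column."""
    from .pwm_core import CountMatrix

    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    counts = np.full((length, 4), float(other_count))
    counts[np.arange(length), consensus] = float(dominant_count)
    return CountMatrix(motif_id, counts, check_length=False)


def gen_promoters(
    n: int,
    length: int,
    gc: float = 0.36,
    seed: int = 0,
    prefix: str = "promoter",
) -> dict[str, str]:
    """i.i.d. random sequences with P(G) + P(C) = gc, reproducible per seed."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    bg = Background.from_gc(gc)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(max(n, 1))))
    seqs = {}
    for i in range(n):
        draw = rng.choice(4, size=length, p=bg.freqs)
        seqs[f"{prefix}{i + 1:0{width}d}"] = "".join(_BASES[draw])
    return seqs


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """One site drawn from the PWM's per-column probability model.

    Column probabilities are recovered from the log-odds weights as
    q_b * e^(w_bj), renormalized for discretization slack.
    """
    probs = pwm.background.freqs * np.exp(pwm.weights)
    probs = probs / probs.sum(axis=1, keepdims=True)
    draws = [rng.choice(4, p=probs[j]) for j in range(len(pwm))]
    return "".join(_BASES[draws])


def _spaced_starts(
    count: int, window: tuple[int, int], site_len: int, rng: np.random.Generator
) -> list[int]:
    """Uniformly random non-overlapping starts inside the window."""
    w_start, w_end = window
    slack = (w_end - w_start) - count * site_len
    if count > 0 and slack < 0:
        raise ValueError(
            f"window of {w_end - w_start} bp cannot fit {count} "
            f"non-overlapping sites of length {site_len}"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=count))
    return [int(w_start + off + i * site_len) for i, off in enumerate(offsets)]


def plant_sites(
    seqs: dict[str, str],
    pwm: PWM,
    count_per_window: int,
    window: tuple[int, int],
    seed: int = 0,
    random_strand: bool = True,
) -> tuple[dict[str, str], PlantedTruth]:
    """Write sampled sites into a window of every sequence.

    Exactly ``count_per_window`` non-overlapping sites per sequence; the
    truth records each planted position, strand and site sequence.
    """
    w_start, w_end = window
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    out = {}
    for seq_id in sorted(seqs):
        seq = seqs[seq_id]
        if not 0 <= w_start < w_end <= len(seq):
            raise ValueError(
                f"window {window} does not fit sequence {seq_id!r} "
                f"of length {len(seq)}"
            )
        chars = list(seq)
        starts = _spaced_starts(count_per_window, window, len(pwm), rng)
        for start in starts:
            site = sample_site(pwm, rng)
            strand = "+"
            written = site
            if random_strand and rng.random() < 0.5:
                strand = "-"
                written = reverse_complement(site)
            chars[start : start + len(pwm)] = written
            truth.sites.append(
                PlantedSite(
                    seq_id=seq_id,
                    start=start,
                    strand=strand,
                    motif_id=pwm.motif_id,
                    site_seq=site,
                )
            )
        if count_per_window > 0:
            truth.windows[seq_id] = (w_start, w_end)
        out[seq_id] = "".join(chars)
    return out, truth


def gen_expression(
    clusters: list[set],
    n_conditions: int,
    within_sd: float,
    between_sd: float,
    seed: int = 0,
    n_background: int = 0,
    gene_prefix: str = "gene",
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with planted coherent clusters.

    Members of a cluster share a base profile (spread ``between_sd``)
    perturbed by ``within_sd`` noise; background genes are independent
    draws with spread ``between_sd``.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    truth = PlantedTruth()
    for ci, genes in enumerate(clusters):
        base = rng.normal(0.0, between_sd, size=n_conditions)
        members = sorted(genes)
        truth.clusters[f"cluster{ci + 1}"] = members
        for g in members:
            rows[g] = base + rng.normal(0.0, within_sd, size=n_conditions)
    for i in range(n_background):
        g = f"{gene_prefix}{i + 1:05d}"
        if g not in rows:
            rows[g] = rng.normal(0.0, between_sd, size=n_conditions)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"cond{j + 1}" for j in range(n_conditions)]
    return ExpressionMatrix(df), truth


def gen_assay(
    occ: OccupancyVector,
    r_target: float,
    seed: int = 0,
    sample_id: str | None = None,
) -> AssayVector:
    """Assay vector with population correlation ``r_target`` to ``occ``."""
    if not abs(r_target) < 1:
        raise ValueError("|r_target| must be < 1")
    rng = np.random.default_rng(seed)
    x = occ.values.to_numpy(dtype=float)
    z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    noise = rng.standard_normal(x.size)
    vals = r_target * z + np.sqrt(1 - r_target**2) * noise
    if sample_id is None:
        sample_id = f"assay_{occ.motif_id}"
    return AssayVector(
        sample_id=sample_id, values=pd.Series(vals, index=occ.values.index)
    )
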
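"""Scoring predicted modules against experimentally defined regions.

Sensitivity counts an experimental region as hit when any prediction on the
same promoter overlaps it by >= 1 bp.  PPV counts a prediction as true
either by the same any-overlap rule (default) or by requiring a fraction of
its length to fall inside experimental regions.  Significance of the
observed metrics is assessed by re-placing each predicted module uniformly
at random within its promoter, preserving per-gene module lengths and
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reporting
from .errors import CoordinateError

#: predicted-module length range used when restricting experimental
#: regions to comparable sizes (inclusive)
SIZE_LO = 27
SIZE_HI = 580

PPV_ANY_OVERLAP = "any_overlap"
PPV_CONTAINMENT = "containment_frac"


@dataclass(frozen=True)
class ExperimentalModule:
    """A literature-curated regulatory interval on a promoter."""

    gene_id: str
    start: int
    end: int
    evidence: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("module end must exceed start")
        if self.start < 0:
            raise CoordinateError("module start must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EvalResult:
    n_exp: int
    n_exp_hit: int
    n_pred: int
    n_pred_true: int

    @classmethod
    def from_counts(
        cls, n_exp: int, n_exp_hit: int, n_pred: int = 0, n_pred_true: int = 0
    ) -> "EvalResult":
        return cls(n_exp, n_exp_hit, n_pred, n_pred_true)

    @property
    def sensitivity(self) -> float:
        return self.n_exp_hit / self.n_exp if self.n_exp else float("nan")

    @property
    def ppv(self) -> float | None:
        """None when there are no predictions (undefined)."""
        if self.n_pred == 0:
            return None
        return self.n_pred_true / self.n_pred

    def sensitivity_percent(self, decimals: int = 1) -> float:
        return reporting.percent(self.n_exp_hit, self.n_exp, decimals)

    def ppv_percent(self, decimals: int = 1) -> float | None:
        if self.n_pred == 0:
            return None
        return reporting.percent(self.n_pred_true, self.n_pred, decimals)

    def as_dict(self) -> dict:
        return {
            "n_exp": self.n_exp,
            "n_exp_hit": self.n_exp_hit,
            "n_pred": self.n_pred,
            "n_pred_true": self.n_pred_true,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "sensitivity_percent": self.sensitivity_percent(),
            "ppv_percent": self.ppv_percent(),
        }


@dataclass(frozen=True)
class SimulationResult:
    mean_sensitivity: float
    sd_sensitivity: float
    mean_ppv: float
    sd_ppv: float
    p_sensitivity: float
    p_ppv: float
    observed: EvalResult
    n_reps: int


def _interval_id(obj) -> str:
    for attr in ("seq_id", "gene_id", "chrom"):
        if hasattr(obj, attr):
            return getattr(obj, attr)
    raise AttributeError(f"{obj!r} has no sequence identifier attribute")


def _group(intervals) -> dict[str, list[tuple[int, int]]]:
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(_interval_id(iv), []).append((iv.start, iv.end))
    return grouped


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def evaluate(
    pred,
    exp,
    ppv_rule: str = PPV_ANY_OVERLAP,
    containment_frac: float = 0.5,
) -> EvalResult:
    """Score predictions against experimental modules grouped per promoter.

    ``pred`` and ``exp`` are iterables of objects carrying an identifier
    attribute (seq_id/gene_id/chrom) plus half-open start/end.
    """
    if ppv_rule not in (PPV_ANY_OVERLAP, PPV_CONTAINMENT):
        raise ValueError(f"unknown ppv_rule {ppv_rule!r}")
    pred_by = _group(pred)
    exp_by = _group(exp)
    n_exp = sum(len(v) for v in exp_by.values())
    n_pred = sum(len(v) for v in pred_by.values())
    n_exp_hit = 0
    for gid, exp_ivs in exp_by.items():
        preds = pred_by.get(gid, [])
        for e in exp_ivs:
            if any(_overlap_len(e, p) > 0 for p in preds):
                n_exp_hit += 1
    n_pred_true = 0
    for gid, pred_ivs in pred_by.items():
        exps = exp_by.get(gid, [])
        union = _union(exps)
        for p in pred_ivs:
            if ppv_rule == PPV_ANY_OVERLAP:
                ok = any(_overlap_len(p, e) > 0 for e in exps)
            else:
                inside = sum(_overlap_len(p, u) for u in union)
                ok = inside >= containment_frac * (p[1] - p[0])
            if ok:
                n_pred_true += 1
    return EvalResult(n_exp, n_exp_hit, n_pred, n_pred_true)


def size_filter(
    exp: list[ExperimentalModule],
    lo: int = SIZE_LO,
    hi: int = SIZE_HI,
) -> list[ExperimentalModule]:
    """Keep modules with lo <= length <= hi (inclusive on both ends)."""
    return [m for m in exp if lo <= m.length <= hi]


def placement_simulation(
    pred,
    exp,
    promoter_lens: dict[str, int],
    n_reps: int = 10000,
    seed: int = 0,
    ppv_rule: str = PPV_ANY_OVERLAP,
    containment_frac: float = 0.5,
) -> SimulationResult:
    """Random re-placement null for the evaluation metrics.

    Each rep re-draws every predicted module's start uniformly within its
    promoter, keeping per-gene module lengths and counts; modules may
    overlap each other.  Empirical p-values are the smoothed fraction of
    reps whose metric is >= the observed one.
    """
    observed = evaluate(pred, exp, ppv_rule, containment_frac)
    pred_by = _group(pred)
    exp_by = _group(exp)
    for gid, ivs in pred_by.items():
        if gid not in promoter_lens:
            raise KeyError(f"no promoter length for {gid!r}")
        for s, e in ivs:
            if e - s > promoter_lens[gid]:
                raise CoordinateError(
                    f"module of length {e - s} exceeds promoter {gid!r} "
                    f"({promoter_lens[gid]} bp)"
                )
    rng = np.random.default_rng(seed)
    n_exp = observed.n_exp
    n_pred = observed.n_pred
    sens = np.zeros(n_reps)
    ppv = np.zeros(n_reps)
    # per gene: module lengths, exp intervals, exp union
    per_gene = []
    for gid, ivs in sorted(pred_by.items()):
        lens = np.array([e - s for s, e in ivs])
        exps = exp_by.get(gid, [])
        per_gene.append((gid, lens, exps, _union(exps), promoter_lens[gid]))
    # genes with experimental modules but no predictions can never be hit,
    # in reps or in the observed evaluation alike
    for rep in range(n_reps):
        hit = 0
        true = 0
        for gid, lens, exps, union, plen in per_gene:
            starts = rng.integers(0, plen - lens + 1)
            ends = starts + lens
            for es, ee in exps:
                if np.any((starts < ee) & (ends > es)):
                    hit += 1
            if ppv_rule == PPV_ANY_OVERLAP:
                for ps, pe in zip(starts, ends):
                    if any(min(pe, ee) - max(ps, es) > 0 for es, ee in exps):
                        true += 1
            else:
                for ps, pe in zip(starts, ends):
                    inside = sum(
                        max(0, min(pe, ue) - max(ps, us)) for us, ue in union
                    )
                    if inside >= containment_frac * (pe - ps):
                        true += 1
        sens[rep] = hit / n_exp if n_exp else np.nan
        ppv[rep] = true / n_pred if n_pred else np.nan
    obs_sens = observed.sensitivity
    obs_ppv = observed.ppv if observed.ppv is not None else np.nan
    p_sens = (np.sum(sens >= obs_sens) + 1) / (n_reps + 1)
    p_ppv = (np.sum(ppv >= obs_ppv) + 1) / (n_reps + 1)
    return SimulationResult(
        mean_sensitivity=float(np.mean(sens)),
        sd_sensitivity=float(np.std(sens)),
        mean_ppv=float(np.mean(ppv)),
        sd_ppv=float(np.std(ppv)),
        p_sensitivity=float(p_sens),
        p_ppv=float(p_ppv),
        observed=observed,
        n_reps=n_reps,
    )
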
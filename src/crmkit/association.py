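"""Motif-phenotype association statistics.

Occupancy of a promoter by a PWM is the sum of exponentiated per-placement
scores over every position on both strands, with no cutoff; it is defined
up to an arbitrary proportionality constant, so only correlations against
assay vectors are interpreted.  Enrichment of motif-associated gene sets
uses the upper-tail hypergeometric distribution (with child-term
propagation for the annotation hierarchy) and the two-sided Fisher exact
test for flat categories.  Expression coherence of a gene cluster is the
fraction of within-cluster profile pairs closer than a genome-calibrated
threshold distance, with a Monte-Carlo p-value from equal-size random sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

from .pwm_core import PWM, score_positions

#: screening threshold on the correlation t statistic used in location
#: analysis (corresponds to corrected p < 0.01 at genome scale)
T_SCREEN = 6.02


@dataclass(frozen=True)
class OccupancyVector:
    """Unnormalized per-promoter occupancy scores for one motif."""

    motif_id: str
    values: pd.Series

    def __post_init__(self):
        object.__setattr__(self, "values", pd.Series(self.values, dtype=float))


@dataclass(frozen=True)
class AssayVector:
    """Per-gene measurements for one sample (ChIP signal, expression, ...)."""

    sample_id: str
    values: pd.Series

    def __post_init__(self):
        v = pd.Series(self.values, dtype=float)
        if np.any(~np.isfinite(v.dropna().to_numpy())):
            raise ValueError("assay values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GeneCluster:
    """A motif-associated gene set."""

    motif_id: str
    gene_ids: frozenset
    min_size: int = field(default=3, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if len(self.gene_ids) < self.min_size:
            raise ValueError(
                f"cluster {self.motif_id!r} has {len(self.gene_ids)} genes, "
                f"below the minimum of {self.min_size}"
            )


@dataclass
class AnnotationMap:
    """Term -> gene assignments plus directed parent -> children edges."""

    direct: dict[str, set]
    children: dict[str, set]

    def propagated(self) -> dict[str, set]:
        """Each term's genes unioned with all descendants' genes.

        Raises on a cyclic hierarchy.
        """
        memo: dict[str, set] = {}
        in_progress: set = set()
        terms = set(self.direct) | set(self.children)

        def visit(term: str) -> set:
            if term in memo:
                return memo[term]
            if term in in_progress:
                raise ValueError(f"annotation hierarchy has a cycle at {term!r}")
            in_progress.add(term)
            genes = set(self.direct.get(term, ()))
            for child in self.children.get(term, ()):
                genes |= visit(child)
            in_progress.discard(term)
            memo[term] = genes
            return genes

        for t in terms:
            visit(t)
        return memo


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x conditions expression values; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).astype(float)
        if df.shape[1] < 2:
            raise ValueError("need >= 2 conditions")
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        object.__setattr__(self, "data", df)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    p: float
    n: int


def occupancy(seq: str, pwm: PWM) -> float:
    """Sum of e^score over every placement on both strands, no cutoff."""
    fwd, rev = score_positions(pwm, seq)
    if fwd.size == 0:
        warnings.warn(
            f"sequence shorter than motif {pwm.motif_id!r}; occupancy = 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.exp(fwd).sum() + np.exp(rev).sum())


def occupancy_vector(seqs: Mapping[str, str], pwm: PWM) -> OccupancyVector:
    vals = {sid: occupancy(seq, pwm) for sid, seq in seqs.items()}
    return OccupancyVector(motif_id=pwm.motif_id, values=pd.Series(vals))


def correlate(occ: OccupancyVector, assay: AssayVector) -> CorrelationResult:
    """Pearson correlation on the shared genes with its t statistic.

    t = r * sqrt(n - 2) / sqrt(1 - r^2); two-sided p from Student's t with
    n - 2 df.  |r| = 1 reports t = +/-inf and p = 0.
    """
    joined = pd.concat([occ.values, assay.values], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need >= 3")
    x = joined.iloc[:, 0].to_numpy()
    y = joined.iloc[:, 1].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        t = float(np.sign(r) * np.inf)
        return CorrelationResult(r=float(np.sign(r)), t=t, p=0.0, n=n)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, t=float(t), p=float(p), n=n)


class CoherenceAnalyzer:
    """Precomputed pairwise-distance machinery for expression coherence.

    The threshold distance D is the ``pair_quantile`` quantile of the
    Euclidean distances over all gene pairs of the matrix (missing values
    dropped pairwise with rescaling).  The coherence of a gene set is the
    fraction of its pairs at distance <= D.
    """

    def __init__(self, expr: ExpressionMatrix, pair_quantile: float = 0.05):
        if not 0 < pair_quantile < 1:
            raise ValueError("pair_quantile must be in (0, 1)")
        self.expr = expr
        self.genes = np.array(expr.genes)
        self._index = {g: i for i, g in enumerate(self.genes)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self._dist = nan_euclidean_distances(expr.data.to_numpy())
        iu = np.triu_indices(len(self.genes), k=1)
        self.threshold = float(np.nanquantile(self._dist[iu], pair_quantile))

    def coherence(self, gene_ids: Iterable[str]) -> float:
        idx = np.array([self._index[g] for g in gene_ids])
        if idx.size < 2:
            raise ValueError("coherence needs >= 2 genes present in the matrix")
        sub = self._dist[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        pair_d = sub[iu]
        ok = ~np.isnan(pair_d)
        if not ok.any():
            raise ValueError("no pair has shared conditions")
        return float((pair_d[ok] <= self.threshold).mean())

    def pvalue(
        self, gene_ids: Iterable[str], n_null: int, seed: int
    ) -> tuple[float, float]:
        """(EC, Monte-Carlo p) with (b+1)/(n_null+1) smoothing."""
        if n_null <= 0:
            raise ValueError("n_null must be positive")
        gene_ids = list(gene_ids)
        ec = self.coherence(gene_ids)
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_null):
            pick = rng.choice(len(self.genes), size=len(gene_ids), replace=False)
            if self.coherence(self.genes[pick]) >= ec:
                b += 1
        return ec, (b + 1) / (n_null + 1)


def expression_coherence(
    cluster: GeneCluster,
    expr: ExpressionMatrix,
    pair_quantile: float = 0.05,
    n_null: int = 99,
    seed: int = 0,
) -> tuple[float, float]:
    """Expression coherence of a gene cluster and its Monte-Carlo p-value.

    See :class:`CoherenceAnalyzer` for the construction.  Cluster genes not
    present in the matrix are ignored; fewer than 2 usable genes is an
    error.
    """
    present = [g for g in sorted(cluster.gene_ids) if g in set(expr.genes)]
    if len(present) < 2:
        raise ValueError("cluster shares fewer than 2 genes with the matrix")
    analyzer = CoherenceAnalyzer(expr, pair_quantile)
    return analyzer.pvalue(present, n_null=n_null, seed=seed)


def hypergeom_enrichment(
    cluster: GeneCluster,
    ann: AnnotationMap,
    universe: set,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per propagated term.

    For each term with propagated gene set of size K (within the universe
    of size N), cluster size n and overlap k, p = P(X >= k).  Returns a
    DataFrame indexed by term with columns term_size, overlap, p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster_genes = set(cluster.gene_ids)
    if not cluster_genes <= universe:
        raise ValueError("cluster is not a subset of the universe")
    n = len(cluster_genes)
    big_n = len(universe)
    rows = {}
    for term, genes in sorted(ann.propagated().items()):
        term_genes = genes & universe
        big_k = len(term_genes)
        k = len(term_genes & cluster_genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows[term] = {"term_size": big_k, "overlap": k, "p": min(p, 1.0)}
    return pd.DataFrame.from_dict(rows, orient="index")


def fisher_enrichment(
    cluster: GeneCluster,
    category: set,
    universe: set,
) -> tuple[float, float]:
    """Two-sided Fisher exact test of cluster x category membership.

    Returns (odds_ratio, p); the odds ratio uses the Haldane 0.5 correction
    when any cell of the 2x2 table is zero, the p-value uses the raw table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster_genes = set(cluster.gene_ids)
    category = set(category)
    if not cluster_genes <= universe or not category <= universe:
        raise ValueError("cluster and category must be subsets of the universe")
    k = len(cluster_genes & category)
    table = np.array(
        [
            [k, len(cluster_genes) - k],
            [len(category) - k, len(universe) - len(cluster_genes) - len(category) + k],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if np.any(table == 0):
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return odds, float(p)


def multitest_correct(pvals: Iterable[float], method: str = "bonferroni") -> list[float]:
    """Bonferroni correction: min(1, m * p) per test."""
    pvals = list(pvals)
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    for p in pvals:
        if not 0 <= p <= 1:
            raise ValueError("p-values must be in [0, 1]")
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]
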
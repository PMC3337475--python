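import math

import numpy as np
import pandas as pd
import pytest

from crmkit import association as assoc
from crmkit import pwm_core as pc

from conftest import hypergeom_tail_enum, fisher_two_sided_enum, random_pwm, random_seq


class TestOccupancy:
    def test_all_zero_pwm_minimal_sequence(self, uniform_bg):
        pwm = pc.PWM("z", np.zeros((4, 4)), uniform_bg)
        # one placement x two strands x e^0
        assert assoc.occupancy("ACGT", pwm) == pytest.approx(2.0)

    def test_too_short_warns_and_zero(self, uniform_bg):
        pwm = pc.PWM("z", np.zeros((4, 4)), uniform_bg)
        with pytest.warns(UserWarning):
            assert assoc.occupancy("AC", pwm) == 0.0

    def test_brute_force_small(self, uniform_bg):
        from conftest import naive_score, revcomp

        rng = np.random.default_rng(0)
        pwm = random_pwm(rng, uniform_bg, length=2)
        seq = random_seq(rng, 10)
        w = pwm.weights.tolist()
        q = uniform_bg.freqs.tolist()
        expected = 0.0
        for start in range(9):
            window = seq[start : start + 2]
            expected += math.exp(naive_score(w, window, q))
            expected += math.exp(naive_score(w, revcomp(window), q))
        assert assoc.occupancy(seq, pwm) == pytest.approx(expected)

    def test_appending_weak_bases_negligible(self, uniform_bg):
        # a PWM that rejects C and G in every column and on both strands:
        # every window crossing into appended C's scores << 0
        rng = np.random.default_rng(1)
        w = rng.normal(size=(6, 4))
        w[:, 1] = w[:, 2] = -40.0
        pwm = pc.PWM("at_only", w, uniform_bg)
        seq = "".join(rng.choice(list("AT"), size=200))
        base = assoc.occupancy(seq, pwm)
        grown = assoc.occupancy(seq + "CCCCC", pwm)
        assert abs(grown - base) / base < 1e-6

    def test_revcomp_invariance(self, uniform_bg):
        from conftest import revcomp

        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, uniform_bg, length=6)
        seq = random_seq(rng, 120)
        assert assoc.occupancy(seq, pwm) == pytest.approx(
            assoc.occupancy(revcomp(seq), pwm)
        )

    def test_inserting_strong_site_increases(self, worm_bg, strong_pwm):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 200)
        consensus = "".join("ACGT"[i] for i in strong_pwm.weights.argmax(axis=1))
        boosted = seq[:100] + consensus + seq[100 + len(consensus):]
        assert assoc.occupancy(boosted, strong_pwm) > assoc.occupancy(seq, strong_pwm)


class TestCorrelate:
    @staticmethod
    def _vectors(n, r, seed=0):
        """Vectors whose sample correlation is exactly r (Gram-Schmidt)."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = r * x + math.sqrt(1 - r * r) * z
        genes = [f"g{i}" for i in range(n)]
        return (
            assoc.OccupancyVector("m", pd.Series(x, index=genes)),
            assoc.AssayVector("a", pd.Series(y, index=genes)),
        )

    def test_zero_correlation_zero_t(self):
        occ, assay = self._vectors(30, 0.0)
        res = assoc.correlate(occ, assay)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.t == pytest.approx(0.0, abs=1e-10)

    def test_hand_arithmetic_t(self):
        occ, assay = self._vectors(20, 0.8)
        res = assoc.correlate(occ, assay)
        assert res.r == pytest.approx(0.8)
        assert res.t == pytest.approx(0.8 * math.sqrt(18) / math.sqrt(0.36))
        assert res.t == pytest.approx(5.6569, abs=1e-4)

    def test_affine_transform_sentinel(self):
        genes = [f"g{i}" for i in range(10)]
        x = pd.Series(np.arange(10.0), index=genes)
        occ = assoc.OccupancyVector("m", x)
        assay = assoc.AssayVector("a", 3.0 * x + 2.0)
        res = assoc.correlate(occ, assay)
        assert res.r == 1.0
        assert res.t == math.inf
        assert res.p == 0.0

    def test_too_few_shared_genes(self):
        occ = assoc.OccupancyVector("m", pd.Series([1.0, 2.0], index=["a", "b"]))
        assay = assoc.AssayVector("a", pd.Series([1.0, 2.0], index=["a", "b"]))
        with pytest.raises(ValueError):
            assoc.correlate(occ, assay)


class TestGeneCluster:
    def test_minimum_size(self):
        with pytest.raises(ValueError):
            assoc.GeneCluster("m", {"g1", "g2"})
        assoc.GeneCluster("m", {"g1", "g2", "g3"})


def _expr(values, genes=None):
    if genes is None:
        genes = [f"g{i}" for i in range(len(values))]
    return assoc.ExpressionMatrix(pd.DataFrame(values, index=genes))


class TestExpressionCoherence:
    def test_identical_profiles_full_coherence(self):
        rng = np.random.default_rng(0)
        others = rng.normal(0, 5, size=(40, 6))
        shared = np.tile(rng.normal(size=6), (5, 1))
        expr = _expr(np.vstack([shared, others]))
        cluster = assoc.GeneCluster("m", {f"g{i}" for i in range(5)})
        ec, p = assoc.expression_coherence(cluster, expr, n_null=49, seed=1)
        assert ec == 1.0
        assert p < 0.5

    def test_calibration_mean_ec_matches_quantile(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.standard_normal((120, 10)))
        analyzer = assoc.CoherenceAnalyzer(expr, pair_quantile=0.10)
        ecs = []
        for _ in range(300):
            pick = rng.choice(120, size=8, replace=False)
            ecs.append(analyzer.coherence(analyzer.genes[pick]))
        # random clusters' pairs are a random sample of all pairs
        assert np.mean(ecs) == pytest.approx(0.10, abs=0.02)

    def test_zero_null_errors(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.standard_normal((10, 4)))
        cluster = assoc.GeneCluster("m", {"g0", "g1", "g2"})
        with pytest.raises(ValueError):
            assoc.expression_coherence(cluster, expr, n_null=0)

    def test_singleton_overlap_errors(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.standard_normal((10, 4)))
        cluster = assoc.GeneCluster("m", {"g0", "x1", "x2"})
        with pytest.raises(ValueError):
            assoc.expression_coherence(cluster, expr)

    def test_missing_values_dropped_pairwise(self):
        vals = np.ones((6, 4))
        vals[0, 0] = np.nan
        expr = _expr(vals)
        analyzer = assoc.CoherenceAnalyzer(expr, pair_quantile=0.5)
        assert analyzer.coherence(["g0", "g1", "g2"]) == 1.0


class TestHypergeomEnrichment:
    def test_cluster_equals_universe(self):
        universe = {f"g{i}" for i in range(6)}
        ann = assoc.AnnotationMap(
            direct={"t1": {"g0", "g1"}, "t2": {"g2"}}, children={}
        )
        cluster = assoc.GeneCluster("m", universe)
        df = assoc.hypergeom_enrichment(cluster, ann, universe)
        assert np.allclose(df["p"], 1.0)

    def test_combinatorial_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term_genes = {f"g{i}" for i in range(5)}
        cluster_genes = {f"g{i}" for i in range(4)}
        ann = assoc.AnnotationMap(direct={"t": term_genes}, children={})
        cluster = assoc.GeneCluster("m", cluster_genes)
        df = assoc.hypergeom_enrichment(cluster, ann, universe)
        assert df.loc["t", "p"] == pytest.approx(5 / 210)

    def test_enumeration_oracle_random(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            N = int(rng.integers(5, 13))
            universe = {f"g{i}" for i in range(N)}
            term = set(rng.choice(sorted(universe), rng.integers(1, N), replace=False))
            n = int(rng.integers(3, N + 1))
            cluster_genes = set(rng.choice(sorted(universe), n, replace=False))
            ann = assoc.AnnotationMap(direct={"t": term}, children={})
            cluster = assoc.GeneCluster("m", cluster_genes)
            df = assoc.hypergeom_enrichment(cluster, ann, universe)
            k = len(term & cluster_genes)
            assert df.loc["t", "p"] == pytest.approx(
                hypergeom_tail_enum(N, len(term), n, k)
            )

    def test_propagation_superset(self):
        ann = assoc.AnnotationMap(
            direct={"parent": {"g0"}, "child": {"g1", "g2"}},
            children={"parent": {"child"}},
        )
        prop = ann.propagated()
        assert prop["child"] <= prop["parent"]
        assert prop["parent"] == {"g0", "g1", "g2"}

    def test_cycle_detection(self):
        ann = assoc.AnnotationMap(
            direct={}, children={"a": {"b"}, "b": {"a"}}
        )
        with pytest.raises(ValueError, match="cycle"):
            ann.propagated()

    def test_empty_universe(self):
        cluster = assoc.GeneCluster("m", {"a", "b", "c"}, min_size=3)
        ann = assoc.AnnotationMap(direct={}, children={})
        with pytest.raises(ValueError):
            assoc.hypergeom_enrichment(cluster, ann, set())


class TestFisherEnrichment:
    def test_table_3113_matches_enumeration(self):
        universe = {f"g{i}" for i in range(8)}
        cluster_genes = {"g0", "g1", "g2", "g3"}  # row 1: 3 in, 1 out
        category = {"g0", "g1", "g2", "g4"}
        cluster = assoc.GeneCluster("m", cluster_genes)
        odds, p = assoc.fisher_enrichment(cluster, category, universe)
        assert p == pytest.approx(fisher_two_sided_enum([[3, 1], [1, 3]]))

    def test_no_association_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        cluster_genes = {"g0", "g1", "g2", "g3"}
        category = {"g0", "g1", "g4", "g5"}  # perfectly proportional 2x2
        cluster = assoc.GeneCluster("m", cluster_genes)
        _, p = assoc.fisher_enrichment(cluster, category, universe)
        assert p == pytest.approx(1.0)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            N = int(rng.integers(8, 16))
            universe = {f"g{i}" for i in range(N)}
            cluster_genes = set(
                rng.choice(sorted(universe), rng.integers(3, N - 1), replace=False)
            )
            category = set(
                rng.choice(sorted(universe), rng.integers(1, N - 1), replace=False)
            )
            cluster = assoc.GeneCluster("m", cluster_genes)
            _, p = assoc.fisher_enrichment(cluster, category, universe)
            k = len(cluster_genes & category)
            table = [
                [k, len(cluster_genes) - k],
                [len(category) - k, N - len(cluster_genes) - len(category) + k],
            ]
            assert p == pytest.approx(fisher_two_sided_enum(table))

    def test_haldane_odds_with_zero_cell(self):
        universe = {f"g{i}" for i in range(6)}
        cluster_genes = {"g0", "g1", "g2"}
        category = {"g3", "g4"}  # overlap 0
        cluster = assoc.GeneCluster("m", cluster_genes)
        odds, _ = assoc.fisher_enrichment(cluster, category, universe)
        assert odds == pytest.approx((0.5 * 1.5) / (3.5 * 2.5))


class TestMultitestCorrect:
    def test_single_unchanged(self):
        assert assoc.multitest_correct([0.03]) == [0.03]

    def test_scaling(self):
        assert assoc.multitest_correct([0.01] * 50)[0] == pytest.approx(0.5)

    def test_capped_at_one(self):
        assert assoc.multitest_correct([0.5, 0.9])[1] == 1.0

    def test_monotone(self):
        raw = [0.001, 0.01, 0.2, 0.04]
        corr = assoc.multitest_correct(raw)
        assert [x for _, x in sorted(zip(raw, corr))] == sorted(corr)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            assoc.multitest_correct([1.5])
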
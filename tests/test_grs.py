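import numpy as np
import pandas as pd
import pytest

from ctmr.grs import (
    ExpressionPanel,
    GRSWeights,
    build_wgrs,
    enrichment_scan,
    hypergeometric_enrichment,
    read_gmt,
    twas_scan,
)
from ctmr.simulate import simulate_expression_panel


def panel_from_arrays(dosages, expression, covariates=None):
    n = len(dosages)
    ids = [f"S{i}" for i in range(n)]
    cov = covariates if covariates is not None else np.empty((n, 0))
    return ExpressionPanel(
        sample_ids=ids,
        dosages=pd.DataFrame(dosages, index=ids,
                             columns=[f"rs{j}" for j in range(dosages.shape[1])]),
        expression=pd.DataFrame(expression, index=ids,
                                columns=[f"g{j}" for j in range(expression.shape[1])]),
        covariates=pd.DataFrame(cov, index=ids,
                                columns=[f"c{j}" for j in range(cov.shape[1])]),
    )


class TestBuildWGRS:
    def test_hand_dot_products(self):
        dos = np.array([[2.0, 0.0], [0.0, 1.0], [1.0, 2.0]])
        panel = panel_from_arrays(dos, np.zeros((3, 1)))
        w = GRSWeights(["rs0", "rs1"], np.array([0.5, -0.2]))
        raw = build_wgrs(panel, w, standardize=False)
        assert np.allclose(raw, [1.0, -0.2, 0.1])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            GRSWeights(["rs0"], np.array([0.0]))

    def test_zero_variance_score_cannot_standardize(self):
        dos = np.ones((4, 1))
        panel = panel_from_arrays(dos, np.zeros((4, 1)))
        w = GRSWeights(["rs0"], np.array([1.0]))
        with pytest.raises(ValueError, match="zero variance"):
            build_wgrs(panel, w, standardize=True)

    def test_missing_weight_snp_rejected(self):
        panel = panel_from_arrays(np.zeros((3, 1)), np.zeros((3, 1)))
        with pytest.raises(KeyError, match="rs9"):
            build_wgrs(panel, GRSWeights(["rs9"], np.array([1.0])), standardize=False)

    def test_linearity_in_weights(self, rng):
        dos = rng.integers(0, 3, size=(30, 4)).astype(float)
        panel = panel_from_arrays(dos, np.zeros((30, 1)))
        ids = [f"rs{j}" for j in range(4)]
        w1 = rng.normal(size=4)
        w2 = rng.normal(size=4)
        s1 = build_wgrs(panel, GRSWeights(ids, w1), standardize=False)
        s2 = build_wgrs(panel, GRSWeights(ids, w2), standardize=False)
        s12 = build_wgrs(panel, GRSWeights(ids, w1 + w2), standardize=False)
        assert np.allclose(s12, s1 + s2)

    def test_standardized_score_unit_sd(self, rng):
        dos = rng.integers(0, 3, size=(50, 3)).astype(float)
        panel = panel_from_arrays(dos, np.zeros((50, 1)))
        s = build_wgrs(panel, GRSWeights(["rs0", "rs1", "rs2"], np.ones(3)))
        assert s.mean() == pytest.approx(0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.0)

    def test_missing_dosages_mean_imputed(self):
        dos = pd.DataFrame(
            {"rs0": [0.0, np.nan, 2.0]}, index=["S0", "S1", "S2"]
        )
        panel = ExpressionPanel(
            ["S0", "S1", "S2"], dos,
            pd.DataFrame(np.zeros((3, 1)), index=["S0", "S1", "S2"]),
            pd.DataFrame(index=["S0", "S1", "S2"]),
        )
        assert panel.dosages["rs0"].tolist() == [0.0, 1.0, 2.0]


class TestTWASScan:
    def test_matches_statsmodels_single_gene(self, rng):
        import statsmodels.api as sm

        n = 120
        score = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        y = 0.3 * score + cov @ [0.2, -0.1] + rng.standard_normal(n)
        panel = panel_from_arrays(
            rng.integers(0, 3, (n, 1)).astype(float), y[:, None], cov
        )
        res = twas_scan(panel, score)
        design = sm.add_constant(np.column_stack([score, cov]))
        fit = sm.OLS(y, design).fit()
        assert res.table["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.table["se"].iloc[0] == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.table["pvalue"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_planted_effect_recovered_at_study_scale(self):
        recovered = 0
        reps = 40
        for seed in range(reps):
            panel, truth = simulate_expression_panel(
                n=445, n_snps=14, gene_effects=[-0.42], seed=seed
            )
            score = build_wgrs(
                panel, GRSWeights(list(panel.dosages.columns), truth["weights"])
            )
            res = twas_scan(panel, score)
            b, se = res.table["beta"].iloc[0], res.table["se"].iloc[0]
            recovered += abs(b - (-0.42)) < 2 * se
        assert recovered / reps >= 0.95

    def test_null_panel_pvalues_uniform(self):
        panel, _ = simulate_expression_panel(n=300, n_snps=8, gene_effects=np.zeros(800),
                                             seed=7)
        score = build_wgrs(panel, GRSWeights(list(panel.dosages.columns),
                                             np.ones(8)))
        res = twas_scan(panel, score)
        frac = (res.table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        from scipy import stats

        ks = stats.kstest(res.table["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_bonferroni_flag_matches_threshold(self, rng):
        panel, _ = simulate_expression_panel(n=200, n_snps=4,
                                             gene_effects=[0.6, 0.0], seed=3)
        score = build_wgrs(panel, GRSWeights(list(panel.dosages.columns),
                                             np.ones(4)))
        res = twas_scan(panel, score, alpha=0.05)
        expected = res.table["pvalue"] < 0.05 / res.n_genes
        assert (res.table["significant"] == expected).all()

    def test_collinear_covariates_named(self, rng):
        n = 50
        c1 = rng.standard_normal(n)
        cov = np.column_stack([c1, 2 * c1])
        panel = panel_from_arrays(
            rng.integers(0, 3, (n, 1)).astype(float),
            rng.standard_normal((n, 1)),
            cov,
        )
        with pytest.raises(ValueError, match="c1"):
            twas_scan(panel, rng.standard_normal(n))


class TestEnrichment:
    def test_exhaustive_tail_example(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2", "g10"}
        overlap, p = hypergeometric_enrichment(hits, gene_set, universe)
        assert overlap == 3
        assert p == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        overlap, p = hypergeometric_enrichment({"g9"}, {"g0", "g1"}, universe)
        assert (overlap, p) == (0, 1.0)

    def test_gene_set_equal_universe_degenerate(self):
        universe = {f"g{i}" for i in range(10)}
        hits = {"g1", "g2"}
        overlap, p = hypergeometric_enrichment(hits, universe, universe)
        assert overlap == len(hits)
        assert p == pytest.approx(1.0)

    def test_p_monotone_decreasing_in_overlap(self):
        universe = {f"g{i}" for i in range(30)}
        gene_set = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(7):
            hits = {f"g{i}" for i in range(k)} | {f"g{20 + i}" for i in range(6 - k)}
            _, p = hypergeometric_enrichment(hits, gene_set, universe)
            ps.append(p)
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_exhaustive_enumeration_small_universes(self, rng):
        """Match an explicit combinatorial tail sum on all |universe| <= 12 cases."""
        from math import comb

        for _ in range(50):
            m = int(rng.integers(2, 13))
            universe = {f"g{i}" for i in range(m)}
            k_set = int(rng.integers(1, m + 1))
            k_hits = int(rng.integers(1, m + 1))
            gene_set = set(rng.choice(sorted(universe), size=k_set, replace=False))
            hits = set(rng.choice(sorted(universe), size=k_hits, replace=False))
            overlap, p = hypergeometric_enrichment(hits, gene_set, universe)
            total = comb(m, k_hits)
            tail = sum(
                comb(k_set, x) * comb(m - k_set, k_hits - x)
                for x in range(overlap, min(k_set, k_hits) + 1)
                if k_hits - x <= m - k_set
            )
            assert p == pytest.approx(tail / total, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment(set(), set(), set())

    def test_scan_with_gmt(self, tmp_path, rng):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "setA\tdesc\tg0\tg1\tg2\n"
            "setB\tdesc\tg5\tg6\n"
        )
        sets = read_gmt(gmt)
        assert sets["setA"] == {"g0", "g1", "g2"}
        universe = {f"g{i}" for i in range(10)}
        df = enrichment_scan({"g0", "g1"}, sets, universe)
        assert set(df.index) == {"setA", "setB"}
        assert df.loc["setA", "n_overlap"] == 2
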
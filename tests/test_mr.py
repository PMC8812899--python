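import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmr.gwas_io import HarmonizedPair, LDMatrix
from ctmr.mr import (
    MRInputSet,
    apply_multiplicity,
    bonferroni_threshold,
    ivw_correlated,
    leave_one_out,
    make_input_set,
    mvmr_correlated,
    scale_odds_ratio,
    wald_ratio,
)


def hp(snp, bx, by, se_out, se_exp=0.01):
    return HarmonizedPair(snp, "A", "G", bx, se_exp, by, se_out)


def gls_oracle(bx, by, se, rho):
    """Independent explicit-matrix GLS estimate of theta and its SE."""
    omega = np.outer(se, se) * rho
    oi = np.linalg.inv(omega)
    theta = float(bx @ oi @ by) / float(bx @ oi @ bx)
    v = 1.0 / float(bx @ oi @ bx)
    resid = by - theta * bx
    phi = max(1.0, math.sqrt(float(resid @ oi @ resid) / (len(bx) - 1)))
    return theta, math.sqrt(v) * phi


class TestWaldRatio:
    def test_unit_denominator_passthrough(self):
        est = wald_ratio(hp("s", 1.0, 0.12, 0.05))
        assert est.theta == pytest.approx(0.12)
        assert est.se_theta == pytest.approx(0.05)

    def test_closed_form_ratio(self):
        est = wald_ratio(hp("s", -0.5, 0.2, 0.05))
        assert est.theta == pytest.approx(-0.4)
        assert est.se_theta == pytest.approx(0.1)

    def test_null_numerator_gives_or_one(self):
        est = wald_ratio(hp("s", 0.3, 0.0, 0.05))
        assert est.odds_ratio == 1.0
        assert est.pvalue == 1.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            wald_ratio(hp("s", 0.0, 0.1, 0.05))


class TestIVWCorrelated:
    def test_single_variant_equals_wald(self, toy_pairs):
        pairs, ld = toy_pairs
        inp = make_input_set(pairs[:1], ld)
        est = ivw_correlated(inp)
        ref = wald_ratio(pairs[0])
        assert est.theta == pytest.approx(ref.theta)
        assert est.se_theta == pytest.approx(ref.se_theta)

    def test_identity_ld_matches_textbook_ivw(self, toy_pairs):
        pairs, _ = toy_pairs
        inp = make_input_set(pairs, LDMatrix.identity([p.snp_id for p in pairs]))
        est = ivw_correlated(inp)
        # classical weighted regression through the origin, weights 1/se_out^2
        bx = np.array([p.beta_exposure for p in pairs])
        by = np.array([p.beta_outcome for p in pairs])
        w = np.array([1 / p.se_outcome**2 for p in pairs])
        theta = (w * bx * by).sum() / (w * bx**2).sum()
        assert est.theta == pytest.approx(theta, abs=1e-14)

    def test_matches_gls_oracle_on_correlated_fixture(self, toy_pairs):
        pairs, ld = toy_pairs
        est = ivw_correlated(make_input_set(pairs, ld))
        bx = np.array([p.beta_exposure for p in pairs])
        by = np.array([p.beta_outcome for p in pairs])
        se = np.array([p.se_outcome for p in pairs])
        theta, se_theta = gls_oracle(bx, by, se, ld.r)
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.se_theta == pytest.approx(se_theta, abs=1e-10)

    def test_exact_fit_floors_phi_at_one(self, toy_pairs):
        pairs, ld = toy_pairs
        theta = 0.15
        exact = [
            HarmonizedPair(p.snp_id, "A", "G", p.beta_exposure, p.se_exposure,
                           theta * p.beta_exposure, p.se_outcome)
            for p in pairs
        ]
        est = ivw_correlated(make_input_set(exact, ld))
        assert est.phi == 1.0
        assert est.theta == pytest.approx(theta)
        # se equals the base (fixed-effects) standard error
        omega = np.outer([p.se_outcome for p in exact], [p.se_outcome for p in exact]) * ld.r
        bx = np.array([p.beta_exposure for p in exact])
        assert est.se_theta == pytest.approx(
            1 / math.sqrt(bx @ np.linalg.inv(omega) @ bx)
        )

    def test_overdispersion_inflates_se(self, rng):
        ids = [f"s{i}" for i in range(6)]
        bx = rng.uniform(0.2, 0.5, 6)
        by = 0.1 * bx + rng.normal(scale=0.2, size=6)  # noisy: phi > 1 likely
        pairs = [hp(ids[i], bx[i], by[i], 0.01) for i in range(6)]
        est = ivw_correlated(make_input_set(pairs, LDMatrix.identity(ids)))
        assert est.phi > 1
        base = ivw_correlated(
            make_input_set(
                [hp(ids[i], bx[i], 0.1 * bx[i], 0.01) for i in range(6)],
                LDMatrix.identity(ids),
            )
        )
        assert est.se_theta > base.se_theta

    def test_orientation_antisymmetry(self, toy_pairs):
        pairs, ld = toy_pairs
        est = ivw_correlated(make_input_set(pairs, ld))
        negated = [
            HarmonizedPair(p.snp_id, "A", "G", -p.beta_exposure, p.se_exposure,
                           p.beta_outcome, p.se_outcome)
            for p in pairs
        ]
        est_neg = ivw_correlated(make_input_set(negated, ld))
        assert est_neg.theta == pytest.approx(-est.theta)
        assert est_neg.odds_ratio == pytest.approx(1 / est.odds_ratio)
        assert est_neg.se_theta == pytest.approx(est.se_theta)

    def test_flipped_reporting_orientation(self, toy_pairs):
        pairs, ld = toy_pairs
        est = ivw_correlated(make_input_set(pairs, ld))
        rep = est.flipped()
        assert rep.theta == -est.theta
        assert rep.orientation == "per_unit_lower_exposure"
        assert rep.ci_low == pytest.approx(1 / est.ci_high)

    def test_dimension_mismatch_rejected(self, toy_pairs):
        pairs, ld = toy_pairs
        with pytest.raises(ValueError):
            MRInputSet(pairs[:2], ld)


class TestScaleOddsRatio:
    def test_null_or_invariant(self):
        est = wald_ratio(hp("s", 0.3, 0.0, 0.05))
        assert scale_odds_ratio(est, 8).odds_ratio == 1.0

    def test_scale_one_is_identity(self, toy_pairs):
        pairs, ld = toy_pairs
        est = ivw_correlated(make_input_set(pairs, ld))
        same = scale_odds_ratio(est, 1.0)
        assert same.theta == est.theta
        assert same.se_theta == est.se_theta
        assert same.pvalue == est.pvalue

    def test_eightfold_scaling_of_printed_or(self):
        # OR 1.13 per unit, scaled to 8 units: exp(8 ln 1.13) ~ 2.66
        theta = math.log(1.13)
        est = wald_ratio(hp("s", 1.0, theta, 0.036))
        scaled = scale_odds_ratio(est, 8)
        assert scaled.odds_ratio == pytest.approx(math.exp(8 * theta))
        assert scaled.odds_ratio == pytest.approx(2.66, abs=0.01)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 4), b=st.floats(0.5, 4))
    def test_scaling_equivariance(self, a, b):
        est = wald_ratio(hp("s", 0.5, 0.08, 0.03))
        direct = scale_odds_ratio(est, a * b)
        stepwise = scale_odds_ratio(scale_odds_ratio(est, a), b)
        assert direct.theta == pytest.approx(stepwise.theta)
        assert direct.se_theta == pytest.approx(stepwise.se_theta)


class TestLeaveOneOut:
    def test_two_variants_reduce_to_wald(self, toy_pairs):
        pairs, ld = toy_pairs
        inp = make_input_set(pairs[:2], ld)
        for excluded, est in leave_one_out(inp):
            (remaining,) = [p for p in pairs[:2] if p.snp_id != excluded]
            ref = wald_ratio(remaining)
            assert est.theta == pytest.approx(ref.theta)

    def test_each_subset_matches_direct_call(self, toy_pairs):
        pairs, ld = toy_pairs
        inp = make_input_set(pairs, ld)
        for excluded, est in leave_one_out(inp):
            subset = [p for p in pairs if p.snp_id != excluded]
            direct = ivw_correlated(make_input_set(subset, ld))
            assert est.theta == pytest.approx(direct.theta, abs=1e-12)
            assert est.se_theta == pytest.approx(direct.se_theta, abs=1e-12)

    def test_bookkeeping(self, toy_pairs):
        pairs, ld = toy_pairs
        results = leave_one_out(make_input_set(pairs, ld))
        assert [snp for snp, _ in results] == [p.snp_id for p in pairs]

    def test_single_variant_rejected(self, toy_pairs):
        pairs, ld = toy_pairs
        with pytest.raises(ValueError, match="leave out"):
            leave_one_out(make_input_set(pairs[:1], ld))

    def test_homogeneous_instrument_has_no_influential_snp(self, rng):
        # removing any single variant moves theta by less than 3 base SEs
        m = 8
        ids = [f"s{i}" for i in range(m)]
        bx = rng.uniform(0.2, 0.5, m)
        theta = 0.1
        by = theta * bx + rng.normal(scale=0.015, size=m)
        pairs = [hp(ids[i], bx[i], by[i], 0.015) for i in range(m)]
        inp = make_input_set(pairs, LDMatrix.identity(ids))
        full = ivw_correlated(inp)
        for _, est in leave_one_out(inp):
            assert abs(est.theta - full.theta) < 3 * full.se_theta


class TestMVMR:
    def make_fixture(self, rng, j=5, theta=(0.1, -0.05)):
        bx = rng.uniform(0.2, 0.6, size=(j, 2))
        se = rng.uniform(0.01, 0.03, j)
        a = rng.normal(size=(j, j))
        c = a @ a.T
        d = np.sqrt(np.diag(c))
        rho = c / np.outer(d, d)
        by = bx @ np.array(theta) + rng.normal(scale=0.01, size=j)
        return bx, by, se, LDMatrix([f"s{i}" for i in range(j)], rho)

    def test_matches_normal_equations_oracle(self, rng):
        bx, by, se, ld = self.make_fixture(rng)
        ests = mvmr_correlated(bx, by, se, ld)
        omega = np.outer(se, se) * ld.r
        oi = np.linalg.inv(omega)
        gram = bx.T @ oi @ bx
        theta = np.linalg.solve(gram, bx.T @ oi @ by)
        resid = by - bx @ theta
        phi = max(1.0, math.sqrt(float(resid @ oi @ resid) / (len(by) - 2)))
        cov = np.linalg.inv(gram)
        for e, est in enumerate(ests):
            assert est.theta == pytest.approx(theta[e], abs=1e-10)
            assert est.se_theta == pytest.approx(math.sqrt(cov[e, e]) * phi, abs=1e-10)

    def test_nuisance_exposure_with_orthogonal_instruments(self, rng):
        # second exposure instrumented by disjoint variants: the first
        # exposure's estimate stays close to its univariable value
        j = 8
        ids = [f"s{i}" for i in range(j)]
        bx1 = np.where(np.arange(j) < 4, rng.uniform(0.3, 0.5, j), 0.0)
        bx2 = np.where(np.arange(j) >= 4, rng.uniform(0.3, 0.5, j), 0.0)
        theta1 = 0.2
        by = theta1 * bx1  # exposure 2 has no effect
        se = np.full(j, 0.02)
        ests = mvmr_correlated(np.column_stack([bx1, bx2]), by, se, LDMatrix.identity(ids))
        assert ests[0].theta == pytest.approx(theta1, abs=1e-10)
        assert ests[1].theta == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_exposures_rejected(self, rng):
        bx, by, se, ld = self.make_fixture(rng)
        dup = np.column_stack([bx[:, 0], bx[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            mvmr_correlated(dup, by, se, ld)

    def test_needs_more_variants_than_exposures(self, rng):
        bx, by, se, ld = self.make_fixture(rng, j=5)
        with pytest.raises(ValueError, match="more variants"):
            mvmr_correlated(bx[:2], by[:2], se[:2], ld.subset(["s0", "s1"]))


class TestMultiplicity:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(0.05, 36) == pytest.approx(0.0014, abs=5e-5)
        assert bonferroni_threshold(0.05, 21_482) == pytest.approx(2.33e-6, rel=0.01)

    def test_tier_assignment(self):
        tiers = {
            t.label: t.tier
            for t in apply_multiplicity(
                {"a": 3.6e-4, "b": 0.01, "c": 0.5}, alpha=0.05, n_tests=36
            )
        }
        assert tiers == {"a": "strong", "b": "weak", "c": "little"}

    def test_weak_upper_boundary(self):
        (t,) = apply_multiplicity({"x": 0.20}, alpha=0.05, n_tests=1)
        assert t.tier == "little"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            apply_multiplicity({})
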
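"""Estimator correctness against independent arithmetic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mr2s
from mr2s.estimators import weighted_median
from conftest import make_instrument


def ratio(snp, b, s):
    return mr2s.WaldRatio(snp_id=snp, beta_xy=b, se_xy=s)


ratio_lists = st.lists(
    st.tuples(
        st.floats(-2.0, 2.0),
        st.floats(0.05, 3.0),
    ),
    min_size=2,
    max_size=12,
).map(lambda ps: [ratio(f"rs{i}", b, s) for i, (b, s) in enumerate(ps)])


class TestWaldRatio:
    def test_table1_rs977747_ratio(self, table1_instruments):
        v = next(x for x in table1_instruments if x.snp_id == "rs977747")
        r = mr2s.wald_ratio(v)
        assert r.beta_xy == pytest.approx(-0.010 / 0.017)

    def test_zero_outcome_beta_gives_zero_ratio(self, table1_instruments):
        v = next(x for x in table1_instruments if x.snp_id == "rs12401738")
        assert mr2s.wald_ratio(v).beta_xy == 0.0

    def test_first_order_se_hand_arithmetic(self, table1_instruments):
        # rs543874: se = 0.019/0.05 = 0.38, weight = 0.38**-2
        v = next(x for x in table1_instruments if x.snp_id == "rs543874")
        r = mr2s.wald_ratio(v, se_method="first_order")
        assert r.beta_xy == pytest.approx(0.78)
        assert r.se_xy == pytest.approx(0.38)
        assert r.weight == pytest.approx(1 / 0.38**2)

    def test_second_order_se_formula(self):
        v = make_instrument(bx=0.05, sx=0.004, by=0.039, sy=0.019)
        r = mr2s.wald_ratio(v)
        expected = math.sqrt(0.019**2 / 0.05**2 + 0.039**2 * 0.004**2 / 0.05**4)
        assert r.se_xy == pytest.approx(expected, rel=1e-12)

    def test_zero_exposure_beta_raises_naming_snp(self):
        v = make_instrument(snp="rsZ", bx=0.0)
        with pytest.raises(mr2s.DegenerateInstrumentError, match="rsZ"):
            mr2s.wald_ratio(v)


class TestIVW:
    def test_single_ratio_is_identity(self):
        est, het = mr2s.ivw_estimate([ratio("rs1", 0.5, 0.2)])
        assert est.beta == 0.5 and est.se == 0.2
        assert het is None

    def test_three_ratios_match_explicit_sum_oracle(self):
        rs = [ratio("a", 0.2, 0.1), ratio("b", 0.4, 0.2), ratio("c", 0.6, 0.3)]
        w = [1 / 0.1**2, 1 / 0.2**2, 1 / 0.3**2]
        b_exp = sum(wi * bi for wi, bi in zip(w, [0.2, 0.4, 0.6])) / sum(w)
        est, het = mr2s.ivw_estimate(rs, model="fixed")
        assert est.beta == pytest.approx(b_exp, rel=1e-12)
        assert est.se == pytest.approx(sum(w) ** -0.5, rel=1e-12)
        q_exp = sum(wi * (bi - b_exp) ** 2 for wi, bi in zip(w, [0.2, 0.4, 0.6]))
        assert het.Q == pytest.approx(q_exp, rel=1e-12)

    @given(ratio_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fixed_ivw_equals_sum_oracle_everywhere(self, rs):
        est, het = mr2s.ivw_estimate(rs, model="fixed")
        w = [r.se_xy**-2 for r in rs]
        b = sum(wi * r.beta_xy for wi, r in zip(w, rs)) / sum(w)
        assert est.beta == pytest.approx(b, rel=1e-9, abs=1e-12)
        assert het.Q >= 0
        # I2 invariant to SNP order
        est2, het2 = mr2s.ivw_estimate(list(reversed(rs)), model="fixed")
        assert het2.i2 == pytest.approx(het.i2, abs=1e-9)

    def test_scaling_outcome_ses_scales_ivw_se_not_point(self, table1_instruments):
        rs = mr2s.wald_ratios(table1_instruments, "first_order")
        scaled = [
            mr2s.wald_ratio(
                make_instrument(
                    snp=v.snp_id, bx=v.beta_exposure, sx=v.se_exposure,
                    by=v.beta_outcome, sy=3.0 * v.se_outcome,
                ),
                "first_order",
            )
            for v in table1_instruments
        ]
        a, _ = mr2s.ivw_estimate(rs, model="fixed")
        b, _ = mr2s.ivw_estimate(scaled, model="fixed")
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.se == pytest.approx(3.0 * a.se, rel=1e-12)

    def test_removing_largest_q_contributor_never_increases_q(self, table1_ratios):
        est, het = mr2s.ivw_estimate(table1_ratios, model="fixed")
        contrib = [r.weight * (r.beta_xy - est.beta) ** 2 for r in table1_ratios]
        worst = int(np.argmax(contrib))
        rest = table1_ratios[:worst] + table1_ratios[worst + 1 :]
        _, het2 = mr2s.ivw_estimate(rest, model="fixed")
        assert het2.Q <= het.Q + 1e-12

    def test_auto_selects_random_only_under_significant_heterogeneity(self):
        homogeneous = [ratio(f"rs{i}", 0.3, 0.1) for i in range(5)]
        est, _ = mr2s.ivw_estimate(homogeneous, model="auto")
        assert est.method == "IVW-fixed"
        spread = [ratio(f"rs{i}", b, 0.05) for i, b in enumerate([-2, -1, 0, 1, 2])]
        est2, het2 = mr2s.ivw_estimate(spread, model="auto")
        assert het2.significant and est2.method == "IVW-random"
        # random-effects SE is never smaller than fixed
        fixed2, _ = mr2s.ivw_estimate(spread, model="fixed")
        assert est2.se >= fixed2.se

    def test_empty_input_rejected(self):
        with pytest.raises(mr2s.InsufficientInstrumentsError):
            mr2s.ivw_estimate([])


def egger_normal_equations(bx, by, sy):
    """Independent weighted-least-squares oracle via explicit normal equations."""
    w = [1 / s**2 for s in sy]
    Sw = sum(w)
    Sx = sum(wi * x for wi, x in zip(w, bx))
    Sy = sum(wi * y for wi, y in zip(w, by))
    Sxx = sum(wi * x * x for wi, x in zip(w, bx))
    Sxy = sum(wi * x * y for wi, x, y in zip(w, bx, by))
    den = Sw * Sxx - Sx**2
    return (Sw * Sxy - Sx * Sy) / den, (Sxx * Sy - Sx * Sxy) / den


class TestEgger:
    def test_exact_collinear_fit_recovers_line(self):
        instr = [
            make_instrument(snp=f"rs{i}", bx=x, by=0.1 + 0.5 * x, sy=0.02)
            for i, x in enumerate([0.01, 0.03, 0.05])
        ]
        slope, intercept = mr2s.egger_regression(instr)
        assert slope.beta == pytest.approx(0.5, rel=1e-9)
        assert intercept.beta == pytest.approx(0.1, rel=1e-9)

    def test_matches_normal_equations_oracle_to_10_decimals(self):
        bx = [0.015, 0.02, 0.03, 0.04, 0.05]
        by = [0.01, -0.005, 0.02, 0.03, 0.015]
        sy = [0.02, 0.015, 0.025, 0.02, 0.03]
        instr = [
            make_instrument(snp=f"rs{i}", bx=x, by=y, sy=s)
            for i, (x, y, s) in enumerate(zip(bx, by, sy))
        ]
        slope, intercept = mr2s.egger_regression(instr)
        s_exp, i_exp = egger_normal_equations(bx, by, sy)
        assert slope.beta == pytest.approx(s_exp, abs=1e-10)
        assert intercept.beta == pytest.approx(i_exp, abs=1e-10)

    def test_orientation_flips_negative_exposure_instruments(self):
        base = [
            make_instrument(snp=f"rs{i}", bx=x, by=0.05 + 0.4 * x, sy=0.02)
            for i, x in enumerate([0.02, 0.03, 0.05])
        ]
        flipped = [
            make_instrument(
                snp=v.snp_id, bx=-v.beta_exposure, by=-v.beta_outcome,
                sy=v.se_outcome,
            )
            for v in base[:1]
        ] + base[1:]
        s1, i1 = mr2s.egger_regression(base)
        s2, i2 = mr2s.egger_regression(flipped)
        assert s2.beta == pytest.approx(s1.beta, rel=1e-12)
        assert i2.beta == pytest.approx(i1.beta, rel=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self, table1_instruments):
        """Weighted regression through the origin (weights 1/se_out^2) is
        algebraically the fixed-effect IVW of first-order Wald ratios."""
        bx = [v.beta_exposure for v in table1_instruments]
        by = [v.beta_outcome for v in table1_instruments]
        sy = [v.se_outcome for v in table1_instruments]
        w = [1 / s**2 for s in sy]
        slope_origin = sum(wi * x * y for wi, x, y in zip(w, bx, by)) / sum(
            wi * x * x for wi, x in zip(w, bx)
        )
        est, _ = mr2s.ivw_estimate(
            mr2s.wald_ratios(table1_instruments, "first_order"), model="fixed"
        )
        assert est.beta == pytest.approx(slope_origin, rel=1e-12)

    def test_too_few_or_singular_inputs_rejected(self):
        two = [make_instrument(snp=f"rs{i}", bx=0.02 + 0.01 * i) for i in range(2)]
        with pytest.raises(mr2s.InsufficientInstrumentsError):
            mr2s.egger_regression(two)
        constant = [make_instrument(snp=f"rs{i}", bx=0.02) for i in range(3)]
        with pytest.raises(mr2s.MRError):
            mr2s.egger_regression(constant)


class TestMedians:
    def test_all_equal_ratios_return_that_value(self):
        rs = [ratio(f"rs{i}", 0.3, 0.1) for i in range(5)]
        est = mr2s.median_estimate(rs, "simple", n_boot=500, seed=1)
        assert est.beta == pytest.approx(0.3)
        tight = [ratio(f"rs{i}", 0.3, 1e-6) for i in range(5)]
        est_t = mr2s.median_estimate(tight, "weighted", n_boot=500, seed=1)
        assert est_t.se < 1e-5  # bootstrap SE -> 0 as ratio SEs -> 0

    def test_interpolated_weighted_median_matches_formula_oracle(self):
        vals = np.array([0.1, 0.4, 0.2, 0.8, 0.5])
        wts = np.array([1.0, 2.0, 3.0, 1.5, 2.5])
        # direct evaluation of the cumulative-weight interpolation
        order = np.argsort(vals)
        v, w = vals[order], wts[order] / wts.sum()
        p = np.cumsum(w) - w / 2
        k = np.searchsorted(p, 0.5) - 1
        expected = v[k] + (v[k + 1] - v[k]) * (0.5 - p[k]) / (p[k + 1] - p[k])
        assert weighted_median(vals, wts) == pytest.approx(expected, rel=1e-12)

    @given(ratio_lists.filter(lambda rs: len(rs) >= 3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_weighted_median_with_equal_weights_is_simple_median(self, rs):
        equal = [ratio(r.snp_id, r.beta_xy, 1.0) for r in rs]
        simple = mr2s.median_estimate(rs, "simple", n_boot=1, seed=1)
        wm_eq = mr2s.median_estimate(equal, "weighted", n_boot=1, seed=1)
        assert wm_eq.beta == pytest.approx(simple.beta, rel=1e-9, abs=1e-12)

    def test_bootstrap_is_deterministic_given_seed(self, table1_ratios):
        a = mr2s.median_estimate(table1_ratios, "weighted", n_boot=300, seed=7)
        b = mr2s.median_estimate(table1_ratios, "weighted", n_boot=300, seed=7)
        c = mr2s.median_estimate(table1_ratios, "weighted", n_boot=300, seed=8)
        assert a.se == b.se and a.se != c.se


class TestPenalizedAndRobust:
    def test_homogeneous_data_penalties_are_inert(self):
        rs = [ratio(f"rs{i}", 0.3, 0.1) for i in range(6)]
        pen = mr2s.penalized_ivw(rs)
        plain, _ = mr2s.ivw_estimate(rs, model="fixed")
        assert pen.beta == pytest.approx(plain.beta, rel=1e-12)
        assert pen.se == pytest.approx(plain.se, rel=1e-12)

    def test_outlier_is_downweighted_toward_concordant_majority(self):
        rs = [ratio("a", 0.30, 0.05), ratio("b", 0.32, 0.05),
              ratio("c", 0.28, 0.05), ratio("d", 3.0, 0.05)]
        plain, _ = mr2s.ivw_estimate(rs, model="fixed")
        pen = mr2s.penalized_ivw(rs)
        # explicit-sum oracle with penalty factors
        from scipy import stats as sps
        w = np.array([r.weight for r in rs])
        b = np.array([r.beta_xy for r in rs])
        b0 = (w * b).sum() / w.sum()
        q = sps.chi2.sf(w * (b - b0) ** 2, 1)
        wp = w * np.minimum(1, 20 * q)
        assert pen.beta == pytest.approx((wp * b).sum() / wp.sum(), rel=1e-12)
        assert abs(pen.beta - 0.30) < abs(plain.beta - 0.30)

    def test_robust_matches_ivw_without_residual_scatter(self):
        rs = [ratio(f"rs{i}", 0.4, s) for i, s in enumerate([0.1, 0.2, 0.3, 0.15])]
        robust = mr2s.robust_ivw(rs)
        plain, _ = mr2s.ivw_estimate(rs, model="fixed")
        assert robust.beta == pytest.approx(plain.beta, rel=1e-9)

    def test_robust_resists_gross_contamination(self):
        rng = np.random.default_rng(11)
        clean = [ratio(f"rs{i}", 0.4 + 0.05 * rng.standard_normal(), 0.05)
                 for i in range(10)]
        ivw_clean, _ = mr2s.ivw_estimate(clean, model="fixed")
        contaminated = clean[:-1] + [ratio("bad", clean[-1].beta_xy + 10.0, 0.05)]
        ivw_bad, _ = mr2s.ivw_estimate(contaminated, model="fixed")
        robust_bad = mr2s.robust_ivw(contaminated)
        assert abs(robust_bad.beta - ivw_clean.beta) < 2 * ivw_clean.se
        assert abs(ivw_bad.beta - ivw_clean.beta) > 2 * ivw_clean.se

    def test_ci_orders_are_valid(self, table1_ratios):
        for est in (
            mr2s.penalized_ivw(table1_ratios),
            mr2s.robust_ivw(table1_ratios),
            mr2s.robust_ivw(table1_ratios, penalized=True),
        ):
            assert est.ci_low <= est.beta <= est.ci_high
            assert 0 < est.or_ci_low <= est.odds_ratio <= est.or_ci_high


class TestEstimateAll:
    def test_fixture_gives_seven_rows_all_or_above_one(self, table1_instruments):
        report = mr2s.estimate_all(table1_instruments, n_boot=500, seed=1)
        assert len(report.estimates) == 7
        assert {e.method for e in report.estimates} == {
            "IVW-fixed", "SimpleMedian", "WeightedMedian",
            "PenalizedWeightedMedian", "PenalizedIVW", "RobustIVW",
            "PenalizedRobustIVW",
        }
        assert all(e.odds_ratio > 1 for e in report.estimates)
        assert all(e.or_ci_low > 1 for e in report.estimates)

    def test_single_snp_input_keeps_only_ivw(self):
        report = mr2s.estimate_all([make_instrument()], n_boot=10)
        assert [e.method for e in report.estimates] == ["IVW-fixed"]
        assert set(report.skipped) == {
            "SimpleMedian", "WeightedMedian", "PenalizedWeightedMedian",
            "PenalizedIVW", "RobustIVW", "PenalizedRobustIVW",
        }

    def test_null_data_cis_cover_one_in_most_replicates(self):
        from mr2s import SimulationConfig, generate_summary_stats, harmonize_pair

        methods = None
        covered = {}
        n_rep = 200
        for rep in range(n_rep):
            exp, out, _ = generate_summary_stats(
                SimulationConfig(true_effect=0.0, seed=10_000 + rep)
            )
            report = mr2s.estimate_all(
                harmonize_pair(exp, out), n_boot=100, seed=rep
            )
            if methods is None:
                methods = [e.method for e in report.estimates]
                covered = {m: 0 for m in methods}
            for e in report.estimates:
                covered[e.method] += e.ci_low <= 0.0 <= e.ci_high
        for m, c in covered.items():
            assert c / n_rep >= 0.90, f"{m} covered null in only {c}/{n_rep}"
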
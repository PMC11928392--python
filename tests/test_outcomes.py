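"""Clinical endpoints and the dose-outcome statistical battery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from rptdose.outcomes import (
    anemia_grade,
    breslow_partial_loglik,
    classify_response,
    cox_univariate,
    fisher_z_compare,
    kaplan_meier,
    mann_whitney_u,
    p_from_z,
    psa_decline_rate,
    run_comparison_analysis,
    spearman,
    steiger_z_compare,
)


class TestEndpoints:
    @pytest.mark.parametrize(
        "baseline,psa,expected",
        [(10.0, 4.0, -0.6), (8.0, 8.0, 0.0), (8.0, 12.0, 0.5)],
    )
    def test_psa_decline_rate(self, baseline, psa, expected):
        assert psa_decline_rate(baseline, psa) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="invalid baseline"):
            psa_decline_rate(0.0, 5.0)

    @pytest.mark.parametrize(
        "rate,expected",
        [(-0.6, "good"), (-0.5, "good"), (-0.49, "poor"), (0.5, "poor")],
    )
    def test_classify_response_boundary(self, rate, expected):
        # a decrease of exactly 50% counts as a good response
        assert classify_response(rate) == expected

    @pytest.mark.parametrize(
        "hgb,expected", [(14.0, 0), (12.0, 1), (10.0, 1), (9.0, 2), (8.0, 2), (7.5, 3)]
    )
    def test_anemia_grading_bands(self, hgb, expected):
        assert anemia_grade(hgb, lln_g_dl=13.0) == expected

    def test_anemia_clinical_flags_and_errors(self):
        assert anemia_grade(7.0, life_threatening=True) == 4
        assert anemia_grade(7.0, fatal=True) == 5
        with pytest.raises(ValueError, match="invalid measurement"):
            anemia_grade(0.0)


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        rho, _ = spearman([1, 2, 5, 9], [0.1, 0.4, 0.5, 3.0])
        assert rho == pytest.approx(1.0)

    def test_hand_value_from_rank_formula(self):
        # d = (ranks x - ranks y): sum d^2 = 6 -> 1 - 6*6/(3*8) = -0.5
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_symmetry(self):
        x, y = [1.0, 4.0, 2.0, 8.0, 3.0], [2.0, 1.0, 9.0, 4.0, 5.0]
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0])

    @given(st.permutations(list(range(8))))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_invariance_under_monotone_transforms(self, perm):
        x = np.arange(8.0)
        y = np.array(perm, dtype=float)
        rho0, _ = spearman(x, y)
        rho1, _ = spearman(np.exp(x / 3), y)
        rho2, _ = spearman(x, y**3 + 5)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert rho2 == pytest.approx(rho0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestFisherZ:
    def test_identical_inputs_give_null(self):
        cmp_ = fisher_z_compare(0.4, 50, 0.4, 50)
        assert cmp_.z_stat == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_tumor_psa_worked_example(self):
        # rho -0.39 vs -0.46 at n ~ 95 per arm gives Z ~ 0.58, p ~ 0.56
        cmp_ = fisher_z_compare(-0.39, 95, -0.46, 95)
        assert cmp_.z_stat == pytest.approx(0.58, abs=0.005)
        assert cmp_.p_value == pytest.approx(0.562, abs=0.005)

    def test_printed_p_values_from_z(self):
        assert round(p_from_z(0.58), 2) == 0.56
        assert round(p_from_z(-0.39), 2) == 0.70

    def test_antisymmetry_in_correlations(self):
        a = fisher_z_compare(0.3, 40, 0.6, 60)
        b = fisher_z_compare(0.6, 60, 0.3, 40)
        assert a.z_stat == pytest.approx(-b.z_stat, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite transform"):
            fisher_z_compare(1.0, 30, 0.5, 30)

    def test_transform_accuracy_against_identities(self):
        # atanh and the normal CDF as used must be accurate to 1e-10
        for rho in (0.1, 0.5, 0.9, 0.99):
            assert abs(math.atanh(rho) - 0.5 * math.log((1 + rho) / (1 - rho))) < 1e-12
        from scipy import stats
        for z in (0.5, 1.0, 2.0, 3.0):
            assert abs(stats.norm.sf(z) + stats.norm.cdf(z) - 1.0) < 1e-10
            assert abs(p_from_z(z) - 2 * stats.norm.sf(z)) < 1e-15

    def test_steiger_null_and_sign(self):
        assert steiger_z_compare(0.4, 0.4, 0.8, 50).z_stat == 0.0
        # stronger rho1 with highly correlated predictors -> larger |Z|
        # than the independent-samples form
        dep = steiger_z_compare(0.5, 0.3, 0.9, 50)
        indep = fisher_z_compare(0.5, 50, 0.3, 50)
        assert abs(dep.z_stat) > abs(indep.z_stat)


def mwu_enumeration(a, b):
    """Brute-force U: pairwise wins of a over b (ties count half)."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_interleaved_hand_value(self):
        u, _ = mann_whitney_u([1, 3], [2, 4])
        assert u == 1.0

    def test_identical_groups_symmetric_u(self):
        u, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n*m/2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            mann_whitney_u([], [1.0])

    def test_statistic_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 7, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            u, _ = mann_whitney_u(a, b)
            assert u == pytest.approx(mwu_enumeration(a, b))


def cox_grid_oracle(times, events, covariate, cap=20.0):
    """1-D maximization of the Breslow partial likelihood over the
    admissible range [-cap, cap] by grid search plus local refinement.

    The log partial likelihood is concave; when its value at a boundary
    is not below the grid maximum, the maximizer sits at (or beyond)
    that boundary — the monotone-likelihood case.
    """
    grid = np.linspace(-cap, cap, 2001)
    ll = [breslow_partial_loglik(b, times, events, covariate) for b in grid]
    k = int(np.argmax(ll))
    if ll[-1] >= ll[k] - 1e-9:
        return cap
    if ll[0] >= ll[k] - 1e-9:
        return -cap
    res = minimize_scalar(
        lambda b: -breslow_partial_loglik(b, times, events, covariate),
        bounds=(grid[k - 1], grid[k + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


class TestCox:
    def test_toy_instance_matches_grid_oracle(self):
        # all x=1 subjects die before all x=0: monotone likelihood,
        # both routes stop at the admissible cap
        t, e, x = [1, 2, 3, 4], [True] * 4, [1, 1, 0, 0]
        with pytest.warns(UserWarning, match="monotone"):
            res = cox_univariate(t, e, x)
        assert res.beta == pytest.approx(cox_grid_oracle(t, e, x), abs=1e-4)

    def test_regular_instance_matches_grid_oracle(self):
        t = [2.0, 5.0, 1.0, 8.0, 3.0, 9.0]
        e = [True, True, False, True, True, False]
        x = [1.2, -0.3, 0.8, -1.1, 0.4, -0.6]
        res = cox_univariate(t, e, x)
        assert res.beta == pytest.approx(cox_grid_oracle(t, e, x), abs=1e-4)
        assert res.hr == pytest.approx(math.exp(res.beta))

    def test_agrees_with_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 40
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x))
        e = rng.random(n) < 0.8
        res = cox_univariate(t, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e"
        )
        assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), rel=1e-3)

    def test_null_calibration(self, rng):
        """Covariate independent of survival: beta near 0, ~5% rejections."""
        betas, rejections = [], 0
        n_reps = 200
        for _ in range(n_reps):
            n = 200
            x = rng.normal(size=n)
            t = rng.exponential(1.0, size=n)
            e = rng.random(n) < 0.7
            res = cox_univariate(t, e, x)
            betas.append(res.beta)
            rejections += res.p_value < 0.05
        assert abs(np.mean(betas)) < 0.2
        assert 0.01 <= rejections / n_reps <= 0.10

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="no events"):
            cox_univariate([1, 2], [False, False], [0.0, 1.0])
        with pytest.raises(ValueError, match="constant covariate"):
            cox_univariate([1, 2, 3], [True, True, False], [1.0, 1.0, 1.0])


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        sf = kaplan_meier([1, 2, 3, 4], [True] * 4)
        steps = sf[sf["time"] > 0]["survival"].tolist()
        assert steps == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        sf = kaplan_meier([5, 8, 13], [False] * 3)
        assert (sf["survival"] == 1.0).all()

    def test_matches_product_limit_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            t = rng.integers(1, 8, size=n).astype(float)
            e = rng.random(n) < 0.7
            if not e.any():
                continue
            sf = kaplan_meier(t, e).set_index("time")["survival"]
            # brute-force product formula over distinct event times
            surv = 1.0
            for tau in sorted(set(t[e])):
                d = np.sum((t == tau) & e)
                at_risk = np.sum(t >= tau)
                surv *= 1.0 - d / at_risk
                assert sf.loc[tau] == pytest.approx(surv)


def _toy_doses_outcomes(rng, link=-0.02):
    """Small cohort-shaped frames with a controllable dose-PSA link."""
    doses, outcomes = [], []
    for p in range(15):
        pid = f"P{p}"
        base = 30 * float(rng.lognormal(0, 0.5))
        outcomes.append({"patient_id": pid, "cycle": 0, "psa": base, "hgb": 13.5,
                         "os_days": 300.0, "os_event": True})
        cum = {"MTPD": 0.0, "STPD": 0.0}
        for cyc in range(1, 6):
            m = float(rng.lognormal(2.0, 0.6))
            for method, val in (("MTPD", m), ("STPD", m * 0.9)):
                cum[method] += val
                doses.append({"patient_id": pid, "cycle": cyc, "organ": "tumor",
                              "method": method, "dose_gy": val,
                              "cumulative_gy": cum[method]})
                doses.append({"patient_id": pid, "cycle": cyc, "organ": "bone_marrow",
                              "method": method, "dose_gy": val / 5,
                              "cumulative_gy": cum[method] / 5})
            rate = max(link * cum["MTPD"] + rng.normal(0, 0.2), -1.0)
            outcomes.append({
                "patient_id": pid, "cycle": cyc, "psa": max(base * (1 + rate), 0.01),
                "hgb": 13.5 - 0.05 * cum["MTPD"] + rng.normal(0, 0.4),
                "os_days": 300.0, "os_event": True,
            })
    return pd.DataFrame(doses), pd.DataFrame(outcomes)


class TestComparisonAnalysis:
    def test_strong_negative_link_detected(self, rng):
        doses, outcomes = _toy_doses_outcomes(rng, link=-0.02)
        report = run_comparison_analysis(doses, outcomes, min_cycles_for_cox=1)
        assert report.psa_corr is not None
        assert report.psa_corr["rho_mtpd"] < 0
        assert report.psa_corr["rho_stpd"] < 0
        # both methods see the same observations; the error is a near
        # constant rescaling, so the correlations should not differ
        assert report.psa_corr["fisher"].p_value > 0.05
        assert len(report.cox) == 4

    def test_shuffled_outcomes_break_link(self, rng):
        # permuting PSA values across all patient-cycles removes both
        # the patient- and cycle-level dose structure
        doses, outcomes = _toy_doses_outcomes(rng, link=-0.02)
        shuffled = outcomes.copy()
        mask = shuffled["cycle"] > 0
        shuffled.loc[mask, "psa"] = rng.permutation(
            shuffled.loc[mask, "psa"].to_numpy()
        )
        report = run_comparison_analysis(doses, shuffled)
        assert abs(report.psa_corr["rho_mtpd"]) < 0.3
        assert report.psa_corr["fisher"].p_value > 0.01

    def test_single_method_input_skipped_with_warning(self, rng):
        doses, outcomes = _toy_doses_outcomes(rng)
        mtpd_only = doses[doses["method"] == "MTPD"]
        report = run_comparison_analysis(mtpd_only, outcomes)
        assert report.psa_corr is None
        assert any("single-method" in w for w in report.warnings)

    def test_report_text_mentions_key_statistics(self, rng):
        doses, outcomes = _toy_doses_outcomes(rng)
        text = run_comparison_analysis(doses, outcomes, min_cycles_for_cox=1).to_text()
        assert "Fisher Z" in text and "U-test" in text and "HR" in text
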
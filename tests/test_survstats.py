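"""Unit tests for the censored-survival kernel."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
import pandas as pd

from gepsig.survstats import (
    cox_fit,
    cox_score_test,
    harrell_c,
    km_estimate,
    logrank_test,
    nelson_aalen,
    null_deviance_residuals,
)


class TestNelsonAalen:
    def test_no_events_hazard_is_zero(self):
        na = nelson_aalen([1, 2, 3], [0, 0, 0])
        assert na(3) == 0.0

    @pytest.mark.parametrize(
        "events,expected",
        [([1, 1, 1], 1 / 3 + 1 / 2 + 1), ([1, 0, 1], 1 / 3 + 1)],
    )
    def test_hand_computed_cumulative_hazard(self, events, expected):
        na = nelson_aalen([1, 2, 3], events)
        assert na(3) == pytest.approx(expected, abs=1e-12)

    def test_right_continuous_nondecreasing(self, survival_cohort):
        time, event = survival_cohort
        na = nelson_aalen(time, event)
        grid = np.linspace(0, time.max(), 200)
        vals = na(grid)
        assert np.all(np.diff(vals) >= 0)
        assert na(0) == 0.0

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            nelson_aalen([0.0, 1.0], [1, 1])


class TestDevianceResiduals:
    def test_closed_form_values(self):
        # one event at t=1 among 2 subjects: Lambda(1) = 1/2, so the
        # event subject has m = 1/2; the censored subject at t=2 carries
        # the full hazard m = -3/2
        res = null_deviance_residuals([1.0, 2.0], [1, 0])
        assert res.martingale[0] == pytest.approx(0.5)
        assert res.deviance[0] == pytest.approx(
            np.sqrt(-2 * (0.5 + np.log(0.5))), abs=1e-6
        )

    def test_censored_full_hazard_unit(self):
        # delta=0 with Lambda = 1 gives m = -1, d = -sqrt(2)
        m = -1.0
        d = np.sign(m) * np.sqrt(-2 * m)
        assert d == pytest.approx(-1.41421, abs=1e-5)

    def test_sign_and_zero_match_martingale(self, survival_cohort):
        time, event = survival_cohort
        res = null_deviance_residuals(time, event)
        assert np.all(np.sign(res.deviance) == np.sign(res.martingale))
        assert np.all((res.deviance == 0) == (res.martingale == 0))

    def test_martingale_residuals_sum_to_zero(self, survival_cohort):
        time, event = survival_cohort
        res = null_deviance_residuals(time, event)
        assert abs(res.martingale.sum()) < 1e-9

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            null_deviance_residuals([1, 2, 3], [0, 0, 0])


class TestKaplanMeier:
    def test_all_censored_survival_one_median_undefined(self):
        est = km_estimate([1, 2, 3], [0, 0, 0])
        assert est.survival(3) == 1.0
        assert not est.median_defined

    def test_median_at_half(self):
        est = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert est.survival(2) == pytest.approx(0.5)
        assert est.median == 2

    def test_survival_nonincreasing_random(self, rng):
        for _ in range(100):
            n = rng.integers(3, 40)
            t = rng.exponential(2, n) + 0.01
            e = rng.integers(0, 2, n)
            est = km_estimate(t, e)
            vals = est.survival(np.sort(t))
            assert np.all(np.diff(vals) <= 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_oe_v_table(self):
        # brute-force O/E/V accumulation over the 6 event times
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e, var = 0.0, 0.0
        for tj in np.sort(t):
            at_risk = t >= tj
            n = at_risk.sum()
            n1 = (at_risk & (g == 0)).sum()
            d = ((t == tj) & (e == 1)).sum()
            o = ((t == tj) & (e == 1) & (g == 0)).sum()
            exp = d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
            o_minus_e += o - exp
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_group_relabeling_and_time_shift(self, survival_cohort):
        time, event = survival_cohort
        g = (np.arange(len(time)) % 2 == 0).astype(int)
        s1 = logrank_test(time, event, g)
        s2 = logrank_test(time, event, 1 - g)
        s3 = logrank_test(time + 7.5, event, g)
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(s3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 0, 1], np.ones((4, 1)))

    def test_score_test_equals_logrank(self, survival_cohort):
        time, event = survival_cohort
        x = (np.arange(len(time)) % 2).astype(float)
        stat, _ = logrank_test(time, event, x)
        assert cox_score_test(time, event, x) == pytest.approx(stat, abs=1e-8)

    def test_agrees_with_lifelines(self, rng):
        # continuous times (no ties), so Breslow and Efron coincide
        for _ in range(5):
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.6 * x))
            c = rng.exponential(2.0, n)
            time = np.maximum(np.minimum(t, c), 1e-6)
            event = (t <= c).astype(int)
            fit = cox_fit(time, event, x.reshape(-1, 1), names=["x"])
            cph = CoxPHFitter().fit(
                pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E"
            )
            ref = float(cph.params_["x"])
            assert fit.coef[0] == pytest.approx(ref, rel=1e-4)
            assert fit.se[0] == pytest.approx(
                float(cph.standard_errors_["x"]), rel=1e-3
            )
            assert fit.converged

    def test_parameter_recovery(self, rng):
        hits = 0
        for _ in range(30):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x))
            c = rng.exponential(t.mean() * 2.5, n)
            time = np.maximum(np.minimum(t, c), 1e-9)
            event = (t <= c).astype(int)
            fit = cox_fit(time, event, x.reshape(-1, 1))
            hits += abs(fit.coef[0] - 0.7) < 3 * fit.se[0]
        assert hits >= 27

    def test_ci_brackets_hr(self, survival_cohort):
        time, event = survival_cohort
        x = (np.arange(len(time)) % 2).astype(float)
        fit = cox_fit(time, event, x.reshape(-1, 1))
        assert fit.ci_lower[0] <= fit.hazard_ratio[0] <= fit.ci_upper[0]
        assert fit.hazard_ratio[0] > 0

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders events before all censorings
        time = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = cox_fit(time, event, x.reshape(-1, 1))
        assert fit.monotone_likelihood


class TestHarrellC:
    def test_perfect_and_tied(self):
        assert harrell_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0
        assert harrell_c([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert harrell_c([10, 1, 8, 2], [2, 4, 6, 8], [1, 1, 1, 1]) == pytest.approx(
            4 / 6
        )

    def test_antisymmetry_without_ties(self, rng):
        for _ in range(20):
            n = 25
            s = rng.normal(size=n)
            t = rng.exponential(1, n) + 0.01
            e = rng.integers(0, 2, n)
            if not e.any():
                e[0] = 1
            assert harrell_c(s, t, e) + harrell_c(-s, t, e) == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            s = rng.integers(0, 6, n).astype(float)  # ties likely
            t = (rng.integers(1, 8, n)).astype(float)  # tied times likely
            e = rng.integers(0, 2, n)
            conc = tied = comp = 0
            for i in range(n):
                for j in range(n):
                    if t[i] < t[j] and e[i] == 1:
                        comp += 1
                        if s[i] > s[j]:
                            conc += 1
                        elif s[i] == s[j]:
                            tied += 1
            if comp == 0:
                with pytest.raises(ValueError):
                    harrell_c(s, t, e)
                continue
            assert harrell_c(s, t, e) == (conc + 0.5 * tied) / comp

    def test_agrees_with_lifelines_on_continuous_data(self, rng):
        # independent reference implementation; no ties so conventions agree
        n = 60
        s = rng.normal(size=n)
        t = rng.exponential(1, n) + 0.01
        e = rng.integers(0, 2, n)
        e[0] = 1
        assert harrell_c(s, t, e) == pytest.approx(
            concordance_index(t, -s, e), abs=1e-12
        )
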
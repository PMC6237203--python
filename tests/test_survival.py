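"""Cox fitting, concordance, Wald screening and the evaluation report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histofusion import survival as sv


def brute_force_cindex(risk, time, event):
    """Exhaustive pair enumeration (independent oracle)."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def simulate(n, beta, rng, censor=0.3, binary=True):
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    lam = 0.05 * np.exp(beta * x)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / (0.05 * censor / max(1 - censor, 1e-9))) \
        if censor > 0 else np.full(n, np.inf)
    return x[:, None], np.minimum(t, c), (t <= c).astype(int)


class TestConcordance:
    def test_single_concordant_pair(self):
        assert sv.concordance_index([2, 1], [1, 2], [1, 1]) == 1.0

    def test_single_discordant_pair(self):
        assert sv.concordance_index([1, 2], [1, 2], [1, 1]) == 0.0

    def test_tied_risks_score_half(self):
        assert sv.concordance_index([1, 1], [1, 2], [1, 1]) == 0.5

    def test_censored_early_time_not_admissible(self):
        with pytest.raises(ValueError, match="admissible"):
            sv.concordance_index([1, 2], [1, 2], [0, 1])

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(50):
            n = 30
            risk = rng.normal(size=n).round(1)  # induce ties
            time = rng.exponential(10, size=n).round(0) + 1
            event = (rng.random(n) < 0.7).astype(int)
            if not ((time[:, None] < time[None, :]) &
                    (event[:, None] == 1)).any():
                continue
            assert sv.concordance_index(risk, time, event) == \
                pytest.approx(brute_force_cindex(risk, time, event))

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index as ll_ci

        n = 60
        risk = rng.normal(size=n)
        time = rng.exponential(10, size=n)
        event = (rng.random(n) < 0.7).astype(int)
        ours = sv.concordance_index(risk, time, event)
        # lifelines scores higher-risk-longer-survival; flip sign
        assert ours == pytest.approx(ll_ci(time, -risk, event))

    @given(st.floats(0.1, 5.0), st.floats(-3, 3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, a, b):
        rng = np.random.default_rng(7)
        risk = rng.normal(size=25)
        time = rng.exponential(10, size=25)
        event = (rng.random(25) < 0.8).astype(int)
        c1 = sv.concordance_index(risk, time, event)
        c2 = sv.concordance_index(a * risk + b, time, event)
        assert c1 == pytest.approx(c2)

    def test_sign_flip_maps_to_complement(self, rng):
        risk = rng.normal(size=40)  # continuous: no risk ties
        time = rng.exponential(10, size=40)
        event = (rng.random(40) < 0.7).astype(int)
        c = sv.concordance_index(risk, time, event)
        assert sv.concordance_index(-risk, time, event) == \
            pytest.approx(1 - c)


class TestFitCox:
    def test_recovers_known_hazard_ratio(self, rng):
        X, t, e = simulate(2000, np.log(2.0), rng, censor=0.2)
        fit = sv.fit_cox(X, t, e)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=0.15)
        assert fit.hazard_ratios[0] == pytest.approx(2.0, rel=0.2)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import CoxPHFitter

        X, t, e = simulate(300, 0.8, rng, binary=False)
        x2 = rng.normal(size=300)
        df = pd.DataFrame({"x1": X[:, 0], "x2": x2, "t": t, "e": e})
        fit = sv.fit_cox(df[["x1", "x2"]], t, e)
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(fit.beta, ll.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.se, ll.standard_errors_.to_numpy(), atol=1e-4)

    def test_breslow_ties_option(self, rng):
        X, t, e = simulate(200, 0.7, rng)
        t = np.ceil(t)  # force heavy ties
        fe = sv.fit_cox(X, t, e, ties="efron")
        fb = sv.fit_cox(X, t, e, ties="breslow")
        assert fe.beta[0] != fb.beta[0]
        assert abs(fe.beta[0] - fb.beta[0]) < 0.2

    def test_null_covariate_small_beta(self, rng):
        x = rng.normal(size=500)[:, None]
        t = rng.exponential(10, size=500)
        e = (rng.random(500) < 0.7).astype(int)
        fit = sv.fit_cox(x, t, e)
        assert abs(fit.beta[0]) < 0.2
        assert fit.wald_p[0] > 0.001

    def test_rank_deficiency_rejected(self):
        X = np.zeros((20, 1))
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20, dtype=int)
        with pytest.raises(ValueError, match="rank"):
            sv.fit_cox(X, t, e)

    def test_perfect_separation_detected(self):
        # covariate perfectly ordered with event times -> monotone likelihood
        n = 40
        x = np.linspace(5, -5, n)[:, None]
        t = np.arange(1, n + 1, dtype=float)
        e = np.ones(n, dtype=int)
        with pytest.raises(sv.ConvergenceError):
            sv.fit_cox(x, t, e)

    def test_baseline_cumhaz_monotone(self, rng):
        X, t, e = simulate(100, 0.5, rng)
        fit = sv.fit_cox(X, t, e)
        assert (np.diff(fit.baseline_cumhaz) > 0).all()


class TestWaldSelect:
    def test_alpha_one_selects_all_convergent(self, rng):
        F = rng.normal(size=(100, 5))
        t = rng.exponential(10, size=100)
        e = np.ones(100, dtype=int)
        assert sv.wald_select(F, t, e, alpha=1.0) == [0, 1, 2, 3, 4]

    def test_strong_feature_selected(self, rng):
        X, t, e = simulate(200, 1.5, rng, binary=False)
        F = np.column_stack([X[:, 0], rng.normal(size=200)])
        assert 0 in sv.wald_select(F, t, e)

    def test_too_few_events_rejected(self, rng):
        F = rng.normal(size=(20, 2))
        t = rng.exponential(10, size=20)
        e = np.zeros(20, dtype=int)
        e[:5] = 1
        with pytest.raises(ValueError, match="events"):
            sv.wald_select(F, t, e)


class TestEvaluateBiomarkers:
    def _cohort(self, rng, n=120):
        risk = rng.normal(size=n)
        lam = 0.05 * np.exp(1.0 * risk)
        t = rng.exponential(1 / lam)
        e = (rng.random(n) < 0.75).astype(int)
        bio = pd.DataFrame({
            "b_true": risk + rng.normal(0, 0.3, n),
            "b_noise": rng.normal(size=n),
        })
        clin = pd.DataFrame({
            "psa": rng.lognormal(2.3, 0.5, n),
            "age": rng.normal(62, 8, n),
        })
        return bio, clin, t, e

    def test_true_biomarker_scores_high(self, rng):
        bio, clin, t, e = self._cohort(rng)
        train = np.arange(120) < 80
        rep = sv.evaluate_biomarkers(bio, clin, t, e,
                                     train_mask=train, test_mask=~train)
        assert "b_true" in rep.table.index
        assert rep.best["biomarker_HR"] > 1
        assert rep.best["cindex"] > 0.6

    def test_report_schema_one_hr_per_covariate(self, rng):
        bio, clin, t, e = self._cohort(rng)
        rep = sv.evaluate_biomarkers(bio, clin, t, e)
        for col in ("biomarker_HR", "HR_psa", "HR_age", "cindex"):
            assert col in rep.table.columns

    def test_collinear_clinical_factor_dropped(self, rng):
        bio, clin, t, e = self._cohort(rng)
        clin["age2"] = 2 * clin["age"] + 7
        with pytest.warns(UserWarning, match="collinear"):
            rep = sv.evaluate_biomarkers(bio, clin, t, e)
        assert rep.table["HR_age2"].isna().all()
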
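"""Contingency and survival statistics against hand calculations and
independent reference implementations (scipy, lifelines)."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from omrs.cohort_stats import (
    ContingencyTable2x2,
    cox_fit,
    encode_covariates,
    fisher_exact,
    fisher_table_probabilities,
    km_fit,
    log_rank,
    odds_ratio,
    progression_table,
    survival_at,
)
from omrs.synthetic import SyntheticCohortSpec, generate_cohort_records

tables = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: sum(t) >= 1)


def random_cohort(rng, n_lo=5, n_hi=40, round_times=True):
    n = int(rng.integers(n_lo, n_hi))
    t = rng.exponential(3, n) + 0.05
    if round_times:
        t = np.round(t, 1) + 0.05  # force ties
    e = rng.integers(0, 2, n)
    if e.sum() == 0:
        e[0] = 1
    return t, e


class TestOddsRatio:
    def test_symmetric_table(self):
        r = odds_ratio(ContingencyTable2x2(5, 5, 5, 5))
        assert r.or_estimate == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_zero_cell_triggers_haldane_correction(self):
        r = odds_ratio(ContingencyTable2x2(5, 0, 3, 4))
        assert r.corrected
        assert r.or_estimate == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    @settings(deadline=None, derandomize=True)
    @given(tables.filter(lambda t: min(t) >= 1))
    def test_group_transpose_inverts_or_and_ci(self, cells):
        a, b, c, d = cells
        r = odds_ratio(ContingencyTable2x2(a, b, c, d))
        rt = odds_ratio(ContingencyTable2x2(c, d, a, b))
        assert rt.or_estimate == pytest.approx(1 / r.or_estimate)
        assert rt.ci_low == pytest.approx(1 / r.ci_high)
        assert rt.ci_high == pytest.approx(1 / r.ci_low)


class TestFisherExact:
    def test_modal_balanced_table_p_one(self):
        # a table at the hypergeometric mode has nothing more extreme
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(tables)
    def test_enumeration_conserves_probability(self, cells):
        _, probs = fisher_table_probabilities(ContingencyTable2x2(*cells))
        assert abs(probs.sum() - 1.0) < 1e-12

    @settings(deadline=None, derandomize=True)
    @given(tables)
    def test_matches_scipy_reference(self, cells):
        a, b, c, d = cells
        ours = fisher_exact(ContingencyTable2x2(a, b, c, d))
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, abs=1e-10)


class TestKaplanMeier:
    def test_three_events_hand_product_limit(self):
        c = km_fit([1, 2, 3], [1, 1, 1])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_single_event_first_step(self):
        n = 8
        times = [1.0] + [2.0 + i for i in range(n - 1)]
        events = [1] + [0] * (n - 1)
        c = km_fit(times, events)
        assert c.survival[0] == pytest.approx((n - 1) / n)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(2, 50), 1) + 0.1
        c = km_fit(t, np.ones(50, int))
        for tau, s in zip(c.event_times, c.survival):
            assert s == pytest.approx((t > tau).mean(), abs=1e-12)

    def test_no_events_degenerate(self):
        c = km_fit([1, 2, 3], [0, 0, 0])
        assert c.degenerate
        assert survival_at(c, 2.0).survival == 1.0

    def test_matches_lifelines_on_random_cohorts(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t, e = random_cohort(rng)
            c = km_fit(t, e)
            ref = KaplanMeierFitter().fit(t, e)
            refs = ref.survival_function_at_times(c.event_times).to_numpy()
            assert np.max(np.abs(refs - c.survival)) < 1e-10

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            km_fit([1.0, 2.0], [1, 2])


class TestSurvivalAt:
    def test_before_first_event_is_one(self):
        c = km_fit([2, 3, 4], [1, 1, 0])
        assert survival_at(c, 1.0).survival == 1.0

    def test_right_continuous_at_event_time(self):
        c = km_fit([1, 2, 3], [1, 1, 1])
        assert survival_at(c, 1.0).survival == pytest.approx(2 / 3)

    def test_beyond_follow_up_flagged_extrapolated(self):
        c = km_fit([1, 2, 3], [1, 1, 0])
        est = survival_at(c, 10.0)
        assert est.extrapolated
        assert est.survival == pytest.approx(c.survival[-1])

    def test_ci_brackets_estimate_both_transforms(self):
        c = km_fit([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0])
        for transform in ("log", "plain"):
            est = survival_at(c, 3.5, transform=transform)
            assert est.ci_low <= est.survival <= est.ci_high

    def test_exponential_cohort_matches_closed_form(self):
        lam, n = 0.15, 2000
        spec = SyntheticCohortSpec(
            n_patients=n, baseline_hazard=lam, log_hazard_coeff=0.0,
            admin_censor_time=12.0, seed=10,
        )
        df = generate_cohort_records(spec)
        c = km_fit(df["ttp_years"], df["event"])
        p_true = 1 - math.exp(-5 * lam)
        est = survival_at(c, 5.0)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs((1 - est.survival) - p_true) < 3 * se


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi, p = log_rank((t, e), (t, e))
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        early = ([1, 1.5, 2, 2.5, 3, 3.5], [1] * 6)
        late = ([10] * 6, [0] * 6)
        chi, p = log_rank(early, late)
        assert p < 0.01

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank(([1.0], [0]), ([2.0], [0]))

    def test_matches_lifelines_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ta, ea = random_cohort(rng)
            tb, eb = random_cohort(rng)
            chi, p = log_rank((ta, ea), (tb, eb))
            ref = logrank_test(ta, tb, ea, eb)
            assert abs(chi - ref.test_statistic) < 1e-8
            assert abs(p - ref.p_value) < 1e-8


def brute_force_partial_likelihood(beta, t, e, x):
    """Independent explicit partial likelihood (no ties in the fixture)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = [j for j in range(len(t)) if t[j] >= t[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    fixture = dict(
        t=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        e=[1, 0, 1, 1, 0, 1],
        x=[1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
    )

    def df6(self):
        return pd.DataFrame(
            {"ttp_years": self.fixture["t"], "event": self.fixture["e"], "x": self.fixture["x"]}
        )

    def test_constant_covariate_gives_null_fit(self):
        df = self.df6().assign(z=0.0)
        fit = cox_fit(df, ["z"])
        assert fit.coefficients[0] == 0.0
        assert fit.hazard_ratios[0] == 1.0
        assert fit.wald_p[0] == pytest.approx(1.0)

    def test_matches_brute_force_maximization(self):
        from scipy.optimize import minimize_scalar

        fit = cox_fit(self.df6(), ["x"])
        res = minimize_scalar(
            lambda b: -brute_force_partial_likelihood(b, **self.fixture),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(fit.coefficients[0] - res.x) < 1e-6
        assert fit.converged

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_with_tied_times(self, ties):
        rng = np.random.default_rng(21)
        t, e = random_cohort(rng, 25, 26)
        x = rng.integers(0, 2, len(t)).astype(float)
        df = pd.DataFrame({"ttp_years": t, "event": e, "x": x})
        fit = cox_fit(df, ["x"], ties=ties)
        cph = CoxPHFitter()
        # lifelines implements the Efron correction
        if ties == "efron":
            cph.fit(df, "ttp_years", "event", fit_options={"precision": 1e-9})
            assert fit.coefficients[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
            assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)
        else:
            assert fit.converged

    def test_score_vanishes_at_optimum(self):
        from omrs.cohort_stats import _cox_loglik

        rng = np.random.default_rng(31)
        for ties in ("efron", "breslow"):
            t, e = random_cohort(rng, 30, 60)
            x1 = rng.normal(size=len(t))
            x2 = rng.integers(0, 2, len(t)).astype(float)
            df = pd.DataFrame({"ttp_years": t, "event": e, "x1": x1, "x2": x2})
            fit = cox_fit(df, ["x1", "x2"], ties=ties)
            assert fit.converged
            order = np.argsort(-t, kind="stable")
            ts, es, Xs = t[order], e[order], np.c_[x1, x2][order]
            groups = []
            i = 0
            while i < len(ts):
                j = i
                while j < len(ts) and ts[j] == ts[i]:
                    j += 1
                groups.append((slice(i, j), es[i:j].astype(bool)))
                i = j
            _, g, _ = _cox_loglik(fit.coefficients, Xs, groups, ties, True)
            assert np.abs(g).max() < 1e-6

    def test_multivariate_recovers_generating_coefficient(self):
        spec = SyntheticCohortSpec(n_patients=800, seed=17)
        df = generate_cohort_records(spec)
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        fit = cox_fit(df, ["true_theta", "noise"])
        beta = math.log(3.0)
        assert abs(fit.coefficients[0] - beta) < 3 * fit.se[0]
        assert abs(fit.coefficients[1]) < 3 * fit.se[1]
        ref = CoxPHFitter().fit(
            df[["true_theta", "noise", "ttp_years", "event"]], "ttp_years", "event"
        )
        assert np.allclose(fit.coefficients, ref.params_.to_numpy(), atol=1e-6)

    def test_perfect_separation_flagged(self):
        # every event carries x=1, every censored x=0: monotone likelihood
        df = pd.DataFrame(
            {
                "ttp_years": [1, 2, 3, 4, 10, 11, 12, 13],
                "event": [1, 1, 1, 1, 0, 0, 0, 0],
                "x": [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            }
        )
        fit = cox_fit(df, ["x"])
        assert fit.monotone_likelihood
        assert not fit.converged

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"ttp_years": [1.0, 2.0], "event": [1, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])


class TestCohortEncoding:
    def test_indicators_and_progression_table(self):
        df = pd.DataFrame(
            {
                "event": [1, 0, 1, 0],
                "group": ["high", "high", "low", "low"],
                "site": ["tongue", "other", "tongue", "other"],
                "dysplasia": ["moderate/severe", "none/mild"] * 2,
                "gender": ["F", "M", "M", "F"],
                "prior_oscc": ["yes", "no", "no", "no"],
                "aveh": ["present", "absent", "absent", "absent"],
            }
        )
        enc = encode_covariates(df)
        assert enc["risk_high"].tolist() == [1, 1, 0, 0]
        assert enc["site_tongue"].tolist() == [1, 0, 1, 0]
        assert enc["dysplasia_high"].tolist() == [1, 0, 1, 0]
        table = progression_table(enc)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)
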
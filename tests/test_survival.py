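import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tinstab as ts
from tinstab.io import ValidationError
from tinstab.survival import (CoxModel, build_survival_groups, cox_ph,
                              kaplan_meier, logrank_test)


def surv_table(times, events, groups, **covs):
    df = pd.DataFrame({"time_years": times, "event": events,
                       "group": np.asarray(groups, dtype=bool)},
                      index=[f"P{i}" for i in range(len(times))])
    for k, v in covs.items():
        df[k] = v
    return df


def sim_cohort(rng, n=200, hr=3.0, frac=0.5, h0=0.1, censor=10.0):
    group = rng.random(n) < frac
    t = rng.exponential(1.0 / (h0 * np.exp(np.log(hr) * group)))
    return surv_table(np.minimum(t, censor), (t <= censor).astype(int), group)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = kaplan_meier(surv_table([1.0, 2.0, 3.0], [1, 0, 1], [1, 1, 1]))
        assert km.survival_at(1.0)[True] == pytest.approx(2 / 3)
        assert km.survival_at(2.5)[True] == pytest.approx(2 / 3)
        assert km.survival_at(3.0)[True] == pytest.approx(0.0)

    def test_no_events_gives_unit_survival(self):
        km = kaplan_meier(surv_table([1.0, 2.0, 3.0], [0, 0, 0], [1, 1, 1]))
        assert km.survival_at(3.0)[True] == pytest.approx(1.0)

    def test_no_censoring_reduces_to_empirical_survivor(self, rng):
        t = np.sort(rng.exponential(5.0, 20))
        km = kaplan_meier(surv_table(t, np.ones(20, int), np.ones(20, int)))
        for q in (t[4], t[12]):
            emp = (t > q).mean()
            assert km.survival_at(q)[True] == pytest.approx(emp)


def oracle_logrank(times, events, groups):
    """Hand-tabulated O/E and hypergeometric variance, 1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        table = surv_table(t + t, e + e, [1] * 4 + [0] * 4)
        chi2, p = logrank_test(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5]
        events = [1, 1, 0, 1, 1, 1, 1, 0]
        groups = [1, 1, 1, 1, 0, 0, 0, 0]
        chi2, p = logrank_test(surv_table(times, events, groups))
        assert chi2 == pytest.approx(oracle_logrank(times, events, groups), abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(chi2, df=1), abs=1e-9)

    def test_statistic_symmetric_under_label_swap(self, rng):
        table = sim_cohort(rng, n=60)
        chi2a, pa = logrank_test(table)
        flipped = table.assign(group=~table["group"])
        chi2b, pb = logrank_test(flipped)
        assert chi2a == pytest.approx(chi2b, abs=1e-9)
        assert pa == pytest.approx(pb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(surv_table([1.0, 2.0], [1, 1], [1, 1]))


def oracle_partial_loglik(beta, times, events, x):
    """Breslow-form partial log-likelihood written straight from the formula
    (no ties in the fixtures that use it)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_tiny_cohort_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 0, 1, 1]
        x = [1, 0, 1, 0, 1]
        table = surv_table(times, events, x)
        res = cox_ph(table, ["group"])
        grid = np.arange(-4.0, 4.0, 1e-4)
        ll = [oracle_partial_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert res.params.loc["group", "coef"] == pytest.approx(best, abs=1e-4)
        assert res.loglik == pytest.approx(max(ll), abs=1e-6)

    def test_matches_lifelines_on_simulated_cohort(self, rng):
        """Independent cross-check: coefficients and SEs from the in-package
        Newton fit agree with lifelines' Efron fit."""
        from lifelines import CoxPHFitter

        table = sim_cohort(rng, n=150)
        table["age"] = rng.normal(70, 10, len(table))
        res = cox_ph(table, ["group", "age"])
        cph = CoxPHFitter()
        cph.fit(table.assign(group=table["group"].astype(int)),
                duration_col="time_years", event_col="event",
                formula="group + age")
        for cov in ("group", "age"):
            assert res.params.loc[cov, "coef"] == pytest.approx(
                cph.params_[cov], abs=1e-5)
            assert res.params.loc[cov, "se"] == pytest.approx(
                cph.standard_errors_[cov], abs=1e-5)

    def test_breslow_ties_differ_from_efron_with_ties(self, rng):
        table = sim_cohort(rng, n=80)
        table["time_years"] = np.round(table["time_years"], 0) + 0.5
        efron = cox_ph(table, ["group"], ties="efron")
        breslow = cox_ph(table, ["group"], ties="breslow")
        assert efron.params.loc["group", "coef"] != pytest.approx(
            breslow.params.loc["group", "coef"], abs=1e-8)

    def test_duplicated_covariate_rejected(self, rng):
        table = sim_cohort(rng, n=50)
        table["group2"] = table["group"].astype(float)
        with pytest.raises(ValidationError, match="singular|collinear"):
            cox_ph(table, ["group", "group2"])

    def test_constant_covariate_rejected(self, rng):
        table = sim_cohort(rng, n=30)
        table["flat"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            cox_ph(table, ["group", "flat"])

    def test_perfect_separation_rejected(self):
        # all events in one group, occurring strictly before the other group's times
        times = [1.0, 1.5, 2.0, 10.0, 11.0, 12.0]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        with pytest.raises(ValidationError, match="separation|converge"):
            cox_ph(surv_table(times, events, x), ["group"])

    def test_ci_and_hr_consistency(self, rng):
        res = cox_ph(sim_cohort(rng), ["group"])
        row = res.params.loc["group"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_high"] == pytest.approx(np.exp(row["coef"] + 1.96 * row["se"]))

    def test_recovers_log_hr_within_2_se(self, rng):
        res = cox_ph(sim_cohort(rng, n=500, hr=3.0), ["group"])
        row = res.params.loc["group"]
        assert abs(row["coef"] - np.log(3.0)) < 2 * row["se"]


class TestBuildGroups:
    @staticmethod
    def profiles(stin, otin):
        n = len(stin)
        return pd.DataFrame({"is_sTIN": stin, "is_oTIN": otin},
                            index=[f"S{i}" for i in range(n)])

    @staticmethod
    def clinical(n):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "time_years": rng.exponential(5, n) + 0.1,
            "event": rng.integers(0, 2, n),
            "stage": ["II"] * n, "msi": [0] * n, "age": [70] * n,
            "sex": ["F"] * n, "location": ["right"] * n,
        }, index=[f"S{i}" for i in range(n)])

    def test_scheme_either_is_union(self):
        prof = self.profiles([True, False, False, False],
                             [False, True, False, False])
        table = build_survival_groups(prof, self.clinical(4), "either")
        assert table["group"].sum() == 2

    def test_scheme_both_without_double_positives_rejected(self):
        prof = self.profiles([True, False, False], [False, True, False])
        with pytest.raises(ValidationError, match="degenerate"):
            build_survival_groups(prof, self.clinical(3), "both")

    def test_group_sizes_match_flag_counts(self, tin_default, default_sim):
        table = build_survival_groups(tin_default.profiles, default_sim.clinical,
                                      "oTIN")
        assert table["group"].sum() == tin_default.profiles["is_oTIN"].sum()

    def test_missing_clinical_record_rejected_unless_allowed(self):
        prof = self.profiles([True, False, False], [False, False, True])
        clin = self.clinical(2)
        with pytest.raises(ValidationError, match="clinical"):
            build_survival_groups(prof, clin, "either")
        table = build_survival_groups(prof, clin, "either", allow_subset=True)
        assert len(table) == 2


def test_min_event_times_required():
    table = surv_table([1.0, 1.0, 2.0], [1, 1, 0], [1, 0, 1])
    with pytest.raises(ValidationError, match="event times"):
        CoxModel(table, ["group"])
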
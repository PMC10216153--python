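import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cansurv
from cansurv.relsurv import (AgeGroupWeights, PeriodDataset, SurvivalEstimate,
                             age_standardize, age_standardized_estimate,
                             build_period_dataset, conditional_ratio,
                             expected_survival, pohar_perme,
                             records_to_dataset)
from cansurv.synthetic import (CohortSpec, ExcessHazard, IndividualRecord,
                               simulate_cohort)
from conftest import random_small_dataset
from pp_oracle import pohar_perme_naive


def make_record(age=60.0, date=2000.0, t=1.0, event="censored"):
    return IndividualRecord(0, "all", "XX", age, date, t, event)


class TestExpectedSurvival:
    def test_unit_table_gives_one(self, unit_lt):
        assert expected_survival(make_record(), unit_lt, 7.3) == 1.0

    def test_constant_table_closed_form(self):
        lt = cansurv.LifeTable("all", "XX", np.arange(1960, 2023),
                               np.full((110, 63), 0.9))
        r = make_record()
        assert expected_survival(r, lt, 3.0) == pytest.approx(0.9**3)
        assert expected_survival(r, lt, 2.5) == pytest.approx(0.9**2.5)

    def test_age_varying_table_hand_product(self):
        surv = np.full((110, 63), 0.95)
        surv[61] = 0.90
        surv[62] = 0.85
        lt = cansurv.LifeTable("all", "XX", np.arange(1960, 2023), surv)
        # diagnosis at exact age 60 on 1 Jan: ages 60, 61 then half of 62
        want = 0.95 * 0.90 * 0.85**0.5
        got = expected_survival(make_record(age=60.0, date=2000.0), lt, 2.5)
        assert got == pytest.approx(want, abs=1e-12)

    def test_negative_time_rejected(self, unit_lt):
        with pytest.raises(ValueError):
            expected_survival(make_record(), unit_lt, -1.0)


class TestPoharPerme:
    def test_single_patient_death(self, unit_lt):
        recs = [make_record(t=2.0, event="death")]
        res = pohar_perme(recs, unit_lt, [1.0, 5.0])
        assert res.survival[0] == 1.0
        assert res.survival[1] == 0.0

    def test_reduces_to_kaplan_meier_exactly(self, unit_lt):
        """Unit expected survival: estimator == KM at every event time."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(42)
        for _ in range(25):
            ds = random_small_dataset(rng, n_max=50, truncated=False)
            T, E = ds.exit, ds.event
            ev = np.unique(T[E])
            if ev.size == 0:
                continue
            km = KaplanMeierFitter().fit(T, E)
            want = km.survival_function_at_times(ev).values
            got = pohar_perme(ds, unit_lt, ev).survival
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_bruteforce_oracle_small_cohorts(self, gm_lt):
        """Direct-enumeration oracle equivalence on cohorts of size <= 10."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            ds = random_small_dataset(rng, n_max=10)
            ev = [0.5, 1.0, 2.5, 5.0]
            res = pohar_perme(ds, gm_lt, ev)
            oracle = pohar_perme_naive(ds, gm_lt, ev)
            for j, (s, v) in enumerate(oracle):
                if np.isnan(res.survival[j]):
                    continue
                assert res.survival[j] == pytest.approx(s, abs=1e-10)
                assert res.sigma2[j] == pytest.approx(v, abs=1e-10)

    def test_net_survival_can_exceed_one(self, gm_lt):
        """All-censored elderly cohort out-survives the population."""
        ds = PeriodDataset(age=np.full(5, 85.0), date=np.full(5, 2000.0),
                           entry=np.zeros(5), exit=np.full(5, 6.0),
                           event=np.zeros(5, dtype=bool))
        res = pohar_perme(ds, gm_lt, [5.0])
        assert res.survival[0] > 1.0

    def test_undefined_after_exhaustion_flagged(self, unit_lt):
        recs = [make_record(t=2.0, event="censored")]
        with pytest.warns(RuntimeWarning, match="risk set exhausted"):
            res = pohar_perme(recs, unit_lt, [1.0, 5.0])
        assert res.survival[0] == 1.0 and np.isnan(res.survival[1])

    def test_constant_excess_hazard_recovery(self, gm_lt):
        """Net survival converges to exp(-lam t) despite background deaths."""
        spec = CohortSpec(n_patients=6000, period=(2005.0, 2010.0),
                          age_mean=70.0, age_sd=8.0,
                          excess=ExcessHazard("constant", lam=0.1386),
                          emigration_rate=0.0, seed=11)
        recs = simulate_cohort(spec, gm_lt)
        res = pohar_perme(recs, gm_lt, [5.0])
        assert res.survival[0] == pytest.approx(np.exp(-0.693), abs=0.03)

    def test_empty_dataset_rejected(self, unit_lt):
        with pytest.raises(ValueError):
            pohar_perme([], unit_lt, [1.0])


class TestAgeStandardize:
    W = AgeGroupWeights()

    def est(self, e, var=1.0, n=10):
        return SurvivalEstimate(e, var, (e - 1, e + 1), n)

    def test_equal_estimates_any_weights(self):
        per = {g: self.est(80.0) for g in range(5)}
        assert age_standardize(per, self.W).estimate == pytest.approx(80.0)

    def test_two_group_arithmetic(self):
        w = AgeGroupWeights(boundaries=(0.0, 65.0, 90.0), weights=(0.25, 0.75))
        per = {0: self.est(60.0), 1: self.est(90.0)}
        out = age_standardize(per, w)
        assert out.estimate == pytest.approx(82.5)
        assert out.variance == pytest.approx(0.25**2 + 0.75**2)

    def test_empty_group_renormalizes(self):
        per = {0: self.est(50.0), 1: self.est(70.0), 2: None,
               3: self.est(80.0), 4: self.est(90.0)}
        with pytest.warns(RuntimeWarning, match="renormalized"):
            out = age_standardize(per, self.W)
        w = np.array([0.07, 0.12, 0.29, 0.29])
        w = w / w.sum()
        want = np.dot(w, [50.0, 70.0, 80.0, 90.0])
        assert out.estimate == pytest.approx(want)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError, match="all age groups empty"):
            age_standardize({g: None for g in range(5)}, self.W)

    def test_standardized_equals_crude_single_occupied_group(self, unit_lt):
        rng = np.random.default_rng(3)
        n = 40
        ds = PeriodDataset(age=rng.uniform(55.1, 64.9, n),
                           date=rng.uniform(2000, 2005, n),
                           entry=np.zeros(n),
                           exit=rng.uniform(0.1, 6.0, n),
                           event=rng.random(n) < 0.5)
        with pytest.warns(RuntimeWarning):
            std = age_standardized_estimate(ds, unit_lt, 5.0)
        crude = pohar_perme(ds, unit_lt, [5.0]).at(5.0)
        assert std.estimate == pytest.approx(crude.estimate, abs=1e-10)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            AgeGroupWeights(boundaries=(0.0, 50.0, 90.0), weights=(0.6, 0.6))


class TestPeriodDataset:
    def make_records(self):
        recs = []
        for i, (date, fut, ev) in enumerate([
            (1972.0, 10.0, "death"), (1974.5, 2.0, "death"),
            (2013.0, 8.0, "censored"), (2014.0, 7.0, "death"),
            (2017.5, 3.5, "censored"), (2018.0, 3.0, "death"),
        ]):
            recs.append(IndividualRecord(i, "all", "XX", 60.0, date, fut, ev))
        return recs

    def test_cohort_mode_truncates_at_horizon(self):
        ds = build_period_dataset(self.make_records(), (1971.0, 1976.0),
                                  "cohort", horizon=5.0)
        assert ds.n == 2
        assert ds.exit.tolist() == [5.0, 2.0]
        assert ds.event.tolist() == [False, True]  # death at 10y > horizon

    def test_hybrid_left_truncates_penultimate_diagnoses(self):
        """A patient diagnosed in 2014 enters the 2016-2020 window at 2y."""
        ds = build_period_dataset(self.make_records(), (2016.0, 2021.0),
                                  "hybrid", horizon=5.0)
        i = int(np.argmin(np.abs(ds.date - 2014.0)))
        assert ds.entry[i] == pytest.approx(2.0)

    def test_hybrid_person_time_inside_window(self):
        """No hybrid person-time predates the final window start."""
        ds = build_period_dataset(self.make_records(), (2016.0, 2021.0),
                                  "hybrid", horizon=5.0)
        assert np.all(ds.date + ds.entry >= 2016.0 - 1e-9)
        assert np.all(ds.date + ds.exit <= 2021.0 + 1e-9)

    def test_hybrid_without_predecessor_rejected(self):
        with pytest.raises(ValueError, match="penultimate"):
            build_period_dataset(self.make_records(), (1971.0, 1976.0),
                                 "hybrid", horizon=5.0,
                                 analysis_start=1971.0)

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            build_period_dataset([], (2000.0, 2005.0), "cohort", horizon=3.0)


class TestConditionalRatio:
    def est(self, e, var=1.0):
        return SurvivalEstimate(e, var, (e - 1, e + 1), 10)

    def test_identity(self):
        out = conditional_ratio(self.est(80.0), self.est(80.0))
        assert out.estimate == pytest.approx(100.0)

    def test_arithmetic(self):
        out = conditional_ratio(self.est(75.0), self.est(90.0))
        assert out.estimate == pytest.approx(83.3333333333)

    @given(s5=st.floats(1.0, 99.0), s1=st.floats(1.0, 99.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_product_recovers_five_year(self, s5, s1):
        ratio = conditional_ratio(self.est(s5), self.est(s1))
        assert self.est(s1).estimate * ratio.estimate / 100.0 == \
            pytest.approx(s5, rel=1e-12)

    def test_zero_one_year_rejected(self):
        with pytest.raises(ValueError):
            conditional_ratio(self.est(50.0), self.est(0.0))


class TestCoverage:
    def test_ci_coverage_constant_excess_hazard(self, unit_lt):
        """~95% CI coverage of true net survival across replicates."""
        truth = np.exp(-0.1386 * 5)
        covered = 0
        reps = 60
        for rep in range(reps):
            spec = CohortSpec(n_patients=1500, period=(2011.0, 2016.0),
                              excess=ExcessHazard("constant", lam=0.1386),
                              emigration_rate=0.0, seed=1000 + rep)
            recs = simulate_cohort(spec, unit_lt)
            res = pohar_perme(recs, unit_lt, [5.0])
            lo, hi = res.ci
            covered += lo[0] <= truth <= hi[0]
        assert 0.88 <= covered / reps <= 1.0
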
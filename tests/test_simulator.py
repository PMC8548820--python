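"""Simulator tests: single events, detection legs, surgery, cohorts."""

import numpy as np
import pytest
from scipy import stats

from relapsim import (
    ModelParams,
    TissueState,
    advance_event,
    apply_surgery,
    classify_tissue,
    deterministic_growth_time,
    run_tissue_for,
    simulate_cohort,
    simulate_patient,
    simulate_until_detection,
    read_cohort,
)
from relapsim.simulator import derive_seeds
from relapsim._engine import _tissue_absorb


class TestDeterministicGrowthTime:
    def test_already_at_detection(self):
        p = ModelParams(N=1000, r2=1.5, d2=1.0)
        assert deterministic_growth_time(p, p.M_detect) == 0.0

    @pytest.mark.parametrize(
        "r2, expected",
        [(1.2, np.log(1e9 / 2000) / 0.2), (1.5, np.log(1e9 / 2000) / 0.5)],
    )
    def test_closed_form(self, r2, expected):
        # ln(5e5)/0.2 ~ 65.61 d and ln(5e5)/0.5 ~ 26.24 d
        p = ModelParams(N=1000, r2=r2, d2=1.0)
        t = deterministic_growth_time(p, 2000)
        assert t == pytest.approx(expected)
        assert t == pytest.approx({1.2: 65.61, 1.5: 26.24}[r2], abs=0.01)

    def test_domain_errors(self):
        p = ModelParams(N=1000, r2=1.5, d2=1.0)
        with pytest.raises(ValueError):
            deterministic_growth_time(p, 0.0)
        with pytest.raises(ValueError):
            deterministic_growth_time(p, 2e9)


class TestApplySurgery:
    def test_preserves_type1_and_clock(self):
        s = TissueState(i=350, x2=10**9, t=123.4, t_last_founding=99.0)
        out = apply_surgery(s)
        assert (out.i, out.x2, out.t) == (350, 0, 123.4)
        assert out.t_last_founding is None

    def test_idempotent(self):
        s = TissueState(i=0, x2=10**9, t=5.0)
        once = apply_surgery(s)
        assert apply_surgery(once) == once


class TestAdvanceEvent:
    def test_silent_tissue_only_advances_clock(self):
        p = ModelParams(N=1000, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0)
        s = TissueState(i=0, x2=0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            s2 = advance_event(s, p, rng)
            assert (s2.i, s2.x2) == (0, 0)
            assert s2.t > s.t
            s = s2

    def test_tumor_extinction_fraction_matches_competing_rates(self):
        # from x2=1 with a frozen tissue, the next tumor event is a
        # death with probability d2/(r2+d2)
        p = ModelParams(N=1000, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0)
        rng = np.random.default_rng(1)
        n, deaths = 4000, 0
        for _ in range(n):
            s = TissueState(i=0, x2=1)
            while True:
                s = advance_event(s, p, rng)
                if s.x2 != 1:
                    deaths += s.x2 == 0
                    break
        frac = deaths / n
        expected = 1.0 / 2.5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_founder_emission_records_founding_time(self):
        # i = N with mu2 = 1: every turnover event emits a founder
        p = ModelParams(N=100, mu1=0.0, mu2=1.0, r2=1.5, d2=1.0)
        s = TissueState(i=100, x2=0)
        rng = np.random.default_rng(2)
        while s.x2 == 0:
            s = advance_event(s, p, rng)
        assert s.t_last_founding == s.t


class TestRunTissueFor:
    def test_zero_duration_is_identity(self):
        p = ModelParams(N=100, mu1=0.01, mu2=0.01, r2=1.5, d2=1.0)
        s = TissueState(i=10, t=5.0)
        assert run_tissue_for(p, s, 0.0, np.random.default_rng(0)) == s

    def test_no_mutation_no_type1_stays_empty(self):
        p = ModelParams(N=100, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0)
        s = run_tissue_for(p, TissueState(i=0), 500.0, np.random.default_rng(0))
        assert s.i == 0
        assert s.t == 500.0

    def test_neutral_absorption(self):
        p = ModelParams(N=20, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0)
        rng = np.random.default_rng(3)
        ends = [
            run_tissue_for(p, TissueState(i=10), 1e5, rng).i for _ in range(60)
        ]
        assert set(ends) <= {0, 20}
        assert 0 in ends and 20 in ends


class TestMoranFixation:
    """The embedded Type1 chain with mu1 = mu2 = 0 is the standard
    Moran birth-death chain; fixation from i=1 has the classic closed
    form."""

    N = 20
    REPS = 5000

    def _fixation_fraction(self, r1, seed0):
        fixed = 0
        for k in range(self.REPS):
            fixed += _tissue_absorb(seed0 + k, self.N, 1.0, 1.0, r1, 1) == self.N
        return fixed / self.REPS

    def test_neutral_fixation_is_one_over_N(self):
        frac = self._fixation_fraction(1.0, 10_000)
        expected = 1.0 / self.N
        se = np.sqrt(expected * (1 - expected) / self.REPS)
        assert abs(frac - expected) < 3 * se

    def test_selective_fixation_closed_form(self):
        r1 = 1.2
        gamma = 1.0 / r1
        expected = (1 - gamma) / (1 - gamma**self.N)
        frac = self._fixation_fraction(r1, 20_000)
        se = np.sqrt(expected * (1 - expected) / self.REPS)
        assert abs(frac - expected) < 3 * se


class TestSimulateUntilDetection:
    def test_impossible_cancer_censors_at_horizon(self):
        p = ModelParams(N=100, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0, t_max=200.0)
        res, state = simulate_until_detection(
            p, TissueState(), np.random.default_rng(0))
        assert res.censored
        assert res.t_detect == p.t_max

    def test_pure_deterministic_leg(self):
        p = ModelParams(N=1000, mu1=0.001, mu2=0.001, r2=1.5, d2=1.0)
        s = TissueState(i=0, x2=2000, t=10.0)
        res, _ = simulate_until_detection(p, s, np.random.default_rng(0))
        assert not res.censored
        assert res.t_detect == pytest.approx(10.0 + np.log(1e9 / 2000) / 0.5)

    def test_detection_happens_at_moderate_parameters(self, moderate_params):
        times = []
        rng = np.random.default_rng(5)
        for _ in range(20):
            res, _ = simulate_until_detection(moderate_params, TissueState(), rng)
            assert not res.censored
            assert res.t_founding is not None
            assert res.t_founding <= res.t_detect
            times.append(res.t_detect)
        assert np.isfinite(np.median(times))


class TestPatientAndCohort:
    def test_patient_deterministic_in_seed(self, moderate_params):
        a = simulate_patient(moderate_params, 123)
        b = simulate_patient(moderate_params, 123)
        assert a == b

    def test_no_mutation_censors_both_legs(self):
        p = ModelParams(N=100, mu1=0.0, mu2=0.0, r2=1.5, d2=1.0, t_max=50.0)
        r = simulate_patient(p, 1)
        assert r.detection_censored and r.recurrence_censored

    def test_class_consistency(self, fast_params):
        for seed in range(10):
            r = simulate_patient(fast_params, seed)
            assert r.class_at_surgery == classify_tissue(
                r.i_at_first_surgery, fast_params.N)
            assert r.t_recurrence > 0

    def test_cohort_reproducible_and_matches_single_runs(self, fast_params):
        c1 = simulate_cohort(fast_params, 20, master_seed=9)
        c2 = simulate_cohort(fast_params, 20, master_seed=9)
        assert c1.table.equals(c2.table)
        seeds = derive_seeds(9, 20)
        r0 = simulate_patient(fast_params, int(seeds[0]))
        row = c1.table.iloc[0]
        assert row.t_first_detection == r0.t_first_detection
        assert row.i_at_first_surgery == r0.i_at_first_surgery
        assert row.t_recurrence == r0.t_recurrence

    def test_disjoint_master_seeds_same_distribution(self, moderate_params):
        """Recurrence times from disjoint seed streams are statistically
        indistinguishable (KS at alpha = 0.01, 200 vs 200)."""
        a = simulate_cohort(moderate_params, 200, master_seed=101)
        b = simulate_cohort(moderate_params, 200, master_seed=202)
        ta = a.recurrence_events["t_recurrence"]
        tb = b.recurrence_events["t_recurrence"]
        assert stats.ks_2samp(ta, tb).pvalue > 0.01

    def test_tsv_roundtrip(self, fast_params, tmp_path):
        c = simulate_cohort(fast_params, 15, master_seed=3)
        path = tmp_path / "cohort.tsv"
        c.write_tsv(path)
        back = read_cohort(path)
        assert back.shape == c.table.shape
        assert np.allclose(back.t_recurrence, c.table.t_recurrence)
        assert (back.class_at_surgery == c.table.class_at_surgery).all()
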
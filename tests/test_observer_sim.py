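import numpy as np
import pytest

from metaroc import observer_sim as osim
from metaroc.observer_sim import (
    ExperimentConfig,
    ObserverParams,
    StaircaseState,
    staircase_update,
)


class TestStaircase:
    def test_two_correct_in_a_row_shrinks_soa(self):
        state = staircase_update(StaircaseState(30.0, 1), correct=True)
        assert state.soa_ms == pytest.approx(27.0)
        assert state.consecutive_correct == 0

    def test_error_grows_soa(self):
        state = staircase_update(StaircaseState(27.0, 0), correct=False)
        assert state.soa_ms == pytest.approx(30.0)
        assert state.consecutive_correct == 0

    def test_single_correct_only_increments_counter(self):
        state = staircase_update(StaircaseState(30.0, 0), correct=True)
        assert state.soa_ms == 30.0
        assert state.consecutive_correct == 1

    def test_long_run_converges_to_707(self):
        """1-up-2-down targets the sqrt(0.5) ~ 70.7% accuracy point."""
        obs = ObserverParams(lapse_rate=0.0, sigma_s1=1.0)
        rng = np.random.default_rng(11)
        state = StaircaseState(30.0, 0)
        n, burn = 20_000, 500
        correct_count = 0
        for i in range(n):
            p = osim.trial_accuracy(osim.psychometric_dprime(state.soa_ms, obs), obs)
            correct = rng.random() < p
            if i >= burn:
                correct_count += correct
            state = staircase_update(state, correct)
        acc = correct_count / (n - burn)
        assert abs(acc - 0.707) < 0.02


class TestPsychometric:
    def test_zero_soa_gives_zero_dprime(self):
        assert osim.psychometric_dprime(0.0, ObserverParams()) == 0.0

    def test_half_point(self):
        obs = ObserverParams(dprime_max=2.0, soa_half_point_ms=20.0)
        assert osim.psychometric_dprime(20.0, obs) == pytest.approx(1.0)

    def test_monotone_and_saturating(self):
        obs = ObserverParams()
        soas = np.linspace(1, 400, 100)
        d = [osim.psychometric_dprime(s, obs) for s in soas]
        assert all(np.diff(d) > 0)
        assert d[-1] < obs.dprime_max

    def test_negative_soa_rejected(self):
        with pytest.raises(ValueError):
            osim.psychometric_dprime(-1.0, ObserverParams())

    def test_soa_inversion_roundtrip(self):
        obs = ObserverParams()
        for d in [0.0, 0.5, 1.3, 2.0]:
            assert osim.psychometric_dprime(osim.soa_for_dprime(d, obs), obs) == (
                pytest.approx(d)
            )


class TestSimulateTrial:
    def test_high_evidence_gives_confident_s1(self, rng):
        """Without metacognitive noise, evidence far above criterion maps to
        a confident S1 response."""
        obs = ObserverParams(
            dprime_max=8.0, soa_half_point_ms=1e-6, sigma_s1=1.0,
            criterion_c=0.0, conf_noise_sd=0.0, lapse_rate=0.0,
        )
        state = StaircaseState(1e9, 0)  # d' ~ 8: evidence almost always extreme
        recs = [
            osim.simulate_trial(state, obs, ExperimentConfig(), rng)
            for _ in range(200)
        ]
        s1_correct = [r for r in recs if r.stimulus == "S1" and r.correct]
        assert np.mean([r.confidence for r in s1_correct]) > 0.9

    def test_separated_distributions_give_high_accuracy(self, rng):
        obs = ObserverParams(
            dprime_max=6.0, soa_half_point_ms=1.0, sigma_s1=1.0,
            criterion_c=3.0, lapse_rate=0.0,
        )
        df = osim.simulate_trials_fixed(4000, obs, dprime=5.9, rng=rng)
        assert df["correct"].mean() > 0.97

    def test_trial_record_invariants(self, rng):
        obs = ObserverParams()
        df = osim.simulate_trials_fixed(500, obs, dprime=1.2, rng=rng)
        assert ((df["stimulus"] == df["response"]) == df["correct"]).all()
        assert df["confidence"].between(0, 1).all()
        assert (df["rt_ms"] > 0).all()

    def test_unequal_variance_produces_type2_asymmetry(self):
        """sigma_s1 > 1 yields higher metacognitive sensitivity for S1
        responses (Monte Carlo at large n)."""
        from metaroc.type2roc import delta_auc

        obs = ObserverParams(
            sigma_s1=1.5, criterion_c=0.75, conf_noise_sd=0.0, lapse_rate=0.0,
            dprime_max=2.5,
        )
        df = osim.simulate_trials_fixed(
            200_000, obs, dprime=1.5, rng=np.random.default_rng(5)
        )
        res = delta_auc(df)
        assert res.auroc_s1 > res.auroc_s2 + 0.05


class TestCohort:
    def test_deterministic_under_fixed_seed(self):
        a = osim.simulate_cohort(3, seed=42)
        b = osim.simulate_cohort(3, seed=42)
        assert a.equals(b)

    def test_participants_stable_across_cohort_sizes(self):
        a = osim.simulate_cohort(2, seed=42)
        b = osim.simulate_cohort(4, seed=42)
        two = b[b["participant_id"].isin(["P001", "P002"])].reset_index(drop=True)
        assert a.equals(two)

    def test_equal_variance_population_delta_auc_symmetric_about_zero(self):
        """With sigma_s1 = 1 and no metacognitive noise the sign of the
        participant-level dAUC is a fair coin (sign test, alpha = 0.01)."""
        from scipy.stats import binomtest

        from metaroc.type2roc import delta_auc

        rng = np.random.default_rng(21)
        deltas = []
        obs = ObserverParams(sigma_s1=1.0, conf_noise_sd=0.0, lapse_rate=0.0,
                             criterion_c=0.55)
        while len(deltas) < 1000:
            df = osim.simulate_trials_fixed(96, obs, dprime=1.1, rng=rng)
            try:
                deltas.append(delta_auc(df).delta)
            except ValueError:
                continue  # no errors for one response: cannot form the curve
        signs = np.sign([d for d in deltas if d != 0])
        p = binomtest(int((signs > 0).sum()), len(signs)).pvalue
        assert p > 0.01

    def test_accuracy_invariant_to_joint_relabeling(self):
        """Under sigma_s1 = 1, swapping S1 and S2 together with c -> d' - c
        leaves the accuracy distribution unchanged (checked via large-n
        simulation)."""
        rng1, rng2 = np.random.default_rng(31), np.random.default_rng(31)
        d = 1.2
        base = dict(sigma_s1=1.0, conf_noise_sd=0.0, lapse_rate=0.0)
        obs_a = ObserverParams(criterion_c=0.9, **base)
        obs_b = ObserverParams(criterion_c=d - 0.9, **base)
        acc_a = osim.simulate_trials_fixed(100_000, obs_a, d, rng1)["correct"].mean()
        acc_b = osim.simulate_trials_fixed(100_000, obs_b, d, rng2)["correct"].mean()
        assert abs(acc_a - acc_b) < 0.01
        # and exactly at the level of expected accuracies
        assert osim.trial_accuracy(d, obs_a) == pytest.approx(
            osim.trial_accuracy(d, obs_b)
        )


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_trials=95),
            dict(step_factor=1.1),
            dict(step_factor=0.0),
            dict(soa_start_ms=-1.0),
        ],
    )
    def test_experiment_config_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs", [dict(sigma_s1=0.8), dict(lapse_rate=0.5), dict(dprime_max=0.0)]
    )
    def test_observer_params_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ObserverParams(**kwargs)
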
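"""Signal-detection metrics, latency statistics, and stage advancement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcptvfa import (AgentParams, BinSpec, RateCorrection, bin_summaries,
                     build_trials, criterion, d_prime, false_alarm_rate,
                     hit_rate, impulsivity_pct, latency_stats, response_rate,
                     session_report, simulate_session, stage12_advances,
                     stage3_promotion_session, tally, tot_probe_schedule)

from oracles import normal_quantile_bisect


def _counts(**kw):
    base = dict(hits=0, misses=0, false_alarms=0, correct_rejections=0,
                iti_touches=0, itis_initiated=0, rewards=0)
    base.update(kw)
    return base


class TestRates:
    def test_hit_rate_formula(self):
        assert hit_rate(_counts(hits=40, misses=10)) == pytest.approx(0.8)

    def test_false_alarm_rate_formula(self):
        assert false_alarm_rate(
            _counts(false_alarms=10, correct_rejections=40)) == pytest.approx(0.2)

    def test_zero_denominators_are_missing(self):
        assert np.isnan(hit_rate(_counts()))
        assert np.isnan(false_alarm_rate(_counts()))

    def test_response_rate_formula(self):
        c = _counts(hits=40, false_alarms=10, misses=20, correct_rejections=30)
        assert response_rate(c) == pytest.approx(0.5)
        assert response_rate(_counts(hits=5, false_alarms=5)) == 1.0

    def test_impulsivity_formula(self):
        assert impulsivity_pct(
            _counts(iti_touches=5, itis_initiated=50)) == pytest.approx(10.0)
        assert impulsivity_pct(
            _counts(iti_touches=0, itis_initiated=50)) == 0.0
        assert np.isnan(impulsivity_pct(_counts()))


class TestDPrime:
    def test_chance_performance_is_zero(self):
        assert d_prime(0.5, 0.5) == pytest.approx(0.0)
        assert criterion(0.5, 0.5) == pytest.approx(0.0)

    def test_matches_bisection_quantile_oracle(self):
        got = d_prime(0.8, 0.2)
        want = normal_quantile_bisect(0.8) - normal_quantile_bisect(0.2)
        assert got == pytest.approx(want, abs=1e-6)
        assert got == pytest.approx(1.6832, abs=1e-3)
        assert criterion(0.8, 0.2) == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry_and_criterion_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            hr, far = rng.uniform(0.01, 0.99, 2)
            assert d_prime(hr, far) == pytest.approx(-d_prime(far, hr),
                                                     abs=1e-9)
            # z(1-p) = -z(p), so swapping to the complements flips c's sign
            assert criterion(hr, far) == pytest.approx(
                -criterion(1 - far, 1 - hr), abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hr=st.floats(0.02, 0.98), far=st.floats(0.02, 0.98),
           eps=st.floats(0.001, 0.01))
    def test_strict_monotonicity(self, hr, far, eps):
        if hr + eps < 1.0:
            assert d_prime(hr + eps, far) > d_prime(hr, far)
        if far + eps < 1.0:
            assert d_prime(hr, far + eps) < d_prime(hr, far)

    def test_half_count_correction_of_extreme_rates(self):
        corr = RateCorrection("half_count")
        assert corr.apply(1.0, 30) == pytest.approx(1.0 - 1.0 / 60.0)
        assert corr.apply(0.0, 30) == pytest.approx(1.0 / 60.0)
        assert corr.apply(0.7, 30) == 0.7
        # 30 hits, 0 misses: corrected HR feeds a finite d'
        v = d_prime(1.0, 0.2, corr, n_signal=30, n_noise=50)
        assert np.isfinite(v)

    def test_uncorrected_extreme_rate_is_missing(self):
        assert np.isnan(d_prime(1.0, 0.2, RateCorrection("none")))
        assert np.isnan(criterion(0.5, 0.0, RateCorrection("none")))

    def test_conservative_agent_has_positive_criterion(self):
        assert criterion(0.3, 0.05) > 0
        assert criterion(0.95, 0.7) < 0


class TestTally:
    def test_counts_match_simulator_truth(self, stage3_session):
        schedule, events, truth = stage3_session
        trials = build_trials(events, schedule)
        bins = BinSpec(900.0, schedule.session_duration)
        counts = tally(trials, events, bins)
        main = truth.trials[~truth.trials["is_correction"]]
        for name, oc in (("hits", "hit"), ("misses", "miss"),
                         ("false_alarms", "false_alarm"),
                         ("correct_rejections", "correct_rejection")):
            assert counts[name].sum() == (main["outcome"] == oc).sum()
        assert counts["correction_trials"].sum() == \
            truth.trials["is_correction"].sum()
        assert counts["rewards"].sum() == truth.n_rewards
        assert counts["iti_touches"].sum() == truth.n_iti_touches
        assert counts["itis_initiated"].sum() == truth.n_iti_episodes

    def test_hr_far_denominators_in_a_bin(self):
        trials = pd.DataFrame({
            "trial_id": range(1, 11),
            "onset": np.linspace(1, 800, 10),
            "outcome_time": np.linspace(2, 801, 10),
            "outcome": ["hit"] * 4 + ["miss"] + ["false_alarm"] * 2
                       + ["correct_rejection"] * 3,
            "is_correction": [False] * 10,
            "response_latency": [1.0] * 10, "reward_latency": [np.nan] * 10,
            "stimulus": ["S+"] * 5 + ["S-"] * 5})
        events = pd.DataFrame({"timestamp_s": [], "event": [],
                               "trial_id": [], "is_correction": []})
        counts = tally(trials, events, BinSpec(900.0, 900.0)).iloc[0]
        assert counts["hits"] + counts["misses"] == 5
        assert counts["false_alarms"] + counts["correct_rejections"] == 5

    def test_empty_bin_yields_zero_counts_and_missing_rates(self):
        trials = pd.DataFrame({
            "trial_id": [1], "onset": [100.0], "outcome_time": [101.0],
            "outcome": ["hit"], "is_correction": [False],
            "response_latency": [1.0], "reward_latency": [0.5],
            "stimulus": ["S+"]})
        events = pd.DataFrame({"timestamp_s": [], "event": [],
                               "trial_id": [], "is_correction": []})
        summary = bin_summaries(trials, events, BinSpec(900.0, 2700.0))
        assert summary["hits"].iloc[1] == 0
        assert np.isnan(summary["hit_rate"].iloc[1])
        assert np.isnan(summary["response_rate"].iloc[2])


class TestLatencies:
    def test_mean_and_sample_sd(self):
        trials = pd.DataFrame({
            "trial_id": [1, 2, 3], "onset": [1.0, 2.0, 3.0],
            "outcome_time": [2.0, 4.0, 6.0], "outcome": ["hit"] * 3,
            "is_correction": [False] * 3,
            "response_latency": [1.0, 2.0, 3.0],
            "reward_latency": [0.5, 0.5, np.nan], "stimulus": ["S+"] * 3})
        lat = latency_stats(trials, BinSpec(900.0, 900.0)).iloc[0]
        assert lat["correct_latency_mean"] == pytest.approx(2.0)
        assert lat["correct_latency_sd"] == pytest.approx(1.0)  # N-1
        assert lat["reward_latency_mean"] == pytest.approx(0.5)

    def test_singleton_bin_has_mean_but_missing_sd(self):
        trials = pd.DataFrame({
            "trial_id": [1], "onset": [1.0], "outcome_time": [2.5],
            "outcome": ["false_alarm"], "is_correction": [False],
            "response_latency": [1.5], "reward_latency": [np.nan],
            "stimulus": ["S-"]})
        lat = latency_stats(trials, BinSpec(900.0, 900.0)).iloc[0]
        assert lat["incorrect_latency_mean"] == pytest.approx(1.5)
        assert np.isnan(lat["incorrect_latency_sd"])

    def test_lognormal_latency_mean_recovered_over_seeds(self):
        """Mean hit latency across seeds matches the (truncated) generator."""
        schedule = tot_probe_schedule(session_duration=900.0)
        agent = AgentParams(hit_propensity_0=0.9, hit_drift=0.0)
        means = []
        for seed in range(20):
            _, truth = simulate_session(schedule, agent, seed=seed)
            hits = truth.trials[truth.trials["outcome"] == "hit"]
            means.append(hits["response_latency"].mean())
        # oracle: empirical mean of the same truncated log-normal
        rng = np.random.default_rng(123456)
        draws = rng.lognormal(agent.correct_latency_mu,
                              agent.correct_latency_sigma, 400_000)
        want = draws[draws < schedule.limited_hold].mean()
        got = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(got - want) < 4 * sem + 0.01


class TestSessionReport:
    def test_six_bins_and_tidy_shape(self, stage3_session):
        schedule = tot_probe_schedule()
        events, truth = simulate_session(schedule, AgentParams(), seed=2)
        trials = build_trials(events, schedule)
        bins = BinSpec(900.0, schedule.session_duration)
        assert bins.n_bins == 6
        summary = bin_summaries(trials, events, bins)
        report = session_report(summary, subject="m1", session="tot1")
        n_metrics = len(summary.columns) - 1
        assert len(report) == 6 * n_metrics
        assert set(report.columns) == {"subject", "session", "bin_index",
                                       "metric", "value"}

    def test_round_trip_preserves_values(self, tmp_path):
        schedule = tot_probe_schedule(session_duration=900.0)
        events, _ = simulate_session(schedule, AgentParams(), seed=3)
        trials = build_trials(events, schedule)
        summary = bin_summaries(trials, events,
                                BinSpec(900.0, schedule.session_duration))
        report = session_report(summary)
        path = tmp_path / "report.csv"
        report.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, report, check_exact=False,
                                      rtol=1e-12)


class TestStageAdvancement:
    def test_stage1_fires_at_sixty_rewards(self):
        assert stage12_advances(60)
        assert not stage12_advances(59)
        assert stage12_advances(150)

    def test_stage3_promotes_at_session_seven_never_earlier(self):
        """Always-above-criterion d' promotes at session 7 exactly."""
        d = [1.2] * 12
        assert stage3_promotion_session(d) == 7
        for k in range(1, 7):
            assert stage3_promotion_session(d[:k]) is None

    def test_stage3_needs_two_consecutive_sessions(self):
        d = [1.0, 0.2] * 5  # never two consecutive above 0.6
        assert stage3_promotion_session(d) is None
        d = [0.2] * 6 + [0.2, 1.0, 1.0]
        assert stage3_promotion_session(d) == 9

    def test_declining_agent_shows_declining_response_rate(self):
        """A declining-propensity agent's per-bin response rate falls."""
        schedule = tot_probe_schedule()
        agent = AgentParams(hit_propensity_0=0.75, hit_drift=-0.005,
                            fa_propensity_0=0.35, fa_drift=-0.003)
        rates = np.zeros(6)
        for seed in range(8):
            events, _ = simulate_session(schedule, agent, seed=100 + seed)
            trials = build_trials(events, schedule)
            s = bin_summaries(trials, events,
                              BinSpec(900.0, schedule.session_duration))
            rates += s["response_rate"].to_numpy()
        rates /= 8
        assert (np.diff(rates) < 0).all()
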
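import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from opponent_ema import (
    CohortConfig,
    Participant,
    TrueDynamics,
    generate_episodes,
    generate_prompt_schedule,
    load_episodes,
    load_observations,
    load_participants,
    simulate_cohort,
    true_state_value,
    write_cohort,
)
from opponent_ema.models import mean_decay
from opponent_ema.synthetic_data import STATE_VARIABLES, default_group_effects


def make_participant(score=5, offsets=None):
    return Participant(
        id="P01",
        incongruence_score=score,
        group="low" if score <= 3 else "high",
        baseline_offsets=offsets or {},
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"compliance": 1.4},
            {"n_days": 0},
            {"prompt_times": (9.0, 9.0, 15.0)},
            {"episode_rate": -0.1},
            {"episode_type_probs": {"porn_only": 0.7}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_group_inconsistent_with_score_rejected(self):
        with pytest.raises(ValueError):
            Participant(id="P01", incongruence_score=2, group="high")


class TestPromptSchedule:
    def test_candidate_count_matches_design(self):
        # 28 days x 5 daily prompts
        config = CohortConfig(n_days=28)
        sched = generate_prompt_schedule(config, make_participant(),
                                         np.random.default_rng(0))
        assert len(sched) == 140

    def test_degenerate_window_gives_exact_prompt_times(self):
        config = CohortConfig(n_days=2, compliance=1.0, response_window=0.0)
        sched = generate_prompt_schedule(config, make_participant(),
                                         np.random.default_rng(0))
        assert sched["answered"].all()
        within_day = (sched["response_min"] % 1440.0) / 60.0
        assert np.allclose(sorted(set(within_day)), [9, 12, 15, 18, 21])

    def test_latency_within_response_window(self):
        config = CohortConfig(compliance=1.0, response_window=3.0)
        sched = generate_prompt_schedule(config, make_participant(),
                                         np.random.default_rng(1))
        latency = sched["response_min"] - sched["scheduled_min"]
        assert (latency >= 0).all() and (latency <= 180.0).all()

    def test_compliance_concentrates_to_configured_rate(self):
        # binomial oracle: mean answered fraction over many replicates
        config = CohortConfig(n_days=28, compliance=0.27)
        rng = np.random.default_rng(2)
        n_rep = 2000
        answered = np.array([
            generate_prompt_schedule(config, make_participant(), rng)
            ["answered"].sum()
            for _ in range(n_rep)
        ])
        frac = answered.mean() / 140.0
        mc_se = np.sqrt(0.27 * 0.73 / (140 * n_rep))
        assert abs(frac - 0.27) < 4 * mc_se


class TestEpisodes:
    def test_zero_rate_gives_no_episodes(self):
        config = CohortConfig(episode_rate=0.0)
        eps = generate_episodes(config, make_participant(),
                                np.random.default_rng(0))
        assert eps.empty

    def test_poisson_mean_count(self):
        # rate 0.3/day over 28 days -> mean 8.4
        config = CohortConfig(episode_rate=0.3, n_days=28)
        rng = np.random.default_rng(3)
        counts = [len(generate_episodes(config, make_participant(), rng))
                  for _ in range(600)]
        se = np.sqrt(8.4 / 600)
        assert abs(np.mean(counts) - 8.4) < 4 * se

    def test_concentrated_type_probs(self):
        probs = {t: 0.0 for t in CohortConfig().episode_type_probs}
        probs["porn_masturbation"] = 1.0
        config = CohortConfig(episode_type_probs=probs)
        eps = generate_episodes(config, make_participant(),
                                np.random.default_rng(4))
        assert (eps["episode_type"] == "porn_masturbation").all()

    def test_peak_mood_reflects_a_process(self):
        config = CohortConfig(noise_sd=0.0, episode_rate=1.0)
        p = make_participant(score=5, offsets={"mood": 0.5})
        eps = generate_episodes(config, p, np.random.default_rng(5))
        mood = config.group_effects["high"]["mood"]
        expected = mood.baseline + 0.5 + mood.peak_mood_shift
        assert np.allclose(eps["peak_mood"], np.clip(expected, 0, 10))


class TestTrueStateValue:
    def test_no_dynamics_returns_baseline_plus_offset(self):
        dyn = TrueDynamics(baseline=4.0)
        p = make_participant(offsets={"mood": 1.25})
        v = true_state_value([0.0, 10.0, 500.0], "mood", p,
                             np.array([100.0]), dyn)
        assert np.allclose(v, 5.25)

    def test_half_life_identity(self):
        # a=-2 decays to half its amplitude after ln2/b hours
        dyn = TrueDynamics(baseline=5.0, post_amplitude=-2.0, post_rate=1.0)
        p = make_participant()
        t = 100.0 + np.log(2.0)
        assert true_state_value(t, "mood", p, np.array([100.0]),
                                dyn) == pytest.approx(4.0)

    def test_superposition_of_two_episodes(self):
        # direct-evaluation oracle: responses add on top of one baseline
        dyn = TrueDynamics(baseline=5.0, post_amplitude=-1.5, post_rate=0.4,
                           pre_amplitude=1.0, pre_rate=0.6)
        p = make_participant()
        t = np.linspace(0.0, 200.0, 97)
        both = true_state_value(t, "mood", p, np.array([80.0, 120.0]), dyn)

        def unclamped(times, eps):
            total = np.full_like(times, dyn.baseline)
            for ep in eps:
                dt = times - ep
                total += np.where(dt > 0,
                                  dyn.post_amplitude * np.exp(-dyn.post_rate * dt),
                                  0.0)
            future = np.array(
                [min((ep - ti for ep in eps if ep >= ti), default=np.nan)
                 for ti in times])
            pre = np.where(np.isnan(future), 0.0,
                           dyn.pre_amplitude * np.exp(-dyn.pre_rate *
                                                      np.nan_to_num(future)))
            return total + pre

        assert np.allclose(both, np.clip(unclamped(t, [80.0, 120.0]), 0, 10))

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            true_state_value(0.0, "mood", make_participant(), np.array([]),
                             TrueDynamics(5.0), noise_sd=1.0)


class TestSimulateCohort:
    def test_seeded_determinism(self):
        config = CohortConfig(n_participants=4, n_days=5, seed=42)
        first = simulate_cohort(config)
        second = simulate_cohort(config)
        for a, b in zip(first, second):
            pd.testing.assert_frame_equal(a, b)

    def test_study_scale_cohort_shape(self):
        obs, eps, parts = simulate_cohort(CohortConfig(seed=0))
        assert parts["id"].nunique() == 22
        # group labels follow the median-split rule on the scores
        expected = np.where(parts["incongruence_score"] <= 3, "low", "high")
        assert (parts["group"] == expected).all()
        assert set(obs["variable"]) == set(STATE_VARIABLES)

    def test_every_episode_has_full_event_survey(self):
        obs, eps, parts = simulate_cohort(
            CohortConfig(n_participants=5, n_days=10, seed=7))
        ev = obs[obs["origin"] == "event"]
        counts = ev.groupby(["participant_id", "time_min"])["variable"].count()
        assert (counts == len(STATE_VARIABLES)).all()
        assert len(counts) == len(eps)

    def test_ratings_clamped(self):
        obs, *_ = simulate_cohort(
            CohortConfig(n_participants=6, n_days=10, noise_sd=4.0, seed=9))
        assert obs["value"].between(0, 10).all()

    def test_integer_rounding_flag(self):
        obs, *_ = simulate_cohort(
            CohortConfig(n_participants=3, n_days=5, integer_ratings=True,
                         seed=3))
        assert np.allclose(obs["value"], np.rint(obs["value"]))

    def test_silent_cohort_variance_structure(self):
        # noise 0 + zero amplitudes: each participant's series is constant
        # and between-person variance equals offset variance
        effects = {
            g: {v: TrueDynamics(5.0) for v in STATE_VARIABLES}
            for g in ("low", "high")
        }
        obs, eps, parts = simulate_cohort(
            CohortConfig(n_participants=8, n_days=20, noise_sd=0.0,
                         group_effects=effects, seed=11))
        mood = obs[obs["variable"] == "mood"]
        per_person_var = mood.groupby("participant_id")["value"].var(ddof=0)
        assert np.allclose(per_person_var, 0.0)
        person_means = mood.groupby("participant_id")["value"].mean()
        clamped_offsets = np.clip(parts["offset_mood"] + 5.0, 0, 10) - 5.0
        assert np.allclose(np.sort(person_means - 5.0),
                           np.sort(clamped_offsets))

    def test_generative_model_matches_fitting_model(self):
        # noise-free post-episode data from one participant recovers
        # (a, b, c) through the decay mean function
        dyn = TrueDynamics(baseline=5.0, post_amplitude=-2.0, post_rate=0.5)
        p = make_participant(offsets={"mood": 0.0})
        t = np.linspace(0.25, 24.0, 60)
        y = true_state_value(100.0 + t, "mood", p, np.array([100.0]), dyn)
        popt, _ = optimize.curve_fit(mean_decay, t, y, p0=(-1.0, 1.0, 4.0))
        a, b, c = popt
        assert np.allclose([a, abs(b), c], [-2.0, 0.5, 5.0], atol=1e-6)


class TestRoundTrip:
    def test_write_and_load_cohort(self, tmp_path):
        obs, eps, parts = simulate_cohort(
            CohortConfig(n_participants=3, n_days=4, seed=5))
        write_cohort(obs, eps, parts, tmp_path)
        obs2 = load_observations(tmp_path / "observations.csv")
        eps2 = load_episodes(tmp_path / "episodes.csv")
        parts2 = load_participants(tmp_path / "participants.csv")
        assert len(obs2) == len(obs)
        assert np.allclose(obs2["value"], obs["value"])
        assert list(eps2["episode_id"]) == list(range(len(eps)))
        assert (parts2["group"] == parts["group"]).all()

    def test_config_yaml_round_trip(self, tmp_path):
        config = CohortConfig(n_participants=5, noise_sd=0.7, seed=13)
        config.to_yaml(tmp_path / "config.yaml")
        loaded = CohortConfig.from_yaml(tmp_path / "config.yaml")
        assert loaded.n_participants == 5
        assert loaded.noise_sd == 0.7
        assert loaded.group_effects["high"]["mood"] == \
            default_group_effects()["high"]["mood"]


@given(seed=st.integers(0, 10_000))
def test_ratings_always_in_scale_bounds(seed):
    obs, *_ = simulate_cohort(
        CohortConfig(n_participants=2, n_days=3, noise_sd=3.0, seed=seed))
    assert obs["value"].between(0.0, 10.0).all()
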
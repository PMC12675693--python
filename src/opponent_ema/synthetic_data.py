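"""Simulate EMA cohorts with known embedded opponent-process dynamics.

The generator reproduces the study design that motivates this package:
~22 participants observed for 28 days, five daily signal-contingent
prompts (9:00, 12:00, 15:00, 18:00, 21:00) with a 3-hour response window
and realistic (~27%) compliance, event-triggered surveys completed
immediately after sexual episodes, and nine cognitive/affective state
variables rated on 0-10 scales. Each participant belongs to a low- or
high-moral-incongruence group; the two groups carry different true
opponent-process dynamics (post-episode spike-and-decay, pre-episode
growth) so that every downstream stage — alignment, model fitting,
Bayes-factor comparison, descriptives — can be validated against known
ground truth.

Time is stored in minutes since study start in the raw tables and
converted to hours for all model work. Episode time t = 0 is anchored at
the event-survey (report) time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The nine state variables collected at every prompt and event survey.
STATE_VARIABLES: tuple[str, ...] = (
    "mood",
    "relationship_connectedness",
    "craving_pornography",
    "craving_sex",
    "loneliness",
    "guilt",
    "shame",
    "anxiety",
    "difficulty_thinking",
)

#: Episode categories available on the event survey.
EPISODE_TYPES: tuple[str, ...] = (
    "intercourse",
    "porn_only",
    "masturbation_only",
    "porn_masturbation",
    "porn_masturbation_orgasm",
    "masturbation_orgasm",
)

MINUTES_PER_DAY = 1440.0


@dataclass
class TrueDynamics:
    """Ground-truth opponent-process response of one state variable.

    The post-episode b-process is ``post_amplitude * exp(-post_rate * dt)``
    for dt hours after an episode; the pre-episode build-up is
    ``pre_amplitude * exp(-pre_rate * dt)`` for dt hours before the next
    upcoming episode. ``peak_mood_shift`` is the a-process height of the
    in-episode mood peak above the participant's baseline (used only for
    the event survey's peak-mood item).
    """

    baseline: float
    post_amplitude: float = 0.0
    post_rate: float = 0.0
    pre_amplitude: float = 0.0
    pre_rate: float = 0.0
    peak_mood_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 10.0:
            raise ValueError(f"baseline must be in [0, 10], got {self.baseline}")
        if self.post_rate < 0 or self.pre_rate < 0:
            raise ValueError("rates must be >= 0")


def default_group_effects() -> dict[str, dict[str, TrueDynamics]]:
    """Default per-group, per-variable true dynamics.

    Amplitudes and rates qualitatively mirror the study's fitted pattern:
    the high-incongruence group shows a post-episode mood drop, rises in
    guilt/shame/loneliness/difficulty thinking, reduced relationship
    connectedness, and a sharp pre-episode craving build-up; the
    low-incongruence group shows smaller post-episode effects and a
    larger in-episode mood peak. Anxiety carries no effect in either
    group. Baselines are close to the study's per-variable means.
    """
    high = {
        "mood": TrueDynamics(5.2, post_amplitude=-1.5, post_rate=0.3,
                             peak_mood_shift=1.0),
        "relationship_connectedness": TrueDynamics(4.4, post_amplitude=-1.2,
                                                   post_rate=0.2),
        "craving_pornography": TrueDynamics(1.5, post_amplitude=-1.0,
                                            post_rate=0.8,
                                            pre_amplitude=2.5, pre_rate=0.5),
        "craving_sex": TrueDynamics(2.1, post_amplitude=1.0, post_rate=0.5,
                                    pre_amplitude=1.5, pre_rate=0.5),
        "loneliness": TrueDynamics(4.0, post_amplitude=1.5, post_rate=0.2),
        "guilt": TrueDynamics(3.2, post_amplitude=2.0, post_rate=0.25),
        "shame": TrueDynamics(3.2, post_amplitude=2.0, post_rate=0.25),
        "anxiety": TrueDynamics(3.0),
        "difficulty_thinking": TrueDynamics(2.9, post_amplitude=1.5,
                                            post_rate=0.3),
    }
    low = {
        "mood": TrueDynamics(5.2, peak_mood_shift=2.5),
        "relationship_connectedness": TrueDynamics(5.3),
        "craving_pornography": TrueDynamics(2.0, post_amplitude=1.0,
                                            post_rate=0.8),
        "craving_sex": TrueDynamics(2.5, post_amplitude=-1.0, post_rate=0.5),
        "loneliness": TrueDynamics(3.4),
        "guilt": TrueDynamics(3.4, post_amplitude=1.0, post_rate=0.25),
        "shame": TrueDynamics(3.3, post_amplitude=1.0, post_rate=0.25),
        "anxiety": TrueDynamics(3.3),
        "difficulty_thinking": TrueDynamics(3.7, post_amplitude=1.2,
                                            post_rate=0.3),
    }
    return {"low": low, "high": high}


def _default_episode_type_probs() -> dict[str, float]:
    # Marginal category mix chosen so that pornography episodes dominate
    # (~81%), masturbation-only episodes are rare (~13%) and intercourse
    # rarer (~6.5%), matching the realized study counts 162/26/13.
    return {
        "porn_only": 0.12,
        "porn_masturbation": 0.20,
        "porn_masturbation_orgasm": 0.485,
        "masturbation_only": 0.065,
        "masturbation_orgasm": 0.065,
        "intercourse": 0.065,
    }


def _default_offset_sd() -> dict[str, float]:
    # per-variable SD of the participant baseline offsets, matching the
    # spread of the study's between-person SDs (guilt/shame/loneliness/
    # connectedness vary far more between people than mood does)
    return {
        "mood": 0.8,
        "relationship_connectedness": 2.2,
        "craving_pornography": 1.6,
        "craving_sex": 1.9,
        "loneliness": 2.3,
        "guilt": 2.3,
        "shame": 2.4,
        "anxiety": 1.5,
        "difficulty_thinking": 1.2,
    }


def _default_duration_dist() -> dict[str, tuple[float, float]]:
    # Per-type log-normal (mu, sigma) of duration in minutes. Pornography
    # episodes are long-tailed (observed range 1-500 min); masturbation
    # alone and intercourse are short and narrow.
    porn = (np.log(20.0), 1.1)
    return {
        "porn_only": porn,
        "porn_masturbation": porn,
        "porn_masturbation_orgasm": porn,
        "masturbation_only": (np.log(10.0), 0.6),
        "masturbation_orgasm": (np.log(10.0), 0.6),
        "intercourse": (np.log(25.0), 0.6),
    }


@dataclass
class CohortConfig:
    """Full design of a simulated EMA cohort.

    Defaults reproduce the study conditions: 22 participants, 28 days,
    five prompts/day at 9:00-21:00 with a 3-h response window, 27%
    compliance, ~0.33 episodes per participant-day, and the default
    group dynamics of :func:`default_group_effects`.
    """

    n_participants: int = 22
    n_days: int = 28
    prompt_times: tuple[float, ...] = (9.0, 12.0, 15.0, 18.0, 21.0)
    response_window: float = 3.0  # hours
    compliance: float = 0.27
    episode_rate: float = 0.33  # expected episodes per participant-day
    episode_type_probs: dict[str, float] = field(
        default_factory=_default_episode_type_probs)
    duration_dist: dict[str, tuple[float, float]] = field(
        default_factory=_default_duration_dist)
    variables: tuple[str, ...] = STATE_VARIABLES
    group_effects: dict[str, dict[str, TrueDynamics]] = field(
        default_factory=default_group_effects)
    noise_sd: float = 1.0
    # SD of per-participant baseline offsets; a single float applies to
    # every variable, a dict sets them per variable
    offset_sd: float | dict[str, float] = field(
        default_factory=_default_offset_sd)
    low_fraction: float = 12 / 22  # share of low-incongruence participants
    integer_ratings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("compliance must be a probability")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        if self.response_window < 0:
            raise ValueError("response_window must be >= 0")
        times = tuple(self.prompt_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("prompt_times must be strictly increasing")
        unknown = set(self.episode_type_probs) - set(EPISODE_TYPES)
        if unknown:
            raise ValueError(f"unknown episode types: {sorted(unknown)}")
        total = sum(self.episode_type_probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"episode_type_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.episode_type_probs.values()):
            raise ValueError("episode_type_probs must be non-negative")
        for grp, effects in self.group_effects.items():
            missing = set(self.variables) - set(effects)
            if missing:
                raise ValueError(
                    f"group {grp!r} lacks dynamics for {sorted(missing)}")

    @property
    def study_span_min(self) -> float:
        return self.n_days * MINUTES_PER_DAY

    # -- serialization -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["group_effects"] = {
            g: {v: dataclasses.asdict(d) for v, d in effects.items()}
            for g, effects in self.group_effects.items()
        }
        data["prompt_times"] = list(self.prompt_times)
        data["variables"] = list(self.variables)
        data["duration_dist"] = {
            k: [float(a), float(b)] for k, (a, b) in self.duration_dist.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "group_effects" in data:
            data["group_effects"] = {
                g: {v: TrueDynamics(**d) for v, d in effects.items()}
                for g, effects in data["group_effects"].items()
            }
        if "prompt_times" in data:
            data["prompt_times"] = tuple(data["prompt_times"])
        if "variables" in data:
            data["variables"] = tuple(data["variables"])
        if "duration_dist" in data:
            data["duration_dist"] = {
                k: (float(v[0]), float(v[1]))
                for k, v in data["duration_dist"].items()
            }
        return cls(**data)


@dataclass
class Participant:
    """One simulated participant with moral-incongruence group membership."""

    id: str
    incongruence_score: int
    group: str  # "low" (score 0-3) or "high" (score 4-6)
    baseline_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.incongruence_score <= 6:
            raise ValueError("incongruence_score must be in 0-6")
        expected = "low" if self.incongruence_score <= 3 else "high"
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with score "
                f"{self.incongruence_score} (median-split rule)")


# ---------------------------------------------------------------------
# Generation operations
# ---------------------------------------------------------------------

def generate_prompt_schedule(
    config: CohortConfig,
    participant: Participant,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Candidate prompts and compliance for one participant.

    Returns a frame with one row per candidate prompt (``n_days`` x
    number of daily prompt times): scheduled time in minutes, whether the
    prompt was answered (independent Bernoulli at the configured
    compliance), and the response time (scheduled time plus a latency
    uniform on [0, response_window]; NaN when unanswered).
    """
    days = np.arange(config.n_days)
    times = np.asarray(config.prompt_times, dtype=float)
    scheduled = (days[:, None] * MINUTES_PER_DAY + times[None, :] * 60.0).ravel()
    answered = rng.random(scheduled.size) < config.compliance
    latency = rng.uniform(0.0, config.response_window * 60.0, scheduled.size)
    response = np.where(answered, scheduled + latency, np.nan)
    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "scheduled_min": scheduled,
            "answered": answered,
            "response_min": response,
        }
    )


def generate_episodes(
    config: CohortConfig,
    participant: Participant,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sexual episodes for one participant from a homogeneous Poisson process.

    Episode count is Poisson(rate x n_days) with times uniform on the
    study span; types follow ``episode_type_probs``; durations are
    per-type log-normal; peak mood is the participant's mood baseline
    plus the group's a-process height plus rating noise, clamped to
    [0, 10].
    """
    n = rng.poisson(config.episode_rate * config.n_days)
    times = np.sort(rng.uniform(0.0, config.study_span_min, n))
    types = list(config.episode_type_probs)
    probs = np.array([config.episode_type_probs[t] for t in types])
    drawn = rng.choice(len(types), size=n, p=probs)
    type_names = [types[i] for i in drawn]
    mu_sig = np.array([config.duration_dist[t] for t in type_names]) \
        if n else np.empty((0, 2))
    durations = np.exp(rng.normal(mu_sig[:, 0], mu_sig[:, 1])) if n else \
        np.empty(0)
    mood_dyn = config.group_effects[participant.group]["mood"]
    peak = (
        mood_dyn.baseline
        + participant.baseline_offsets.get("mood", 0.0)
        + mood_dyn.peak_mood_shift
        + rng.normal(0.0, config.noise_sd, n)
    )
    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "time_min": times,
            "episode_type": pd.Series(type_names, dtype=object),
            "duration_min": durations,
            "peak_mood": np.clip(peak, 0.0, 10.0),
        }
    )


def _mean_trajectory(
    t_hr: np.ndarray,
    episode_times_hr: np.ndarray,
    dynamics: TrueDynamics,
) -> np.ndarray:
    """Noise-free state trajectory (baseline excluded from clamping).

    Post-episode responses of all past episodes superpose; the
    pre-episode build-up is tied only to the next upcoming episode.
    """
    t_hr = np.atleast_1d(np.asarray(t_hr, dtype=float))
    ep = np.sort(np.asarray(episode_times_hr, dtype=float))
    value = np.full(t_hr.shape, dynamics.baseline)
    if ep.size:
        dt_post = t_hr[:, None] - ep[None, :]  # >0 means after episode
        post = np.where(
            dt_post > 0,
            dynamics.post_amplitude * np.exp(-dynamics.post_rate * dt_post),
            0.0,
        )
        value = value + post.sum(axis=1)
        # next upcoming episode (episode at exactly t counts as upcoming)
        idx = np.searchsorted(ep, t_hr, side="left")
        has_next = idx < ep.size
        dt_pre = np.where(has_next, ep[np.minimum(idx, ep.size - 1)] - t_hr, 0.0)
        value = value + np.where(
            has_next,
            dynamics.pre_amplitude * np.exp(-dynamics.pre_rate * dt_pre),
            0.0,
        )
    return value


def true_state_value(
    t_hr: float | np.ndarray,
    variable: str,
    participant: Participant,
    episode_times_hr: np.ndarray,
    dynamics: TrueDynamics,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ground-truth rating(s) of ``variable`` at time(s) ``t_hr`` (hours).

    value = baseline + participant offset
            + sum over past episodes of post_amplitude * exp(-post_rate*dt)
            + pre_amplitude * exp(-pre_rate * (t_next - t))
            + Gaussian noise, clamped to [0, 10].
    """
    t_arr = np.atleast_1d(np.asarray(t_hr, dtype=float))
    value = _mean_trajectory(t_arr, episode_times_hr, dynamics)
    value = value + participant.baseline_offsets.get(variable, 0.0)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        value = value + rng.normal(0.0, noise_sd, value.shape)
    out = np.clip(value, 0.0, 10.0)
    return out if np.ndim(t_hr) else float(out[0])


def _make_participants(
    config: CohortConfig, rng: np.random.Generator
) -> list[Participant]:
    n_low = int(round(config.n_participants * config.low_fraction))
    n_low = min(max(n_low, 0), config.n_participants)
    width = max(2, len(str(config.n_participants)))
    participants = []
    for i in range(config.n_participants):
        if i < n_low:
            score = int(rng.integers(0, 4))
        else:
            score = int(rng.integers(4, 7))
        if isinstance(config.offset_sd, dict):
            sds = {v: config.offset_sd.get(v, 1.5) for v in config.variables}
        else:
            sds = {v: config.offset_sd for v in config.variables}
        offsets = {
            v: float(rng.normal(0.0, sds[v])) for v in config.variables
        }
        participants.append(
            Participant(
                id=f"P{i + 1:0{width}d}",
                incongruence_score=score,
                group="low" if score <= 3 else "high",
                baseline_offsets=offsets,
            )
        )
    return participants


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; deterministic given ``config.seed``.

    Returns ``(observations, episodes, participants)``:

    * observations — long format, one row per (participant, time,
      variable): ``participant_id, time_min, variable, value, origin``
      with origin ``scheduled`` (answered prompt) or ``event``
      (event-triggered survey at the episode's report time, all
      variables).
    * episodes — ``episode_id, participant_id, time_min, episode_type,
      duration_min, peak_mood``.
    * participants — ``id, incongruence_score, group`` plus one
      ``offset_<variable>`` column per state variable.
    """
    root = np.random.SeedSequence(config.seed)
    part_seq, *per_part = root.spawn(1 + config.n_participants)
    participants = _make_participants(config,
                                      np.random.default_rng(part_seq))

    obs_frames: list[pd.DataFrame] = []
    ep_frames: list[pd.DataFrame] = []
    for participant, seq in zip(participants, per_part):
        rng = np.random.default_rng(seq)
        schedule = generate_prompt_schedule(config, participant, rng)
        episodes = generate_episodes(config, participant, rng)
        ep_frames.append(episodes)

        sched_t = schedule.loc[schedule["answered"], "response_min"].to_numpy()
        event_t = episodes["time_min"].to_numpy()
        all_t_min = np.concatenate([sched_t, event_t])
        origin = np.array(["scheduled"] * sched_t.size +
                          ["event"] * event_t.size, dtype=object)
        order = np.argsort(all_t_min, kind="stable")
        all_t_min, origin = all_t_min[order], origin[order]

        effects = config.group_effects[participant.group]
        ep_hr = event_t / 60.0
        rows = {
            "time_min": np.repeat(all_t_min, len(config.variables)),
            "variable": np.tile(np.asarray(config.variables, dtype=object),
                                all_t_min.size),
            "origin": np.repeat(origin, len(config.variables)),
        }
        values = np.empty((all_t_min.size, len(config.variables)))
        for j, var in enumerate(config.variables):
            values[:, j] = true_state_value(
                all_t_min / 60.0, var, participant, ep_hr, effects[var],
                noise_sd=config.noise_sd, rng=rng,
            )
        vals = values.ravel()
        if config.integer_ratings:
            vals = np.clip(np.rint(vals), 0, 10)
        obs_frames.append(
            pd.DataFrame(
                {
                    "participant_id": participant.id,
                    "time_min": rows["time_min"],
                    "variable": rows["variable"],
                    "value": vals,
                    "origin": rows["origin"],
                }
            )
        )

    observations = pd.concat(obs_frames, ignore_index=True)
    episodes = pd.concat(ep_frames, ignore_index=True)
    episodes.insert(0, "episode_id", np.arange(len(episodes)))

    part_df = pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "incongruence_score": [p.incongruence_score for p in participants],
            "group": [p.group for p in participants],
        }
    )
    for v in config.variables:
        part_df[f"offset_{v}"] = [p.baseline_offsets[v] for p in participants]
    return observations, episodes, part_df


# ---------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------

def write_cohort(
    observations: pd.DataFrame,
    episodes: pd.DataFrame,
    participants: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write observations.csv / episodes.csv / participants.csv (UTF-8)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs_cols = ["participant_id", "time_min", "variable", "value", "origin"]
    observations[obs_cols].to_csv(out / "observations.csv", index=False)
    ep_cols = ["participant_id", "time_min", "episode_type", "duration_min",
               "peak_mood"]
    episodes[ep_cols].to_csv(out / "episodes.csv", index=False)
    part_cols = ["id", "incongruence_score", "group"]
    participants[part_cols].to_csv(out / "participants.csv", index=False)


def load_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_episodes(path: str | Path) -> pd.DataFrame:
    """Read episodes.csv, assigning sequential ``episode_id`` by row order."""
    df = pd.read_csv(path)
    if "episode_id" not in df.columns:
        df.insert(0, "episode_id", np.arange(len(df)))
    return df


def load_participants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
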
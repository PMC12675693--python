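"""Episode-centered alignment of EMA observations.

Builds the pre/post, full/truncated analysis datasets: every in-group
episode is placed at relative time t = 0 and each same-participant state
rating within a horizon on the requested side becomes one aligned row.
In the full dataset a rating lying between two episodes belongs to both
the earlier episode's post-set and the later episode's pre-set; the
truncated dataset drops ratings that lie closer to a different in-group
episode than the one under analysis. The 12-hour window-difference score
summarises each participant's near-episode versus away-from-episode
state levels for the group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import EPISODE_TYPES

_GROUP_A_TYPES = frozenset(
    {"porn_only", "porn_masturbation", "porn_masturbation_orgasm"})
_GROUP_B_TYPES = _GROUP_A_TYPES | frozenset(
    {"masturbation_only", "masturbation_orgasm"})


@dataclass(frozen=True)
class EpisodeGroup:
    """Episode subset under analysis.

    Group A: episodes involving pornography use, with or without
    masturbation or orgasm. Group B: all Group A episodes plus episodes
    of masturbation without pornography. Intercourse belongs to neither.
    """

    label: str
    member_types: frozenset

    @classmethod
    def A(cls) -> "EpisodeGroup":
        return cls("A", _GROUP_A_TYPES)

    @classmethod
    def B(cls) -> "EpisodeGroup":
        return cls("B", _GROUP_B_TYPES)

    @classmethod
    def from_label(cls, label: str) -> "EpisodeGroup":
        try:
            return {"A": cls.A, "B": cls.B}[label.upper()]()
        except KeyError:
            raise ValueError(f"unknown episode group {label!r}") from None


def classify_episode(episode_type: str, group: EpisodeGroup) -> bool:
    """True iff an episode of ``episode_type`` belongs to ``group``."""
    if episode_type not in EPISODE_TYPES:
        raise ValueError(f"unknown episode type {episode_type!r}")
    return episode_type in group.member_types


def _in_group(episodes: pd.DataFrame, group: EpisodeGroup) -> pd.DataFrame:
    unknown = set(episodes["episode_type"]) - set(EPISODE_TYPES)
    if unknown:
        raise ValueError(f"unknown episode types: {sorted(unknown)}")
    return episodes[episodes["episode_type"].isin(group.member_types)]


def _check_direction(direction: str) -> str:
    if direction not in ("pre", "post"):
        raise ValueError(f"direction must be 'pre' or 'post', got {direction!r}")
    return direction


ALIGNED_COLUMNS = [
    "participant_id", "episode_id", "rel_time", "variable", "value",
    "direction", "nearest_episode_id",
]


def center_observations(
    observations: pd.DataFrame,
    episodes: pd.DataFrame,
    group: EpisodeGroup,
    direction: str,
    horizon: float = 72.0,
) -> pd.DataFrame:
    """Full episode-centered dataset for one side of the episodes.

    For every in-group episode and every same-participant observation
    with 0 < |dt| <= horizon hours on the requested side, emits one row
    with ``rel_time`` in signed hours (negative = pre). Observations at
    exactly dt = 0 (the event survey itself) are excluded; its rating of
    the episode is analysed separately as peak mood. A rating between
    two episodes appears on both sides.
    """
    _check_direction(direction)
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    eps = _in_group(episodes, group)
    if eps.empty or observations.empty:
        return pd.DataFrame(columns=ALIGNED_COLUMNS)

    merged = observations.merge(
        eps[["participant_id", "episode_id", "time_min"]].rename(
            columns={"time_min": "ep_time_min"}),
        on="participant_id",
        how="inner",
    )
    dt_hr = (merged["time_min"] - merged["ep_time_min"]) / 60.0
    if direction == "post":
        keep = (dt_hr > 0) & (dt_hr <= horizon)
    else:
        keep = (dt_hr < 0) & (dt_hr >= -horizon)
    out = merged.loc[keep].copy()
    out["rel_time"] = dt_hr[keep]
    out["direction"] = direction

    # nearest in-group episode per observation (ties -> earliest episode)
    out["_absdt"] = out["rel_time"].abs()
    nearest = (
        merged.assign(_absdt=dt_hr.abs())
        .sort_values(["_absdt", "ep_time_min"], kind="stable")
        .drop_duplicates(["participant_id", "time_min", "variable"])
        .set_index(["participant_id", "time_min", "variable"])["episode_id"]
    )
    idx = pd.MultiIndex.from_frame(
        out[["participant_id", "time_min", "variable"]])
    out["nearest_episode_id"] = nearest.reindex(idx).to_numpy()
    out = out.sort_values(
        ["participant_id", "episode_id", "rel_time", "variable"],
        kind="stable")
    return out[ALIGNED_COLUMNS + ["time_min"]].reset_index(drop=True)


def truncate(
    aligned: pd.DataFrame,
    episodes: pd.DataFrame,
    group: EpisodeGroup,
) -> pd.DataFrame:
    """Truncated dataset: drop rows closer to a different in-group episode.

    A row survives iff |rel_time| <= |t_obs - t_e'| for every other
    same-participant in-group episode e'; equidistant ties are retained
    (for both episodes). Idempotent, and the identity on
    single-episode participants.
    """
    if aligned.empty:
        return aligned.copy()
    eps = _in_group(episodes, group)
    missing = set(aligned["episode_id"]) - set(eps["episode_id"])
    if missing:
        raise ValueError(
            f"aligned rows reference episodes outside the group: "
            f"{sorted(missing)}")
    if "time_min" in aligned.columns:
        t_obs = aligned["time_min"].to_numpy(float)
    else:
        ep_time = eps.set_index("episode_id")["time_min"]
        t_obs = (ep_time.reindex(aligned["episode_id"]).to_numpy(float)
                 + aligned["rel_time"].to_numpy(float) * 60.0)

    keep = np.ones(len(aligned), dtype=bool)
    for pid, grp_idx in aligned.groupby("participant_id").indices.items():
        ep_p = eps.loc[eps["participant_id"] == pid]
        times = ep_p["time_min"].to_numpy(float)
        ids = ep_p["episode_id"].to_numpy()
        rows = aligned.iloc[grp_idx]
        # distance (hours) from each obs to every in-group episode
        dist = np.abs(t_obs[grp_idx][:, None] - times[None, :]) / 60.0
        own = rows["episode_id"].to_numpy()[:, None] == ids[None, :]
        other = np.where(own, np.inf, dist)
        min_other = other.min(axis=1) if ids.size else np.inf
        keep[grp_idx] = (np.abs(rows["rel_time"].to_numpy(float))
                         <= min_other + 1e-12)
    return aligned.loc[keep].reset_index(drop=True)


def window_difference(
    observations: pd.DataFrame,
    episodes: pd.DataFrame,
    group: EpisodeGroup,
    direction: str,
    window: float = 12.0,
) -> pd.DataFrame:
    """Per-participant near-vs-far window difference scores.

    For each participant and state variable, the difference between the
    mean of ratings within ``window`` hours of an in-group episode on
    the requested side and the mean of ratings more than ``window``
    hours from every in-group episode (either side). Participants with
    an empty near or far stratum get NaN for that cell and are excluded
    from downstream group tests.
    """
    _check_direction(direction)
    if window <= 0:
        raise ValueError("window must be > 0")
    eps = _in_group(episodes, group)
    records = []
    for pid, obs_p in observations.groupby("participant_id"):
        times = eps.loc[eps["participant_id"] == pid, "time_min"] \
            .to_numpy(float)
        t_obs = obs_p["time_min"].to_numpy(float)
        if times.size:
            dt_hr = (t_obs[:, None] - times[None, :]) / 60.0
            if direction == "post":
                near = ((dt_hr > 0) & (dt_hr <= window)).any(axis=1)
            else:
                near = ((dt_hr < 0) & (dt_hr >= -window)).any(axis=1)
            far = (np.abs(dt_hr) > window).all(axis=1)
        else:
            near = np.zeros(t_obs.size, dtype=bool)
            far = np.ones(t_obs.size, dtype=bool)
        for var, obs_v in obs_p.groupby("variable"):
            loc = obs_p.index.get_indexer(obs_v.index)
            near_vals = obs_v["value"].to_numpy(float)[near[loc]]
            far_vals = obs_v["value"].to_numpy(float)[far[loc]]
            diff = (near_vals.mean() - far_vals.mean()
                    if near_vals.size and far_vals.size else np.nan)
            records.append(
                {
                    "participant_id": pid,
                    "variable": var,
                    "direction": direction,
                    "n_near": int(near_vals.size),
                    "n_far": int(far_vals.size),
                    "difference": diff,
                }
            )
    return pd.DataFrame.from_records(records)
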
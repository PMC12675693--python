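"""Descriptive layer: variance components, ICC and within-person correlations.

Within- and between-person standard deviations come from the one-way
random-effects ANOVA decomposition (unbalanced-design estimator, with a
negative between component floored at zero); the intraclass correlation
is the between share of total variance. Within-person correlations are
Pearson correlations of person-mean-centered paired ratings pooled
across participants, i.e. purely intra-individual covariation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _subset(observations: pd.DataFrame, participants: pd.DataFrame | None,
            group: str | None) -> pd.DataFrame:
    if group is not None:
        if participants is None:
            raise ValueError("participants table required for group filtering")
        ids = participants.loc[participants["group"] == group, "id"]
        observations = observations[
            observations["participant_id"].isin(ids)]
    return observations


def variance_components(
    observations: pd.DataFrame,
    variable: str,
    participants: pd.DataFrame | None = None,
    group: str | None = None,
    raw_between: bool = False,
) -> tuple[float, float, float]:
    """(within_person_SD, between_person_SD, ICC) for one state variable.

    One-way random-effects ANOVA estimator: within variance is the mean
    square within persons; the between component is (MSB - MSW) / n0
    with the unbalanced-design n0, floored at zero. ``raw_between=True``
    returns instead the plain SD of person means.
    ICC = between^2 / (between^2 + within^2).
    """
    obs = _subset(observations, participants, group)
    obs = obs[obs["variable"] == variable]
    counts = obs.groupby("participant_id")["value"].count()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise ValueError(
            "variance decomposition needs >= 2 participants with >= 2 "
            "observations each")
    obs = obs[obs["participant_id"].isin(counts.index)]

    k = len(counts)
    n_total = counts.sum()
    grand = obs["value"].mean()
    means = obs.groupby("participant_id")["value"].mean()
    ssw = ((obs["value"] - obs["participant_id"].map(means)) ** 2).sum()
    ssb = (counts * (means - grand) ** 2).sum()
    msw = ssw / (n_total - k)
    msb = ssb / (k - 1)
    n0 = (n_total - (counts**2).sum() / n_total) / (k - 1)
    within_var = msw
    between_var = max((msb - msw) / n0, 0.0)
    if raw_between:
        between_var = means.var(ddof=1)
    total = between_var + within_var
    icc = between_var / total if total > 0 else 0.0
    return float(np.sqrt(within_var)), float(np.sqrt(between_var)), float(icc)


def within_person_correlation(
    observations: pd.DataFrame,
    var1: str,
    var2: str,
    participants: pd.DataFrame | None = None,
    group: str | None = None,
) -> float:
    """Pooled person-mean-centered Pearson correlation of two variables.

    Ratings are paired by (participant, prompt time), centered on each
    participant's mean for each variable, then pooled into a single
    Pearson correlation. A variable that is constant within every person
    has no within-person signal; the correlation is 0 by convention.
    """
    obs = _subset(observations, participants, group)
    obs = obs[obs["variable"].isin([var1, var2])]
    wide = obs.pivot_table(index=["participant_id", "time_min"],
                           columns="variable", values="value",
                           aggfunc="mean")
    if var1 not in wide.columns or var2 not in wide.columns:
        raise ValueError("no paired observations of both variables")
    wide = wide.dropna(subset=[var1, var2])
    if wide.empty:
        raise ValueError("no paired observations of both variables")
    centered = wide.groupby(level="participant_id")[[var1, var2]] \
        .transform(lambda s: s - s.mean())
    a = centered[var1].to_numpy()
    b = centered[var2].to_numpy()
    if a.size < 2 or np.allclose(a.std(), 0) or np.allclose(b.std(), 0):
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def variable_summary(
    observations: pd.DataFrame,
    participants: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptive table: M, SD, median, variance components, ICC."""
    variables = variables or sorted(observations["variable"].unique())
    records = []
    for group in ("high", "low"):
        for var in variables:
            obs = _subset(observations, participants, group)
            vals = obs.loc[obs["variable"] == var, "value"]
            within, between, icc = variance_components(
                observations, var, participants, group)
            records.append(
                {
                    "group": group,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "median": float(vals.median()),
                    "within_person_sd": within,
                    "between_person_sd": between,
                    "icc": icc,
                }
            )
    return pd.DataFrame.from_records(records)


def correlation_matrix(
    observations: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    group: str | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pooled within-person Pearson correlations."""
    variables = variables or sorted(observations["variable"].unique())
    mat = pd.DataFrame(np.eye(len(variables)), index=variables,
                       columns=variables)
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1:]:
            r = within_person_correlation(observations, v1, v2,
                                          participants, group)
            mat.loc[v1, v2] = mat.loc[v2, v1] = r
    return mat
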
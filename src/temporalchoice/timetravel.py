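"""Mental time-travel response-time contrasts.

The headline group x session x event-time interaction on log RT is tested
with a transparent two-stage approach: per participant and session, the mean
log-RT difference between relative-future and relative-past events is
computed; the interaction score is the post-minus-pre change of that
difference; scores are compared between stimulation groups with a
Mann-Whitney test.  In a balanced, complete design this score equals the
indicator-coded fixed-effects regression interaction coefficient exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import groupstats

__all__ = [
    "RtContrast",
    "cell_means",
    "compute_contrasts",
    "interaction_test",
    "crosstask_correlation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RtContrast:
    """Per-participant future-minus-past log-RT contrasts.

    ``interaction`` is the post-session contrast minus the pre-session
    contrast; positive values mean future-event processing slowed more (or
    sped up less) after stimulation.
    """

    participant_id: str
    group: str
    pre_diff: float
    post_diff: float

    @property
    def interaction(self) -> float:
        return self.post_diff - self.pre_diff


def cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean log RT per participant x session x event_time cell.

    Rows with an ``exclude`` column set truthy are dropped first.  Returns a
    tidy table with columns participant_id, group, session, event_time,
    mean_log_rt, n_trials.
    """
    if trials.empty:
        raise ValueError("trials must be non-empty")
    if "exclude" in trials.columns:
        trials = trials[~trials["exclude"].astype(bool)]
    grouped = (
        trials.groupby(["participant_id", "group", "session", "event_time"],
                       observed=True)["log_rt"]
        .agg(mean_log_rt="mean", n_trials="size")
        .reset_index()
    )
    return grouped


def compute_contrasts(trials: pd.DataFrame) -> list[RtContrast]:
    """Two-stage contrasts for every participant with complete cells.

    Participants missing any of the four session x event-time cells are
    excluded with a logged warning.
    """
    means = cell_means(trials)
    wide = means.pivot_table(index=["participant_id", "group"],
                             columns=["session", "event_time"],
                             values="mean_log_rt", observed=True)
    contrasts = []
    needed = [("pre", "future"), ("pre", "past"), ("post", "future"), ("post", "past")]
    for (pid, group), row in wide.iterrows():
        if any(col not in row.index or pd.isna(row[col]) for col in needed):
            log.warning("participant %s excluded: incomplete design cells", pid)
            continue
        contrasts.append(RtContrast(
            participant_id=pid,
            group=group,
            pre_diff=float(row[("pre", "future")] - row[("pre", "past")]),
            post_diff=float(row[("post", "future")] - row[("post", "past")]),
        ))
    return contrasts


def interaction_test(
    contrasts: list[RtContrast],
    tail: str = "one",
) -> groupstats.GroupTestResult:
    """Mann-Whitney test of interaction scores, rTPJ vs. vertex.

    The one-tailed direction is that rTPJ stimulation slows future-event
    processing post-session more than vertex stimulation (rTPJ scores
    larger).
    """
    rtpj = [c.interaction for c in contrasts if c.group == "rTPJ"]
    vertex = [c.interaction for c in contrasts if c.group == "vertex"]
    if not rtpj or not vertex:
        raise ValueError("both groups must be represented")
    direction = "x_greater" if tail == "one" else None
    return groupstats.mann_whitney(rtpj, vertex, tail=tail, direction=direction)


def crosstask_correlation(
    rt_scores: pd.Series,
    delta_s: pd.Series,
    tail: str = "one",
) -> tuple[float, float]:
    """Spearman correlation of RT interaction scores with changes in ``s``.

    Both inputs are indexed by participant and must cover the same
    participants (both groups pooled).
    """
    if set(rt_scores.index) != set(delta_s.index):
        raise ValueError("rt_scores and delta_s must cover the same participants")
    aligned = delta_s.reindex(rt_scores.index)
    return groupstats.spearman_correlation(rt_scores.to_numpy(),
                                           aligned.to_numpy(), tail=tail)
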
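"""Interval group-cohesion score β over a session timeline.

For a time interval [t, t+T), β = |C(t,t+T)| / |A(t,t+T)| where A is the
set of all posts in the interval and C the subset whose final label is
cohesion. The session is covered by ceil(duration / T) half-open intervals
anchored at 0 (default T = 30 minutes over a 90-minute session, i.e. three
intervals); a post landing exactly on a boundary belongs to the later
interval, and a post at the very end of the session is counted in the last
interval. An interval with no posts has β undefined (serialized as an empty
cell / null), never 0 — absent data is not absent cohesion.

β is computed per group and, with ``scope="participant:<id>"``, restricted
to one participant's posts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

DEFAULT_INTERVAL_MINUTES = 30.0

#: (timestamp_seconds, final_label, participant_id)
LabeledPost = tuple[float, str, str]


@dataclass(frozen=True)
class IntervalScore:
    t_start: float  # minutes
    T: float  # minutes
    n_posts: int
    n_cohesion: int
    beta: float | None
    scope: str

    def __post_init__(self) -> None:
        assert 0 <= self.n_cohesion <= self.n_posts


def beta_series(
    labeled: Sequence[LabeledPost],
    T: float = DEFAULT_INTERVAL_MINUTES,
    session_duration: float = 90.0,
    scope: str = "group",
) -> list[IntervalScore]:
    """β for every interval of the session, in timeline order.

    ``labeled`` carries timestamps in seconds from session start; ``T`` and
    ``session_duration`` are minutes. Posts outside [0, duration] or a
    non-positive ``T`` are rejected.
    """
    if T <= 0:
        raise ValueError(f"interval length T must be > 0 minutes, got {T}")
    if session_duration <= 0:
        raise ValueError("session_duration must be > 0")
    duration_s = session_duration * 60.0
    T_s = T * 60.0
    n_intervals = math.ceil(session_duration / T)

    if scope.startswith("participant:"):
        pid = scope.split(":", 1)[1]
        posts = [p for p in labeled if p[2] == pid]
    elif scope == "group":
        posts = list(labeled)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    n_posts = [0] * n_intervals
    n_cohesion = [0] * n_intervals
    for ts, label, _pid in posts:
        if not 0.0 <= ts <= duration_s:
            raise ValueError(f"timestamp {ts}s outside [0, {duration_s}]s")
        idx = int(ts // T_s)
        if idx == n_intervals:  # post exactly at session end
            idx -= 1
        n_posts[idx] += 1
        if label == "cohesion":
            n_cohesion[idx] += 1

    return [
        IntervalScore(
            t_start=i * T,
            T=T,
            n_posts=n_posts[i],
            n_cohesion=n_cohesion[i],
            beta=(n_cohesion[i] / n_posts[i]) if n_posts[i] else None,
            scope=scope,
        )
        for i in range(n_intervals)
    ]


def write_csv(
    series: Sequence[tuple[str, IntervalScore]], path: str | Path
) -> None:
    """Write (session_id, IntervalScore) rows; undefined β as empty cell."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["session_id", "scope", "t_start", "T", "n_posts", "n_cohesion", "beta"]
        )
        for session_id, s in series:
            w.writerow(
                [
                    session_id,
                    s.scope,
                    s.t_start,
                    s.T,
                    s.n_posts,
                    s.n_cohesion,
                    "" if s.beta is None else f"{s.beta:.6f}",
                ]
            )
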
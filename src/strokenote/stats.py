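"""Group comparison of metric tables and session superposition.

Collectives (e.g. the sessions of a "negative feeling" vs a "positive
feeling" task) are compared metric by metric with a classic one-way ANOVA:
F = MS_between / MS_within with df = (k−1, N−k), the effect size
η² = SS_between / SS_total, and per-group means with SEM = sd/√n.
Observations are treated as independent; no multiple-testing correction is
applied by default (a Benjamini–Hochberg option is available).

Superposition pools several sessions onto a common start-aligned timeline,
as used by the overlay reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from strokenote.art import ArtMetrics
from strokenote.events import MusicSession, NoteEvent
from strokenote.music import MusicMetrics

#: significance stars, mirroring the report legend
STAR_THRESHOLDS = ((0.001, "***"), (0.05, "*"))


@dataclass(frozen=True)
class GroupStats:
    name: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA summary for one metric across ≥ 2 groups."""

    metric_name: str
    groups: tuple[GroupStats, ...]
    f_stat: float
    df: tuple[int, int]
    p_value: float
    eta_squared: float
    degenerate: bool = False  # zero within-group variance with unequal means

    @property
    def stars(self) -> str:
        for threshold, mark in STAR_THRESHOLDS:
            if self.p_value < threshold:
                return mark
        return ""


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def one_way_f(
    groups: Sequence[Sequence[float]],
    metric_name: str = "value",
    group_names: Optional[Sequence[str]] = None,
) -> GroupComparison:
    """Classic one-way ANOVA over ≥ 2 samples of numbers.

    Returns F, df = (k−1, N−k), the p-value from the F distribution,
    η² = SS_between / SS_total, and per-group (n, mean, SEM).  With zero
    within-group variance and unequal means, F is infinite and p is 0
    (flagged ``degenerate``); with all values identical, F = 0 and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2 or any(len(a) < 1 for a in arrays):
        raise ValueError("need at least two groups, each with at least one value")
    n_total = sum(len(a) for a in arrays)
    if n_total <= k:
        raise ValueError("need more observations than groups")
    if group_names is None:
        group_names = [chr(ord("A") + i) for i in range(k)]
    grand = float(np.concatenate(arrays).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    ss_total = ss_between + ss_within
    df = (k - 1, n_total - k)
    gstats = tuple(
        GroupStats(name, len(a), float(a.mean()), _sem(a))
        for name, a in zip(group_names, arrays)
    )
    # float-noise guard: SS components below ~1e-12 of the total are zero
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_between <= tol:
        return GroupComparison(metric_name, gstats, 0.0, df, 1.0, 0.0)
    if ss_within <= tol:
        return GroupComparison(
            metric_name, gstats, float("inf"), df, 0.0, 1.0, degenerate=True
        )
    f_stat = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f_stat, *df))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return GroupComparison(metric_name, gstats, float(f_stat), df, p, float(eta2))


def compare_collectives(
    table_a: Sequence[MusicMetrics | ArtMetrics],
    table_b: Sequence[MusicMetrics | ArtMetrics],
    group_names: tuple[str, str] = ("A", "B"),
    fdr: bool = False,
) -> list[GroupComparison]:
    """One :class:`GroupComparison` per numeric metric field of two
    same-modality metric tables.

    Histogram bins a session never touched count as 0% for that session;
    metrics undefined for a session (None, e.g. concurrency of an empty
    session) drop that session from the metric's sample.  ``fdr`` applies a
    Benjamini–Hochberg adjustment to the p-values (off by default).
    """
    if not table_a or not table_b:
        raise ValueError("both groups must be nonempty")
    modalities = {m.modality for m in list(table_a) + list(table_b)}
    if len(modalities) != 1:
        raise ValueError(f"modality mismatch: {sorted(modalities)}")
    rows_a = [m.to_flat_dict() for m in table_a]
    rows_b = [m.to_flat_dict() for m in table_b]
    keys = []
    seen: set[str] = set()
    for row in rows_a + rows_b:
        for key in row:
            if key not in seen:
                seen.add(key)
                keys.append(key)
    results: list[GroupComparison] = []
    for key in keys:
        ga = [row.get(key, 0.0) for row in rows_a]
        gb = [row.get(key, 0.0) for row in rows_b]
        ga = [float(v) for v in ga if v is not None]
        gb = [float(v) for v in gb if v is not None]
        if not ga or not gb or len(ga) + len(gb) <= 2:
            continue
        results.append(one_way_f([ga, gb], key, group_names))
    if fdr and results:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, ps[idx] * m / rank)
            adj[idx] = running
        results = [replace(r, p_value=float(adj[i])) for i, r in enumerate(results)]
    return results


def comparison_table_csv(results: Sequence[GroupComparison], path: str | Path) -> None:
    """Export as CSV: metric, mean/sem per group, F, df, p, eta2, stars."""
    lines = ["metric,mean_A,sem_A,mean_B,sem_B,F,df1,df2,p,eta2,stars"]
    for r in results:
        a, b = r.groups[0], r.groups[1]
        lines.append(
            f"{r.metric_name},{a.mean:.6g},{a.sem:.6g},{b.mean:.6g},{b.sem:.6g},"
            f"{r.f_stat:.6g},{r.df[0]},{r.df[1]},{r.p_value:.6g},"
            f"{r.eta_squared:.6g},{r.stars}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class SuperposedSession:
    """Several music sessions pooled on a common start-aligned timeline."""

    sources: list[str]
    events: list[tuple[int, NoteEvent]]  # (source index, shifted note)
    duration: float
    alignment: str = "start"

    def split(self) -> list[list[NoteEvent]]:
        """Recover the per-source note lists (shifted timeline)."""
        out: list[list[NoteEvent]] = [[] for _ in self.sources]
        for idx, note in self.events:
            out[idx].append(note)
        return out


def superimpose_music(
    sessions: Sequence[MusicSession], names: Optional[Sequence[str]] = None
) -> SuperposedSession:
    """Pool note events of ≥ 1 session, each shifted to start at t = 0.

    The merged note count is the sum of the source counts; the merged
    duration is the maximum shifted source duration.
    """
    if not sessions:
        raise ValueError("need at least one session to superimpose")
    if names is None:
        names = [str(s.meta.get("id", i)) for i, s in enumerate(sessions)]
    events: list[tuple[int, NoteEvent]] = []
    duration = 0.0
    for idx, s in enumerate(sessions):
        shift = min((n.onset for n in s.notes), default=0.0)
        duration = max(duration, s.duration - shift)
        for n in s.notes:
            events.append(
                (idx, NoteEvent(n.onset - shift, n.offset - shift, n.pitch,
                                n.intensity, n.channel))
            )
    events.sort(key=lambda e: (e[1].onset, e[0], e[1].pitch))
    return SuperposedSession(sources=list(names), events=events, duration=duration)
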
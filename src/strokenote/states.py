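"""State-interval derivation: the event stream as a labeled timeline.

Raw events transfer a session between a small set of states — a music
session is ``playing`` exactly while at least one key is sounding and
``idle`` otherwise; an art session is ``drawing`` during non-eraser strokes,
``erasing`` during eraser strokes and ``idle`` otherwise.  The derived
intervals tile the whole session span [0, duration] without overlap or gap,
with adjacent equal-label intervals merged and zero-length intervals
dropped; every time metric downstream is a function of these intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from strokenote.events import ArtSession, MusicSession

_EPS = 1e-12


@dataclass(frozen=True)
class StateInterval:
    """A labeled span of session time."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"state interval [{self.start}, {self.end}] is empty")

    @property
    def duration(self) -> float:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sorted disjoint union of (start, end) spans (touching spans merge)."""
    ivs = sorted(intervals)
    merged: list[list[float]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"interval [{s}, {e}] is empty")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_union_length(intervals: Iterable[tuple[float, float]]) -> float:
    """Total measure of the union of (start, end) intervals (sweep-line)."""
    return sum(e - s for s, e in merge_intervals(intervals))


def _tile(
    active: Sequence[tuple[float, float, str]], duration: float
) -> list[StateInterval]:
    """Tile [0, duration] with labeled spans; gaps become ``idle``."""
    out: list[StateInterval] = []
    cursor = 0.0
    for s, e, label in active:
        s, e = max(s, 0.0), min(e, duration)
        if e - s <= _EPS:
            continue
        if s - cursor > _EPS:
            out.append(StateInterval("idle", cursor, s))
        if out and out[-1].label == label and abs(out[-1].end - s) <= _EPS:
            out[-1] = StateInterval(label, out[-1].start, e)
        else:
            out.append(StateInterval(label, s, e))
        cursor = e
    if duration - cursor > _EPS:
        out.append(StateInterval("idle", cursor, duration))
    return out


def derive_music_states(session: MusicSession) -> list[StateInterval]:
    """``playing`` wherever ≥ 1 note sounds, ``idle`` elsewhere."""
    session.validate()
    spans = merge_intervals((n.onset, n.offset) for n in session.notes)
    return _tile([(s, e, "playing") for s, e in spans], session.duration)


def derive_art_states(session: ArtSession) -> list[StateInterval]:
    """``drawing``/``erasing`` during strokes, ``idle`` elsewhere.

    Strokes may not overlap in time (single-pen assumption); back-to-back
    strokes of the same kind merge into one interval.  One-sample strokes
    have zero extent and contribute no interval.
    """
    session.validate()
    spans = sorted(
        (st.start, st.end, "erasing" if st.is_eraser else "drawing")
        for st in session.strokes
    )
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 < e1 - _EPS:
            raise ValueError(
                f"strokes overlap in time ([{s1}, {e1}] and [{s2}, {e2}]); "
                "a single pen cannot draw two strokes at once"
            )
    return _tile(spans, session.duration)


def write_states_tsv(states: Sequence[StateInterval], path: str | Path) -> None:
    """Debug dump: one ``label<TAB>start<TAB>end`` row per interval."""
    lines = [f"{iv.label}\t{iv.start:.6f}\t{iv.end:.6f}" for iv in states]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
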
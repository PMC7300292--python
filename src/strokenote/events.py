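"""Domain types for both session modalities and their on-disk formats.

A music session is a set of sounded piano keys (note events with onset,
offset, pitch and MIDI intensity) plus sustain-pedal hold intervals.  An art
session is a set of pen strokes, each a pen-down→pen-up trace of timed,
pressure-annotated canvas samples with a tool and color token.

Three interchange formats are supported:

* Standard MIDI File (format 0/1) → :func:`read_midi_session`
* art event log, JSONL (canonical) or CSV → :func:`read_art_log` /
  :func:`write_art_log`
* a lossless versioned session JSON mirroring the types →
  :func:`write_session` / :func:`read_session`
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

from strokenote import smf

SCHEMA_VERSION = 1

#: drawing tools offered on the tablet; the eraser is a tool like any other
TOOLS = ("oils", "pastel", "ink_pen", "water_color", "pencil", "eraser")

#: the 10-color palette
COLORS = (
    "white",
    "yellow",
    "orange",
    "pink",
    "skin",
    "red",
    "violet",
    "green",
    "blue",
    "black",
)

#: pitch classes with a black key on the piano (C#, D#, F#, G#, A#)
BLACK_PITCH_CLASSES = frozenset({1, 3, 6, 8, 10})


class ParseError(ValueError):
    """Raised when an on-disk session file violates its format contract."""


@dataclass(frozen=True)
class NoteEvent:
    """One sounded piano key: press at ``onset``, release at ``offset``.

    ``pitch`` is the MIDI note number (0–127, C4 = 60) and ``intensity`` the
    MIDI velocity of the press (1–127; a velocity-0 note-on is a release by
    MIDI convention and never becomes an event).
    """

    onset: float
    offset: float
    pitch: int
    intensity: int
    channel: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError(f"need 0 <= onset < offset, got [{self.onset}, {self.offset}]")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside 0..127")
        if not 1 <= self.intensity <= 127:
            raise ValueError(f"intensity {self.intensity} outside 1..127")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def octave(self) -> int:
        """Scientific-pitch octave number; pitch 60 (middle C) → 4."""
        return self.pitch // 12 - 1

    @property
    def pitch_class(self) -> int:
        return self.pitch % 12

    @property
    def is_black(self) -> bool:
        return self.pitch_class in BLACK_PITCH_CLASSES


@dataclass(frozen=True)
class PedalInterval:
    """A contiguous sustain-pedal hold (one "press")."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"pedal interval [{self.start}, {self.end}] is empty")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MusicSession:
    """A played musical work: its note events, pedal holds and clock span."""

    notes: list[NoteEvent] = field(default_factory=list)
    pedal: list[PedalInterval] = field(default_factory=list)
    duration: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.notes:
            last = max(n.offset for n in self.notes)
            if self.duration < last - 1e-9:
                raise ValueError(f"duration {self.duration} < last note offset {last}")
        ends = [p.end for p in self.pedal]
        if ends and self.duration < max(ends) - 1e-9:
            raise ValueError("duration < last pedal end")
        for a, b in zip(self.pedal, self.pedal[1:]):
            if b.start < a.end:
                raise ValueError("pedal intervals must be disjoint and sorted")


@dataclass(frozen=True)
class StrokeSample:
    """One digitizer sample: time, canvas position (origin top-left,
    y downward), normalized pen pressure."""

    t: float
    x: float
    y: float
    pressure: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pressure <= 1.0:
            raise ValueError(f"pressure {self.pressure} outside [0, 1]")


@dataclass
class Stroke:
    """One pen-down→pen-up trace with its tool and color tokens.

    Eraser strokes still carry a color token; color metrics ignore it.
    """

    tool: str
    color: str
    samples: list[StrokeSample]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("a stroke needs at least one sample")
        ts = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("stroke samples must be strictly increasing in t")

    @property
    def start(self) -> float:
        return self.samples[0].t

    @property
    def end(self) -> float:
        return self.samples[-1].t

    @property
    def is_eraser(self) -> bool:
        return self.tool == "eraser"


@dataclass
class ArtSession:
    """A drawn artwork: its strokes, canvas geometry and configured
    toolset/palette."""

    strokes: list[Stroke] = field(default_factory=list)
    canvas_width: float = 800.0
    canvas_height: float = 600.0
    duration: float = 0.0
    palette: tuple[str, ...] = COLORS
    toolset: tuple[str, ...] = TOOLS
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.palette = tuple(self.palette)
        self.toolset = tuple(self.toolset)
        self.validate()

    def validate(self) -> None:
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise ValueError("canvas must have positive area")
        for st in self.strokes:
            if st.tool not in self.toolset:
                raise ValueError(f"tool {st.tool!r} not in toolset")
            if st.color not in self.palette:
                raise ValueError(f"color {st.color!r} not in palette")
            for s in st.samples:
                if not (0 <= s.x <= self.canvas_width and 0 <= s.y <= self.canvas_height):
                    raise ValueError(f"sample ({s.x}, {s.y}) outside canvas")
        if self.strokes:
            last = max(st.end for st in self.strokes)
            if self.duration < last - 1e-9:
                raise ValueError(f"duration {self.duration} < last sample time {last}")


# ---------------------------------------------------------------------------
# MIDI
# ---------------------------------------------------------------------------

def read_midi_session(
    path: str | Path,
    default_tempo_bpm: float = 120.0,
    origin: float | None = None,
) -> MusicSession:
    """Read a Standard MIDI File (format 0/1) into a :class:`MusicSession`.

    Note-on/note-off pairs are matched FIFO per (channel, pitch); a
    velocity-0 note-on counts as a note-off.  Tick times are converted to
    seconds through the file's tempo map (``default_tempo_bpm`` when the
    file carries no tempo meta event).  The control-change-64 stream is
    thresholded at value ≥ 64 into sustain-pedal intervals.

    The session clock starts at the first note or pedal event of the file
    unless ``origin`` gives an explicit origin (seconds in file time).
    """
    notes, pedal, end_time = smf.read_note_stream(Path(path), default_tempo_bpm)
    starts = [t for t, *_ in notes] + [s for s, _ in pedal]
    if origin is None:
        origin = min(starts) if starts else 0.0
    note_events = [
        NoteEvent(onset=on - origin, offset=off - origin, pitch=p, intensity=v, channel=ch)
        for on, off, p, v, ch in notes
    ]
    note_events.sort(key=lambda n: (n.onset, n.pitch))
    pedal_iv = [PedalInterval(s - origin, e - origin) for s, e in pedal]
    duration = max(
        [end_time - origin]
        + [n.offset for n in note_events]
        + [p.end for p in pedal_iv]
        + [0.0]
    )
    return MusicSession(notes=note_events, pedal=pedal_iv, duration=duration)


def write_midi_session(session: MusicSession, path: str | Path, tempo_bpm: float = 120.0) -> None:
    """Write a session as a format-0 Standard MIDI File (480 PPQ)."""
    smf.write_note_stream(
        Path(path),
        notes=[(n.onset, n.offset, n.pitch, n.intensity, n.channel) for n in session.notes],
        pedal=[(p.start, p.end) for p in session.pedal],
        duration=session.duration,
        tempo_bpm=tempo_bpm,
    )


# ---------------------------------------------------------------------------
# Art event logs
# ---------------------------------------------------------------------------

_ART_FIELDS = ("t", "x", "y", "pressure", "tool", "color", "pen")


def _records_to_session(
    records: list[dict[str, Any]],
    header: dict[str, Any],
    path: str | Path,
) -> ArtSession:
    palette = tuple(header.get("palette", COLORS))
    toolset = tuple(header.get("toolset", TOOLS))
    strokes: list[Stroke] = []
    cur: list[StrokeSample] | None = None
    cur_tool = cur_color = ""
    prev_t = -math.inf
    for rec in records:
        line = rec.pop("_line", "?")
        t = float(rec["t"])
        if t < prev_t:
            raise ParseError(f"{path}:{line}: records out of time order (t={t} after {prev_t})")
        prev_t = t
        pen = rec["pen"]
        if pen not in ("down", "move", "up"):
            raise ParseError(f"{path}:{line}: unknown pen token {pen!r}")
        tool, color = rec["tool"], rec["color"]
        if tool not in toolset:
            raise ParseError(f"{path}:{line}: unknown tool token {tool!r}")
        if color not in palette:
            raise ParseError(f"{path}:{line}: unknown color token {color!r}")
        sample = StrokeSample(t=t, x=float(rec["x"]), y=float(rec["y"]),
                              pressure=float(rec["pressure"]))
        if pen == "down":
            if cur is not None:
                raise ParseError(f"{path}:{line}: 'down' while pen already down")
            cur = [sample]
            cur_tool, cur_color = tool, color
        elif pen == "move":
            if cur is None:
                raise ParseError(f"{path}:{line}: 'move' without matching 'down'")
            cur.append(sample)
        else:  # up
            if cur is None:
                raise ParseError(f"{path}:{line}: 'up' without matching 'down'")
            if sample.t > cur[-1].t:
                cur.append(sample)
            strokes.append(Stroke(tool=cur_tool, color=cur_color, samples=cur))
            cur = None
    if cur is not None:
        raise ParseError(f"{path}: pen still down at end of log")
    duration = float(header.get("duration", strokes[-1].end if strokes else 0.0))
    return ArtSession(
        strokes=strokes,
        canvas_width=float(header.get("canvas_width", 800.0)),
        canvas_height=float(header.get("canvas_height", 600.0)),
        duration=duration,
        palette=palette,
        toolset=toolset,
        meta=dict(header.get("meta", {})),
    )


def read_art_log(path: str | Path) -> ArtSession:
    """Read a tablet stroke log (JSONL canonical, CSV accepted).

    JSONL: the first line is a metadata object (canvas_width, canvas_height,
    palette, toolset, optional duration/meta); every following line is a
    sample record with keys t, x, y, pressure, tool, color, pen where pen ∈
    {down, move, up}.  CSV: ``# key=value`` metadata comment lines, then a
    header row with the same columns.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        lines = [ln for ln in text.splitlines() if ln.strip()]
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:1: bad metadata line: {exc}") from exc
        records = []
        for i, ln in enumerate(lines[1:], start=2):
            try:
                rec = json.loads(ln)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{i}: bad record: {exc}") from exc
            missing = [k for k in _ART_FIELDS if k not in rec]
            if missing:
                raise ParseError(f"{path}:{i}: record missing fields {missing}")
            rec["_line"] = i
            records.append(rec)
        return _records_to_session(records, header, path)
    # CSV dialect
    header: dict[str, Any] = {}
    body: list[str] = []
    for ln in text.splitlines():
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            key, val = key.strip(), val.strip()
            if key in ("palette", "toolset"):
                header[key] = tuple(v.strip() for v in val.split(","))
            elif key:
                header[key] = val
        elif ln.strip():
            body.append(ln)
    if not body:
        raise ParseError(f"{path}: no header row")
    reader = csv.DictReader(body)
    if reader.fieldnames is None or set(_ART_FIELDS) - set(reader.fieldnames):
        raise ParseError(f"{path}: CSV header must contain columns {_ART_FIELDS}")
    records = []
    for i, rec in enumerate(reader, start=2):
        rec["_line"] = i
        records.append(rec)
    return _records_to_session(records, header, path)


def write_art_log(session: ArtSession, path: str | Path) -> None:
    """Write a session as a JSONL stroke log (inverse of :func:`read_art_log`)."""
    path = Path(path)
    header = {
        "canvas_width": session.canvas_width,
        "canvas_height": session.canvas_height,
        "palette": list(session.palette),
        "toolset": list(session.toolset),
        "duration": session.duration,
        "meta": session.meta,
    }
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps(header, ensure_ascii=False) + "\n")
        for st in session.strokes:
            n = len(st.samples)
            for i, s in enumerate(st.samples):
                pen = "down" if i == 0 else ("up" if i == n - 1 and n > 1 else "move")
                rec = {"t": s.t, "x": s.x, "y": s.y, "pressure": s.pressure,
                       "tool": st.tool, "color": st.color, "pen": pen}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            if n == 1:
                s = st.samples[0]
                rec = {"t": s.t, "x": s.x, "y": s.y, "pressure": s.pressure,
                       "tool": st.tool, "color": st.color, "pen": "up"}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Session JSON (lossless round-trip)
# ---------------------------------------------------------------------------

def session_to_dict(session: MusicSession | ArtSession) -> dict[str, Any]:
    if isinstance(session, MusicSession):
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "music",
            "duration": session.duration,
            "meta": session.meta,
            "notes": [
                {"onset": n.onset, "offset": n.offset, "pitch": n.pitch,
                 "intensity": n.intensity, "channel": n.channel}
                for n in session.notes
            ],
            "pedal": [[p.start, p.end] for p in session.pedal],
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "art",
        "duration": session.duration,
        "canvas_width": session.canvas_width,
        "canvas_height": session.canvas_height,
        "palette": list(session.palette),
        "toolset": list(session.toolset),
        "meta": session.meta,
        "strokes": [
            {"tool": st.tool, "color": st.color,
             "samples": [[s.t, s.x, s.y, s.pressure] for s in st.samples]}
            for st in session.strokes
        ],
    }


def session_from_dict(obj: dict[str, Any]) -> MusicSession | ArtSession:
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"unsupported schema_version {obj.get('schema_version')!r}")
    kind = obj.get("kind")
    if kind == "music":
        return MusicSession(
            notes=[NoteEvent(**n) for n in obj["notes"]],
            pedal=[PedalInterval(s, e) for s, e in obj["pedal"]],
            duration=obj["duration"],
            meta=dict(obj.get("meta", {})),
        )
    if kind == "art":
        return ArtSession(
            strokes=[
                Stroke(tool=st["tool"], color=st["color"],
                       samples=[StrokeSample(*s) for s in st["samples"]])
                for st in obj["strokes"]
            ],
            canvas_width=obj["canvas_width"],
            canvas_height=obj["canvas_height"],
            duration=obj["duration"],
            palette=tuple(obj["palette"]),
            toolset=tuple(obj["toolset"]),
            meta=dict(obj.get("meta", {})),
        )
    raise ParseError(f"unknown session kind {kind!r}")


def write_session(session: MusicSession | ArtSession, path: str | Path) -> None:
    """Lossless JSON serialization; ``read_session(write_session(s)) == s``."""
    Path(path).write_text(
        json.dumps(session_to_dict(session), ensure_ascii=False, indent=1) + "\n",
        encoding="utf-8",
    )


def read_session(path: str | Path) -> MusicSession | ArtSession:
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid session JSON: {exc}") from exc
    return session_from_dict(obj)
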
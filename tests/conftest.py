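import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from strokenote.events import (
    ArtSession,
    MusicSession,
    NoteEvent,
    PedalInterval,
    Stroke,
    StrokeSample,
)


def note(onset, offset, pitch=60, intensity=64, channel=0):
    return NoteEvent(onset, offset, pitch, intensity, channel)


def stroke(samples, tool="pencil", color="blue"):
    """samples: iterable of (t, x, y[, pressure])"""
    out = []
    for s in samples:
        t, x, y = s[:3]
        p = s[3] if len(s) > 3 else 0.5
        out.append(StrokeSample(t, x, y, p))
    return Stroke(tool=tool, color=color, samples=out)


@pytest.fixture
def two_voice_session():
    """Two keys held in parallel over the whole playing time."""
    return MusicSession(notes=[note(0, 10, 60, 80), note(0, 10, 64, 90)], duration=10)


@pytest.fixture
def empty_music_session():
    return MusicSession(duration=10.0)


@pytest.fixture
def three_stroke_art_session():
    """Hand-checkable fixture: pencil, blue ink, one eraser stroke.

    Canvas 300x300 (3x3 cells of 100).  Stroke spans: [0,2] pencil blue,
    [4,6] ink_pen red, [8,9] eraser.  Session duration 12 s.
    """
    s1 = stroke([(0, 10, 10), (1, 60, 10), (2, 90, 10)], tool="pencil", color="blue")
    s2 = stroke([(4, 50, 150), (5, 150, 150), (6, 250, 150)], tool="ink_pen", color="red")
    s3 = stroke([(8, 150, 150), (9, 160, 150)], tool="eraser", color="black")
    return ArtSession(strokes=[s1, s2, s3], canvas_width=300, canvas_height=300,
                      duration=12.0)


def brute_force_concurrency(notes, duration, dt=0.001):
    """1 ms sampling oracle: per-bin count of sounding keys."""
    if duration <= 0:
        return np.zeros(0)
    t = np.arange(dt / 2, duration, dt)
    k = np.zeros_like(t, dtype=int)
    for n in notes:
        k += (t >= n.onset) & (t < n.offset)
    return k
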
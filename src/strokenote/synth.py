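"""Seeded synthetic session generators and a parameter-recovery harness.

No deposited session data exist for either modality, so testable streams
are simulated with controllable statistical structure.  A music profile
draws note onsets from a homogeneous Poisson process, cluster sizes from a
categorical distribution, octaves from a discretized normal, pitch classes
black/white by a Bernoulli probability, intensities from a clipped normal
and note/pedal durations from exponentials.  An art profile draws stroke
start times from a Poisson process (sequentialized: one pen), stroke paths
as smoothed random walks at a target speed from grid cells sampled by a
bias map, tools/colors from weight vectors and pressures from a clipped
normal.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
profile always yields the same session.  :func:`recovery_report` closes the
loop: it simulates replicates, runs the matching metrics module and
tabulates estimate-vs-truth errors for the estimable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from strokenote.art import art_metrics
from strokenote.events import (
    BLACK_PITCH_CLASSES,
    COLORS,
    TOOLS,
    ArtSession,
    MusicSession,
    NoteEvent,
    PedalInterval,
    Stroke,
    StrokeSample,
)
from strokenote.music import music_metrics

_WHITE_CLASSES = tuple(c for c in range(12) if c not in BLACK_PITCH_CLASSES)
_BLACK_CLASSES = tuple(sorted(BLACK_PITCH_CLASSES))


@dataclass
class MusicProfile:
    """Generative parameters for a synthetic improvisation."""

    duration_s: float = 120.0
    onset_rate_per_min: float = 60.0
    octave_center: float = 4.0
    octave_spread: float = 1.0
    intensity_mean: float = 64.0
    intensity_sd: float = 15.0
    black_key_prob: float = 5.0 / 12.0
    cluster_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    note_duration_mean_s: float = 0.8
    pedal_rate_per_min: float = 2.0
    pedal_duration_mean_s: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.cluster_size_dist.values())
        if not probs or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("cluster_size_dist must be a probability distribution")
        if min(self.cluster_size_dist) < 1:
            raise ValueError("cluster sizes start at 1")
        if not 0.0 <= self.black_key_prob <= 1.0:
            raise ValueError("black_key_prob must be in [0, 1]")
        for name in ("onset_rate_per_min", "pedal_rate_per_min", "note_duration_mean_s",
                     "pedal_duration_mean_s", "intensity_sd", "octave_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ArtProfile:
    """Generative parameters for a synthetic drawing session."""

    duration_s: float = 120.0
    stroke_rate_per_min: float = 12.0
    stroke_length_mean: float = 200.0
    speed_mean: float = 150.0
    color_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in COLORS}
    )
    tool_weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TOOLS if t != "eraser"}
    )
    eraser_prob: float = 0.1
    pressure_mean: float = 0.5
    pressure_sd: float = 0.15
    canvas_bias: Optional[np.ndarray] = None  # grid of nonneg cell weights
    canvas_width: float = 800.0
    canvas_height: float = 600.0
    seed: int = 0

    def validate(self) -> None:
        if any(w < 0 for w in self.color_weights.values()) or not self.color_weights:
            raise ValueError("color_weights must be nonnegative and nonempty")
        if sum(self.color_weights.values()) <= 0:
            raise ValueError("color_weights must not all be zero")
        if any(w < 0 for w in self.tool_weights.values()) or not self.tool_weights:
            raise ValueError("tool_weights must be nonnegative and nonempty")
        if sum(self.tool_weights.values()) <= 0:
            raise ValueError("tool_weights must not all be zero")
        if not 0.0 <= self.eraser_prob <= 1.0:
            raise ValueError("eraser_prob must be in [0, 1]")
        if self.speed_mean <= 0 or self.stroke_length_mean <= 0:
            raise ValueError("speed_mean and stroke_length_mean must be positive")


def _poisson_times(rng: np.random.Generator, rate_per_min: float, duration: float):
    """Event times of a homogeneous Poisson process on [0, duration)."""
    times = []
    rate = rate_per_min / 60.0
    if rate <= 0:
        return times
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += rng.exponential(1.0 / rate)
    return times


def _weighted_choice(rng: np.random.Generator, weights: dict):
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def simulate_music_session(profile: MusicProfile) -> MusicSession:
    """Draw one seeded :class:`MusicSession` from the profile."""
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    duration = profile.duration_s
    notes: list[NoteEvent] = []
    for onset in _poisson_times(rng, profile.onset_rate_per_min, duration):
        size = _weighted_choice(rng, profile.cluster_size_dist)
        length = max(0.05, rng.exponential(profile.note_duration_mean_s))
        offset = min(onset + length, duration)
        if offset <= onset:
            continue
        intensity = int(np.clip(round(rng.normal(profile.intensity_mean,
                                                 profile.intensity_sd)), 1, 127))
        used: set[int] = set()
        for _ in range(size):
            for _attempt in range(16):
                octave = int(np.clip(round(rng.normal(profile.octave_center,
                                                      profile.octave_spread)), 0, 8))
                classes = (_BLACK_CLASSES if rng.random() < profile.black_key_prob
                           else _WHITE_CLASSES)
                pc = classes[rng.integers(len(classes))]
                pitch = 12 * (octave + 1) + pc
                if pitch not in used and 0 <= pitch <= 127:
                    used.add(pitch)
                    notes.append(NoteEvent(onset, offset, pitch, intensity))
                    break
    notes.sort(key=lambda n: (n.onset, n.pitch))
    pedal: list[PedalInterval] = []
    last_end = -math.inf
    for start in _poisson_times(rng, profile.pedal_rate_per_min, duration):
        if start <= last_end:
            continue
        end = min(start + max(0.1, rng.exponential(profile.pedal_duration_mean_s)),
                  duration)
        if end > start:
            pedal.append(PedalInterval(start, end))
            last_end = end
    return MusicSession(notes=notes, pedal=pedal, duration=duration,
                        meta={"profile_seed": profile.seed})


def simulate_art_session(profile: ArtProfile) -> ArtSession:
    """Draw one seeded :class:`ArtSession` from the profile."""
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    bias = profile.canvas_bias
    if bias is None:
        bias = np.ones((3, 3))
    bias = np.asarray(bias, dtype=float)
    if (bias < 0).any() or bias.sum() <= 0:
        raise ValueError("canvas_bias must be nonnegative with positive sum")
    rows, cols = bias.shape
    w, h = profile.canvas_width, profile.canvas_height
    fs = 50.0  # sampling rate of the simulated digitizer, Hz

    starts = _poisson_times(rng, profile.stroke_rate_per_min, profile.duration_s)
    strokes: list[Stroke] = []
    cursor = 0.0  # single pen: strokes are sequentialized in time
    for start in starts:
        start = max(start, cursor + 0.02)
        length = rng.exponential(profile.stroke_length_mean)
        stroke_dur = max(length / profile.speed_mean, 1.0 / fs)
        if start + stroke_dur > profile.duration_s:
            break
        cell = int(rng.choice(rows * cols, p=(bias / bias.sum()).ravel()))
        r, c = divmod(cell, cols)
        x = (c + rng.random()) * w / cols
        y = (r + rng.random()) * h / rows
        heading = rng.uniform(0, 2 * math.pi)
        n = max(2, int(round(stroke_dur * fs)) + 1)
        step = length / (n - 1)
        samples = []
        for i in range(n):
            t = start + stroke_dur * i / (n - 1)
            pressure = float(np.clip(rng.normal(profile.pressure_mean,
                                                profile.pressure_sd), 0.0, 1.0))
            samples.append(StrokeSample(t, min(max(x, 0.0), w),
                                        min(max(y, 0.0), h), pressure))
            heading += rng.normal(0.0, 0.35)
            x += step * math.cos(heading)
            y += step * math.sin(heading)
            # reflect off canvas edges
            if x < 0 or x > w:
                x = min(max(-x if x < 0 else 2 * w - x, 0.0), w)
                heading = math.pi - heading
            if y < 0 or y > h:
                y = min(max(-y if y < 0 else 2 * h - y, 0.0), h)
                heading = -heading
        is_eraser = rng.random() < profile.eraser_prob
        tool = "eraser" if is_eraser else _weighted_choice(rng, profile.tool_weights)
        color = _weighted_choice(rng, profile.color_weights)
        strokes.append(Stroke(tool=tool, color=color, samples=samples))
        cursor = samples[-1].t
    return ArtSession(strokes=strokes, canvas_width=w, canvas_height=h,
                      duration=profile.duration_s,
                      meta={"profile_seed": profile.seed})


def recovery_report(
    profile: MusicProfile | ArtProfile, n_replicates: int = 20
) -> pd.DataFrame:
    """Simulate ``n_replicates`` sessions and tabulate estimate vs truth.

    Columns: parameter, true, estimated, error.  Replicate seeds are spawned
    deterministically from the profile's seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    seeds = np.random.SeedSequence(profile.seed).generate_state(n_replicates) % (2**31)
    rows: list[tuple[str, float, float]] = []
    if isinstance(profile, MusicProfile):
        base = profile
        sessions = [
            simulate_music_session(MusicProfile(**{**base.__dict__, "seed": int(s)}))
            for s in seeds
        ]
        mets = [music_metrics(s) for s in sessions]
        per_rep = [np.mean([n.intensity for n in s.notes]) for s in sessions if s.notes]
        if per_rep:
            rows.append(("intensity_mean", base.intensity_mean, float(np.mean(per_rep))))
        modal_oct = [m.octave_modal for m in mets if m.octave_modal is not None]
        if modal_oct:
            rows.append(("octave_modal", round(base.octave_center),
                         float(np.median(modal_oct))))
        modal_k = [m.modal_cluster for m in mets if m.modal_cluster is not None]
        if modal_k:
            true_k = max(base.cluster_size_dist, key=base.cluster_size_dist.get)
            rows.append(("modal_cluster", true_k, float(np.median(modal_k))))
        black = [m.pct_black_presses for m in mets if m.pct_black_presses is not None]
        if black:
            rows.append(("pct_black_presses", 100.0 * base.black_key_prob,
                         float(np.mean(black))))
    elif isinstance(profile, ArtProfile):
        base = profile
        mets = []
        for s in seeds:
            kwargs = dict(base.__dict__)
            kwargs["seed"] = int(s)
            mets.append(art_metrics(simulate_art_session(ArtProfile(**kwargs))))
        eras = [m.erasure_pct_of_drawing_time for m in mets
                if m.erasure_pct_of_drawing_time is not None]
        if eras:
            rows.append(("erasure_pct", 100.0 * base.eraser_prob, float(np.mean(eras))))
        wsum = sum(base.color_weights.values())
        # expected color share of non-eraser time equals its weight share
        for color in sorted(base.color_weights):
            est = float(np.mean([
                m.color_use_pct.get(color, 0.0)
                / max(1e-12, sum(m.color_use_pct.values())) * 100.0
                if m.color_use_pct else np.nan
                for m in mets
            ]))
            rows.append((f"color_share_{color}", 100.0 * base.color_weights[color] / wsum,
                         est))
        rows.append(("pressure_mean", base.pressure_mean,
                     float(np.mean([m.mean_pressure for m in mets
                                    if m.mean_pressure is not None]))))
    else:
        raise TypeError(f"unknown profile type {type(profile)!r}")
    df = pd.DataFrame(rows, columns=["parameter", "true", "estimated"])
    df["error"] = df["estimated"] - df["true"]
    return df
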
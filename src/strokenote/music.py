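"""Music-modality metrics for a played session.

Every parameter is a deterministic function of the note/pedal event stream:
time budget (net playing vs idle), concurrent playing percentage (summed
note durations over net playing time — 200% means two keys held in parallel
throughout), key usage and press density, cluster (simultaneously held
keys) profile, octave and intensity preference profiles, pitch-class and
black/white-key distributions, chromatic transitions, crescendo /
diminuendo / accelerando / ritardando run counts, and pedal use.

Conventions: middle C (MIDI 60) is C4; the keyboard denominator is the
88-key range A0–C8; dynamics are eight equal 16-value bands pppp…ffff;
modal statistics are duration-weighted with ties broken toward the lower
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from strokenote.events import BLACK_PITCH_CLASSES, MusicSession, NoteEvent
from strokenote.states import interval_union_length

KEYBOARD_SIZE = 88  # A0 (21) … C8 (108)

PITCH_CLASS_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")

#: eight equal 16-value dynamics bands, softest to loudest; mf starts at 64
DYNAMICS_BANDS = ("pppp", "ppp", "pp", "p", "mf", "f", "ff", "ffff")

MF_INTENSITY = 64  # mezzo-forte guide value used in plots

TRANSITION_KEYS = ("white_white", "white_black", "black_white", "black_black")

#: minimum run length for crescendo/diminuendo (onsets) and
#: accelerando/ritardando (inter-onset intervals); strict monotonicity
MIN_RUN = 3


@dataclass
class MusicMetrics:
    """The flat per-session music parameter record (one table row)."""

    total_duration_min: float
    net_playing_time_s: float
    idle_time_s: float
    concurrent_playing_pct: Optional[float]
    distinct_notes: int
    total_presses: int
    pct_keys_used: float
    note_density_presses_per_min: float
    max_cluster: int
    modal_cluster: Optional[int]
    cluster_histogram: dict[int, float]
    octave_min: Optional[int]
    octave_max: Optional[int]
    octave_modal: Optional[int]
    octave_histogram: dict[int, float]
    intensity_min: Optional[int]
    intensity_max: Optional[int]
    intensity_modal: Optional[int]
    intensity_histogram: dict[str, float]
    pitch_class_histogram: dict[str, float]
    pct_black_presses: Optional[float]
    transition_counts: dict[str, float]
    n_crescendo: int
    n_diminuendo: int
    n_accelerando: int
    n_ritardando: int
    pedal_presses: int
    pedal_mean_s_per_press: Optional[float]

    modality = "music"

    def to_flat_dict(self) -> dict[str, Any]:
        """Flatten into scalar columns (histogram bins become ``*_pct_*``)."""
        out: dict[str, Any] = {
            k: v for k, v in self.__dict__.items() if not isinstance(v, dict)
        }
        for k, v in sorted(self.cluster_histogram.items()):
            out[f"cluster_pct_{k}"] = v
        for k, v in sorted(self.octave_histogram.items()):
            out[f"octave_pct_{k}"] = v
        for band in DYNAMICS_BANDS:
            out[f"intensity_pct_{band}"] = self.intensity_histogram.get(band, 0.0)
        for name in PITCH_CLASS_NAMES:
            out[f"pitch_class_pct_{name}"] = self.pitch_class_histogram.get(name, 0.0)
        for key in TRANSITION_KEYS:
            out[f"transition_pct_{key}"] = self.transition_counts.get(key, 0.0)
        return out


def _canonical(notes: Sequence[NoteEvent]) -> list[NoteEvent]:
    """Fixed accumulation order so metrics are exactly invariant to the
    order notes are listed in (float sums associate)."""
    return sorted(notes, key=lambda n: (n.onset, n.pitch, n.offset, n.intensity))


def _concurrency_segments(notes: Sequence[NoteEvent]) -> list[tuple[float, int]]:
    """Sweep-line over note spans → (segment length, #keys held) pieces, k ≥ 1."""
    events: list[tuple[float, int]] = []
    for n in notes:
        events.append((n.onset, +1))
        events.append((n.offset, -1))
    events.sort()
    segs: list[tuple[float, int]] = []
    k = 0
    prev = None
    for t, delta in events:
        if prev is not None and k > 0 and t > prev:
            segs.append((t - prev, k))
        k += delta
        prev = t
    return segs


def _modal(weights: dict, tie_low: bool = True):
    """Key with the greatest weight; ties broken toward the lower key."""
    if not weights:
        return None
    best = None
    best_w = -1.0
    for key in sorted(weights):
        if weights[key] > best_w + 1e-12:
            best, best_w = key, weights[key]
    return best


def _pct(weights: dict) -> dict:
    total = sum(weights.values())
    if total <= 0:
        return {k: 0.0 for k in weights}
    return {k: 100.0 * v / total for k, v in weights.items()}


def net_playing_time(session: MusicSession) -> float:
    """Union length of all note spans (seconds)."""
    return interval_union_length((n.onset, n.offset) for n in session.notes)


def concurrent_playing_pct(session: MusicSession) -> Optional[float]:
    """100 × Σ individual note durations / net (union) playing time.

    100% is strictly single-voice playing; two keys held in parallel
    throughout yield 200%.  Undefined (None) for a session with no notes.
    """
    if not session.notes:
        return None
    union = net_playing_time(session)
    total = sum(n.duration for n in _canonical(session.notes))
    return 100.0 * total / union


def note_usage(session: MusicSession) -> tuple[int, int, float, float]:
    """(distinct pitches, total presses, % of the 88 keys, presses/min of
    net playing time)."""
    if not session.notes:
        return 0, 0, 0.0, 0.0
    distinct = len({n.pitch for n in session.notes})
    total = len(session.notes)
    net = net_playing_time(session)
    density = total / (net / 60.0) if net > 0 else 0.0
    return distinct, total, 100.0 * distinct / KEYBOARD_SIZE, density


def cluster_profile(session: MusicSession) -> tuple[int, Optional[int], dict[int, float]]:
    """(max cluster, modal cluster, % of playing time per cluster size).

    The cluster size at an instant is the number of keys held (overlapping
    sustains, not merely simultaneous onsets).
    """
    segs = _concurrency_segments(session.notes)
    if not segs:
        return 0, None, {}
    weights: dict[int, float] = {}
    for length, k in segs:
        weights[k] = weights.get(k, 0.0) + length
    return max(weights), _modal(weights), _pct(weights)


def octave_profile(
    session: MusicSession,
) -> tuple[Optional[int], Optional[int], Optional[int], dict[int, float]]:
    """Octave (C4 = MIDI 60) min/max/modal and playing-time % histogram,
    each note weighted by its sounding duration."""
    if not session.notes:
        return None, None, None, {}
    weights: dict[int, float] = {}
    for n in _canonical(session.notes):
        weights[n.octave] = weights.get(n.octave, 0.0) + n.duration
    octs = [n.octave for n in session.notes]
    return min(octs), max(octs), _modal(weights), _pct(weights)


def intensity_profile(
    session: MusicSession,
) -> tuple[Optional[int], Optional[int], Optional[int], dict[str, float]]:
    """Raw-velocity min/max/modal and a duration-weighted histogram over the
    eight dynamics bands pppp…ffff (equal 16-value bins)."""
    if not session.notes:
        return None, None, None, {}
    raw: dict[int, float] = {}
    bands: dict[str, float] = {}
    for n in _canonical(session.notes):
        raw[n.intensity] = raw.get(n.intensity, 0.0) + n.duration
        band = DYNAMICS_BANDS[min(n.intensity // 16, 7)]
        bands[band] = bands.get(band, 0.0) + n.duration
    vals = [n.intensity for n in session.notes]
    return min(vals), max(vals), _modal(raw), _pct(bands)


def pitch_class_profile(session: MusicSession) -> tuple[dict[str, float], Optional[float]]:
    """(duration-weighted 12-bin pitch-class histogram, % black-key presses
    by press count)."""
    if not session.notes:
        return {}, None
    weights: dict[str, float] = {}
    for n in _canonical(session.notes):
        name = PITCH_CLASS_NAMES[n.pitch_class]
        weights[name] = weights.get(name, 0.0) + n.duration
    black = sum(1 for n in session.notes if n.is_black)
    return _pct(weights), 100.0 * black / len(session.notes)


def _count_runs(values: Sequence[float], direction: int, min_run: int) -> int:
    """Count maximal runs of ≥ ``min_run`` values strictly monotone in
    ``direction`` (+1 increasing, -1 decreasing)."""
    count = 0
    run = 1
    for a, b in zip(values, values[1:]):
        if (b - a) * direction > 0:
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 1
    if run >= min_run:
        count += 1
    return count


def transition_profile(
    session: MusicSession, min_run: int = MIN_RUN
) -> tuple[dict[str, float], int, int, int, int]:
    """Chromatic transition percentages and expressive run counts.

    Notes are ordered by onset (ties by pitch ascending).  Each consecutive
    onset pair is classified white/black × white/black; the four categories
    are reported as % of all transitions.  A crescendo (diminuendo) is a
    maximal run of ≥ ``min_run`` onsets with strictly increasing
    (decreasing) intensity; an accelerando (ritardando) is a maximal run of
    ≥ ``min_run`` inter-onset intervals strictly decreasing (increasing).
    """
    ordered = sorted(session.notes, key=lambda n: (n.onset, n.pitch))
    counts = {k: 0 for k in TRANSITION_KEYS}
    for a, b in zip(ordered, ordered[1:]):
        key = f"{'black' if a.is_black else 'white'}_{'black' if b.is_black else 'white'}"
        counts[key] += 1
    total = sum(counts.values())
    pcts = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    intensities = [n.intensity for n in ordered]
    n_cresc = _count_runs(intensities, +1, min_run)
    n_dim = _count_runs(intensities, -1, min_run)
    iois = [b.onset - a.onset for a, b in zip(ordered, ordered[1:])]
    n_accel = _count_runs(iois, -1, min_run)
    n_rit = _count_runs(iois, +1, min_run)
    return pcts, n_cresc, n_dim, n_accel, n_rit


def pedal_stats(session: MusicSession) -> tuple[int, Optional[float]]:
    """(number of pedal presses, mean seconds per press)."""
    n = len(session.pedal)
    if n == 0:
        return 0, None
    return n, sum(p.duration for p in session.pedal) / n


def music_metrics(session: MusicSession) -> MusicMetrics:
    """Populate the full :class:`MusicMetrics` record (pure function)."""
    session.validate()
    net = net_playing_time(session)
    distinct, presses, pct_keys, density = note_usage(session)
    max_k, modal_k, k_hist = cluster_profile(session)
    o_min, o_max, o_mod, o_hist = octave_profile(session)
    i_min, i_max, i_mod, i_hist = intensity_profile(session)
    pc_hist, pct_black = pitch_class_profile(session)
    trans, n_cresc, n_dim, n_accel, n_rit = transition_profile(session)
    pedal_n, pedal_mean = pedal_stats(session)
    return MusicMetrics(
        total_duration_min=session.duration / 60.0,
        net_playing_time_s=net,
        idle_time_s=session.duration - net,
        concurrent_playing_pct=concurrent_playing_pct(session),
        distinct_notes=distinct,
        total_presses=presses,
        pct_keys_used=pct_keys,
        note_density_presses_per_min=density,
        max_cluster=max_k,
        modal_cluster=modal_k,
        cluster_histogram=k_hist,
        octave_min=o_min,
        octave_max=o_max,
        octave_modal=o_mod,
        octave_histogram=o_hist,
        intensity_min=i_min,
        intensity_max=i_max,
        intensity_modal=i_mod,
        intensity_histogram=i_hist,
        pitch_class_histogram=pc_hist,
        pct_black_presses=pct_black,
        transition_counts=trans,
        n_crescendo=n_cresc,
        n_diminuendo=n_dim,
        n_accelerando=n_accel,
        n_ritardando=n_rit,
        pedal_presses=pedal_n,
        pedal_mean_s_per_press=pedal_mean,
    )
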
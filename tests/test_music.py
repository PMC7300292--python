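"""Music-modality metrics: worked examples, oracles, and invariances."""

import numpy as np
import pytest

from strokenote.events import MusicSession, PedalInterval
from strokenote.music import (
    cluster_profile,
    concurrent_playing_pct,
    intensity_profile,
    music_metrics,
    note_usage,
    octave_profile,
    pedal_stats,
    pitch_class_profile,
    transition_profile,
)
from strokenote.synth import MusicProfile, simulate_music_session

from conftest import brute_force_concurrency, note


class TestConcurrentPlaying:
    def test_two_parallel_voices_are_200_pct(self, two_voice_session):
        assert concurrent_playing_pct(two_voice_session) == 200.0

    def test_single_voice_is_100_pct(self):
        session = MusicSession(notes=[note(0, 5)], duration=5)
        assert concurrent_playing_pct(session) == 100.0

    def test_partial_overlap_matches_sampling_oracle(self):
        session = MusicSession(notes=[note(0, 4), note(2, 6, pitch=62)], duration=6)
        got = concurrent_playing_pct(session)
        assert got == pytest.approx(133.3333, abs=1e-3)
        k = brute_force_concurrency(session.notes, 6.0)
        oracle = 100.0 * k[k > 0].mean()
        assert got == pytest.approx(oracle, rel=0.005)

    def test_empty_session_is_undefined(self, empty_music_session):
        assert concurrent_playing_pct(empty_music_session) is None


class TestNoteUsage:
    def test_distinct_vs_total_presses(self):
        session = MusicSession(notes=[note(0, 1, 60), note(2, 3, 60), note(4, 5, 61)],
                               duration=5)
        distinct, total, pct, _ = note_usage(session)
        assert (distinct, total) == (2, 3)
        assert pct == pytest.approx(100 * 2 / 88, abs=0.005)  # 2.27% of 88 keys

    def test_empty(self, empty_music_session):
        assert note_usage(empty_music_session) == (0, 0, 0.0, 0.0)

    def test_density_per_net_playing_minute(self):
        # 12 presses tiling exactly 2 minutes of playing
        notes = [note(10 * i, 10 * (i + 1), 60 + i % 3) for i in range(12)]
        session = MusicSession(notes=notes, duration=120)
        assert note_usage(session)[3] == pytest.approx(6.0)


class TestClusterProfile:
    def test_two_parallel_notes(self, two_voice_session):
        mx, modal, hist = cluster_profile(two_voice_session)
        assert (mx, modal) == (2, 2)
        assert hist[2] == pytest.approx(100.0)

    def test_sweep_line_matches_sampling_oracle(self):
        session = MusicSession(
            notes=[note(0, 2), note(1, 3, pitch=62), note(2.5, 4, pitch=64)],
            duration=4)
        mx, modal, hist = cluster_profile(session)
        assert mx == 2
        k = brute_force_concurrency(session.notes, 4.0)
        counts = np.bincount(k)
        for size, pct in hist.items():
            assert pct == pytest.approx(100 * counts[size] / counts[1:].sum(),
                                        rel=0.005, abs=0.05)

    def test_empty(self, empty_music_session):
        assert cluster_profile(empty_music_session) == (0, None, {})


class TestOctaveProfile:
    def test_middle_c_is_octave_4(self):
        session = MusicSession(notes=[note(0, 1, pitch=60)], duration=1)
        assert octave_profile(session)[:3] == (4, 4, 4)

    def test_octave_5_is_12_semitones_up(self):
        session = MusicSession(notes=[note(0, 1, pitch=72)], duration=1)
        assert octave_profile(session)[2] == 5

    def test_single_octave_band(self):
        notes = [note(i, i + 1, pitch=36 + i) for i in range(6)]  # all octave 2..2
        session = MusicSession(notes=notes[:3], duration=10)
        o_min, o_max, o_mod, hist = octave_profile(session)
        assert o_min == o_max == o_mod == 2
        assert sum(hist.values()) == pytest.approx(100.0)


class TestIntensityProfile:
    def test_single_note(self):
        session = MusicSession(notes=[note(0, 1, intensity=64)], duration=1)
        assert intensity_profile(session)[:3] == (64, 64, 64)

    def test_uniform_velocities_give_equal_bands(self):
        # one equal-duration note per velocity 16..127: seven full 16-wide bands
        session = MusicSession(notes=[note(i, i + 1, 60, 16 + i) for i in range(112)],
                               duration=113)
        _, _, _, hist = intensity_profile(session)
        # velocities 8..127 cover the last 7 bands fully and half of the first
        assert hist["ffff"] == pytest.approx(hist["f"])
        assert sum(hist.values()) == pytest.approx(100.0)

    def test_modal_is_duration_weighted_not_press_weighted(self):
        session = MusicSession(
            notes=[note(0, 9, intensity=40)] + [note(9 + i, 9.1 + i, intensity=100)
                                                for i in range(3)],
            duration=13)
        assert intensity_profile(session)[2] == 40


class TestPitchClassProfile:
    def test_black_press_share(self):
        session = MusicSession(notes=[note(0, 1, 60), note(1, 2, 61), note(2, 3, 63)],
                               duration=3)
        hist, pct_black = pitch_class_profile(session)
        assert pct_black == pytest.approx(66.6667, abs=1e-3)

    def test_all_classes_equal_duration_uniform(self):
        notes = [note(i, i + 1, pitch=60 + i) for i in range(12)]
        session = MusicSession(notes=notes, duration=12)
        hist, _ = pitch_class_profile(session)
        assert all(v == pytest.approx(100 / 12) for v in hist.values())

    def test_only_middle_c(self):
        session = MusicSession(notes=[note(0, 1, 60)], duration=1)
        hist, pct_black = pitch_class_profile(session)
        assert hist == {"C": pytest.approx(100.0)}
        assert pct_black == 0.0


class TestTransitions:
    def test_chromatic_pairs_enumerated_by_hand(self):
        # 60 (white) → 61 (black) → 66 (black) → 65 (white)
        notes = [note(i, i + 0.5, p) for i, p in enumerate([60, 61, 66, 65])]
        session = MusicSession(notes=notes, duration=4)
        pcts, *_ = transition_profile(session)
        assert pcts["white_black"] == pytest.approx(100 / 3)
        assert pcts["black_black"] == pytest.approx(100 / 3)
        assert pcts["black_white"] == pytest.approx(100 / 3)
        assert pcts["white_white"] == 0.0

    def test_crescendo_run_of_three(self):
        notes = [note(i, i + 0.5, 60 + i, intensity=v)
                 for i, v in enumerate([40, 60, 80])]
        session = MusicSession(notes=notes, duration=3)
        _, n_cresc, n_dim, _, _ = transition_profile(session)
        assert (n_cresc, n_dim) == (1, 0)

    def test_constant_tempo_has_no_tempo_runs(self):
        notes = [note(t, t + 0.5, 60) for t in [0, 1, 2, 3]]
        session = MusicSession(notes=notes, duration=4)
        _, _, _, n_accel, n_rit = transition_profile(session)
        assert (n_accel, n_rit) == (0, 0)

    def test_accelerando_needs_three_shrinking_gaps(self):
        # gaps 4, 2, 1: three strictly decreasing inter-onset intervals
        notes = [note(t, t + 0.2, 60) for t in [0, 4, 6, 7]]
        session = MusicSession(notes=notes, duration=8)
        _, _, _, n_accel, n_rit = transition_profile(session)
        assert n_accel == 1 and n_rit == 0

    def test_fewer_than_two_onsets_zero_transitions(self):
        session = MusicSession(notes=[note(0, 1, 60)], duration=1)
        pcts, *_ = transition_profile(session)
        assert all(v == 0.0 for v in pcts.values())


class TestPedal:
    def test_mean_press_duration(self):
        session = MusicSession(pedal=[PedalInterval(0, 3), PedalInterval(4, 9)],
                               duration=10)
        assert pedal_stats(session) == (2, 4.0)

    def test_no_pedal(self, empty_music_session):
        assert pedal_stats(empty_music_session) == (0, None)


class TestFullRecord:
    def test_empty_session_all_zero_or_absent(self, empty_music_session):
        m = music_metrics(empty_music_session)
        assert m.distinct_notes == 0 and m.total_presses == 0
        assert m.concurrent_playing_pct is None and m.modal_cluster is None
        assert m.octave_modal is None and m.intensity_modal is None
        assert m.net_playing_time_s == 0.0 and m.idle_time_s == 10.0

    def test_two_voice_fixture(self, two_voice_session):
        m = music_metrics(two_voice_session)
        assert m.concurrent_playing_pct == 200.0
        assert m.distinct_notes == 2

    def test_recomputation_identical(self, two_voice_session):
        assert music_metrics(two_voice_session) == music_metrics(two_voice_session)


class TestInvariances:
    @pytest.fixture
    def session(self):
        return simulate_music_session(MusicProfile(duration_s=30, seed=11))

    def test_transposition_shifts_octaves_keeps_pitch_classes(self, session):
        m0 = music_metrics(session)
        up = MusicSession(
            notes=[note(n.onset, n.offset, n.pitch - 12, n.intensity)
                   for n in session.notes],
            duration=session.duration)
        m1 = music_metrics(up)
        assert m1.octave_min == m0.octave_min - 1
        assert m1.octave_max == m0.octave_max - 1
        assert m1.octave_modal == m0.octave_modal - 1
        for k, v in m0.pitch_class_histogram.items():
            assert m1.pitch_class_histogram[k] == pytest.approx(v)
        assert m1.transition_counts == pytest.approx(m0.transition_counts)

    def test_time_scaling_scales_durations_keeps_percentages(self, session):
        c = 2.5
        scaled = MusicSession(
            notes=[note(c * n.onset, c * n.offset, n.pitch, n.intensity)
                   for n in session.notes],
            pedal=[PedalInterval(c * p.start, c * p.end) for p in session.pedal],
            duration=c * session.duration)
        m0, m1 = music_metrics(session), music_metrics(scaled)
        assert m1.net_playing_time_s == pytest.approx(c * m0.net_playing_time_s)
        assert m1.concurrent_playing_pct == pytest.approx(m0.concurrent_playing_pct)
        assert m1.pct_black_presses == pytest.approx(m0.pct_black_presses)
        for k, v in m0.octave_histogram.items():
            assert m1.octave_histogram[k] == pytest.approx(v)
        assert m1.cluster_histogram == pytest.approx(m0.cluster_histogram)

    def test_note_order_permutation_invariant(self, session):
        rng = np.random.default_rng(0)
        shuffled = list(session.notes)
        rng.shuffle(shuffled)
        permuted = MusicSession(notes=shuffled, duration=session.duration,
                                pedal=session.pedal)
        assert music_metrics(permuted) == music_metrics(session)

    def test_histograms_sum_to_100(self, session):
        m = music_metrics(session)
        for hist in (m.octave_histogram, m.intensity_histogram,
                     m.pitch_class_histogram, m.cluster_histogram):
            assert sum(hist.values()) == pytest.approx(100.0, abs=1e-6)
        assert m.concurrent_playing_pct >= 100.0
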
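"""Minimal Standard MIDI File (format 0/1) reading and writing.

Only the events the session model needs are interpreted: note-on/note-off
(with the velocity-0-note-on-is-note-off convention), control change 64
(sustain pedal, pressed at value ≥ 64), and set-tempo meta events, which
build the tempo map used to convert delta ticks to seconds.  Running status
is honored; sysex and other meta events are skipped; channel aftertouch and
pitch-bend are ignored with a warning (non-piano semantics are out of
scope).  SMPTE time division is not supported.
"""

from __future__ import annotations

import struct
import warnings
from collections import defaultdict, deque
from pathlib import Path

PPQ = 480  # resolution used when writing
_PEDAL_THRESHOLD = 64  # CC64 half-point convention: >= 64 means pressed


class MidiFormatError(ValueError):
    """Raised for a malformed or unsupported Standard MIDI File."""


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    """Variable-length quantity at ``pos`` → (value, new position)."""
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiFormatError("variable-length quantity longer than 4 bytes")


def _parse_track(data: bytes):
    """Yield (abs_tick, status, data1, data2) channel events and
    (abs_tick, 'tempo', us_per_qn, None) meta tempo events."""
    pos = 0
    tick = 0
    running = None
    while pos < len(data):
        delta, pos = _read_vlq(data, pos)
        tick += delta
        if pos >= len(data):
            raise MidiFormatError("truncated track")
        byte = data[pos]
        if byte == 0xFF:  # meta
            if pos + 2 > len(data):
                raise MidiFormatError("truncated meta event")
            mtype = data[pos + 1]
            length, pos2 = _read_vlq(data, pos + 2)
            payload = data[pos2:pos2 + length]
            pos = pos2 + length
            if mtype == 0x51:
                if length != 3:
                    raise MidiFormatError("bad set-tempo length")
                yield tick, "tempo", int.from_bytes(payload, "big"), None
            elif mtype == 0x2F:
                yield tick, "eot", 0, None  # keep trailing silence in duration
                return
        elif byte in (0xF0, 0xF7):  # sysex: length-prefixed, skip
            length, pos2 = _read_vlq(data, pos + 1)
            pos = pos2 + length
            running = None
        else:
            if byte & 0x80:
                status = byte
                running = status
                pos += 1
            else:
                if running is None:
                    raise MidiFormatError("data byte with no running status")
                status = running
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            if pos + n_data > len(data):
                raise MidiFormatError("truncated channel event")
            d1 = data[pos]
            d2 = data[pos + 1] if n_data == 2 else 0
            pos += n_data
            yield tick, status, d1, d2


def _parse_file(data: bytes):
    """Parse an SMF byte string → (ppq, merged event list sorted by tick)."""
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("not a Standard MIDI File (missing MThd)")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if hlen < 6:
        raise MidiFormatError("bad MThd length")
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division not supported")
    if division == 0:
        raise MidiFormatError("zero ticks-per-quarter division")
    pos = 8 + hlen
    events = []
    for tno in range(ntrks):
        if pos + 8 > len(data):
            raise MidiFormatError(f"missing track chunk {tno}")
        if data[pos:pos + 4] != b"MTrk":
            raise MidiFormatError(f"expected MTrk chunk at offset {pos}")
        (tlen,) = struct.unpack(">I", data[pos + 4:pos + 8])
        chunk = data[pos + 8:pos + 8 + tlen]
        if len(chunk) < tlen:
            raise MidiFormatError(f"truncated track chunk {tno}")
        pos += 8 + tlen
        for i, ev in enumerate(_parse_track(chunk)):
            # (tick, track, index) keeps merged order stable and deterministic
            events.append((ev[0], tno, i, ev[1], ev[2], ev[3]))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return division, events


class _TempoMap:
    """Piecewise-constant tempo; converts absolute ticks to seconds."""

    def __init__(self, ppq: int, changes: list[tuple[int, int]], default_us: int):
        self.ppq = ppq
        changes = sorted(changes)
        if not changes or changes[0][0] > 0:
            changes.insert(0, (0, default_us))
        # prefix seconds at each change point
        self.ticks = [c[0] for c in changes]
        self.us = [c[1] for c in changes]
        self.secs = [0.0]
        for i in range(1, len(changes)):
            dt = self.ticks[i] - self.ticks[i - 1]
            self.secs.append(self.secs[-1] + dt * self.us[i - 1] / (1e6 * ppq))

    def to_seconds(self, tick: int) -> float:
        i = 0
        for j, t in enumerate(self.ticks):
            if t <= tick:
                i = j
            else:
                break
        return self.secs[i] + (tick - self.ticks[i]) * self.us[i] / (1e6 * self.ppq)


def read_note_stream(path: Path, default_tempo_bpm: float = 120.0):
    """Read an SMF into matched notes and pedal intervals, in seconds.

    Returns ``(notes, pedal, end_time)`` where notes are
    ``(onset, offset, pitch, velocity, channel)`` tuples, pedal holds are
    ``(start, end)`` and ``end_time`` is the time of the final event.
    Note pairs are matched FIFO per (channel, pitch); a dangling note-on is
    closed at the final event time with a warning.
    """
    data = Path(path).read_bytes()
    ppq, events = _parse_file(data)
    default_us = round(60e6 / default_tempo_bpm)
    tempo = _TempoMap(ppq, [(e[0], e[4]) for e in events if e[3] == "tempo"], default_us)

    open_notes: dict[tuple[int, int], deque] = defaultdict(deque)
    notes = []
    pedal = []
    pedal_down: float | None = None
    end_tick = 0
    warned_other = False
    for tick, _tno, _i, status, d1, d2 in events:
        end_tick = max(end_tick, tick)
        if status in ("tempo", "eot"):
            continue
        kind, ch = status & 0xF0, status & 0x0F
        t = tempo.to_seconds(tick)
        if kind == 0x90 and d2 > 0:
            open_notes[(ch, d1)].append((t, d2))
        elif kind == 0x80 or (kind == 0x90 and d2 == 0):
            q = open_notes[(ch, d1)]
            if q:
                onset, vel = q.popleft()
                if t > onset:
                    notes.append((onset, t, d1, vel, ch))
            # note-off with no matching on: ignore
        elif kind == 0xB0 and d1 == 64:
            if d2 >= _PEDAL_THRESHOLD and pedal_down is None:
                pedal_down = t
            elif d2 < _PEDAL_THRESHOLD and pedal_down is not None:
                if t > pedal_down:
                    pedal.append((pedal_down, t))
                pedal_down = None
        elif kind in (0xA0, 0xD0, 0xE0) and not warned_other:
            warnings.warn("ignoring aftertouch/pitch-bend events (non-piano semantics)")
            warned_other = True
    end_time = tempo.to_seconds(end_tick)
    dangling = [(ch, p) for (ch, p), q in open_notes.items() if q]
    for ch, p in sorted(dangling):
        for onset, vel in open_notes[(ch, p)]:
            warnings.warn(f"dangling note-on pitch {p} closed at end of track")
            if end_time > onset:
                notes.append((onset, end_time, p, vel, ch))
    if pedal_down is not None and end_time > pedal_down:
        pedal.append((pedal_down, end_time))
    notes.sort()
    return notes, pedal, end_time


def _vlq(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def write_note_stream(
    path: Path,
    notes,
    pedal,
    duration: float,
    tempo_bpm: float = 120.0,
) -> None:
    """Write matched notes/pedal (seconds) as a format-0 SMF at 480 PPQ."""
    us_per_qn = round(60e6 / tempo_bpm)
    ticks_per_s = PPQ * 1e6 / us_per_qn

    def tk(t: float) -> int:
        return max(0, round(t * ticks_per_s))

    # (tick, order, message): offs (order 0) precede ons (order 1) at a tick
    msgs: list[tuple[int, int, bytes]] = []
    for onset, offset, pitch, vel, ch in notes:
        msgs.append((tk(onset), 1, bytes([0x90 | ch, pitch, vel])))
        msgs.append((tk(offset), 0, bytes([0x80 | ch, pitch, 0])))
    for start, end in pedal:
        msgs.append((tk(start), 1, bytes([0xB0, 64, 127])))
        msgs.append((tk(end), 0, bytes([0xB0, 64, 0])))
    msgs.sort(key=lambda m: (m[0], m[1]))

    body = bytearray()
    body += _vlq(0) + bytes([0xFF, 0x51, 0x03]) + us_per_qn.to_bytes(3, "big")
    prev = 0
    for tick, _order, msg in msgs:
        body += _vlq(tick - prev) + msg
        prev = tick
    end_tick = max(prev, tk(duration))
    body += _vlq(end_tick - prev) + bytes([0xFF, 0x2F, 0x00])

    out = bytearray()
    out += b"MThd" + struct.pack(">IHHH", 6, 0, 1, PPQ)
    out += b"MTrk" + struct.pack(">I", len(body)) + body
    Path(path).write_bytes(bytes(out))
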
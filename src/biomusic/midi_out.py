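"""Standard MIDI File (format 1) serialization of a music event stream.

The writer converts wall-clock event times to ticks through the stream's own
piecewise-constant tempo map, so a tempo change mid-song never desynchronizes
voices.  Track 0 carries the tempo map, a 4/4 time signature and a JSON text
meta event embedding the effective sonification config plus the melody degree
sequence and key timeline (provenance for song summarization); tracks 1-4
carry the melody, chord, drum and whoosh voices on channels 0-3.

A minimal parser is included so rendered files can be round-tripped and
summarized without external tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .sonify import VOICES, MusicEvent, MusicEventStream, SonifyConfig

DEFAULT_PPQ = 480

_META_TEXT = 0x01
_META_TEMPO = 0x51
_META_TIME_SIG = 0x58
_META_EOT = 0x2F


def _vlq(value: int) -> bytes:
    """Variable-length quantity encoding of a non-negative integer."""
    if value < 0:
        raise ValidationError(f"cannot encode negative delta time {value}")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


class _TempoMap:
    """Seconds <-> ticks conversion through piecewise-constant tempo."""

    def __init__(self, segments: list[tuple[float, float]], ppq: int):
        # segments: (start_time_s, bpm), first at t=0
        self.ppq = ppq
        self.starts_s = [s for s, _ in segments]
        self.bpms = [b for _, b in segments]
        self.start_ticks = [0.0]
        for (t0, bpm), (t1, _) in zip(segments, segments[1:]):
            self.start_ticks.append(self.start_ticks[-1] + (t1 - t0) * bpm / 60.0 * ppq)

    def to_ticks(self, t: float) -> int:
        i = 0
        for j, s in enumerate(self.starts_s):
            if s <= t + 1e-12:
                i = j
        ticks = self.start_ticks[i] + (t - self.starts_s[i]) * self.bpms[i] / 60.0 * self.ppq
        return round_half_up(ticks)

    def to_seconds(self, ticks: float) -> float:
        i = 0
        for j, s in enumerate(self.start_ticks):
            if s <= ticks + 1e-9:
                i = j
        return self.starts_s[i] + (ticks - self.start_ticks[i]) * 60.0 / (self.bpms[i] * self.ppq)


def round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def _track_chunk(events: list[tuple[int, bytes]], end_tick: int) -> bytes:
    """Assemble one MTrk chunk from (absolute_tick, message_bytes) pairs."""
    events = sorted(events, key=lambda e: e[0])
    data = bytearray()
    prev = 0
    for tick, msg in events:
        data += _vlq(tick - prev)
        data += msg
        prev = tick
    data += _vlq(max(0, end_tick - prev))
    data += bytes([0xFF, _META_EOT, 0x00])
    return b"MTrk" + len(data).to_bytes(4, "big") + bytes(data)


def _meta(mtype: int, payload: bytes) -> bytes:
    return bytes([0xFF, mtype]) + _vlq(len(payload)) + payload


def render_midi(
    stream: MusicEventStream,
    ppq: int = DEFAULT_PPQ,
    path: Path | str | None = None,
) -> bytes | Path:
    """Serialize a stream to SMF format-1 bytes; write to ``path`` if given.

    Tick conversion goes through the stream's tempo map; per-event quantization
    error is at most one tick.  Output is byte-identical for identical input
    (the only embedded text is the deterministic config/provenance JSON).
    """
    if any(ev.time_s < 0 for ev in stream.events):
        raise ValidationError("stream contains an event before t=0")
    tempo_segments = stream.tempo_map()
    tmap = _TempoMap(tempo_segments, ppq)
    end_tick = tmap.to_ticks(stream.duration_s)

    embedded = {
        "config": stream.config.to_dict() if stream.config else None,
        "melody_degrees": [
            ev.degree for ev in stream.events
            if ev.etype == "note_on" and ev.voice == "melody"
        ],
        "key_timeline": [
            [ev.time_s, ev.key_offset]
            for ev in stream.events
            if ev.etype == "note_on" and ev.voice == "chord" and ev.key_offset is not None
        ],
        "duration_s": stream.duration_s,
    }
    # one key entry per chord update, not per triad note
    seen = []
    for t, k in embedded["key_timeline"]:
        if not seen or seen[-1] != [t, k]:
            seen.append([t, k])
    embedded["key_timeline"] = seen
    text = json.dumps(embedded, sort_keys=True, separators=(",", ":")).encode()

    meta_events: list[tuple[int, bytes]] = [(0, _meta(_META_TEXT, text))]
    meta_events.append((0, _meta(_META_TIME_SIG, bytes([4, 2, 24, 8]))))
    for t, bpm in tempo_segments:
        usec = round_half_up(60_000_000.0 / bpm)
        meta_events.append((tmap.to_ticks(t), _meta(_META_TEMPO, usec.to_bytes(3, "big"))))

    voice_events: dict[str, list[tuple[int, bytes]]] = {v: [] for v in VOICES}
    for ev in stream.events:
        if ev.voice is None:
            continue
        ch = VOICES.index(ev.voice)
        tick = tmap.to_ticks(ev.time_s)
        if ev.etype == "program_change":
            voice_events[ev.voice].append((tick, bytes([0xC0 | ch, ev.note])))
        elif ev.etype == "note_on":
            voice_events[ev.voice].append((tick, bytes([0x90 | ch, ev.note, ev.velocity])))
        elif ev.etype == "note_off":
            voice_events[ev.voice].append((tick, bytes([0x80 | ch, ev.note, 64])))

    header = b"MThd" + (6).to_bytes(4, "big") + (1).to_bytes(2, "big") \
        + (1 + len(VOICES)).to_bytes(2, "big") + ppq.to_bytes(2, "big")
    chunks = [_track_chunk(meta_events, end_tick)]
    for v in VOICES:
        chunks.append(_track_chunk(voice_events[v], end_tick))
    payload = header + b"".join(chunks)

    if path is not None:
        path = Path(path)
        path.write_bytes(payload)
        return path
    return payload


@dataclass
class _RawEvent:
    tick: int
    msg: bytes


def _parse_track(data: bytes) -> list[_RawEvent]:
    events = []
    pos = 0
    tick = 0
    running = None
    while pos < len(data):
        delta, pos = _read_vlq(data, pos)
        tick += delta
        status = data[pos]
        if status == 0xFF:
            mtype = data[pos + 1]
            length, npos = _read_vlq(data, pos + 2)
            events.append(_RawEvent(tick, data[pos:npos + length]))
            pos = npos + length
            running = None
        elif status in (0xF0, 0xF7):  # SysEx, skipped
            length, npos = _read_vlq(data, pos + 1)
            pos = npos + length
            running = None
        else:
            if status < 0x80:  # running status
                status = running
                body_start = pos
            else:
                running = status
                body_start = pos + 1
            n_data = 1 if (status & 0xF0) in (0xC0, 0xD0) else 2
            events.append(_RawEvent(tick, bytes([status]) + data[body_start:body_start + n_data]))
            pos = body_start + n_data
    return events


def parse_midi(source: Path | str | bytes) -> MusicEventStream:
    """Parse an SMF written by :func:`render_midi` back into an event stream.

    Voices are recovered from channels 0-3; melody degrees, the key timeline
    and the config are recovered from the embedded JSON text meta event.
    """
    data = source if isinstance(source, bytes) else Path(source).read_bytes()
    if data[:4] != b"MThd":
        raise ValidationError("not a Standard MIDI File (missing MThd)")
    ppq = int.from_bytes(data[12:14], "big")
    n_tracks = int.from_bytes(data[10:12], "big")
    pos = 8 + int.from_bytes(data[4:8], "big")
    tracks = []
    for _ in range(n_tracks):
        if data[pos:pos + 4] != b"MTrk":
            raise ValidationError("malformed MIDI: expected MTrk chunk")
        length = int.from_bytes(data[pos + 4:pos + 8], "big")
        tracks.append(_parse_track(data[pos + 8:pos + 8 + length]))
        pos += 8 + length

    # tempo map and embedded provenance from track 0
    tempo_ticks: list[tuple[int, float]] = []
    embedded = None
    for ev in tracks[0]:
        if ev.msg[1] == _META_TEMPO:
            usec = int.from_bytes(ev.msg[-3:], "big")
            tempo_ticks.append((ev.tick, 60_000_000.0 / usec))
        elif ev.msg[1] == _META_TEXT:
            length, start = _read_vlq(ev.msg, 2)
            try:
                embedded = json.loads(ev.msg[start:start + length].decode())
            except (UnicodeDecodeError, json.JSONDecodeError):
                embedded = None
    if not tempo_ticks or tempo_ticks[0][0] > 0:
        tempo_ticks.insert(0, (0, 120.0))

    # build seconds-domain tempo segments by walking tick segments
    segments: list[tuple[float, float]] = []
    t = 0.0
    for i, (tick, bpm) in enumerate(tempo_ticks):
        if i > 0:
            ptick, pbpm = tempo_ticks[i - 1]
            t += (tick - ptick) * 60.0 / (pbpm * ppq)
        segments.append((t, bpm))
    tmap = _TempoMap(segments, ppq)

    events: list[MusicEvent] = [MusicEvent(t, "tempo_change", bpm=bpm) for t, bpm in segments]
    end_tick = 0
    for track in tracks[1:]:
        for ev in track:
            end_tick = max(end_tick, ev.tick)
            status = ev.msg[0]
            kind = status & 0xF0
            ch = status & 0x0F
            if ch >= len(VOICES):
                continue
            voice = VOICES[ch]
            time_s = tmap.to_seconds(ev.tick)
            if kind == 0xC0:
                events.append(MusicEvent(time_s, "program_change", voice=voice, note=ev.msg[1]))
            elif kind == 0x90 and ev.msg[2] > 0:
                events.append(MusicEvent(time_s, "note_on", voice=voice, note=ev.msg[1],
                                         velocity=ev.msg[2]))
            elif kind == 0x80 or (kind == 0x90 and ev.msg[2] == 0):
                events.append(MusicEvent(time_s, "note_off", voice=voice, note=ev.msg[1]))
    for track in tracks:
        for ev in track:
            end_tick = max(end_tick, ev.tick)

    # reattach provenance
    config = None
    if embedded:
        if embedded.get("config"):
            config = SonifyConfig.from_dict(embedded["config"])
        degrees = list(embedded.get("melody_degrees", []))
        key_timeline = [(float(t), int(k)) for t, k in embedded.get("key_timeline", [])]
        deg_iter = iter(degrees)
        patched = []
        for ev in sorted(events, key=MusicEvent.sort_key):
            if ev.etype == "note_on" and ev.voice == "melody":
                try:
                    ev = MusicEvent(ev.time_s, "note_on", voice="melody", note=ev.note,
                                    velocity=ev.velocity, degree=next(deg_iter))
                except StopIteration:
                    pass
            elif ev.etype == "note_on" and ev.voice == "chord":
                key = None
                for kt, k in key_timeline:
                    if kt <= ev.time_s + 1e-6:
                        key = k
                ev = MusicEvent(ev.time_s, "note_on", voice="chord", note=ev.note,
                                velocity=ev.velocity, key_offset=key)
            patched.append(ev)
        events = patched

    duration = float(embedded["duration_s"]) if embedded and "duration_s" in embedded \
        else tmap.to_seconds(end_tick)
    return MusicEventStream(events=events, duration_s=duration, config=config)
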
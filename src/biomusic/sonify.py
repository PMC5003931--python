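"""The signal-to-music mapping engine.

Four physiological features drive four concurrent voices on a shared,
tempo-dependent musical clock:

* **melody** — skin conductance.  The first windowed EDA value anchors the
  tonic; each subsequent value maps linearly to a major-scale degree offset,
  three octaves (21 scale degrees) per 1 μS of change.  Extreme excursions
  are folded by octaves into a comfortable pitch range.
* **chords** — skin temperature.  The first temperature value anchors the
  tonic major chord; every 0.25 °C of change shifts the key (and chord) by
  one semitone.  The chord is re-voiced every two bars.
* **drum** — heart rate.  The beat tempo in BPM is 60 divided by the mean
  interbeat interval over the last four heart periods, re-evaluated at every
  bar boundary and clamped to a playable range.
* **whoosh** — respiration.  A seashore-timbre note sounds for exactly the
  duration of each detected exhalation and is silent during inhalation.

Every mapping constant lives in :class:`SonifyConfig` so the whole mapping
is auditable and overridable from a single place.  All quantization uses
round-half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import NothingToSonifyError, ValidationError
from .features import FeatureSeries

VOICES = ("melody", "chord", "drum", "whoosh")
EVENT_TYPES = ("tempo_change", "program_change", "note_off", "note_on")

#: fixed pitch of the whoosh (seashore) voice
WHOOSH_NOTE = 60

#: semitone offsets of the major-scale degrees within one octave
MAJOR_SCALE_OFFSETS = (0, 2, 4, 5, 7, 9, 11)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (used everywhere)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class SonifyConfig:
    """All mapping constants of the physiological signal-to-music interface."""

    eda_window_s: float = 0.25
    #: three 7-degree octaves of a major scale per 1 μS
    degrees_per_microsiemens: int = 21
    tonic_note: int = 60  # middle C
    mode: str = "major"
    comfortable_range: tuple[int, int] = (48, 96)
    #: temperature change per one-semitone key shift
    temp_quantum_c: float = 0.25
    key_update_bars: int = 2
    beats_per_bar: int = 4
    ibi_periods: int = 4
    tempo_clamp_bpm: tuple[float, float] = (40.0, 200.0)
    #: starting tempo before the first interbeat estimate is available
    initial_bpm: float = 60.0
    #: wall-clock spacing of instantaneous temperature samples fed to the chords
    temp_sample_interval_s: float = 1.0
    # General MIDI programs, 1-based as in the GM tables
    melody_program: int = 102  # FX 6 (goblins)
    chord_program: int = 53  # Choir Aahs
    drum_program: int = 118  # Melodic Tom
    whoosh_program: int = 123  # Seashore
    melody_velocity: int = 96
    chord_velocity: int = 64
    drum_velocity: int = 100
    whoosh_velocity: int = 80
    drum_note: int = 48

    def __post_init__(self) -> None:
        self.comfortable_range = tuple(self.comfortable_range)  # type: ignore[assignment]
        self.tempo_clamp_bpm = tuple(self.tempo_clamp_bpm)  # type: ignore[assignment]
        lo, hi = self.comfortable_range
        if hi - lo < 24:
            raise ValidationError(f"comfortable_range must span >= 2 octaves, got [{lo}, {hi}]")
        if not (0 <= lo and hi <= 127):
            raise ValidationError(f"comfortable_range must lie within MIDI [0, 127], got [{lo}, {hi}]")
        if self.mode != "major":
            raise ValidationError(f"only the major mode is implemented, got {self.mode!r}")
        if self.degrees_per_microsiemens <= 0:
            raise ValidationError("degrees_per_microsiemens must be positive")
        if self.temp_quantum_c <= 0:
            raise ValidationError("temp_quantum_c must be positive")
        clo, chi = self.tempo_clamp_bpm
        if not (0 < clo < chi):
            raise ValidationError(f"tempo_clamp_bpm must satisfy 0 < lower < upper, got [{clo}, {chi}]")
        if self.eda_window_s <= 0 or self.temp_sample_interval_s <= 0:
            raise ValidationError("window and sampling intervals must be positive")
        if self.key_update_bars < 1 or self.beats_per_bar < 1 or self.ibi_periods < 1:
            raise ValidationError("key_update_bars, beats_per_bar, ibi_periods must be >= 1")
        for name in ("melody_program", "chord_program", "drum_program", "whoosh_program"):
            if not (1 <= getattr(self, name) <= 128):
                raise ValidationError(f"{name} must be a GM program in 1..128")
        for name in ("melody_velocity", "chord_velocity", "drum_velocity", "whoosh_velocity"):
            if not (1 <= getattr(self, name) <= 127):
                raise ValidationError(f"{name} must be in 1..127")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SonifyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Path | str) -> "SonifyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def with_overrides(self, **kwargs) -> "SonifyConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MusicEvent:
    """One timestamped event of the multi-voice stream."""

    time_s: float
    etype: str
    voice: Optional[str] = None  # None for tempo changes
    note: Optional[int] = None
    velocity: Optional[int] = None
    bpm: Optional[float] = None
    #: melody scale-degree (pre-transposition) on melody note_ons
    degree: Optional[int] = None
    #: semitone key offset on chord note_ons
    key_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValidationError(f"event time must be >= 0, got {self.time_s}")
        if self.etype not in EVENT_TYPES:
            raise ValidationError(f"etype must be one of {EVENT_TYPES}, got {self.etype!r}")
        if self.voice is not None and self.voice not in VOICES:
            raise ValidationError(f"voice must be one of {VOICES}, got {self.voice!r}")
        if self.etype in ("note_on", "note_off"):
            if self.note is None or not (0 <= self.note <= 127):
                raise ValidationError(f"{self.etype} must carry a MIDI note in 0..127")
            if self.etype == "note_on" and (self.velocity is None or not (1 <= self.velocity <= 127)):
                raise ValidationError("note_on must carry a velocity in 1..127")
        if self.etype == "tempo_change" and (self.bpm is None or self.bpm <= 0):
            raise ValidationError("tempo_change must carry a positive bpm")

    def sort_key(self) -> tuple:
        return (
            self.time_s,
            EVENT_TYPES.index(self.etype),
            VOICES.index(self.voice) if self.voice is not None else -1,
            self.note if self.note is not None else -1,
        )


@dataclass
class MusicEventStream:
    """A validated, time-ordered multi-voice event stream."""

    events: list[MusicEvent]
    duration_s: float
    config: Optional[SonifyConfig] = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=MusicEvent.sort_key)
        self.validate()

    def validate(self) -> None:
        open_notes: dict[tuple[str, int], int] = {}
        for ev in self.events:
            if ev.etype == "note_on":
                key = (ev.voice, ev.note)
                open_notes[key] = open_notes.get(key, 0) + 1
                if open_notes[key] > 1:
                    raise ValidationError(f"overlapping note_on for {key} at t={ev.time_s}")
            elif ev.etype == "note_off":
                key = (ev.voice, ev.note)
                if open_notes.get(key, 0) < 1:
                    raise ValidationError(f"note_off without matching note_on for {key} at t={ev.time_s}")
                open_notes[key] -= 1
        dangling = [k for k, v in open_notes.items() if v]
        if dangling:
            raise ValidationError(f"note_on without matching note_off: {dangling}")

    def voice_events(self, voice: str) -> list[MusicEvent]:
        return [ev for ev in self.events if ev.voice == voice]

    def tempo_map(self) -> list[tuple[float, float]]:
        """Piecewise-constant (time, bpm) segments; defaults to 120 BPM."""
        tempos = [(ev.time_s, ev.bpm) for ev in self.events if ev.etype == "tempo_change"]
        if not tempos or tempos[0][0] > 0:
            tempos.insert(0, (0.0, 120.0))
        return tempos

    def note_spans(self, voice: str) -> list[tuple[float, float, int]]:
        """(start_s, end_s, note) spans for one voice, in onset order."""
        spans = []
        open_at: dict[int, float] = {}
        for ev in self.voice_events(voice):
            if ev.etype == "note_on":
                open_at[ev.note] = ev.time_s
            elif ev.etype == "note_off":
                spans.append((open_at.pop(ev.note), ev.time_s, ev.note))
        return sorted(spans)


def eda_to_degree(eda_level: float, eda_ref: float, cfg: SonifyConfig | None = None) -> int:
    """Scale-degree offset of an EDA level relative to the session reference.

    Linear map: ``degrees_per_microsiemens`` (21 = three 7-note octaves) scale
    degrees per μS of change from the first windowed EDA value.
    """
    cfg = cfg or SonifyConfig()
    if eda_level < 0 or eda_ref < 0:
        raise ValidationError("skin conductance cannot be negative")
    return round_half_away((eda_level - eda_ref) * cfg.degrees_per_microsiemens)


def degree_to_note(degree: int, key_offset_semitones: int = 0, cfg: SonifyConfig | None = None) -> int:
    """MIDI note of a major-scale degree offset from the (possibly shifted) tonic.

    Walks the diatonic interval pattern from ``tonic_note + key_offset``, then
    folds by octaves until the note lies inside the comfortable range.
    """
    cfg = cfg or SonifyConfig()
    octave, step = divmod(degree, 7)
    note = cfg.tonic_note + key_offset_semitones + 12 * octave + MAJOR_SCALE_OFFSETS[step]
    lo, hi = cfg.comfortable_range
    while note > hi:
        note -= 12
    while note < lo:
        note += 12
    return note


def temp_to_key(temp_c: float, temp_ref_c: float, cfg: SonifyConfig | None = None) -> int:
    """Semitone key offset: one ``temp_quantum_c`` of change = one semitone."""
    cfg = cfg or SonifyConfig()
    return round_half_away((temp_c - temp_ref_c) / cfg.temp_quantum_c)


def ibi_to_bpm(mean_ibi_s: float, cfg: SonifyConfig | None = None) -> float:
    """Tempo in BPM from a mean interbeat interval, clamped to a playable range."""
    cfg = cfg or SonifyConfig()
    if mean_ibi_s <= 0:
        raise ValidationError(f"mean interbeat interval must be positive, got {mean_ibi_s}")
    lo, hi = cfg.tempo_clamp_bpm
    return float(min(max(60.0 / mean_ibi_s, lo), hi))


def build_chord(key_offset: int, cfg: SonifyConfig | None = None) -> list[int]:
    """Root-position major triad one octave below the (shifted) tonic.

    The triad is folded up by octaves if it would fall below MIDI 24, and
    down if its fifth would exceed 127.
    """
    cfg = cfg or SonifyConfig()
    root = cfg.tonic_note - 12 + key_offset
    while root < 24:
        root += 12
    while root + 7 > 127:
        root -= 12
    return [root, root + 4, root + 7]


def _stream_duration(feats: dict[str, FeatureSeries], cfg: SonifyConfig) -> float:
    ends = []
    if "eda_level" in feats:
        ends.append(feats["eda_level"].times_s[-1] + cfg.eda_window_s)
    if "temp_sample" in feats:
        ends.append(feats["temp_sample"].times_s[-1])
    if "ibi" in feats:
        ends.append(feats["ibi"].times_s[-1])
    if "exhalation" in feats:
        exh = feats["exhalation"]
        ends.append(float(np.max(exh.times_s + exh.values)))
    return max(ends)


def schedule(features: dict[str, FeatureSeries], cfg: SonifyConfig | None = None) -> MusicEventStream:
    """Convert the four feature series into one multi-voice event stream.

    A single musical clock runs from t = 0: the drum voice lays one note per
    beat, the tempo is re-evaluated at every bar boundary from the latest
    interbeat value, the chord voice is re-voiced every ``key_update_bars``
    bars from the temperature at that moment, the melody voice changes note
    whenever the windowed EDA maps to a new scale degree (equal consecutive
    degrees sustain), and the whoosh voice sounds for the duration of each
    exhalation.  Absent series silence their voice.  Output is deterministic:
    identical features and config give an identical stream.
    """
    cfg = cfg or SonifyConfig()
    feats = {k: v for k, v in features.items() if v is not None and len(v) > 0}
    if not feats:
        raise NothingToSonifyError("nothing-to-sonify: all four feature series are absent")
    for kind, series in feats.items():
        if series.kind != kind:
            raise ValidationError(f"feature under key {kind!r} has kind {series.kind!r}")

    duration = _stream_duration(feats, cfg)
    events: list[MusicEvent] = []

    for voice, program in (
        ("melody", cfg.melody_program),
        ("chord", cfg.chord_program),
        ("drum", cfg.drum_program),
        ("whoosh", cfg.whoosh_program),
    ):
        events.append(MusicEvent(0.0, "program_change", voice=voice, note=program - 1))

    ibi = feats.get("ibi")
    temp = feats.get("temp_sample")
    eda = feats.get("eda_level")
    exh = feats.get("exhalation")

    # --- musical clock: beats, bars, tempo re-evaluation, key updates -------
    bpm = ibi_to_bpm(float(ibi.values[0]), cfg) if ibi is not None else cfg.initial_bpm
    events.append(MusicEvent(0.0, "tempo_change", bpm=bpm))
    key_timeline: list[tuple[float, int]] = []  # (time, semitone offset)
    prev_triad: list[int] | None = None
    temp_ref = float(temp.values[0]) if temp is not None else None

    t = 0.0
    beat_idx = 0
    bar_idx = 0
    eps = 1e-9
    while t < duration - eps:
        if beat_idx % cfg.beats_per_bar == 0:
            if ibi is not None:
                new_bpm = ibi_to_bpm(ibi.latest_at(t, default=float(ibi.values[0])), cfg)
                if new_bpm != bpm:
                    bpm = new_bpm
                    events.append(MusicEvent(t, "tempo_change", bpm=bpm))
            if temp is not None and bar_idx % cfg.key_update_bars == 0:
                key = temp_to_key(temp.latest_at(t), temp_ref, cfg)
                key_timeline.append((t, key))
                triad = build_chord(key, cfg)
                if prev_triad is not None:
                    for note in prev_triad:
                        events.append(MusicEvent(t, "note_off", voice="chord", note=note))
                for note in triad:
                    events.append(
                        MusicEvent(t, "note_on", voice="chord", note=note,
                                   velocity=cfg.chord_velocity, key_offset=key)
                    )
                prev_triad = triad
            bar_idx += 1
        if ibi is not None:
            beat_period = 60.0 / bpm
            off_t = min(t + 0.5 * beat_period, duration)
            events.append(MusicEvent(t, "note_on", voice="drum", note=cfg.drum_note,
                                     velocity=cfg.drum_velocity))
            events.append(MusicEvent(off_t, "note_off", voice="drum", note=cfg.drum_note))
        t += 60.0 / bpm
        beat_idx += 1
    if prev_triad is not None:
        for note in prev_triad:
            events.append(MusicEvent(duration, "note_off", voice="chord", note=note))

    def key_at(time_s: float) -> int:
        key = 0
        for kt, k in key_timeline:
            if kt <= time_s + eps:
                key = k
            else:
                break
        return key

    # --- melody: one potential note per EDA window, sustained across equal
    # degrees; key changes transpose future notes ----------------------------
    if eda is not None:
        eda_ref = float(eda.values[0])
        current_degree: int | None = None
        current_note: int | None = None
        for t_i, v_i in zip(eda.times_s, eda.values):
            degree = eda_to_degree(float(v_i), eda_ref, cfg)
            if current_degree is None or degree != current_degree:
                if current_note is not None:
                    events.append(MusicEvent(float(t_i), "note_off", voice="melody", note=current_note))
                note = degree_to_note(degree, key_at(float(t_i)), cfg)
                events.append(
                    MusicEvent(float(t_i), "note_on", voice="melody", note=note,
                               velocity=cfg.melody_velocity, degree=degree)
                )
                current_degree, current_note = degree, note
        if current_note is not None:
            events.append(MusicEvent(duration, "note_off", voice="melody", note=current_note))

    # --- whoosh: sounds exactly for each exhalation -------------------------
    if exh is not None:
        prev_end = -math.inf
        for t_i, d_i in zip(exh.times_s, exh.values):
            if t_i < prev_end - 1e-9:
                raise ValidationError(
                    f"overlapping exhalations: one starting at {t_i:.3f} s begins before "
                    f"the previous ends at {prev_end:.3f} s"
                )
            events.append(MusicEvent(float(t_i), "note_on", voice="whoosh", note=WHOOSH_NOTE,
                                     velocity=cfg.whoosh_velocity))
            events.append(MusicEvent(float(t_i + d_i), "note_off", voice="whoosh", note=WHOOSH_NOTE))
            prev_end = float(t_i + d_i)

    full_duration = max(duration, max(ev.time_s for ev in events))
    return MusicEventStream(events=events, duration_s=full_duration, config=cfg)
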
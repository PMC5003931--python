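"""Data-to-songs study workflow.

Mirrors the study design the sonification was evaluated under: sessions are
kept only when the child's self-reported state score rose from the relaxed
to the anxious condition; one 80-s segment per condition is randomly
extracted away from condition transitions; each segment is run through the
feature -> sonification -> MIDI chain; and musical summary descriptors are
compared between anxious and relaxed songs of the same child.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import (
    BiomusicError,
    ConditionTooShortError,
    NothingToSonifyError,
    UnscorableError,
    ValidationError,
)
from .features import (
    FeatureSeries,
    average_ibi,
    detect_beats,
    detect_exhalations,
    extract_eda_levels,
    sample_temperature,
)
from .midi_out import parse_midi, render_midi
from .physio_io import PhysioRecording, SessionMeta, slice_recording
from .sonify import MusicEventStream, SonifyConfig, schedule
from .synthgen import generate_child_session

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT_S = 80.0
DEFAULT_MARGIN_S = 30.0


@dataclass(frozen=True)
class Segment:
    """An 80-s condition-homogeneous window of one recording."""

    subject_id: str
    label: str
    start_s: float
    length_s: float = DEFAULT_SEGMENT_S

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s


@dataclass
class SongEntry:
    subject_id: str
    population: str
    label: str
    midi_path: Optional[str]
    start_s: float
    length_s: float
    status: str = "ok"
    reason: str = ""


@dataclass
class SongManifest:
    entries: list[SongEntry] = field(default_factory=list)

    @property
    def songs(self) -> list[SongEntry]:
        return [e for e in self.entries if e.status == "ok"]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.songs:
            out[e.label] = out.get(e.label, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.subject_id, e.population, e.label, e.midi_path, e.start_s, e.length_s, e.status, e.reason)
                for e in self.entries
            ],
            columns=["subject_id", "population", "label", "midi_path", "start_s", "length_s", "status", "reason"],
        )

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: Path | str) -> "SongManifest":
        df = pd.read_csv(path, keep_default_na=False)
        entries = [
            SongEntry(
                subject_id=str(r.subject_id), population=str(r.population), label=str(r.label),
                midi_path=str(r.midi_path) or None, start_s=float(r.start_s),
                length_s=float(r.length_s), status=str(r.status), reason=str(r.reason),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries)


@dataclass
class SummaryStats:
    """Deterministic musical descriptors of one song."""

    mean_bpm: float = 0.0
    note_rate_per_s: float = 0.0
    mean_melody_degree_offset: float = 0.0
    pitch_range_semitones: float = 0.0
    net_key_shift_semitones: float = 0.0
    mean_whoosh_s: float = 0.0
    whoosh_count: int = 0

    def __post_init__(self) -> None:
        values = [self.mean_bpm, self.note_rate_per_s, self.mean_melody_degree_offset,
                  self.pitch_range_semitones, self.net_key_shift_semitones, self.mean_whoosh_s]
        if not all(math.isfinite(v) for v in values):
            raise ValidationError("summary statistics must be finite")
        if self.mean_bpm < 0 or self.note_rate_per_s < 0 or self.whoosh_count < 0:
            raise ValidationError("rates and counts must be >= 0")


def validate_state(meta: SessionMeta) -> bool:
    """True iff the self-reported state score strictly increased from relaxed
    to anxious, the study's validity gate for a session."""
    if meta.relaxed_state_score is None or meta.anxious_state_score is None:
        raise UnscorableError(
            f"unscorable: subject {meta.subject_id!r} lacks a relaxed and/or anxious state score"
        )
    return meta.anxious_state_score > meta.relaxed_state_score


def extract_segments(
    rec: PhysioRecording,
    length_s: float = DEFAULT_SEGMENT_S,
    margin_s: float = DEFAULT_MARGIN_S,
    per_condition: int = 1,
    seed: int = 0,
) -> list[Segment]:
    """Randomly place condition-homogeneous segments away from transitions.

    For each condition label, a segment of ``length_s`` seconds is placed at
    a uniformly random admissible offset inside one same-label annotation
    interval shrunk by ``margin_s`` at both ends.  If no interval admits a
    window at the default margin (e.g. 2-min anxious trials), the margin
    auto-shrinks symmetrically to ``floor((interval - length) / 2)`` with a
    logged note.  Segments never span intervals and never overlap each other.
    """
    rng = np.random.default_rng(seed)
    chosen: list[Segment] = []
    for label in ("relaxed", "anxious"):
        intervals = [iv for iv in rec.annotations if iv.label == label]
        if not intervals:
            raise ConditionTooShortError(label, "no annotated interval")

        def admissible(margin: float):
            out = []
            for iv in intervals:
                span = iv.length_s - 2 * margin - length_s
                if span >= 0:
                    out.append((iv.start_s + margin, span))
            return out

        windows = admissible(margin_s)
        if not windows:
            shrunk = max((math.floor((iv.length_s - length_s) / 2.0) for iv in intervals), default=-1)
            if shrunk >= 0:
                logger.info(
                    "label %r: margin auto-shrunk from %.0f to %.0f s (short intervals)",
                    label, margin_s, shrunk,
                )
                windows = admissible(float(shrunk))
        if not windows:
            raise ConditionTooShortError(label, f"no interval fits {length_s} s")

        total = sum(span for _, span in windows)
        for _ in range(per_condition):
            for _attempt in range(1000):
                if total > 0:
                    u = rng.uniform(0.0, total)
                    for lo, span in windows:
                        if u <= span:
                            start = lo + u
                            break
                        u -= span
                else:
                    lo, _ = windows[rng.integers(len(windows))]
                    start = lo
                seg = Segment(rec.meta.subject_id, label, float(start), float(length_s))
                if all(seg.end_s <= o.start_s or seg.start_s >= o.end_s for o in chosen):
                    chosen.append(seg)
                    break
            else:
                raise ConditionTooShortError(label, "could not place non-overlapping segments")
    return chosen


def features_for_sonification(
    rec: PhysioRecording, cfg: SonifyConfig | None = None
) -> dict[str, FeatureSeries]:
    """Run the per-channel extractors on whichever channels are present."""
    cfg = cfg or SonifyConfig()
    feats: dict[str, FeatureSeries] = {}
    if "eda" in rec.channels:
        feats["eda_level"] = extract_eda_levels(rec, cfg)
    if "temp" in rec.channels:
        times = np.arange(0.0, rec.duration_s, cfg.temp_sample_interval_s)
        feats["temp_sample"] = sample_temperature(rec, times)
    if "bvp" in rec.channels:
        beats = detect_beats(rec.channels["bvp"], rec.sampling_rate_hz)
        feats["ibi"] = average_ibi(beats, cfg.ibi_periods)
    if "resp" in rec.channels:
        feats["exhalation"] = detect_exhalations(rec.channels["resp"], rec.sampling_rate_hz)
    return feats


def sonify_recording(rec: PhysioRecording, cfg: SonifyConfig | None = None) -> MusicEventStream:
    """Feature extraction plus scheduling for one (segment) recording."""
    cfg = cfg or SonifyConfig()
    feats = features_for_sonification(rec, cfg)
    if not feats:
        raise NothingToSonifyError("nothing-to-sonify: recording has no usable channels")
    return schedule(feats, cfg)


def _population_key(meta: SessionMeta) -> str:
    return f"{meta.population}_{meta.elicitation_task}"


def batch_generate(
    recs: list[PhysioRecording],
    cfg: SonifyConfig | None = None,
    out_dir: Path | str = ".",
    seed: int = 0,
    length_s: float = DEFAULT_SEGMENT_S,
    margin_s: float = DEFAULT_MARGIN_S,
) -> SongManifest:
    """Extract segments from every valid recording and render one song each.

    Sessions failing the state-score validity gate are excluded with a logged
    reason; per-segment failures are recorded in the manifest and the batch
    continues.  The manifest row order is randomized (seeded), mirroring
    random presentation order; a ``manifest.csv`` is written next to the
    songs.  The whole batch is deterministic for a fixed seed.
    """
    cfg = cfg or SonifyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(recs) + 1)
    entries: list[SongEntry] = []
    for rec, child_seed in zip(recs, child_seeds[:-1]):
        pop = _population_key(rec.meta)
        try:
            valid = validate_state(rec.meta)
        except UnscorableError as exc:
            logger.warning("excluding %s: %s", rec.meta.subject_id, exc)
            entries.append(SongEntry(rec.meta.subject_id, pop, "other", None, 0.0, 0.0,
                                     status="excluded", reason=str(exc)))
            continue
        if not valid:
            reason = "state score did not increase from relaxed to anxious"
            logger.warning("excluding %s: %s", rec.meta.subject_id, reason)
            entries.append(SongEntry(rec.meta.subject_id, pop, "other", None, 0.0, 0.0,
                                     status="excluded", reason=reason))
            continue
        seg_seed = int(np.random.default_rng(child_seed).integers(0, 2**31 - 1))
        try:
            segments = extract_segments(rec, length_s=length_s, margin_s=margin_s, seed=seg_seed)
        except ConditionTooShortError as exc:
            entries.append(SongEntry(rec.meta.subject_id, pop, "other", None, 0.0, 0.0,
                                     status="failed", reason=str(exc)))
            continue
        for seg in segments:
            midi_path = out_dir / f"{rec.meta.subject_id}_{seg.label}.mid"
            try:
                sub = slice_recording(rec, seg.start_s, seg.length_s)
                stream = sonify_recording(sub, cfg)
                render_midi(stream, path=midi_path)
                entries.append(SongEntry(rec.meta.subject_id, pop, seg.label, str(midi_path),
                                         seg.start_s, seg.length_s))
                logger.info("song subject=%s label=%s start=%.1f ok", rec.meta.subject_id,
                            seg.label, seg.start_s)
            except BiomusicError as exc:
                entries.append(SongEntry(rec.meta.subject_id, pop, seg.label, None,
                                         seg.start_s, seg.length_s, status="failed", reason=str(exc)))
                logger.warning("song subject=%s label=%s failed: %s", rec.meta.subject_id,
                               seg.label, exc)
    order = np.random.default_rng(child_seeds[-1]).permutation(len(entries))
    manifest = SongManifest([entries[i] for i in order])
    manifest.write(out_dir / "manifest.csv")
    return manifest


def summarize_song(song: Union[Path, str, MusicEventStream]) -> SummaryStats:
    """Deterministic musical descriptors of one rendered or in-memory song.

    mean_bpm is the time-weighted mean of the tempo map over the song;
    note_rate is melody note onsets per second; the mean melody degree offset
    is measured pre-transposition (recovered from embedded provenance when
    reading a MIDI file); pitch range is max - min melody note; net key shift
    is the final minus initial key offset; whoosh stats come from the whoosh
    voice's note spans.
    """
    stream = song if isinstance(song, MusicEventStream) else parse_midi(song)
    duration = stream.duration_s
    if duration <= 0 or not stream.events:
        return SummaryStats()

    tempo = stream.tempo_map()
    weighted = 0.0
    for (t0, bpm), (t1, _) in zip(tempo, tempo[1:] + [(duration, 0.0)]):
        weighted += bpm * max(0.0, min(t1, duration) - t0)
    mean_bpm = weighted / duration

    melody_ons = [ev for ev in stream.events if ev.etype == "note_on" and ev.voice == "melody"]
    note_rate = len(melody_ons) / duration
    degrees = [ev.degree for ev in melody_ons if ev.degree is not None]
    mean_degree = float(np.mean(degrees)) if degrees else 0.0
    notes = [ev.note for ev in melody_ons]
    pitch_range = float(max(notes) - min(notes)) if len(notes) >= 2 else 0.0

    keys = [ev.key_offset for ev in stream.events
            if ev.etype == "note_on" and ev.voice == "chord" and ev.key_offset is not None]
    net_key = float(keys[-1] - keys[0]) if keys else 0.0

    whooshes = stream.note_spans("whoosh")
    whoosh_durs = [end - start for start, end, _ in whooshes]
    return SummaryStats(
        mean_bpm=mean_bpm,
        note_rate_per_s=note_rate,
        mean_melody_degree_offset=mean_degree,
        pitch_range_semitones=pitch_range,
        net_key_shift_semitones=net_key,
        mean_whoosh_s=float(np.mean(whoosh_durs)) if whoosh_durs else 0.0,
        whoosh_count=len(whoosh_durs),
    )


#: descriptor -> expected anxious-vs-relaxed direction (+1 higher, -1 lower),
#: following the physiology: faster heart rate, faster breathing with shorter
#: exhalations, and busier melodic activity under anxiety.
SEPARABILITY_DIRECTIONS = {
    "mean_bpm": +1,
    "mean_whoosh_s": -1,
    "note_rate_per_s": +1,
}


def separability_report(manifest: SongManifest) -> pd.DataFrame:
    """Anxious-vs-relaxed descriptor contrasts over subject pairs.

    For each descriptor, reports the fraction of subject pairs whose anxious
    song lies in the physiologically predicted direction relative to the
    relaxed song, with an exact paired sign-test p-value.  Subjects lacking
    one ok song per condition are skipped (and n=1 cohorts are flagged in
    the ``note`` column).
    """
    from scipy.stats import binomtest

    by_subject: dict[str, dict[str, SummaryStats]] = {}
    for e in manifest.songs:
        if e.label in ("relaxed", "anxious") and e.midi_path:
            by_subject.setdefault(e.subject_id, {})[e.label] = summarize_song(e.midi_path)
    pairs = {s: d for s, d in by_subject.items() if {"relaxed", "anxious"} <= set(d)}
    labels_present = {e.label for e in manifest.songs}
    if not {"relaxed", "anxious"} <= labels_present or not pairs:
        raise ValidationError("nothing-to-compare: manifest lacks both condition labels")

    rows = []
    n = len(pairs)
    note = "n=1: single pair, direction only" if n == 1 else ""
    for descriptor, direction in SEPARABILITY_DIRECTIONS.items():
        hits = 0
        ties = 0
        for d in pairs.values():
            delta = getattr(d["anxious"], descriptor) - getattr(d["relaxed"], descriptor)
            if delta == 0:
                ties += 1
            elif delta * direction > 0:
                hits += 1
        effective = n - ties
        frac = hits / effective if effective else 0.0
        p = binomtest(hits, effective, 0.5).pvalue if effective else 1.0
        rows.append((descriptor, "anxious_higher" if direction > 0 else "anxious_lower",
                     n, frac, p, note))
    return pd.DataFrame(rows, columns=["descriptor", "predicted", "n_pairs",
                                       "fraction_predicted", "sign_test_p", "note"])


def bpm_median_rule_accuracy(manifest: SongManifest) -> float:
    """Accuracy of the one-rule rater: anxious iff mean_bpm > cohort median."""
    stats = [(e.label, summarize_song(e.midi_path).mean_bpm)
             for e in manifest.songs if e.midi_path and e.label in ("relaxed", "anxious")]
    if not stats:
        raise ValidationError("nothing-to-compare: no songs in manifest")
    median = float(np.median([bpm for _, bpm in stats]))
    correct = sum((bpm > median) == (label == "anxious") for label, bpm in stats)
    return correct / len(stats)


EXPERIMENT1_POPULATIONS = ("td_anagram",) * 5
EXPERIMENT2_POPULATIONS = ("td_anagram",) * 5 + ("td_stroop",) * 5 + ("asd",) * 5


def build_cohort(
    design: str = "exp1",
    seed: int = 0,
    sampling_rate_hz: float = 256.0,
) -> list[PhysioRecording]:
    """Synthetic cohorts mirroring the two study designs.

    ``exp1``: five typically-developing children on the anagram task.
    ``exp2``: those five plus five typically-developing Stroop children and
    five children with ASD (fifteen sessions, thirty songs).
    """
    if design not in ("exp1", "exp2"):
        raise ValidationError(f"design must be 'exp1' or 'exp2', got {design!r}")
    populations = EXPERIMENT1_POPULATIONS if design == "exp1" else EXPERIMENT2_POPULATIONS
    seeds = np.random.SeedSequence(seed).spawn(len(populations))
    recs = []
    for i, (pop, child_seed) in enumerate(zip(populations, seeds)):
        s = int(np.random.default_rng(child_seed).integers(0, 2**31 - 1))
        recs.append(
            generate_child_session(pop, seed=s, sampling_rate_hz=sampling_rate_hz,
                                   subject_id=f"{design}-{pop}-{i:02d}")
        )
    return recs
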
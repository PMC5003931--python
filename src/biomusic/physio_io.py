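"""Reading, writing and validation of physiological session recordings.

A session is a uniformly sampled multichannel recording (EDA in μS, skin
temperature in °C, blood volume pulse and respiration in arbitrary units)
stored as a UTF-8 comma-delimited text file with one header row and one
sample per row.  The sampling rate is supplied out-of-band (argument or a
JSON metadata sidecar), never inferred from timestamps.  Condition
annotations (labeled, half-open time intervals in seconds from recording
start) live in a separate CSV sidecar with header ``label,start_s,end_s``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MissingChannelError, ValidationError

logger = logging.getLogger(__name__)

#: Channel names the data model recognises, in canonical column order.
KNOWN_CHANNELS = ("eda", "temp", "bvp", "resp")

CONDITION_LABELS = ("relaxed", "anxious", "other")
POPULATIONS = ("td", "asd")
ELICITATION_TASKS = ("anagram", "stroop", "synthetic")

#: Plausible fingertip skin-temperature band; samples outside it are flagged,
#: not rejected (sensor detachment shows up as out-of-band temperature).
TEMP_PLAUSIBLE_C = (15.0, 45.0)


@dataclass
class SessionMeta:
    """Subject-level metadata attached to one recording session."""

    subject_id: str = "unknown"
    population: str = "td"
    relaxed_state_score: Optional[float] = None
    anxious_state_score: Optional[float] = None
    elicitation_task: str = "synthetic"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(f"population must be one of {POPULATIONS}, got {self.population!r}")
        if self.elicitation_task not in ELICITATION_TASKS:
            raise ValidationError(
                f"elicitation_task must be one of {ELICITATION_TASKS}, got {self.elicitation_task!r}"
            )
        for name in ("relaxed_state_score", "anxious_state_score"):
            score = getattr(self, name)
            if score is not None:
                score = float(score)
                if not np.isfinite(score) or score < 0:
                    raise ValidationError(f"{name} must be finite and >= 0, got {score}")
                setattr(self, name, score)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "population": self.population,
            "relaxed_state_score": self.relaxed_state_score,
            "anxious_state_score": self.anxious_state_score,
            "elicitation_task": self.elicitation_task,
        }


@dataclass(frozen=True)
class ConditionInterval:
    """A labeled half-open time interval [start_s, end_s) within a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValidationError(f"interval label must be one of {CONDITION_LABELS}, got {self.label!r}")
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"interval must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PhysioRecording:
    """A uniformly sampled multichannel physiological session.

    Sample ``i`` of every channel corresponds to time ``i / sampling_rate_hz``
    seconds from recording start; the reader and writer never reorder or
    resample.
    """

    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    meta: SessionMeta = field(default_factory=SessionMeta)
    annotations: list[ConditionInterval] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sampling_rate_hz = float(self.sampling_rate_hz)
        if not (self.sampling_rate_hz > 0 and np.isfinite(self.sampling_rate_hz)):
            raise ValidationError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        lengths = set()
        for name, data in list(self.channels.items()):
            if name not in KNOWN_CHANNELS:
                raise ValidationError(f"unknown channel {name!r}; expected subset of {KNOWN_CHANNELS}")
            arr = np.asarray(data, dtype=np.float64)
            if arr.ndim != 1 or arr.size < 1:
                raise ValidationError(f"channel {name!r} must be a non-empty 1-D vector")
            self.channels[name] = arr
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise ValidationError(f"channel vectors differ in length: {sorted(lengths)}")
        if "eda" in self.channels and np.any(self.channels["eda"] < 0):
            raise ValidationError("eda channel contains negative conductance values")
        if "temp" in self.channels:
            lo, hi = TEMP_PLAUSIBLE_C
            temp = self.channels["temp"]
            if np.any((temp < lo) | (temp > hi)):
                flag = f"temp outside plausible band [{lo}, {hi}] °C"
                if flag not in self.flags:
                    self.flags.append(flag)
        self._validate_annotations()

    def _validate_annotations(self) -> None:
        ivs = sorted(self.annotations, key=lambda iv: iv.start_s)
        for iv in ivs:
            if iv.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"annotation [{iv.start_s}, {iv.end_s}) extends past recording end {self.duration_s}"
                )
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValidationError(
                    f"annotations overlap: [{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )
        self.annotations = ivs

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def require_channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise MissingChannelError(name)
        return self.channels[name]


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.annotations.csv"), Path(f"{stem}.meta.json")


def read_annotations(path: Path | str) -> list[ConditionInterval]:
    """Read a ``label,start_s,end_s`` CSV sidecar into interval objects."""
    df = pd.read_csv(path)
    required = {"label", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValidationError(f"annotation file {path} must have columns {sorted(required)}")
    return [
        ConditionInterval(str(row.label), float(row.start_s), float(row.end_s))
        for row in df.itertuples(index=False)
    ]


def write_annotations(annotations: list[ConditionInterval], path: Path | str) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(iv.label, iv.start_s, iv.end_s) for iv in annotations],
        columns=["label", "start_s", "end_s"],
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_recording(
    path: Path | str,
    sampling_rate_hz: Optional[float] = None,
    annotations_path: Optional[Path | str] = None,
) -> PhysioRecording:
    """Read a delimited-text session file into a validated :class:`PhysioRecording`.

    ``sampling_rate_hz`` may be omitted only when a ``<stem>.meta.json``
    sidecar (as written by :func:`write_recording`) provides it.  Unknown
    columns are ignored with a logged warning.  If ``annotations_path`` is
    omitted, a ``<stem>.annotations.csv`` sidecar is used when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ann_sidecar, meta_sidecar = _sidecar_paths(path)

    meta = SessionMeta()
    if meta_sidecar.exists():
        payload = json.loads(meta_sidecar.read_text())
        if sampling_rate_hz is None:
            sampling_rate_hz = payload.get("sampling_rate_hz")
        meta = SessionMeta(**payload.get("meta", {}))
    if sampling_rate_hz is None:
        raise ValidationError(f"sampling rate for {path} not given and no metadata sidecar found")
    if float(sampling_rate_hz) <= 0:
        raise ValidationError(f"sampling_rate_hz must be positive, got {sampling_rate_hz}")

    try:
        # round_trip parsing so written float64 samples are recovered bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas reports the line
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    known = [c for c in df.columns if c in KNOWN_CHANNELS]
    unknown = [c for c in df.columns if c not in KNOWN_CHANNELS]
    if unknown:
        logger.warning("ignoring unknown columns %s in %s", unknown, path)
    if not known:
        raise ValidationError(f"{path} names no known channel (expected some of {KNOWN_CHANNELS})")
    channels = {}
    for name in known:
        col = pd.to_numeric(df[name], errors="raise")
        channels[name] = col.to_numpy(dtype=np.float64)

    annotations: list[ConditionInterval] = []
    if annotations_path is not None:
        annotations = read_annotations(annotations_path)
    elif ann_sidecar.exists():
        annotations = read_annotations(ann_sidecar)

    return PhysioRecording(
        sampling_rate_hz=float(sampling_rate_hz),
        channels=channels,
        meta=meta,
        annotations=annotations,
    )


def write_recording(rec: PhysioRecording, path: Path | str) -> Path:
    """Write a recording plus annotation/metadata sidecars.

    Samples are written with 17 significant digits so that
    ``read_recording(write_recording(rec))`` reproduces every float64 sample
    bit-exactly.
    """
    path = Path(path)
    cols = [c for c in KNOWN_CHANNELS if c in rec.channels]
    df = pd.DataFrame({c: rec.channels[c] for c in cols})
    df.to_csv(path, index=False, float_format="%.17g")

    ann_sidecar, meta_sidecar = _sidecar_paths(path)
    if rec.annotations:
        write_annotations(rec.annotations, ann_sidecar)
    meta_sidecar.write_text(
        json.dumps(
            {"sampling_rate_hz": rec.sampling_rate_hz, "meta": rec.meta.to_dict()},
            indent=2,
            sort_keys=True,
        )
    )
    return path


def slice_recording(rec: PhysioRecording, start_s: float, length_s: float) -> PhysioRecording:
    """Return the sub-recording covering [start_s, start_s + length_s).

    Annotations are dropped (a slice is condition-homogeneous by construction
    in the study pipeline); metadata is carried over.
    """
    i0 = int(round(start_s * rec.sampling_rate_hz))
    i1 = int(round((start_s + length_s) * rec.sampling_rate_hz))
    if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
        raise ValidationError(
            f"slice [{start_s}, {start_s + length_s}) outside recording of {rec.duration_s} s"
        )
    return PhysioRecording(
        sampling_rate_hz=rec.sampling_rate_hz,
        channels={k: v[i0:i1].copy() for k, v in rec.channels.items()},
        meta=rec.meta,
    )
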
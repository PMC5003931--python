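"""Seeded synthetic physiological-session generator.

Emulates relaxed vs anxious sessions of typically-developing children and
children with autism spectrum disorders, with channel means taken from the
cohort means reported for each population x condition cell:

* **EDA** — a tonic conductance level with slow AR(1) wander, plus phasic
  skin conductance responses (Poisson arrivals, half-cosine rise over 1 s,
  exponential decay with 4-s time constant, exponentially distributed
  amplitudes).  The tonic level is back-computed from the expected phasic
  load so the session mean of windowed EDA converges to the preset mean.
* **Temperature** — mean plus linear drift (centered so the session mean is
  the preset mean) plus Gaussian sensor noise.
* **BVP** — a unit pulse (Gaussian systolic peak, +/-20% amplitude jitter)
  repeated with interbeat intervals following an AR(1) process around the
  preset mean, truncated to [0.4, 1.5] s.
* **Respiration** — concatenated sinusoid cycles with per-breath periods
  jittered around the preset inter-breath interval.

Every generated event (beat, breath peak/trough, SCR onset) is returned as
ground truth so detector fidelity can be measured exactly.  Output is fully
reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ValidationError
from .physio_io import ConditionInterval, PhysioRecording, SessionMeta

SCR_RISE_S = 1.0
SCR_DECAY_TAU_S = 4.0
PULSE_SIGMA_S = 0.04
IBI_TRUNCATION_S = (0.4, 1.5)
CROSSFADE_S = 10.0

#: population key -> (SessionMeta population, elicitation task)
POPULATION_INFO = {
    "td_anagram": ("td", "anagram"),
    "td_stroop": ("td", "stroop"),
    "asd": ("asd", "stroop"),
}


@dataclass
class ConditionPreset:
    """Stochastic generator parameters for one population x condition cell."""

    name: str
    eda_mean_us: float
    eda_scr_rate_per_min: float
    eda_scr_amp_us: float
    temp_mean_c: float
    temp_drift_c_per_min: float
    ibi_mean_s: float
    ibi_jitter_sd_s: float
    breath_interval_s: float
    breath_jitter_sd_s: float
    noise_sd: dict[str, float] = field(default_factory=lambda: {"eda": 0.01, "temp": 0.02, "bvp": 0.02, "resp": 0.02})
    eda_wander_sd_us: float = 0.02

    def __post_init__(self) -> None:
        for name in ("eda_mean_us", "temp_mean_c", "ibi_mean_s", "breath_interval_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("eda_scr_rate_per_min", "eda_scr_amp_us", "ibi_jitter_sd_s",
                     "breath_jitter_sd_s", "eda_wander_sd_us"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.breath_interval_s <= 2 * self.breath_jitter_sd_s:
            raise ValidationError("breath_interval_s must exceed twice its jitter SD")
        missing = {"eda", "temp", "bvp", "resp"} - set(self.noise_sd)
        if missing:
            raise ValidationError(f"noise_sd missing channels {sorted(missing)}")


@dataclass
class GroundTruth:
    """Exact event times underlying one generated session."""

    beat_times_s: np.ndarray
    breath_peak_times_s: np.ndarray
    breath_trough_times_s: np.ndarray
    scr_onset_times_s: np.ndarray

    def shifted(self, offset_s: float) -> "GroundTruth":
        return GroundTruth(
            self.beat_times_s + offset_s,
            self.breath_peak_times_s + offset_s,
            self.breath_trough_times_s + offset_s,
            self.scr_onset_times_s + offset_s,
        )


def _load_registry() -> dict[str, ConditionPreset]:
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: ConditionPreset(name=name, **params) for name, params in raw.items()}


_REGISTRY: dict[str, ConditionPreset] | None = None


def preset_registry() -> dict[str, ConditionPreset]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def get_preset(name: str) -> ConditionPreset:
    registry = preset_registry()
    if name not in registry:
        raise ValidationError(f"unknown preset {name!r}; available: {sorted(registry)}")
    return registry[name]


def _scr_kernel(fs: float) -> np.ndarray:
    """Unit-amplitude SCR bump: half-cosine rise, exponential decay (5 tau)."""
    n = int(round((SCR_RISE_S + 5 * SCR_DECAY_TAU_S) * fs))
    t = np.arange(n) / fs
    rise = 0.5 * (1 - np.cos(np.pi * np.minimum(t, SCR_RISE_S) / SCR_RISE_S))
    decay = np.exp(-np.maximum(t - SCR_RISE_S, 0.0) / SCR_DECAY_TAU_S)
    return np.where(t < SCR_RISE_S, rise, decay)


def _synth_eda(preset: ConditionPreset, n: int, fs: float, rng: np.random.Generator):
    duration = n / fs
    kernel = _scr_kernel(fs)
    kernel_integral_s = kernel.sum() / fs
    rate_per_s = preset.eda_scr_rate_per_min / 60.0
    n_scr = rng.poisson(rate_per_s * duration)
    onsets = np.sort(rng.uniform(0.0, duration, n_scr))
    amps = rng.exponential(preset.eda_scr_amp_us, n_scr) if n_scr else np.array([])

    phasic = np.zeros(n)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            phasic[i0:i0 + seg] += amp * kernel[:seg]

    # expected phasic load (shot-noise mean) so session mean -> eda_mean_us
    tonic = preset.eda_mean_us - rate_per_s * preset.eda_scr_amp_us * kernel_integral_s
    if tonic <= 0:
        raise ValidationError(
            f"preset {preset.name!r}: expected phasic load exceeds eda_mean_us"
        )
    rho = np.exp(-1.0 / (fs * 30.0))  # ~30-s wander time constant
    innov = rng.normal(0.0, preset.eda_wander_sd_us * np.sqrt(1 - rho**2), n)
    from scipy.signal import lfilter

    wander = lfilter([1.0], [1.0, -rho], innov)
    noise = rng.normal(0.0, preset.noise_sd["eda"], n)
    eda = np.maximum(tonic + wander + phasic + noise, 0.0)
    return eda, onsets


def _synth_temp(preset: ConditionPreset, n: int, fs: float, rng: np.random.Generator):
    t = np.arange(n) / fs
    duration = n / fs
    drift = preset.temp_drift_c_per_min * (t - duration / 2.0) / 60.0
    return preset.temp_mean_c + drift + rng.normal(0.0, preset.noise_sd["temp"], n)


def _synth_bvp(preset: ConditionPreset, n: int, fs: float, rng: np.random.Generator):
    duration = n / fs
    lo, hi = IBI_TRUNCATION_S
    beats = []
    t_b = rng.uniform(0.6, 1.2)
    y = 0.0
    rho = 0.6
    innov_sd = preset.ibi_jitter_sd_s * np.sqrt(1 - rho**2)
    while t_b < duration - 0.6:
        beats.append(t_b)
        y = rho * y + rng.normal(0.0, innov_sd)
        t_b += float(np.clip(preset.ibi_mean_s + y, lo, hi))
    beats = np.array(beats)

    bvp = rng.normal(0.0, preset.noise_sd["bvp"], n)
    half = int(round(4 * PULSE_SIGMA_S * fs))
    for b in beats:
        amp = rng.uniform(0.8, 1.2)
        ic = int(round(b * fs))
        i0, i1 = max(0, ic - half), min(n, ic + half + 1)
        tt = np.arange(i0, i1) / fs
        bvp[i0:i1] += amp * np.exp(-0.5 * ((tt - b) / PULSE_SIGMA_S) ** 2)
    return bvp, beats


def _synth_resp(preset: ConditionPreset, n: int, fs: float, rng: np.random.Generator):
    """Respiration as a unit-amplitude oscillation with per-breath period jitter.

    The instantaneous period is piecewise-linear between breath midpoints and
    the waveform is -cos of the accumulated phase, so the signal and its
    derivative are continuous everywhere (no corners at breath boundaries).
    Ground-truth peak/trough times are the phase crossings of odd/even
    multiples of pi, interpolated to sub-sample precision.
    """
    duration = n / fs
    periods = []
    total = 0.0
    while total < duration + 2 * preset.breath_interval_s:
        period = max(0.8, rng.normal(preset.breath_interval_s, preset.breath_jitter_sd_s))
        periods.append(period)
        total += period
    periods = np.asarray(periods)
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    mids = starts + periods / 2
    t = np.arange(n) / fs
    inst_period = np.interp(t, mids, periods)
    phase = np.cumsum(2 * np.pi / inst_period) / fs
    phase -= phase[0]  # trough at t = 0
    resp = -np.cos(phase) + rng.normal(0.0, preset.noise_sd["resp"], n)

    k_max = int(phase[-1] // np.pi)
    crossings = np.interp(np.arange(1, k_max + 1) * np.pi, phase, t)
    peaks = crossings[0::2]
    troughs = crossings[1::2]
    return resp, peaks, troughs


def _synth_channels(preset: ConditionPreset, duration_s: float, fs: float, rng: np.random.Generator):
    n = int(round(duration_s * fs))
    eda, scr_onsets = _synth_eda(preset, n, fs, rng)
    temp = _synth_temp(preset, n, fs, rng)
    bvp, beats = _synth_bvp(preset, n, fs, rng)
    resp, peaks, troughs = _synth_resp(preset, n, fs, rng)
    channels = {"eda": eda, "temp": temp, "bvp": bvp, "resp": resp}
    gt = GroundTruth(beats, peaks, troughs, scr_onsets)
    return channels, gt


def generate_session(
    preset: ConditionPreset | str,
    duration_s: float,
    sampling_rate_hz: float = 256.0,
    seed: int = 0,
    subject_id: str | None = None,
) -> tuple[PhysioRecording, GroundTruth]:
    """Generate one single-condition session plus its ground-truth event lists."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if duration_s < 10:
        raise ValidationError(f"duration_s must be >= 10 s, got {duration_s}")
    rng = np.random.default_rng(seed)
    channels, gt = _synth_channels(preset, duration_s, sampling_rate_hz, rng)
    population = "asd" if preset.name.startswith("asd") else "td"
    meta = SessionMeta(
        subject_id=subject_id or f"synthetic-{preset.name}-{seed}",
        population=population,
        elicitation_task="synthetic",
    )
    rec = PhysioRecording(sampling_rate_hz=sampling_rate_hz, channels=channels, meta=meta)
    return rec, gt


def _stitch_blocks(
    blocks: list[tuple[str, ConditionPreset, float]],
    sampling_rate_hz: float,
    seed: int,
    population: str,
    subject_id: str,
) -> PhysioRecording:
    """Concatenate condition blocks with a linear signal cross-fade at boundaries.

    Each block is generated independently (spawned sub-seed), extended by half
    the cross-fade on each interior side, and blended linearly over the 10-s
    boundary window.  Condition annotations are shrunk away from the fades,
    which are labeled ``other`` (transitional state).
    """
    fs = sampling_rate_hz
    half = CROSSFADE_S / 2.0
    total = sum(d for _, _, d in blocks)
    n_total = int(round(total * fs))
    out = {c: np.zeros(n_total) for c in ("eda", "temp", "bvp", "resp")}

    seeds = np.random.SeedSequence(seed).spawn(len(blocks) + 1)
    start = 0.0
    boundaries = []
    annotations = []
    for i, (label, preset, dur) in enumerate(blocks):
        first, last = i == 0, i == len(blocks) - 1
        ext_l = 0.0 if first else half
        ext_r = 0.0 if last else half
        rng = np.random.default_rng(seeds[i])
        channels, _ = _synth_channels(preset, dur + ext_l + ext_r, fs, rng)
        i0 = int(round((start - ext_l) * fs))
        n_blk = next(iter(channels.values())).size
        weight = np.ones(n_blk)
        n_fade = int(round(CROSSFADE_S * fs))
        if not first:
            weight[:n_fade] = np.linspace(0.0, 1.0, n_fade, endpoint=False)
        if not last:
            weight[-n_fade:] = np.linspace(1.0, 0.0, n_fade, endpoint=False)
        i1 = min(n_total, i0 + n_blk)
        for c in out:
            out[c][i0:i1] += channels[c][: i1 - i0] * weight[: i1 - i0]
        ann_start = start + (0.0 if first else half)
        ann_end = start + dur - (0.0 if last else half)
        annotations.append(ConditionInterval(label, ann_start, ann_end))
        if not last:
            boundaries.append(start + dur)
        start += dur
    for b in boundaries:
        annotations.append(ConditionInterval("other", b - half, b + half))
    out["eda"] = np.maximum(out["eda"], 0.0)

    score_rng = np.random.default_rng(seeds[-1])
    relaxed_score = float(score_rng.uniform(31.0, 52.0))
    anxious_score = float(score_rng.uniform(42.0, 57.0))
    if anxious_score <= relaxed_score:
        anxious_score = relaxed_score + float(score_rng.uniform(1.0, 5.0))

    pop, task = POPULATION_INFO[population]
    meta = SessionMeta(
        subject_id=subject_id,
        population=pop,
        relaxed_state_score=relaxed_score,
        anxious_state_score=anxious_score,
        elicitation_task=task,
    )
    return PhysioRecording(
        sampling_rate_hz=fs, channels=out, meta=meta, annotations=annotations
    )


#: Experiment-1 acquisition timeline: 20-min relaxed baseline, then three
#: cycles of a 2-min anxiety task followed by a 5-min relaxed break (41 min).
CHILD_SESSION_TIMELINE = (
    ("relaxed", 1200.0),
    ("anxious", 120.0),
    ("relaxed", 300.0),
    ("anxious", 120.0),
    ("relaxed", 300.0),
    ("anxious", 120.0),
    ("relaxed", 300.0),
)


def generate_child_session(
    population: str = "td_anagram",
    seed: int = 0,
    sampling_rate_hz: float = 256.0,
    subject_id: str | None = None,
) -> PhysioRecording:
    """Generate a full child session following the study acquisition timeline."""
    if population not in POPULATION_INFO:
        raise ValidationError(f"population must be one of {sorted(POPULATION_INFO)}")
    presets = {
        "relaxed": get_preset(f"{population}_relaxed"),
        "anxious": get_preset(f"{population}_anxious"),
    }
    blocks = [(label, presets[label], dur) for label, dur in CHILD_SESSION_TIMELINE]
    return _stitch_blocks(
        blocks, sampling_rate_hz, seed, population,
        subject_id or f"{population}-child-{seed}",
    )


def generate_pair_session(
    population: str = "td_anagram",
    seed: int = 0,
    block_s: float = 160.0,
    sampling_rate_hz: float = 256.0,
    subject_id: str | None = None,
) -> PhysioRecording:
    """A compact two-block (relaxed then anxious) session for cohort studies.

    Same construction as :func:`generate_child_session` but with a single
    relaxed and a single anxious block of ``block_s`` seconds each, which is
    the smallest design from which one 80-s segment per condition can be
    extracted clear of the transition.
    """
    if population not in POPULATION_INFO:
        raise ValidationError(f"population must be one of {sorted(POPULATION_INFO)}")
    blocks = [
        ("relaxed", get_preset(f"{population}_relaxed"), float(block_s)),
        ("anxious", get_preset(f"{population}_anxious"), float(block_s)),
    ]
    return _stitch_blocks(
        blocks, sampling_rate_hz, seed, population,
        subject_id or f"{population}-pair-{seed}",
    )
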
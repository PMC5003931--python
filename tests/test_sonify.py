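import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import biomusic as bm
from biomusic.sonify import MAJOR_SCALE_OFFSETS, round_half_away

from conftest import constant_features


class TestEdaToDegree:
    def test_one_microsiemens_is_three_octaves(self, cfg):
        assert bm.eda_to_degree(2.131, 1.131, cfg) == 21

    def test_reference_is_tonic(self, cfg):
        assert bm.eda_to_degree(3.0, 3.0, cfg) == 0

    def test_one_twenty_first_is_one_degree(self, cfg):
        assert bm.eda_to_degree(1.0 + 1 / 21, 1.0, cfg) == 1

    @given(st.integers(-100, 100))
    def test_multiples_of_quantum_enumerate_exactly(self, k):
        """Brute check: k/21 uS from reference always maps to degree k."""
        ref = 2.0
        if ref + k / 21 >= 0:
            assert bm.eda_to_degree(ref + k / 21, ref) == k

    def test_round_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(1.49) == 1
        assert round_half_away(-1.5) == -2

    def test_negative_conductance_rejected(self, cfg):
        with pytest.raises(bm.ValidationError):
            bm.eda_to_degree(-0.1, 1.0, cfg)


def diatonic_walk(degree: int, tonic: int) -> int:
    """Independent oracle: step through the major-scale interval pattern."""
    pattern = [2, 2, 1, 2, 2, 2, 1]
    note = tonic
    if degree >= 0:
        for i in range(degree):
            note += pattern[i % 7]
    else:
        for i in range(-degree):
            note -= pattern[(-i - 1) % 7]
    return note


class TestDegreeToNote:
    def test_tonic_anchor(self, cfg):
        assert bm.degree_to_note(0, 0, cfg) == 60

    def test_octave_and_three_octave_walk(self, cfg):
        assert bm.degree_to_note(7, 0, cfg) == 72
        assert bm.degree_to_note(21, 0, cfg) == 96

    def test_extreme_degree_folds_into_range(self, cfg):
        # degree 28 walks to 108, folded down one octave to 96
        assert diatonic_walk(28, 60) == 108
        assert bm.degree_to_note(28, 0, cfg) == 96

    @given(st.integers(-60, 60), st.integers(-12, 12))
    def test_matches_walk_oracle_inside_range(self, degree, key):
        cfg = bm.SonifyConfig()
        raw = diatonic_walk(degree, 60 + key)
        note = bm.degree_to_note(degree, key, cfg)
        lo, hi = cfg.comfortable_range
        assert lo <= note <= hi
        assert (note - raw) % 12 == 0  # folding only ever moves whole octaves

    def test_scale_offsets_consistent_with_pattern(self):
        assert [diatonic_walk(d, 0) for d in range(7)] == list(MAJOR_SCALE_OFFSETS)


class TestTempToKey:
    def test_one_quantum_is_one_semitone(self, cfg):
        assert bm.temp_to_key(32.25, 32.0, cfg) == 1

    def test_reference_is_c_major(self, cfg):
        assert bm.temp_to_key(31.0, 31.0, cfg) == 0

    def test_three_quanta_down(self, cfg):
        assert bm.temp_to_key(31.25, 32.0, cfg) == -3


class TestIbiToBpm:
    @pytest.mark.parametrize("ibi,expected", [(1.0, 60.0), (0.5, 120.0), (0.2, 200.0), (2.0, 40.0)])
    def test_inverse_mapping_with_clamp(self, cfg, ibi, expected):
        assert bm.ibi_to_bpm(ibi, cfg) == pytest.approx(expected)

    def test_nonpositive_rejected(self, cfg):
        with pytest.raises(bm.ValidationError):
            bm.ibi_to_bpm(0.0, cfg)

    @given(st.floats(0.3, 1.5), st.floats(0.3, 1.5))
    def test_strictly_decreasing_within_clamp(self, a, b):
        cfg = bm.SonifyConfig()
        if a < b and 60 / a <= 200 and 60 / b >= 40:
            assert bm.ibi_to_bpm(a, cfg) > bm.ibi_to_bpm(b, cfg)


class TestBuildChord:
    def test_c_major_triad_below_middle_c(self, cfg):
        assert bm.build_chord(0, cfg) == [48, 52, 55]

    def test_semitone_transposition(self, cfg):
        assert bm.build_chord(1, cfg) == [49, 53, 56]

    def test_low_keys_fold_up(self, cfg):
        triad = bm.build_chord(-30, cfg)
        assert triad[0] >= 24
        assert triad[1] - triad[0] == 4 and triad[2] - triad[0] == 7


class TestSchedule:
    def test_constant_features_hand_simulation(self, cfg):
        """Constant physiology: one sustained tonic note, one re-affirmed C-major
        triad every two bars, one drum beat per second at 60 BPM, no whoosh."""
        stream = bm.schedule(constant_features(), cfg)
        assert stream.duration_s == pytest.approx(80.0)
        melody = stream.note_spans("melody")
        assert melody == [(0.0, 80.0, 60)]
        drums = stream.note_spans("drum")
        assert len(drums) == 80
        np.testing.assert_allclose([d[0] for d in drums], np.arange(80.0))
        chords = stream.note_spans("chord")
        assert len(chords) == 30  # 10 updates x 3 triad notes over 20 bars
        assert sorted({c[2] for c in chords}) == [48, 52, 55]
        assert {c[0] for c in chords} == set(np.arange(0.0, 80.0, 8.0))
        assert stream.note_spans("whoosh") == []

    def test_eda_step_jumps_three_octaves(self, cfg):
        feats = constant_features()
        values = feats["eda_level"].values.copy()
        values[160:] += 1.0  # +1 uS at t = 40 s
        feats["eda_level"] = bm.FeatureSeries("eda_level", feats["eda_level"].times_s, values)
        stream = bm.schedule(feats, cfg)
        melody = stream.note_spans("melody")
        assert [m[2] for m in melody] == [60, 96]
        assert melody[1][0] == pytest.approx(40.0)

    def test_empty_features_rejected(self, cfg):
        with pytest.raises(bm.NothingToSonifyError):
            bm.schedule({}, cfg)

    def test_tempo_doubles_when_ibi_halves(self, cfg):
        feats = constant_features(ibi_s=1.0)
        halved = dict(feats)
        halved["ibi"] = bm.FeatureSeries("ibi", feats["ibi"].times_s, feats["ibi"].values / 2)
        bpms = [e.bpm for e in bm.schedule(feats, cfg).events if e.etype == "tempo_change"]
        bpms2 = [e.bpm for e in bm.schedule(halved, cfg).events if e.etype == "tempo_change"]
        assert all(b2 == pytest.approx(2 * b1) for b1, b2 in zip(bpms, bpms2))

    def test_whoosh_occupancy_equals_exhalation_time(self, cfg):
        rng = np.random.default_rng(8)
        times = np.cumsum(rng.uniform(2.5, 4.0, 20))
        durs = rng.uniform(1.0, 1.6, 20)
        feats = constant_features()
        feats["exhalation"] = bm.FeatureSeries("exhalation", times, durs)
        stream = bm.schedule(feats, cfg)
        spans = stream.note_spans("whoosh")
        assert len(spans) == 20
        total = sum(end - start for start, end, _ in spans)
        assert total == pytest.approx(durs.sum(), abs=1e-3)

    def test_overlapping_exhalations_rejected(self, cfg):
        feats = constant_features()
        feats["exhalation"] = bm.FeatureSeries(
            "exhalation", np.array([1.0, 2.0]), np.array([1.5, 1.0])
        )
        with pytest.raises(bm.ValidationError):
            bm.schedule(feats, cfg)

    def test_melody_monotone_in_eda(self, cfg):
        """Pointwise-larger EDA never maps to a lower degree at any window."""
        rng = np.random.default_rng(4)
        times = np.arange(40) * 0.25
        base = 1.0 + np.abs(np.cumsum(rng.normal(0, 0.02, 40)))
        base[0] = 1.0
        bigger = base + np.concatenate([[0.0], rng.uniform(0, 0.3, 39)])
        deg_a = [bm.eda_to_degree(v, bigger[0], cfg) for v in bigger]
        deg_b = [bm.eda_to_degree(v, base[0], cfg) for v in base]
        assert all(a >= b for a, b in zip(deg_a, deg_b))
        # and the scheduled melody emits exactly those degrees at change points
        stream = bm.schedule(
            {"eda_level": bm.FeatureSeries("eda_level", times, bigger)}, cfg
        )
        emitted = [e.degree for e in stream.events if e.etype == "note_on" and e.voice == "melody"]
        changes = [deg_a[0]] + [d for i, d in enumerate(deg_a[1:], 1) if d != deg_a[i - 1]]
        assert emitted == changes

    def test_determinism(self, cfg):
        a = bm.schedule(constant_features(), cfg)
        b = bm.schedule(constant_features(), cfg)
        assert a.events == b.events

    def test_stream_sorted_with_fixed_tiebreak(self, cfg):
        stream = bm.schedule(constant_features(), cfg)
        keys = [e.sort_key() for e in stream.events]
        assert keys == sorted(keys)

    def test_note_pairing_and_ranges(self, cfg, relaxed_session):
        rec, _ = relaxed_session
        stream = bm.sonify_recording(bm.slice_recording(rec, 30.0, 80.0), cfg)
        lo, hi = cfg.comfortable_range
        for voice in ("melody", "chord", "drum", "whoosh"):
            ons = [e for e in stream.events if e.voice == voice and e.etype == "note_on"]
            offs = [e for e in stream.events if e.voice == voice and e.etype == "note_off"]
            assert len(ons) == len(offs)
        assert all(lo <= e.note <= hi
                   for e in stream.events if e.voice == "melody" and e.etype == "note_on")


def test_config_validation_and_roundtrip(tmp_path):
    cfg = bm.SonifyConfig(temp_quantum_c=0.5, tonic_note=62)
    d = cfg.to_dict()
    assert bm.SonifyConfig.from_dict(d) == cfg
    path = tmp_path / "cfg.yaml"
    import yaml

    path.write_text(yaml.safe_dump(d))
    assert bm.SonifyConfig.from_file(path) == cfg
    with pytest.raises(bm.ValidationError):
        bm.SonifyConfig(comfortable_range=(60, 70))
    with pytest.raises(bm.ValidationError):
        bm.SonifyConfig(tempo_clamp_bpm=(200, 40))
    with pytest.raises(bm.ValidationError):
        bm.SonifyConfig.from_dict({"bogus_key": 1})
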
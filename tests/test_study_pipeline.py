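import numpy as np
import pytest

import biomusic as bm
from biomusic.sonify import MusicEventStream
from biomusic.study_pipeline import SongManifest

from conftest import constant_features


def meta(relaxed, anxious):
    return bm.SessionMeta(subject_id="s", relaxed_state_score=relaxed, anxious_state_score=anxious)


class TestValidateState:
    def test_score_increase_is_valid(self):
        assert bm.validate_state(meta(31.0, 42.0)) is True

    def test_equal_scores_invalid(self):
        assert bm.validate_state(meta(50.0, 50.0)) is False

    def test_decrease_invalid(self):
        assert bm.validate_state(meta(57.0, 42.0)) is False

    def test_missing_score_unscorable(self):
        with pytest.raises(bm.UnscorableError):
            bm.validate_state(bm.SessionMeta(relaxed_state_score=30.0))


class TestExtractSegments:
    def test_cohort_yields_ten_80s_segments(self, exp1_cohort):
        segments = [s for i, rec in enumerate(exp1_cohort)
                    for s in bm.extract_segments(rec, seed=i)]
        assert len(segments) == 10
        labels = [s.label for s in segments]
        assert labels.count("relaxed") == 5 and labels.count("anxious") == 5
        assert all(s.length_s == 80.0 for s in segments)

    def test_segments_respect_margins_and_transitions(self, exp1_cohort):
        rec = exp1_cohort[0]
        others = [iv for iv in rec.annotations if iv.label == "other"]
        for seed in range(10):
            for seg in bm.extract_segments(rec, seed=seed):
                host = [iv for iv in rec.annotations
                        if iv.label == seg.label and iv.start_s <= seg.start_s and seg.end_s <= iv.end_s]
                assert host, "segment must lie inside one same-label interval"
                assert all(seg.end_s <= iv.start_s or seg.start_s >= iv.end_s for iv in others)
                if seg.label == "relaxed":  # long intervals keep the full margin
                    assert seg.start_s >= host[0].start_s + 30.0
                    assert seg.end_s <= host[0].end_s - 30.0

    def test_short_condition_raises(self):
        rec = bm.PhysioRecording(
            256.0, {"eda": np.ones(256 * 200)},
            annotations=[bm.ConditionInterval("relaxed", 0.0, 60.0),
                         bm.ConditionInterval("anxious", 60.0, 120.0)],
        )
        with pytest.raises(bm.ConditionTooShortError):
            bm.extract_segments(rec)

    def test_margin_autoshrinks_for_two_minute_trials(self, caplog):
        """A 2-min anxious trial leaves < 80 s at the default margin; the
        margin shrinks symmetrically so the study's own design is feasible."""
        rec = bm.PhysioRecording(
            256.0, {"eda": np.ones(256 * 400)},
            annotations=[bm.ConditionInterval("relaxed", 0.0, 250.0),
                         bm.ConditionInterval("anxious", 260.0, 380.0)],
        )
        with caplog.at_level("INFO"):
            segs = bm.extract_segments(rec, seed=0)
        anxious = [s for s in segs if s.label == "anxious"][0]
        assert anxious.start_s >= 280.0 and anxious.end_s <= 360.0
        assert any("auto-shrunk" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self, exp1_cohort):
        a = bm.extract_segments(exp1_cohort[0], seed=123)
        b = bm.extract_segments(exp1_cohort[0], seed=123)
        assert a == b


class TestBatchGenerate:
    def test_experiment1_manifest_has_ten_songs(self, exp1_cohort, tmp_path):
        manifest = bm.batch_generate(exp1_cohort, out_dir=tmp_path, seed=1)
        assert len(manifest.songs) == 10
        assert manifest.counts() == {"relaxed": 5, "anxious": 5}
        assert (tmp_path / "manifest.csv").exists()
        back = SongManifest.read(tmp_path / "manifest.csv")
        assert len(back.entries) == len(manifest.entries)

    def test_empty_cohort_empty_manifest(self, tmp_path):
        manifest = bm.batch_generate([], out_dir=tmp_path, seed=1)
        assert manifest.entries == []

    def test_invalid_state_excluded_with_reason(self, tmp_path):
        rec = bm.generate_pair_session("td_anagram", seed=3)
        rec.meta.relaxed_state_score = 55.0
        rec.meta.anxious_state_score = 41.0
        manifest = bm.batch_generate([rec], out_dir=tmp_path, seed=1)
        assert manifest.songs == []
        assert manifest.entries[0].status == "excluded"

    def test_end_to_end_determinism(self, tmp_path):
        recs = [bm.generate_pair_session("td_anagram", seed=s) for s in (1, 2)]
        m1 = bm.batch_generate(recs, out_dir=tmp_path / "a", seed=9)
        m2 = bm.batch_generate(recs, out_dir=tmp_path / "b", seed=9)
        assert [e.subject_id + e.label for e in m1.entries] == [e.subject_id + e.label for e in m2.entries]
        for e1, e2 in zip(m1.songs, m2.songs):
            b1 = open(e1.midi_path, "rb").read()
            b2 = open(e2.midi_path, "rb").read()
            assert b1 == b2


class TestSummarizeSong:
    def test_constant_song_descriptors(self, cfg):
        stream = bm.schedule(constant_features(ibi_s=1.0), cfg)
        stats = bm.summarize_song(stream)
        assert stats.mean_bpm == pytest.approx(60.0)
        assert stats.note_rate_per_s == pytest.approx(1 / 80.0)
        assert stats.net_key_shift_semitones == 0.0
        assert stats.whoosh_count == 0

    def test_eda_step_song_pitch_range(self, cfg):
        feats = constant_features()
        values = feats["eda_level"].values.copy()
        values[160:] += 1.0
        feats["eda_level"] = bm.FeatureSeries("eda_level", feats["eda_level"].times_s, values)
        stats = bm.summarize_song(bm.schedule(feats, cfg))
        assert stats.pitch_range_semitones >= 36.0

    def test_empty_stream_all_zero(self):
        stats = bm.summarize_song(MusicEventStream(events=[], duration_s=0.0))
        assert stats == bm.SummaryStats()

    def test_midi_and_stream_paths_agree(self, cfg, tmp_path):
        stream = bm.schedule(constant_features(), cfg)
        path = bm.render_midi(stream, path=tmp_path / "x.mid")
        a, b = bm.summarize_song(stream), bm.summarize_song(path)
        assert a.mean_bpm == pytest.approx(b.mean_bpm, rel=1e-3)
        assert a.note_rate_per_s == pytest.approx(b.note_rate_per_s, rel=1e-3)


@pytest.fixture(scope="module")
def pair_manifest(tmp_path_factory):
    recs = [bm.generate_pair_session("td_anagram", seed=s) for s in range(8)]
    return bm.batch_generate(recs, out_dir=tmp_path_factory.mktemp("songs"), seed=2)


class TestSeparability:
    def test_predicted_directions_dominate(self, pair_manifest):
        report = bm.separability_report(pair_manifest)
        assert set(report.descriptor) == {"mean_bpm", "mean_whoosh_s", "note_rate_per_s"}
        assert (report.fraction_predicted >= 0.8).all()

    def test_label_shuffle_destroys_direction(self, pair_manifest):
        entries = []
        for i, e in enumerate(sorted(pair_manifest.songs, key=lambda e: (e.subject_id, e.label))):
            flipped = dict(vars(e))
            if (i // 2) % 2 == 0:  # swap labels for alternate subjects
                flipped["label"] = "anxious" if e.label == "relaxed" else "relaxed"
            entries.append(type(e)(**flipped))
        shuffled = SongManifest(entries)
        report = bm.separability_report(shuffled)
        assert (report.fraction_predicted <= 0.65).all()

    def test_single_pair_flagged(self, tmp_path):
        recs = [bm.generate_pair_session("td_anagram", seed=31)]
        manifest = bm.batch_generate(recs, out_dir=tmp_path, seed=3)
        report = bm.separability_report(manifest)
        assert (report.n_pairs == 1).all()
        assert report.note.str.contains("n=1").all()

    def test_single_label_rejected(self, pair_manifest):
        only_relaxed = SongManifest([e for e in pair_manifest.songs if e.label == "relaxed"])
        with pytest.raises(bm.ValidationError):
            bm.separability_report(only_relaxed)

    def test_bpm_median_rule_beats_chance(self, pair_manifest):
        assert bm.bpm_median_rule_accuracy(pair_manifest) > 0.5
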
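"""Roster, WAV and segment-annotation I/O contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import speechdep as sd
from speechdep.corpus import (
    load_segments,
    read_wav,
    resample_to_canonical,
    save_segments,
    trim_silence,
    write_wav,
)


@pytest.mark.parametrize(
    "score,label",
    [(10, 1), (9, 0), (0, 0), (24, 1), (11, 1)],
)
def test_phq8_binarization_threshold(score, label):
    """Scores of 10 or more mark the speaker depressed; below, not."""
    assert sd.binarize_phq8(score) == label


@pytest.mark.parametrize("score", [-1, 25, 100])
def test_phq8_out_of_range_rejected(score):
    with pytest.raises(sd.ValidationError):
        sd.binarize_phq8(score)


@given(st.integers(0, 24), st.integers(0, 24))
def test_phq8_binarization_monotone(a, b):
    """A higher questionnaire score can never flip the label back to healthy."""
    lo, hi = sorted((a, b))
    assert sd.binarize_phq8(lo) <= sd.binarize_phq8(hi)


def test_roster_round_trip(tmp_path):
    records = [
        sd.SpeakerRecord("303", 10, 1, "train"),
        sd.SpeakerRecord("304", 9, 0, "test"),
        sd.SpeakerRecord("305", 0, 0, "train"),
    ]
    path = tmp_path / "labels.csv"
    sd.save_roster(records, path)
    assert sd.load_roster(path) == records


def test_roster_labels_and_exclusions(tmp_path):
    path = tmp_path / "labels.csv"
    path.write_text("speaker_id,phq8\n303,10\n304,9\nbad,12\n")
    roster = sd.load_roster(path, exclude=["bad"])
    assert [r.label for r in roster] == [1, 0]
    assert all(r.split == "train" for r in roster)  # split column absent


def test_roster_rejects_bad_tables(tmp_path):
    missing = tmp_path / "m.csv"
    missing.write_text("speaker_id,score\n1,3\n")
    with pytest.raises(sd.FormatError):
        sd.load_roster(missing)
    dup = tmp_path / "d.csv"
    dup.write_text("speaker_id,phq8\n1,3\n1,4\n")
    with pytest.raises(sd.ValidationError):
        sd.load_roster(dup)
    out_of_range = tmp_path / "r.csv"
    out_of_range.write_text("speaker_id,phq8\n1,3\n2,31\n")
    with pytest.raises(sd.ValidationError, match="row 1"):
        sd.load_roster(out_of_range)


def _write_tone(path, duration_s, rate, channels=1):
    t = np.arange(int(duration_s * rate)) / rate
    x = 0.4 * np.sin(2 * np.pi * 220 * t)
    if channels == 2:
        x = np.stack([x, x], axis=1)
    from scipy.io import wavfile

    wavfile.write(str(path), rate, (x * 32767).astype(np.int16))


def test_participant_segments_concatenated(tmp_path):
    """Keeping spans (0,3) and (5,9) of a 10-s file leaves 7 s of audio."""
    wav = tmp_path / "s1.wav"
    _write_tone(wav, 10.0, 16000)
    ann = sd.SegmentAnnotation(
        "s1",
        [(0.0, 3.0, "participant"), (3.0, 5.0, "interviewer"), (5.0, 9.0, "participant")],
    )
    rec = sd.load_participant_audio(wav, ann)
    assert rec.rate == 16000
    assert rec.duration == pytest.approx(7.0, abs=1.0 / 16000)


def test_audio_canonicalized_to_16k(tmp_path):
    wav = tmp_path / "s2.wav"
    _write_tone(wav, 2.0, 44100)
    rec = sd.load_participant_audio(wav)
    assert rec.rate == 16000
    assert rec.duration == pytest.approx(2.0, abs=1e-3)


def test_interviewer_only_annotation_is_empty(tmp_path):
    wav = tmp_path / "s3.wav"
    _write_tone(wav, 2.0, 16000)
    ann = sd.SegmentAnnotation("s3", [(0.0, 2.0, "interviewer")])
    with pytest.raises(sd.EmptyRecordingError):
        sd.load_participant_audio(wav, ann)


def test_multichannel_averaged_to_mono(tmp_path):
    wav = tmp_path / "s4.wav"
    _write_tone(wav, 1.0, 16000, channels=2)
    samples, rate = read_wav(wav)
    assert samples.ndim == 1 and rate == 16000


def test_segment_table_round_trip(tmp_path):
    anns = [
        sd.SegmentAnnotation("a", [(0.0, 1.0, "participant"), (1.5, 2.0, "interviewer")]),
        sd.SegmentAnnotation("b", [(0.0, 4.0, "participant")]),
    ]
    path = tmp_path / "seg.csv"
    save_segments(anns, path)
    loaded = load_segments(path)
    assert loaded["a"].segments == anns[0].segments
    assert loaded["b"].segments == anns[1].segments


def test_overlapping_segments_rejected():
    with pytest.raises(sd.ValidationError):
        sd.SegmentAnnotation("x", [(0.0, 2.0, "participant"), (1.0, 3.0, "participant")])


def test_silence_trimming_drops_quiet_frames():
    rate = 16000
    loud = 0.4 * np.sin(2 * np.pi * 220 * np.arange(rate) / rate)
    quiet = np.zeros(rate)
    trimmed = trim_silence(np.concatenate([loud, quiet, loud]), rate)
    assert len(trimmed) == pytest.approx(2 * rate, abs=rate * 0.05)


def test_resampling_preserves_duration():
    x = np.random.default_rng(0).standard_normal(44100)
    y = resample_to_canonical(x, 44100)
    assert len(y) == 16000


def test_wav_round_trip(tmp_path):
    x = 0.3 * np.sin(np.linspace(0, 100, 16000))
    path = tmp_path / "t.wav"
    write_wav(path, x, 16000)
    y, rate = read_wav(path)
    assert rate == 16000
    assert np.max(np.abs(x - y)) < 1e-3  # 16-bit quantization only
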
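import numpy as np
import pytest

from hemoqol.beats import (
    FiducialSet,
    artifact_score,
    beat_metrics,
    beats_table,
    detect_beats,
    locate_fiducials,
    rhythm_flag,
    select_timeframes,
)
from hemoqol.exceptions import (
    DegenerateBeatError,
    InsufficientDataError,
    NoBeatsError,
    PatientExclusionError,
    ValidationError,
)
from hemoqol.signal_io import WaveformRecord
from hemoqol.synthgen import generate_procedure_record, generate_waveform


def test_detect_beats_rate_matches_truth(clean_record):
    record, truth = clean_record
    feet = detect_beats(record)
    rate = (len(feet) - 1) / ((feet[-1] - feet[0]) / record.fs) * 60.0
    assert rate == pytest.approx(75.0, abs=1.0)


def test_detect_beats_follows_rate_change():
    r1, _ = generate_waveform(hr=60, duration=15, seed=5)
    r2, _ = generate_waveform(hr=90, duration=15, seed=6)
    rec = WaveformRecord(np.concatenate([r1.samples, r2.samples]), fs=200.0)
    feet = detect_beats(rec)
    t = feet / rec.fs
    first = np.sum(t < 14.0) / 14.0 * 60.0
    second = np.sum(t > 16.0) / 14.0 * 60.0
    assert first == pytest.approx(60.0, abs=4.0)
    assert second == pytest.approx(90.0, abs=4.0)


def test_flatline_raises_no_beats():
    rec = WaveformRecord(np.full(2000, 90.0), fs=200.0)
    with pytest.raises(NoBeatsError):
        detect_beats(rec)


def test_lvet_recovered_within_two_samples(clean_record):
    record, truth = clean_record
    feet = detect_beats(record)
    lvets = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        fid = locate_fiducials(record, (f0, f1))
        if fid.notch is not None:
            lvets.append((fid.notch - f0) / record.fs * 1000.0)
    assert np.mean(lvets) == pytest.approx(332.0, abs=10.0)


def test_smooth_decay_without_notch_component_flagged():
    # a beat whose decline is a pure exponential has no valve-closure kink
    fs = 200.0
    t = np.arange(int(2.4 * fs)) / fs
    one = 60 + 60 * np.where(
        t % 0.8 < 0.12, (t % 0.8) / 0.12, np.exp(-((t % 0.8) - 0.12) / 0.35)
    )
    rec = WaveformRecord(one, fs=fs)
    fid = locate_fiducials(rec, (int(0.8 * fs), int(1.6 * fs)))
    assert fid.notch is None


def test_triangular_pulse_peak_is_argmax():
    fs = 200.0
    n = int(0.8 * fs)
    beat = np.concatenate([np.linspace(60, 120, int(0.4 * n)), np.linspace(120, 60, n - int(0.4 * n))])
    rec = WaveformRecord(np.tile(beat, 3), fs=fs)
    fid = locate_fiducials(rec, (n, 2 * n))
    assert fid.peak == n + int(0.4 * n) - 1


def test_short_beat_is_degenerate(clean_record):
    record, _ = clean_record
    with pytest.raises(DegenerateBeatError):
        locate_fiducials(record, (100, 130))


def test_fiducial_ordering_enforced():
    with pytest.raises(DegenerateBeatError):
        FiducialSet(foot=100, peak=90, notch=None, next_foot=200)
    with pytest.raises(DegenerateBeatError):
        FiducialSet(foot=100, peak=150, notch=140, next_foot=200)


def test_ramp_dpdt_max():
    # linear upstroke 60 -> 120 mmHg over 0.05 s: slope 1200 mmHg/s
    fs = 200.0
    up = np.linspace(60, 120, int(0.05 * fs) + 1)
    down = np.linspace(120, 60, int(0.75 * fs))
    beat = np.concatenate([up, down[1:]])
    rec = WaveformRecord(np.tile(beat, 3), fs=fs)
    n = len(beat)
    fid = locate_fiducials(rec, (n, 2 * n))
    m = beat_metrics(rec, fid)
    assert m.dpdt_max == pytest.approx(1200.0, rel=0.02)
    assert m.hr == pytest.approx(60.0 / m.ibi)


def test_sine_beat_map_is_offset():
    fs = 200.0
    n = int(0.8 * fs)
    t = np.arange(n) / fs
    beat = 93 + 20 * np.sin(2 * np.pi * t / 0.8)
    rec = WaveformRecord(np.tile(beat, 3), fs=fs)
    m = beat_metrics(rec, FiducialSet(foot=n, peak=n + n // 4, notch=None, next_foot=2 * n))
    assert m.map == pytest.approx(93.0, abs=0.1)


def test_pressure_ordering_on_every_beat(clean_record):
    record, _ = clean_record
    tab = beats_table(record)
    assert len(tab) > 15
    assert (tab["dbp"] <= tab["map"] + 1e-9).all()
    assert (tab["map"] <= tab["sbp"] + 1e-9).all()


def test_artifact_score_clean_window(clean_record):
    record, _ = clean_record
    assert artifact_score(record, (0.0, 20.0)) < 0.05


def test_artifact_score_clipping_and_monotonicity(clean_record):
    record, _ = clean_record
    base = record.samples.copy()
    prev = -1.0
    for frac in (0.0, 0.2, 0.5, 0.8):
        x = base.copy()
        k = int(frac * len(x))
        x[:k] = 250.0
        score = artifact_score(WaveformRecord(x, fs=record.fs), (0.0, 20.0))
        assert score >= prev - 1e-12  # more clipping never lowers the score
        prev = score
        if frac == 0.5:
            assert score > 0.4


def test_artifact_score_empty_window_errors(clean_record):
    record, _ = clean_record
    with pytest.raises(ValidationError):
        artifact_score(record, (5.0, 5.0))


def test_select_timeframes_bav_branch(procedure_record):
    record, _ = procedure_record
    wins = select_timeframes(record)
    bav = record.events["bav"]
    assert wins["baseline"].end - wins["baseline"].start == pytest.approx(600.0)
    assert wins["pre_tavi"].end - wins["pre_tavi"].start == pytest.approx(20.0)
    assert wins["pre_tavi"].end <= bav + 1e-9
    assert wins["pre_tavi"].start >= bav - 180.0 - 1e-9
    imp = record.events["implant"]
    assert imp <= wins["post_tavi"].start and wins["post_tavi"].end <= imp + 180.0 + 1e-9


def test_select_timeframes_without_bav_uses_implant():
    record, _ = generate_procedure_record(bav=False, seed=3, baseline_len=600.0)
    wins = select_timeframes(record)
    imp = record.events["implant"]
    assert wins["pre_tavi"].end <= imp + 1e-9
    assert wins["pre_tavi"].start >= imp - 180.0 - 1e-9


def test_select_timeframes_exclusion_on_ruined_pre_interval(procedure_record):
    record, _ = procedure_record
    x = record.samples.copy()
    ref = record.events["bav"]
    i0, i1 = int((ref - 185) * record.fs), int(ref * record.fs)
    x[i0:i1] = 250.0
    ruined = WaveformRecord(x, fs=record.fs, events=dict(record.events))
    with pytest.raises(PatientExclusionError) as err:
        select_timeframes(ruined)
    assert err.value.reason == "no_artifact_free_window"


def test_rhythm_flags(rng):
    regular = [type("B", (), {"ibi": i})() for i in rng.normal(0.8, 0.8 * 0.03, 40)]
    assert rhythm_flag(regular) == "regular"
    irregular = [type("B", (), {"ibi": i})() for i in np.abs(rng.normal(0.8, 0.8 * 0.25, 200)) + 0.2]
    assert rhythm_flag(irregular) == "irregular_suspect"
    assert rhythm_flag(irregular, events={"paced": 10.0}) == "annotated_paced"
    with pytest.raises(InsufficientDataError):
        rhythm_flag(regular[:5])
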
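import numpy as np
import pytest

from hemoqol.beats import detect_beats, locate_fiducials
from hemoqol.exceptions import ConfigError
from hemoqol.stats import little_mcar, mixed_association
from hemoqol.synthgen import (
    TABLE_DEFAULTS,
    CohortConfig,
    generate_cohort,
    generate_procedure_record,
    generate_waveform,
    split_truth,
)


def test_same_seed_identical_samples():
    a, _ = generate_waveform(duration=5, seed=3)
    b, _ = generate_waveform(duration=5, seed=3)
    np.testing.assert_array_equal(a.samples, b.samples)
    c, _ = generate_waveform(duration=5, seed=4)
    assert not np.array_equal(a.samples, c.samples)


def test_lvet_longer_than_beat_rejected():
    with pytest.raises(ConfigError):
        generate_waveform(hr=100, lvet_ms=700)


def test_diastolic_decay_monotone_without_noise():
    record, truth = generate_waveform(
        noise_sd=0.0, rp=2.0, c=2.0, duration=10, seed=1, ibi_cv=0.0
    )
    fs = record.fs
    ft = truth.foot_times[2]
    start = int((ft + truth.lvet_ms[2] / 1000.0 + 0.35) * fs)  # past the notch transient
    end = int((ft + truth.ibi[2]) * fs) - 1
    seg = record.samples[start:end]
    assert np.all(np.diff(seg) <= 1e-9)


def test_procedure_record_event_layout():
    rec, _ = generate_procedure_record(bav=False, seed=2, baseline_len=60.0, post_len=40.0)
    assert set(rec.events) == {"baseline_start", "implant", "end"}
    rec2, _ = generate_procedure_record(bav=True, seed=2, baseline_len=60.0, post_len=40.0)
    assert rec2.events["implant"] - rec2.events["bav"] == pytest.approx(336.0)


def test_procedure_record_post_lvet_drops():
    rec, truth = generate_procedure_record(
        bav=False, seed=8, baseline_len=30.0, pre_gap=10.0, post_len=40.0,
        pre={"lvet_ms": 340.0}, post={"lvet_ms": 300.0},
    )
    imp = rec.events["implant"]

    def mean_lvet(t0, t1):
        sub = rec.slice(t0, t1)
        feet = detect_beats(sub)
        vals = []
        for f0, f1 in zip(feet[:-1], feet[1:]):
            fid = locate_fiducials(sub, (f0, f1))
            if fid.notch is not None:
                vals.append((fid.notch - f0) / sub.fs * 1000)
        return np.mean(vals)

    assert mean_lvet(5.0, imp - 5.0) > mean_lvet(imp + 5.0, imp + 35.0)


def test_truth_recovery_full_chain():
    record, truth = generate_waveform(sv=70, hr=75, lvet_ms=332, duration=30, seed=12)
    feet = detect_beats(record)
    ibis = np.diff(feet) / record.fs
    hr_est = 60.0 / ibis.mean()
    assert abs(hr_est - 60.0 / truth.ibi.mean()) <= 1.0
    maps = [record.samples[f0:f1].mean() for f0, f1 in zip(feet[:-1], feet[1:])]
    assert abs(np.mean(maps) - truth.mean_pressure) <= 1.0


# ---------------------------------------------------------------------------
# cohort generator


def test_cohort_moments_converge():
    cfg = CohortConfig(n=10_000, missing_pre_frac=0.0, missing_post_frac=0.0)
    big = generate_cohort(cfg, seed=5)
    for var, spec in TABLE_DEFAULTS.items():
        assert big[f"{var}_pre"].mean() == pytest.approx(spec["pre_mean"], rel=0.02)
        assert big[f"{var}_pre"].std() == pytest.approx(spec["pre_sd"], rel=0.02)
    assert big["dpdt_max_pre"].mean() == pytest.approx(724.0, rel=0.02)
    assert big["dpdt_max_pre"].std() == pytest.approx(368.0, rel=0.02)


def test_cohort_percent_change_asymmetry():
    big = generate_cohort(CohortConfig(n=10_000), seed=6)
    per_patient = big["pct_dpdt_max"].mean()
    of_means = 100 * big["delta_dpdt_max"].mean() / big["dpdt_max_pre"].mean()
    assert per_patient > of_means + 5.0  # the published 67% vs 57% asymmetry


def test_cohort_mean_lvet_change_matches_default():
    means = [generate_cohort(seed=100 + i)["delta_lvet"].mean() for i in range(30)]
    assert np.mean(means) == pytest.approx(-10.0, abs=3.0)


def test_cohort_missing_counts_exact():
    c = generate_cohort(seed=0)
    assert c["hrqol_pre"].isna().sum() == 9
    assert c["hrqol_post"].isna().sum() == 1
    assert c.loc[c["hrqol_pre"].isna(), "eq5d_pre"].isna().all()


def test_cohort_no_missing_and_mcar_p_one():
    c = generate_cohort(CohortConfig(missing_pre_frac=0.0, missing_post_frac=0.0), seed=1)
    assert not c["hrqol_pre"].isna().any()
    res = little_mcar(c[["hrqol_pre", "hrqol_post", "delta_lvet"]])
    assert res.p_value == 1.0


def test_cohort_hrqol_within_tariff_range():
    c = generate_cohort(seed=2)
    vals = np.concatenate([c["truth_hrqol_pre"], c["truth_hrqol_post"]])
    assert vals.min() >= -0.446 - 1e-9 and vals.max() <= 1.0 + 1e-9


def test_cohort_cpi_class_boundary():
    c = generate_cohort(CohortConfig(n=500), seed=3)
    low = c["cpi_class"] == "low"
    assert (c.loc[low, "cpi_baseline"] < 0.44).all()
    assert (c.loc[~low, "cpi_baseline"] >= 0.44).all()


def test_null_effect_covers_zero():
    cover = 0
    reps = 40
    for i in range(reps):
        c = generate_cohort(CohortConfig(lvet_effect=0.0), seed=500 + i)
        r = mixed_association(c)
        cover += r.ci_low <= 0.0 <= r.ci_high
    assert cover / reps >= 0.85


def test_split_truth_separates_columns():
    c = generate_cohort(seed=4)
    obs, truth = split_truth(c)
    assert not any(col.startswith("truth_") for col in obs.columns)
    assert {"patient_id", "truth_hrqol_pre"} <= set(truth.columns)


def test_bad_config_rejected():
    with pytest.raises(ConfigError):
        CohortConfig(n=2)
    with pytest.raises(ConfigError):
        CohortConfig(missing_pre_frac=1.5)
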
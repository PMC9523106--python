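"""Beat segmentation, fiducial points, per-beat hemodynamics and window selection.

The chain is: low-pass filter -> systolic upstroke (foot) detection by the
intersecting-tangent method -> per-beat fiducials (systolic peak, dicrotic
notch) -> per-beat variables (SBP, DBP, MAP, HR, LVET, dP/dt max) -> artifact
scoring -> selection of the three analysis time frames (baseline, direct
pre-implantation, direct post-implantation).

LVET (left ventricular ejection time) is measured from the pressure-upstroke
foot to the dicrotic notch, the incisura marking aortic valve closure.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import (
    DegenerateBeatError,
    InsufficientDataError,
    NoBeatsError,
    PatientExclusionError,
    ValidationError,
)
from .signal_io import WaveformRecord

HR_MIN, HR_MAX = 20.0, 220.0  # plausible heart-rate band, bpm
FLATLINE_SD = 0.5             # mmHg over a 2-s window
SBP_RANGE = (50.0, 250.0)
DBP_RANGE = (20.0, 150.0)
SBP_JUMP_FRAC = 0.20          # beat-to-beat systolic jump flagged as artifact
ARTIFACT_THRESHOLD = 0.2      # window rejected above this score
NOTCH_CURVATURE_RATIO = 0.3   # notch acceptance: curvature peak vs decline rate


@dataclasses.dataclass
class FiducialSet:
    """Landmark sample indices for one beat. ``notch`` is None when no
    dicrotic notch could be located (the beat is then excluded from LVET
    and stroke-volume averaging)."""

    foot: int
    peak: int
    notch: int | None
    next_foot: int

    def __post_init__(self):
        if not self.foot < self.peak < self.next_foot:
            raise DegenerateBeatError(
                f"need foot < peak < next_foot, got {self.foot}, {self.peak}, {self.next_foot}"
            )
        if self.notch is not None and not (self.peak < self.notch < self.next_foot):
            raise DegenerateBeatError("notch must lie between peak and next foot")


@dataclasses.dataclass
class BeatMetrics:
    """Per-beat hemodynamic variables in conventional units."""

    sbp: float            # mmHg
    dbp: float            # mmHg
    map: float            # mmHg, true time average over the beat
    ibi: float            # s
    hr: float             # beats/min
    lvet: float | None    # ms, None when the notch is absent
    dpdt_max: float       # mmHg/s
    sv: float | None = None   # ml, filled by the pulse-contour step
    quality: float = 0.0      # artifact score in [0, 1]; 0 = clean

    def __post_init__(self):
        if not (self.dbp <= self.map <= self.sbp):
            raise DegenerateBeatError(
                f"need dbp <= map <= sbp, got {self.dbp}, {self.map}, {self.sbp}"
            )
        if self.lvet is not None and not self.lvet < self.ibi * 1000.0:
            raise DegenerateBeatError("LVET must be shorter than the beat interval")


@dataclasses.dataclass
class WindowSelection:
    """One selected analysis time frame."""

    kind: str             # baseline | pre_tavi | post_tavi
    start: float          # s
    end: float            # s
    mean_artifact_score: float
    rhythm_flag: str = "regular"


def lowpass(x: np.ndarray, fs: float, fc: float = 15.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; 15 Hz keeps all pulse-contour detail."""
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def smooth_derivative(x: np.ndarray, fs: float, window_ms: float = 25.0, order: int = 3) -> np.ndarray:
    """dP/dt via a Savitzky-Golay local polynomial (finite differences at
    200 Hz are noise-dominated)."""
    w = max(order + 2, int(round(window_ms * fs / 1000.0)))
    if w % 2 == 0:
        w += 1
    return sps.savgol_filter(x, w, order, deriv=1, delta=1.0 / fs)


def _prepared(record: WaveformRecord):
    """Filtered trace and its first/second smoothed derivatives, cached on
    the record instance (the fiducial routines are called once per beat)."""
    cache = getattr(record, "_beat_cache", None)
    if cache is not None and cache[0] is record.samples:
        return cache[1:]
    x = np.asarray(record.samples, float)
    fs = record.fs
    filt = lowpass(x, fs)
    dp = smooth_derivative(filt, fs)
    w = max(5, int(round(0.045 * fs)) | 1)
    d2 = sps.savgol_filter(filt, w, 3, deriv=2, delta=1.0 / fs)
    record._beat_cache = (record.samples, filt, dp, d2)
    return filt, dp, d2


def detect_beats(record: WaveformRecord) -> np.ndarray:
    """Systolic-foot indices by the intersecting-tangent method.

    The tangent through the point of maximal upstroke slope (on a 15 Hz
    low-passed trace) is intersected with the preceding diastolic minimum
    level; the crossing is the foot.

    Returns a strictly increasing integer array. Raises
    :class:`NoBeatsError` on a flatline trace (SD < 0.5 mmHg over 2 s).
    """
    x = np.asarray(record.samples, float)
    fs = record.fs
    if len(x) < 2 * fs:
        raise ValidationError("record shorter than 2 s")
    if fs < 100:
        raise ValidationError("need fs >= 100 Hz")
    # flatline: every 2-s block nearly constant
    nblk = int(2 * fs)
    blocks = [x[i : i + nblk] for i in range(0, len(x) - nblk + 1, nblk)]
    if max(b.std() for b in blocks) < FLATLINE_SD:
        raise NoBeatsError("flatline trace: pressure SD < 0.5 mmHg over 2 s")

    filt, dp, d2 = _prepared(record)
    min_dist = int(fs * 60.0 / HR_MAX)
    pos = dp[dp > 0]
    if pos.size == 0:
        raise NoBeatsError("no rising pressure segments")
    height = 0.25 * np.percentile(pos, 95)
    upstrokes, _ = sps.find_peaks(dp, height=height, distance=min_dist)
    if upstrokes.size == 0:
        raise NoBeatsError("no systolic upstrokes found")

    feet = []
    back = int(0.35 * fs)  # search window for the diastolic minimum
    for d in upstrokes:
        lo = max(0, d - back)
        seg = filt[lo : d + 1]
        if seg.size == 0:
            continue
        imin = lo + int(np.argmin(seg))
        pmin = filt[imin]
        slope = dp[d]
        if slope <= 0:
            continue
        # tangent through (d, filt[d]) meets the horizontal level pmin;
        # used as a guard band for the refined estimators below
        t_foot = d - (filt[d] - pmin) / slope * fs
        cand = int(round(np.clip(t_foot, imin, d)))
        # two complementary onset estimators whose smoothing-induced biases
        # have opposite signs: (a) the last negative smoothed-derivative
        # sample before the max-slope point (runs early on the zero-phase-
        # filtered corner), (b) the curvature maximum around the diastolic
        # minimum (runs late). Their average is nearly bias-free.
        neg = np.where(dp[lo:d] < 0)[0]
        if neg.size:
            f_cross = int(np.clip(lo + neg[-1] + 1, imin - int(0.05 * fs), d))
        else:
            f_cross = min(imin, cand)
        s0 = max(lo, imin - int(0.05 * fs))
        s1 = min(d, imin + int(0.05 * fs)) + 1
        f_curv = s0 + int(np.argmax(d2[s0:s1]))
        feet.append(int(round((f_cross + f_curv) / 2)))
    feet = np.unique(np.asarray(feet, dtype=int))
    if feet.size == 0:
        raise NoBeatsError("no feet located")
    # drop implausibly short intervals (double detections)
    keep = [feet[0]]
    for f in feet[1:]:
        if f - keep[-1] >= int(fs * 60.0 / HR_MAX):
            keep.append(f)
    return np.asarray(keep, dtype=int)


def _notch_window(foot: int, next_foot: int, fs: float) -> tuple[int, int]:
    ibi = (next_foot - foot) / fs
    lo = foot + int(round((0.15 * ibi + 0.100) * fs))
    hi = foot + int(round(min(0.5, 0.6 * ibi) * fs))
    return lo, min(hi, next_foot - 1)


def locate_fiducials(record: WaveformRecord, foot_pair: Sequence[int]) -> FiducialSet:
    """Systolic peak and dicrotic notch for the beat between two feet.

    The notch is searched in a physiologic window after the foot (from
    0.15 IBI + 100 ms to at most min(0.5 s, 0.6 IBI)). Aortic valve closure
    interrupts the late-systolic pressure decline, so the notch is located
    as the maximum of the smoothed second derivative immediately after the
    steepest post-peak decline - which coincides with the incisura's
    negative-to-positive derivative crossing whenever one exists. The
    candidate is accepted only when that curvature peak is large relative to
    the decline rate; a smooth notch-free decay fails the test and the notch
    is reported absent (the beat is then excluded from LVET and
    stroke-volume averaging).
    """
    foot, next_foot = int(foot_pair[0]), int(foot_pair[1])
    fs = record.fs
    if (next_foot - foot) / fs < 0.25:
        raise DegenerateBeatError("beat shorter than 0.25 s")
    _, dp, d2 = _prepared(record)
    peak = foot + int(np.argmax(record.samples[foot:next_foot]))
    if peak <= foot:
        peak = foot + 1
    lo, hi = _notch_window(foot, next_foot, fs)
    lo = max(lo, peak + 1)
    notch: int | None = None
    if hi - lo >= 5:
        seg = dp[lo:hi]
        imin = int(np.argmin(seg))
        j1 = min(len(seg), imin + int(round(0.08 * fs)))
        if j1 - imin >= 3 and seg[imin] < 0:
            sub = d2[lo + imin : lo + j1]
            cand = lo + imin + int(np.argmax(sub))
            # significance: curvature must clearly exceed what the decline
            # rate alone produces over the ~50 ms closure transient
            if np.max(sub) >= NOTCH_CURVATURE_RATIO * abs(seg[imin]) / 0.05:
                notch = cand
    if notch is not None and not (peak < notch < next_foot):
        notch = None
    return FiducialSet(foot=foot, peak=peak, notch=notch, next_foot=next_foot)


def beat_metrics(record: WaveformRecord, fid: FiducialSet) -> BeatMetrics:
    """Per-beat variables: SBP = max, DBP = pressure at the foot, MAP = time
    average over the beat, dP/dt max over the upstroke."""
    x = np.asarray(record.samples, float)
    fs = record.fs
    seg = x[fid.foot : fid.next_foot]
    sbp = float(seg.max())
    dbp = float(x[fid.foot])
    mean_p = float(seg.mean())
    if dbp >= sbp:
        raise DegenerateBeatError(f"dbp {dbp} >= sbp {sbp}")
    ibi = (fid.next_foot - fid.foot) / fs
    lvet = None if fid.notch is None else (fid.notch - fid.foot) / fs * 1000.0
    dp = smooth_derivative(x[fid.foot : fid.peak + 1], fs) if fid.peak - fid.foot >= 5 else np.gradient(x[fid.foot : fid.peak + 1]) * fs
    dpdt = float(np.max(dp))
    return BeatMetrics(
        sbp=sbp,
        dbp=min(dbp, mean_p),
        map=mean_p,
        ibi=ibi,
        hr=60.0 / ibi,
        lvet=lvet,
        dpdt_max=dpdt,
    )


def beats_table(record: WaveformRecord) -> pd.DataFrame:
    """One row per detected beat; the exported beat-table interface."""
    feet = detect_beats(record)
    rows = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        try:
            fid = locate_fiducials(record, (f0, f1))
            m = beat_metrics(record, fid)
        except DegenerateBeatError:
            continue
        rows.append(
            {
                "foot_s": record.start_time + f0 / record.fs,
                "foot_idx": int(f0),
                "peak_idx": int(fid.peak),
                "notch_idx": -1 if fid.notch is None else int(fid.notch),
                "next_foot_idx": int(f1),
                "sbp": m.sbp,
                "dbp": m.dbp,
                "map": m.map,
                "ibi": m.ibi,
                "hr": m.hr,
                "lvet_ms": np.nan if m.lvet is None else m.lvet,
                "dpdt_max": m.dpdt_max,
                "quality": m.quality,
            }
        )
    return pd.DataFrame(rows)


def artifact_score(record: WaveformRecord, window: tuple[float, float]) -> float:
    """Automated surrogate for manual artifact-free window selection.

    0 is clean. Components: per-beat out-of-range pressures, >20 %
    beat-to-beat systolic jumps, missing dicrotic notch (half weight),
    flatline segments, and the fraction of samples clipped outside
    [20, 250] mmHg. The score is the larger of the clipped-sample fraction
    and the (capped) weighted beat-violation fraction, so adding clipped
    samples to a window can only raise it.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValidationError("empty window")
    sub = record.slice(t0, t1)
    x = sub.samples
    clip_frac = float(np.mean((x >= SBP_RANGE[1]) | (x <= DBP_RANGE[0])))
    try:
        tab = beats_table(sub)
    except (NoBeatsError, ValidationError):
        return 1.0
    if len(tab) == 0:
        return 1.0
    out_range = ((tab.sbp < SBP_RANGE[0]) | (tab.sbp > SBP_RANGE[1] - 1e-9)
                 | (tab.dbp < DBP_RANGE[0]) | (tab.dbp > DBP_RANGE[1])).to_numpy()
    jumps = np.zeros(len(tab), bool)
    sb = tab.sbp.to_numpy()
    jumps[1:] = np.abs(np.diff(sb)) > SBP_JUMP_FRAC * sb[:-1]
    no_notch = tab.lvet_ms.isna().to_numpy()
    hr_bad = ((tab.hr < HR_MIN) | (tab.hr > HR_MAX)).to_numpy()
    beat_score = float(
        np.mean(np.minimum(1.0, 1.0 * out_range + 1.0 * jumps + 0.5 * no_notch + 1.0 * hr_bad))
    )
    return max(clip_frac, min(1.0, beat_score))


def select_timeframes(
    record: WaveformRecord,
    threshold: float = ARTIFACT_THRESHOLD,
    step: float = 1.0,
    pre_len: float = 20.0,
    search_len: float = 180.0,
    baseline_len: float = 600.0,
) -> dict[str, WindowSelection]:
    """Select the three analysis time frames.

    baseline: the 10 min from ``baseline_start``. pre_tavi: the cleanest 20-s
    window in the 3 min before valvuloplasty when performed, else before
    implantation. post_tavi: the cleanest 20-s window in the 3 min after
    implantation. Raises :class:`PatientExclusionError` (reason
    ``no_artifact_free_window``) when no candidate scores below ``threshold``.
    """
    ev = record.events
    if "implant" not in ev:
        raise ValidationError("record lacks an 'implant' event")
    if "baseline_start" not in ev:
        raise ValidationError("record lacks a 'baseline_start' event")
    ref = ev.get("bav", ev["implant"])
    t_end = record.start_time + record.duration

    def best_window(lo: float, hi: float, kind: str) -> WindowSelection:
        lo = max(lo, record.start_time)
        hi = min(hi, t_end)
        starts = np.arange(lo, hi - pre_len + 1e-9, step)
        if starts.size == 0:
            raise PatientExclusionError(
                "no_artifact_free_window", f"no room for a {pre_len}-s {kind} window"
            )
        best_s, best_score = None, np.inf
        for s in starts:
            sc = artifact_score(record, (s, s + pre_len))
            if sc < best_score:
                best_s, best_score = s, sc
        if best_score > threshold:
            raise PatientExclusionError(
                "no_artifact_free_window",
                f"cleanest {kind} window scores {best_score:.2f} > {threshold}",
            )
        return WindowSelection(kind, float(best_s), float(best_s + pre_len), float(best_score))

    b0 = ev["baseline_start"]
    if b0 + baseline_len > t_end + 1e-9:
        raise ValidationError("record too short for the baseline time frame")
    baseline = WindowSelection(
        "baseline", float(b0), float(b0 + baseline_len),
        artifact_score(record, (b0, b0 + baseline_len)),
    )
    pre = best_window(ref - search_len, ref, "pre_tavi")
    post = best_window(ev["implant"], ev["implant"] + search_len, "post_tavi")
    return {"baseline": baseline, "pre_tavi": pre, "post_tavi": post}


def rhythm_flag(
    beats: Sequence[BeatMetrics] | pd.DataFrame,
    events: dict | None = None,
    cv_threshold: float = 0.15,
    alternation_threshold: float = 0.60,
) -> str:
    """Screening rhythm flag; never diagnostic.

    ``annotated_paced`` only from an explicit ``paced`` event label;
    ``irregular_suspect`` when the IBI coefficient of variation exceeds 0.15
    AND successive-difference sign changes occur in more than 60 % of beats.
    """
    if events and "paced" in events:
        return "annotated_paced"
    if isinstance(beats, pd.DataFrame):
        ibis = beats["ibi"].to_numpy(float)
    else:
        ibis = np.asarray([b.ibi for b in beats], float)
    if ibis.size < 10:
        raise InsufficientDataError("need at least 10 beats for a rhythm flag")
    cv = ibis.std() / ibis.mean()
    d = np.diff(ibis)
    signs = np.sign(d[np.abs(d) > 1e-12])
    altern = float(np.mean(np.diff(signs) != 0)) if signs.size > 1 else 0.0
    if cv > cv_threshold and altern > alternation_threshold:
        return "irregular_suspect"
    return "regular"
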
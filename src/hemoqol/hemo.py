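"""Pulse-contour stroke volume and the derived hemodynamic indices.

Stroke volume follows the pulse-contour rule: the time integral of the
systolic part of the arterial pressure curve divided by the aortic input
impedance. Derived indices: CO = SV x HR, SVR = 80 (MAP - CVP)/CO,
SW = SV x MAP, CPI = (MAP x CO / 451) / BSA with the low/normal boundary at
0.44 W m^-2 (0.44 itself is normal).
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .beats import BeatMetrics, FiducialSet
from .exceptions import CannotComputeError, InsufficientDataError, ValidationError
from .signal_io import WaveformRecord

CPI_LOW_BOUNDARY = 0.44   # W m^-2; >= 0.44 is classified normal
CPI_DENOMINATOR = 451.0   # unit conversion mmHg L min^-1 -> W
SVR_FACTOR = 80.0         # mmHg min L^-1 -> dynes s cm^-5


@dataclasses.dataclass
class WindowSummary:
    """Time-frame-averaged hemodynamics; the unit compared pre vs post."""

    kind: str
    sbp: float
    dbp: float
    map: float
    hr: float
    sv: float | None
    co: float | None        # L/min
    svr: float | None       # dynes s cm^-5
    lvet: float | None      # ms
    dpdt_max: float
    sw: float | None        # ml mmHg
    n_beats: int

    #: variables participating in change tables, in reporting order
    VARIABLES = ("sbp", "dbp", "map", "hr", "sv", "co", "svr", "lvet", "dpdt_max", "sw")


@dataclasses.dataclass
class ChangeRecord:
    """Per-patient immediate change (post minus pre) and percent change.

    The percent change is computed per patient before any cohort averaging:
    100 * (post - pre) / pre.
    """

    delta: dict
    pct: dict


def stroke_volume(
    record: WaveformRecord,
    fid: FiducialSet,
    z_ao: float,
    offset: str = "foot",
) -> float:
    """Pulse-contour stroke volume for one beat, in ml.

    Integrates pressure over [foot, notch] and divides by the aortic input
    impedance ``z_ao`` (mmHg s ml^-1). With ``offset='foot'`` (default) the
    pressure is taken above the beat's foot pressure, which removes the
    diastolic offset; ``offset='absolute'`` integrates the raw pressure.
    """
    if fid.notch is None:
        raise CannotComputeError("no dicrotic notch: stroke volume undefined for this beat")
    if not z_ao > 0:
        raise ValidationError("z_ao must be positive")
    if offset not in ("foot", "absolute"):
        raise ValidationError(f"unknown offset convention {offset!r}")
    x = np.asarray(record.samples, float)
    seg = x[fid.foot : fid.notch + 1]
    base = x[fid.foot] if offset == "foot" else 0.0
    pti = float(np.trapezoid(seg - base, dx=1.0 / record.fs))  # mmHg s
    return pti / z_ao


def estimate_z_ao(
    record: WaveformRecord, fid: FiducialSet, nominal_sv: float = 70.0
) -> float:
    """Fallback aortic input impedance from a calibration beat: the systolic
    pressure-time integral divided by a nominal stroke volume (70 ml)."""
    if fid.notch is None:
        raise CannotComputeError("calibration beat has no notch")
    x = np.asarray(record.samples, float)
    seg = x[fid.foot : fid.notch + 1]
    pti = float(np.trapezoid(seg - x[fid.foot], dx=1.0 / record.fs))
    if pti <= 0:
        raise CannotComputeError("non-positive systolic pressure-time integral")
    return pti / nominal_sv


def derive_window_summary(
    beats: Sequence[BeatMetrics],
    kind: str = "window",
    cvp: float = 0.0,
    min_beats: int = 10,
) -> WindowSummary:
    """Average accepted beats into a :class:`WindowSummary`.

    CO is the mean of per-beat sv*hr (L/min); SVR uses the conventional
    factor 80 with central venous pressure defaulting to 0 mmHg; SW is the
    mean per-beat sv*map.
    """
    beats = list(beats)
    if len(beats) < min_beats:
        raise InsufficientDataError(f"need >= {min_beats} beats, got {len(beats)}")
    arr = lambda f: np.asarray([f(b) for b in beats], float)  # noqa: E731
    sbp, dbp, mp, hr = arr(lambda b: b.sbp), arr(lambda b: b.dbp), arr(lambda b: b.map), arr(lambda b: b.hr)
    dpdt = arr(lambda b: b.dpdt_max)
    lvets = np.asarray([b.lvet for b in beats if b.lvet is not None], float)
    svs = np.asarray([(b.sv, b.hr, b.map) for b in beats if b.sv is not None], float)
    sv = co = sw = svr = None
    if svs.size:
        sv = float(svs[:, 0].mean())
        co = float(np.mean(svs[:, 0] * svs[:, 1]) / 1000.0)
        sw = float(np.mean(svs[:, 0] * svs[:, 2]))
        if co > 0:
            svr = SVR_FACTOR * (float(mp.mean()) - cvp) / co
    return WindowSummary(
        kind=kind,
        sbp=float(sbp.mean()),
        dbp=float(dbp.mean()),
        map=float(mp.mean()),
        hr=float(hr.mean()),
        sv=sv,
        co=co,
        svr=svr,
        lvet=float(lvets.mean()) if lvets.size else None,
        dpdt_max=float(dpdt.mean()),
        sw=sw,
        n_beats=len(beats),
    )


def compute_bsa(height: float, weight: float, formula: str = "dubois") -> float:
    """Body surface area in m^2.

    Du Bois (default): 0.007184 * height^0.725 * weight^0.425 with height in
    cm and weight in kg; Mosteller available as an alternative. Weights below
    40 kg are rejected (outside the studied population).
    """
    if not (100.0 <= height <= 230.0):
        raise ValidationError(f"height {height} cm outside [100, 230]")
    if weight < 40.0:
        raise ValidationError(f"weight {weight} kg below the 40 kg minimum")
    if formula == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    if formula == "mosteller":
        return float(np.sqrt(height * weight / 3600.0))
    raise ValidationError(f"unknown BSA formula {formula!r}")


def compute_cpi(map_mmhg: float, co_lmin: float, bsa_m2: float) -> tuple[float, str]:
    """Cardiac power index in W m^-2 and its low/normal class.

    CPI = (MAP * CO / 451) / BSA; values >= 0.44 W m^-2 are 'normal'.
    """
    if min(map_mmhg, co_lmin, bsa_m2) <= 0:
        raise ValidationError("MAP, CO and BSA must all be positive")
    cpi = (map_mmhg * co_lmin / CPI_DENOMINATOR) / bsa_m2
    return cpi, ("normal" if cpi >= CPI_LOW_BOUNDARY else "low")


def immediate_change(pre: WindowSummary, post: WindowSummary) -> ChangeRecord:
    """Post-minus-pre delta and per-patient percent change for every
    variable present on both sides; a variable missing on either side is
    simply omitted from the result."""
    delta, pct = {}, {}
    for var in WindowSummary.VARIABLES:
        a, b = getattr(pre, var), getattr(post, var)
        if a is None or b is None:
            continue
        delta[var] = b - a
        pct[var] = 100.0 * (b - a) / a if a != 0 else np.nan
    return ChangeRecord(delta=delta, pct=pct)
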
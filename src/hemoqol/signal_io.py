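"""Waveform record container and CSV/EDF I/O.

This module is the pipeline's only I/O boundary. The reference on-disk dialect
is a two-column CSV ``time_s,pressure_mmHg`` with procedure events in a
``<stem>.events.csv`` sidecar (columns ``label,time_s``). EDF (one channel
labelled ``ABP`` in mmHg) is supported when ``pyedflib`` is importable.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: event labels with defined pipeline semantics; extra labels (e.g. ``paced``)
#: are carried through untouched.
KNOWN_EVENTS = ("baseline_start", "baseline_end", "bav", "implant", "end")

_PRESSURE_LO, _PRESSURE_HI = -50.0, 400.0  # plausibility bounds, mmHg


@dataclasses.dataclass
class WaveformRecord:
    """Uniformly sampled arterial pressure trace with labelled procedure events.

    Parameters
    ----------
    samples : ndarray
        Pressure in mmHg.
    fs : float
        Sampling rate in Hz (finger-cuff monitors record at 200 Hz).
    start_time : float
        Offset of the first sample, seconds.
    events : dict
        Mapping from event label to time in seconds (on the same clock as
        ``start_time``). ``bav`` marks balloon aortic valvuloplasty, ``implant``
        the valve deployment.
    """

    samples: np.ndarray
    fs: float = 200.0
    start_time: float = 0.0
    events: dict = dataclasses.field(default_factory=dict)
    patient_id: str | None = None
    warnings: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        dur = self.duration
        for label, t in self.events.items():
            if not (self.start_time - 1e-9 <= t <= self.start_time + dur + 1e-9):
                raise ValidationError(
                    f"event {label!r} at {t} s lies outside the record "
                    f"[{self.start_time}, {self.start_time + dur}] s"
                )
        if "bav" in self.events and "implant" in self.events:
            if not self.events["bav"] < self.events["implant"]:
                raise ValidationError("bav must precede implant")
        lo, hi = float(self.samples.min()), float(self.samples.max())
        if lo < _PRESSURE_LO or hi > _PRESSURE_HI:
            self.warnings.append(
                f"pressure range [{lo:.1f}, {hi:.1f}] mmHg outside plausible "
                f"[{_PRESSURE_LO:.0f}, {_PRESSURE_HI:.0f}] mmHg"
            )

    @property
    def duration(self) -> float:
        """Record length in seconds (= n_samples / fs)."""
        return len(self.samples) / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def slice(self, t0: float, t1: float) -> "WaveformRecord":
        """Sub-record covering [t0, t1) seconds; events outside are dropped."""
        if not t1 > t0:
            raise ValidationError(f"empty slice [{t0}, {t1})")
        i0 = max(0, int(math.ceil((t0 - self.start_time) * self.fs - 1e-9)))
        i1 = min(len(self.samples), int(round((t1 - self.start_time) * self.fs)))
        if i1 <= i0:
            raise ValidationError(f"slice [{t0}, {t1}) contains no samples")
        ev = {k: v for k, v in self.events.items() if t0 <= v <= t1}
        return WaveformRecord(
            self.samples[i0:i1],
            fs=self.fs,
            start_time=self.start_time + i0 / self.fs,
            events=ev,
            patient_id=self.patient_id,
        )


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + ".events.csv")


def read_waveform(path, format: str = "csv") -> WaveformRecord:
    """Read a :class:`WaveformRecord` from ``path``.

    CSV files must carry the header ``time_s,pressure_mmHg`` and strictly
    uniform timestamps; a sidecar ``<stem>.events.csv`` is read when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["time_s", "pressure_mmHg"]:
            raise FormatError(
                f"{path}: expected columns time_s,pressure_mmHg, got {list(df.columns)}"
            )
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least two samples")
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * max(dt.mean(), 1e-12):
            raise FormatError(f"{path}: non-uniform timestamps (gap or jitter)")
        fs = 1.0 / dt.mean()
        events = {}
        ep = _events_path(path)
        if ep.exists():
            edf = pd.read_csv(ep)
            events = dict(zip(edf["label"], edf["time_s"].astype(float)))
        return WaveformRecord(
            df["pressure_mmHg"].to_numpy(float),
            fs=float(round(fs, 6)),
            start_time=float(t[0]),
            events=events,
            patient_id=path.stem,
        )
    if format == "edf":
        return _read_edf(path)
    raise FormatError(f"unknown format {format!r}")


def write_waveform(record: WaveformRecord, path, format: str = "csv") -> None:
    """Write ``record`` so that :func:`read_waveform` reproduces it."""
    path = Path(path)
    if format == "csv":
        pd.DataFrame(
            {"time_s": record.time, "pressure_mmHg": record.samples}
        ).to_csv(path, index=False, float_format="%.10g")
        if record.events:
            pd.DataFrame(
                {"label": list(record.events), "time_s": list(record.events.values())}
            ).to_csv(_events_path(path), index=False)
        return
    if format == "edf":
        _write_edf(record, path)
        return
    raise FormatError(f"unknown format {format!r}")


def _read_edf(path: Path) -> WaveformRecord:  # pragma: no cover - optional backend
    try:
        import pyedflib
    except ImportError as exc:
        raise FormatError("EDF support requires the optional pyedflib package") from exc
    with pyedflib.EdfReader(str(path)) as r:
        labels = r.getSignalLabels()
        if "ABP" not in labels:
            raise FormatError(f"{path}: no channel labelled 'ABP'")
        ch = labels.index("ABP")
        samples = r.readSignal(ch)
        fs = r.getSampleFrequency(ch)
    events = {}
    ep = _events_path(path)
    if ep.exists():
        edf = pd.read_csv(ep)
        events = dict(zip(edf["label"], edf["time_s"].astype(float)))
    return WaveformRecord(samples, fs=fs, events=events, patient_id=path.stem)


def _write_edf(record: WaveformRecord, path: Path) -> None:  # pragma: no cover
    try:
        import pyedflib
    except ImportError as exc:
        raise FormatError("EDF support requires the optional pyedflib package") from exc
    info = {
        "label": "ABP",
        "dimension": "mmHg",
        "sample_frequency": record.fs,
        "physical_min": float(record.samples.min()) - 1,
        "physical_max": float(record.samples.max()) + 1,
        "digital_min": -32768,
        "digital_max": 32767,
    }
    with pyedflib.EdfWriter(str(path), 1) as w:
        w.setSignalHeaders([info])
        w.writeSamples([np.asarray(record.samples, float)])
    if record.events:
        pd.DataFrame(
            {"label": list(record.events), "time_s": list(record.events.values())}
        ).to_csv(_events_path(path), index=False)


def events_from_mapping(events: Mapping[str, float]) -> dict:
    """Normalise an event mapping to float times, keeping unknown labels."""
    return {str(k): float(v) for k, v in events.items()}
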
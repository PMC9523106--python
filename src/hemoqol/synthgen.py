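"""Synthetic-data engine.

Two generators with known ground truth:

* beat-resolved arterial pressure waveforms from a forward three-element
  Windkessel model (characteristic impedance Zc, compliance C, peripheral
  resistance Rp) driven by a half-sine aortic inflow of configurable stroke
  volume and ejection time, with a damped oscillation superimposed at flow
  cessation so a dicrotic notch is detectable; and

* patient cohorts whose pre-implantation means/SDs, immediate changes,
  quality-of-life distribution, LVET-HRQoL association and missingness
  mirror the published cohort structure.

Every pipeline stage is testable against these generators with no download.
"""
from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sst

from .exceptions import ConfigError
from .hemo import compute_cpi
from .hrqol import attainable_indices, load_tariff, nearest_state
from .signal_io import WaveformRecord

# ---------------------------------------------------------------------------
# waveform generator


@dataclasses.dataclass
class WaveformTruth:
    """Ground truth carried alongside a generated waveform."""

    foot_times: np.ndarray   # s, true beat onsets
    sv: np.ndarray           # ml per beat
    lvet_ms: np.ndarray      # ms per beat
    ibi: np.ndarray          # s per beat
    zc: float                # mmHg s ml^-1
    c: float                 # ml mmHg^-1
    rp: float                # mmHg s ml^-1
    notch_amp: float         # mmHg
    z_ao: float              # effective aortic input impedance of the
                             # generated pressure curve, mmHg s ml^-1
    mean_pressure: float = float("nan")  # time average of the noiseless trace, mmHg


def generate_waveform(
    sv: float = 70.0,
    hr: float = 75.0,
    lvet_ms: float = 332.0,
    duration: float = 20.0,
    fs: float = 200.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    ibi_cv: float = 0.03,
    zc: float = 0.06,
    c: float = 1.3,
    rp: float = 0.75,
    p_out: float = 25.0,
    notch_amp: float = 3.0,
    notch_freq: float = 8.0,
    notch_tau: float = 0.05,
    patient_id: str | None = None,
) -> tuple[WaveformRecord, WaveformTruth]:
    """Generate a pressure record with known per-beat SV, LVET and HR.

    Per beat, a half-sine inflow of duration ``lvet_ms`` and area ``sv``
    drives the Windkessel; the pressure is Zc*Q plus the compliance response
    plus a decaying offset ``p_out``; a damped sinusoid of amplitude
    ``notch_amp`` starts exactly at flow cessation. Gaussian sample noise of
    ``noise_sd`` mmHg is added last. Raises :class:`ConfigError` when the
    ejection time does not fit in the beat interval.
    """
    if fs < 100:
        raise ConfigError("need fs >= 100 Hz")
    if duration < 2:
        raise ConfigError("need duration >= 2 s")
    ibi_mean = 60.0 / hr
    lvet_s = lvet_ms / 1000.0
    if lvet_s >= ibi_mean:
        raise ConfigError(f"LVET {lvet_ms} ms >= beat interval {ibi_mean * 1000:.0f} ms")
    rng = np.random.default_rng(seed)

    ibis, total = [], 0.0
    while total < duration + ibi_mean:
        ibi = max(lvet_s + 0.15, rng.normal(ibi_mean, ibi_cv * ibi_mean))
        ibis.append(ibi)
        total += ibi
    ibis = np.asarray(ibis)
    foot_times = np.concatenate([[0.0], np.cumsum(ibis)[:-1]])

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    q = np.zeros(n)
    notch = np.zeros(n)
    qm = math.pi * sv / (2.0 * lvet_s)  # peak inflow so the half-sine area = sv
    for ft in foot_times:
        i0 = int(np.ceil(ft * fs))
        i1 = min(n, int(np.floor((ft + lvet_s) * fs)) + 1)
        if i0 >= n:
            break
        tt = t[i0:i1] - ft
        q[i0:i1] += qm * np.sin(np.clip(tt, 0, lvet_s) * math.pi / lvet_s)
        j0 = int(np.ceil((ft + lvet_s) * fs))
        j1 = min(n, j0 + int(6 * notch_tau * fs))
        if j0 < n:
            tn = t[j0:j1] - (ft + lvet_s)
            notch[j0:j1] += notch_amp * np.exp(-tn / notch_tau) * np.sin(
                2 * math.pi * notch_freq * tn
            )

    # exact first-order discretisation of C dPw/dt = Q - Pw/Rp
    a = math.exp(-1.0 / (fs * rp * c))
    pw0 = rp * q.mean()
    pw = sps.lfilter([(1 - a) * rp], [1, -a], q, zi=np.array([a * pw0]))[0]
    clean = p_out + pw + zc * q + notch

    # the impedance that relates this curve's systolic pressure-time integral
    # to the true stroke volume (the "matched" z_ao for recovery tests)
    zs = []
    for ft in foot_times:
        i0 = int(round(ft * fs))
        i1 = int(round((ft + lvet_s) * fs))
        if i1 >= n:
            break
        seg = clean[i0 : i1 + 1]
        zs.append(np.trapezoid(seg - seg[0], dx=1.0 / fs) / sv)
    z_ao = float(np.mean(zs)) if zs else float("nan")

    samples = clean + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else clean
    complete = foot_times + ibis <= duration
    truth = WaveformTruth(
        foot_times=foot_times[complete],
        sv=np.full(int(complete.sum()), float(sv)),
        lvet_ms=np.full(int(complete.sum()), float(lvet_ms)),
        ibi=ibis[complete],
        zc=zc,
        c=c,
        rp=rp,
        notch_amp=notch_amp,
        z_ao=z_ao,
        mean_pressure=float(clean.mean()),
    )
    record = WaveformRecord(samples, fs=fs, patient_id=patient_id)
    return record, truth


def generate_procedure_record(
    pre: dict | None = None,
    post: dict | None = None,
    bav: bool = False,
    seed: int = 0,
    fs: float = 200.0,
    baseline_len: float = 600.0,
    pre_gap: float = 120.0,
    bav_extra: float = 336.0,
    post_len: float = 200.0,
    noise_sd: float = 1.0,
    patient_id: str | None = None,
) -> tuple[WaveformRecord, dict]:
    """A full procedure timeline: baseline and pre-implantation epochs at the
    pre hemodynamics, then a step change to the post hemodynamics at valve
    implantation. Valvuloplasty patients get a ``bav`` event and the
    configured extra elapsed time (default 336 s) before implantation.

    ``pre``/``post`` are keyword dicts for :func:`generate_waveform`
    (``sv``, ``hr``, ``lvet_ms``, ...). Returns the event-annotated record
    and a dict of the two :class:`WaveformTruth` objects.
    """
    pre = {**{"sv": 69.2, "hr": 72.7, "lvet_ms": 332.0}, **(pre or {})}
    post = {**{"sv": 72.6, "hr": 76.2, "lvet_ms": 322.0}, **(post or {})}
    t_ref = baseline_len + pre_gap              # bav when performed, else implant
    t_implant = t_ref + (bav_extra if bav else 0.0)
    t_end = t_implant + post_len
    if baseline_len < 2 or post_len < 25:
        raise ConfigError("duration budget too small for the analysis windows")
    rec_pre, truth_pre = generate_waveform(
        duration=t_implant, fs=fs, noise_sd=noise_sd, seed=seed, **pre
    )
    rec_post, truth_post = generate_waveform(
        duration=post_len, fs=fs, noise_sd=noise_sd, seed=seed + 1, **post
    )
    samples = np.concatenate([rec_pre.samples, rec_post.samples])
    events = {"baseline_start": 0.0, "implant": t_implant, "end": t_end}
    if bav:
        events["bav"] = t_ref
    record = WaveformRecord(samples, fs=fs, events=events, patient_id=patient_id)
    truth_post = dataclasses.replace(
        truth_post, foot_times=truth_post.foot_times + t_implant
    )
    return record, {"pre": truth_pre, "post": truth_post}


# ---------------------------------------------------------------------------
# cohort generator

#: Pre-implantation mean/SD and immediate change mean with its 95% CI for the
#: directly simulated variables. Change SDs are reconstructed from the CIs of
#: the mean change in the reference cohort of 97 patients
#: (SD = halfwidth / 1.96 * sqrt(97)).
TABLE_DEFAULTS = {
    "sbp": {"pre_mean": 137.5, "pre_sd": 27.0, "change_mean": 14.2, "change_ci": (9.4, 19.0)},
    "dbp": {"pre_mean": 65.6, "pre_sd": 11.2, "change_mean": 3.2, "change_ci": (1.3, 5.2)},
    "map": {"pre_mean": 91.4, "pre_sd": 15.8, "change_mean": 6.6, "change_ci": (3.7, 9.5)},
    "hr": {"pre_mean": 72.7, "pre_sd": 15.5, "change_mean": 3.6, "change_ci": (1.3, 5.8)},
    "sv": {"pre_mean": 69.2, "pre_sd": 21.2, "change_mean": 3.4, "change_ci": (1.4, 5.4)},
    "lvet": {"pre_mean": 332.0, "pre_sd": 33.0, "change_mean": -10.0, "change_ci": (-16.0, -4.0)},
}
_N_REF = 97  # cohort size behind the printed CIs

#: correlations imposed on the pre draws and on the deltas
_PRE_CORR = {("sbp", "map"): 0.8, ("dbp", "map"): 0.8, ("sbp", "dbp"): 0.5}
_DELTA_CORR_DEFAULT = {("sbp", "map"): 0.5, ("dbp", "map"): 0.5}


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the published cohort: n = 97; the directly simulated
    hemodynamic variables at their pre-implantation means/SDs with additive
    immediate changes whose SDs derive from the printed CIs; dP/dt changed
    multiplicatively with a mean per-patient change of +67 %; the
    quality-of-life index drawn from a scaled Beta calibrated to the
    pre-procedural median 0.810 with IQR [0.662, 0.914]; the LVET-HRQoL
    effect of +0.02 index points per 10 ms LVET decrease; 9/97 pre and 1/97
    post indices missing completely at random; half the cohort undergoing
    valvuloplasty with 336 s extra elapsed time.
    """

    n: int = 97
    variables: dict = dataclasses.field(default_factory=lambda: {k: dict(v) for k, v in TABLE_DEFAULTS.items()})
    dpdt_pre_mean: float = 724.0
    dpdt_pre_sd: float = 368.0
    dpdt_pct_mean: float = 0.67       # mean per-patient fractional change
    dpdt_pct_sd: float = 0.55         # SD of the fractional change (from the CI)
    dpdt_pre_coupling: float = 0.38   # negative pre <-> %change coupling, see methods
    lvet_hr_delta_corr: float = -0.3
    hrqol_beta_a: float = 5.7926      # Beta shape calibrated to the index quantiles
    hrqol_beta_b: float = 1.1281
    lvet_effect: float = -0.002       # index points per ms LVET change
    hrqol_resid_sd: float = 0.15
    missing_pre_frac: float = 9.0 / 97.0
    missing_post_frac: float = 1.0 / 97.0
    bav_fraction: float = 0.5
    bav_extra_elapsed: float = 336.0
    base_elapsed_mean: float = 240.0
    base_elapsed_sd: float = 60.0
    tariff: str = "dutch"
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ConfigError("need n >= 3")
        for name, spec in self.variables.items():
            if not spec["pre_sd"] > 0:
                raise ConfigError(f"{name}: pre_sd must be positive")
        for frac in (self.missing_pre_frac, self.missing_post_frac, self.bav_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if not self.hrqol_resid_sd >= 0:
            raise ConfigError("residual SD must be non-negative")


def _change_sd(spec: dict) -> float:
    lo, hi = spec["change_ci"]
    return (hi - lo) / 2.0 / 1.96 * math.sqrt(_N_REF)


def _corr_normal(rng, means, sds, corr_pairs, names, n):
    """Multivariate normal draws with the given marginals and pairwise corr."""
    k = len(names)
    r = np.eye(k)
    for (a, b), rho in corr_pairs.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            r[i, j] = r[j, i] = rho
    # nearest PD safeguard
    w, v = np.linalg.eigh(r)
    r = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(k), r, size=n, method="cholesky")
    return {nm: means[i] + sds[i] * z[:, i] for i, nm in enumerate(names)}


@lru_cache(maxsize=4)
def _index_table(tariff_name: str) -> pd.DataFrame:
    return attainable_indices(load_tariff(tariff_name))


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """One synthetic cohort as a flat table with hidden ``truth_`` columns.

    Observable columns: demographics, valvuloplasty flag and elapsed time,
    ``{var}_pre`` / ``{var}_post`` / ``delta_{var}`` / ``pct_{var}`` for the
    ten reported hemodynamic variables (CO, SVR and SW derived per patient
    from SV, HR and MAP), EQ-5D-5L states and index values pre/post with the
    configured missingness. ``truth_`` columns retain the pre-missingness
    indices and the applied association coefficient.
    """
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    names = list(cfg.variables)
    pre = _corr_normal(
        rng,
        [cfg.variables[v]["pre_mean"] for v in names],
        [cfg.variables[v]["pre_sd"] for v in names],
        _PRE_CORR,
        names,
        n,
    )
    delta_corr = dict(_DELTA_CORR_DEFAULT)
    delta_corr[("lvet", "hr")] = cfg.lvet_hr_delta_corr
    delta = _corr_normal(
        rng,
        [cfg.variables[v]["change_mean"] for v in names],
        [_change_sd(cfg.variables[v]) for v in names],
        delta_corr,
        names,
        n,
    )
    # physiologic floors; rare at the configured moments
    pre["sbp"] = np.clip(pre["sbp"], 60, 250)
    pre["dbp"] = np.clip(pre["dbp"], 25, 150)
    pre["hr"] = np.clip(pre["hr"], 30, 180)
    pre["sv"] = np.clip(pre["sv"], 15, 160)
    pre["lvet"] = np.clip(pre["lvet"], 180, 500)
    pre["map"] = np.clip(pre["map"], pre["dbp"] + 1.0, pre["sbp"] - 1.0)

    post = {v: pre[v] + delta[v] for v in names}
    post["sbp"] = np.clip(post["sbp"], 60, 260)
    post["dbp"] = np.clip(post["dbp"], 25, 150)
    post["hr"] = np.clip(post["hr"], 30, 200)
    post["sv"] = np.clip(post["sv"], 15, 170)
    post["lvet"] = np.clip(post["lvet"], 160, 500)
    post["map"] = np.clip(post["map"], post["dbp"] + 1.0, post["sbp"] - 1.0)

    # dP/dt: lognormal pre (positive, matches mean/SD exactly); multiplicative
    # change whose per-patient fractional mean is the configured target, with
    # a negative coupling to the pre value reproducing the published
    # mean-change asymmetry (see docs/methods.md)
    cv2 = (cfg.dpdt_pre_sd / cfg.dpdt_pre_mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(cfg.dpdt_pre_mean) - sigma2 / 2.0
    dpdt_pre = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    coup = cfg.dpdt_pre_coupling
    resid_var = cfg.dpdt_pct_sd**2 - coup**2 * cv2
    resid_sd = math.sqrt(max(resid_var, 0.01))
    pct = (
        cfg.dpdt_pct_mean
        + resid_sd * rng.standard_normal(n)
        - coup * (dpdt_pre - cfg.dpdt_pre_mean) / cfg.dpdt_pre_mean
    )
    pct = np.maximum(pct, -0.9)
    pre["dpdt_max"] = dpdt_pre
    post["dpdt_max"] = dpdt_pre * (1.0 + pct)

    # derived indices, per patient
    for d in (pre, post):
        d["co"] = d["sv"] * d["hr"] / 1000.0
        d["svr"] = 80.0 * d["map"] / d["co"]
        d["sw"] = d["sv"] * d["map"]

    # demographics
    age = np.clip(rng.normal(81.0, 5.6, n), 60, 100)
    male = rng.random(n) < 0.443
    height = np.clip(rng.normal(167.0, 9.0, n), 140, 200)
    weight = np.clip(rng.normal(79.2, 18.3, n), 40, 150)
    bsa = 0.007184 * height**0.725 * weight**0.425
    lvef = np.clip(rng.normal(54.0, 17.0, n), 10, 85)
    bav = rng.random(n) < cfg.bav_fraction
    elapsed = rng.normal(cfg.base_elapsed_mean, cfg.base_elapsed_sd, n)
    elapsed = np.maximum(60.0, elapsed + np.where(bav, cfg.bav_extra_elapsed, 0.0))

    cpi = np.empty(n)
    cpi_class = np.empty(n, object)
    for i in range(n):
        cpi[i], cpi_class[i] = compute_cpi(pre["map"][i], pre["co"][i], bsa[i])

    # quality of life: latent pre utility from the calibrated scaled Beta,
    # snapped to the nearest attainable EQ-5D-5L state and scored
    table = _index_table(cfg.tariff)
    lo_idx = float(table["index"].iloc[0])
    hi_idx = float(table["index"].iloc[-1])
    span = hi_idx - lo_idx
    latent_pre = lo_idx + span * rng.beta(cfg.hrqol_beta_a, cfg.hrqol_beta_b, size=n)
    pre_states = nearest_state(latent_pre, table)
    hrqol_pre = pre_states["index"].to_numpy(float)

    beta_ms = cfg.lvet_effect
    shift = beta_ms * delta["lvet"]
    sd = cfg.hrqol_resid_sd
    if sd > 0:
        # censoring-aware calibration: inflate the latent shift by the mean
        # in-range probability so the realized slope of the observed, ceiling-
        # censored index equals the configured coefficient
        w = sst.norm.cdf((hi_idx - hrqol_pre - shift) / sd) - sst.norm.cdf(
            (lo_idx - hrqol_pre - shift) / sd
        )
        beta_applied = beta_ms / float(np.mean(w))
        latent_post = hrqol_pre + beta_applied * delta["lvet"] + rng.normal(0.0, sd, n)
    else:
        beta_applied = beta_ms
        latent_post = hrqol_pre + beta_applied * delta["lvet"]
    latent_post = np.clip(latent_post, lo_idx, hi_idx)
    post_states = nearest_state(latent_post, table)
    hrqol_post = post_states["index"].to_numpy(float)

    # missingness, completely at random, as fixed patient counts
    n_miss_pre = int(round(cfg.missing_pre_frac * n))
    n_miss_post = int(round(cfg.missing_post_frac * n))
    chosen = rng.choice(n, size=min(n, n_miss_pre + n_miss_post), replace=False)
    miss_pre = np.zeros(n, bool)
    miss_post = np.zeros(n, bool)
    miss_pre[chosen[:n_miss_pre]] = True
    miss_post[chosen[n_miss_pre : n_miss_pre + n_miss_post]] = True

    out = {
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "age": age,
        "sex": np.where(male, "M", "F"),
        "height": height,
        "weight": weight,
        "bsa": bsa,
        "lvef": lvef,
        "valvuloplasty": bav,
        "elapsed_s": elapsed,
        "cpi_baseline": cpi,
        "cpi_class": cpi_class,
    }
    for v in list(names) + ["dpdt_max", "co", "svr", "sw"]:
        out[f"{v}_pre"] = pre[v]
        out[f"{v}_post"] = post[v]
        out[f"delta_{v}"] = post[v] - pre[v]
        out[f"pct_{v}"] = 100.0 * (post[v] - pre[v]) / pre[v]
    out["eq5d_pre"] = pre_states["state"].to_numpy(object)
    out["eq5d_post"] = post_states["state"].to_numpy(object)
    out["hrqol_pre"] = np.where(miss_pre, np.nan, hrqol_pre)
    out["hrqol_post"] = np.where(miss_post, np.nan, hrqol_post)
    out["truth_hrqol_pre"] = hrqol_pre
    out["truth_hrqol_post"] = hrqol_post
    out["truth_lvet_effect"] = np.full(n, beta_ms)
    out["truth_lvet_effect_applied"] = np.full(n, beta_applied)
    df = pd.DataFrame(out)
    df["eq5d_missing"] = miss_pre | miss_post
    df.loc[miss_pre, "eq5d_pre"] = None
    df.loc[miss_post, "eq5d_post"] = None
    return df


def split_truth(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the observable table from the hidden ``truth_`` columns."""
    truth_cols = [c for c in cohort.columns if c.startswith("truth_")]
    truth = cohort[["patient_id"] + truth_cols].copy()
    return cohort.drop(columns=truth_cols), truth
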
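"""Study orchestration: waveforms -> windows -> summaries -> cohort table ->
statistics, as one reproducible run.

A run either analyzes a directory of waveform records plus a patient CSV, or
generates a synthetic cohort (optionally with synthetic procedure waveforms).
Exclusions mirror the study rules: no artifact-free analysis window,
suspected new arrhythmia in the analysis windows, annotated pacing. The
report contains the cohort flow, the ten-variable change table, the
quality-of-life medians with their rank-test p-value, mixed-model
associations of each hemodynamic change with the index change, and the
contrasts by baseline cardiac-power class and by valvuloplasty.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import beats_table, rhythm_flag, select_timeframes
from .exceptions import (
    ConfigError,
    HemoqolError,
    InsufficientDataError,
    PatientExclusionError,
)
from .hemo import WindowSummary, immediate_change
from .signal_io import read_waveform
from .stats import (
    compare_distributions,
    mice_impute,
    mixed_association,
    rubin_pool,
    summarize_changes,
)
from .synthgen import CohortConfig, generate_cohort, split_truth

CHANGE_VARIABLES = ("sbp", "dbp", "map", "hr", "sv", "co", "svr", "lvet", "dpdt_max", "sw")


@dataclasses.dataclass
class StudyReport:
    """Everything a study run produces, serialisable to JSON."""

    flow: dict                    # enrolled / excluded-by-reason / analyzed
    change_table: list            # one dict per variable
    hrqol: dict                   # medians, IQRs, rank-test p
    associations: dict            # variable -> ModelResult dict
    cpi_contrasts: dict
    valvuloplasty_contrast: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, default=_jsonify)

    def validate(self):
        excl = sum(self.flow["excluded"].values())
        if self.flow["analyzed"] != self.flow["enrolled"] - excl:
            raise HemoqolError("exclusion accounting does not sum")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _result_dict(r) -> dict:
    return {
        "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p_value": r.p_value, "n": r.n, "method": r.method,
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _summary_from_window(record, window, z_ao: float) -> WindowSummary:
    """Beat table over a selected window -> WindowSummary with pulse-contour SV."""
    from .beats import BeatMetrics, FiducialSet, detect_beats, locate_fiducials, beat_metrics
    from .hemo import derive_window_summary, stroke_volume
    from .exceptions import CannotComputeError, DegenerateBeatError

    sub = record.slice(window.start, window.end)
    feet = detect_beats(sub)
    metrics = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        try:
            fid = locate_fiducials(sub, (f0, f1))
            m = beat_metrics(sub, fid)
        except DegenerateBeatError:
            continue
        if fid.notch is not None:
            try:
                m.sv = stroke_volume(sub, fid, z_ao)
            except CannotComputeError:
                pass
        metrics.append(m)
    return derive_window_summary(metrics, kind=window.kind)


def analyze_waveform_patient(
    record, z_ao: float = None, threshold: float = 0.2, baseline_len: float = 600.0
) -> dict:
    """Windows, rhythm checks and pre/post summaries for one record.

    Raises :class:`PatientExclusionError` with a machine-readable reason when
    the study's exclusion rules apply.
    """
    from .hemo import estimate_z_ao
    from .beats import detect_beats, locate_fiducials

    windows = select_timeframes(record, threshold=threshold, baseline_len=baseline_len)
    if z_ao is None:
        sub = record.slice(windows["pre_tavi"].start, windows["pre_tavi"].end)
        feet = detect_beats(sub)
        z_ao = None
        for f0, f1 in zip(feet[:-1], feet[1:]):
            fid = locate_fiducials(sub, (f0, f1))
            if fid.notch is not None:
                z_ao = estimate_z_ao(sub, fid)
                break
        if z_ao is None:
            raise PatientExclusionError("no_artifact_free_window", "no calibration beat")
    summaries = {}
    for kind in ("pre_tavi", "post_tavi"):
        w = windows[kind]
        sub = record.slice(w.start, w.end)
        tab = beats_table(sub)
        if len(tab) < 10:
            raise PatientExclusionError("no_artifact_free_window", f"too few beats in {kind}")
        flag = rhythm_flag(tab, record.events)
        if flag == "annotated_paced":
            raise PatientExclusionError("pacemaker_support")
        if flag == "irregular_suspect":
            raise PatientExclusionError("new_onset_arrhythmia")
        summaries[kind] = _summary_from_window(record, w, z_ao)
    return {"windows": windows, "pre": summaries["pre_tavi"], "post": summaries["post_tavi"]}


def _cohort_from_waveforms(cfg: dict) -> tuple[pd.DataFrame, dict]:
    wf_dir = Path(cfg["waveforms"]["dir"])
    patients = pd.read_csv(cfg["waveforms"]["patients"])
    excluded = {"no_artifact_free_window": 0, "new_onset_arrhythmia": 0, "pacemaker_support": 0}
    rows = []
    for _, p in patients.iterrows():
        path = wf_dir / f"{p.patient_id}.csv"
        record = read_waveform(path)
        try:
            res = analyze_waveform_patient(
                record,
                z_ao=p.get("z_ao"),
                threshold=cfg.get("artifact_threshold", 0.2),
                baseline_len=cfg.get("baseline_len", 600.0),
            )
        except PatientExclusionError as exc:
            excluded[exc.reason] = excluded.get(exc.reason, 0) + 1
            continue
        row = dict(p)
        pre, post = res["pre"], res["post"]
        chg = immediate_change(pre, post)
        for v in CHANGE_VARIABLES:
            row[f"{v}_pre"] = getattr(pre, v)
            row[f"{v}_post"] = getattr(post, v)
            row[f"delta_{v}"] = chg.delta.get(v)
            row[f"pct_{v}"] = chg.pct.get(v)
        rows.append(row)
    cohort = pd.DataFrame(rows)
    if "eq5d_pre" in cohort.columns:
        from .hrqol import EQ5DState, load_tariff, score_eq5d

        tariff = load_tariff(cfg.get("tariff", "dutch"))
        for col, out in (("eq5d_pre", "hrqol_pre"), ("eq5d_post", "hrqol_post")):
            cohort[out] = [
                score_eq5d(EQ5DState.from_string(str(s)), tariff) if pd.notna(s) else np.nan
                for s in cohort[col]
            ]
    return cohort, excluded


def run_study(config, output_dir: str | Path | None = None) -> StudyReport:
    """Run the full analysis described by ``config`` (YAML path or dict).

    The config must contain either a ``synthgen`` block (synthetic cohort)
    or a ``waveforms`` block (``dir`` with ``<patient_id>.csv`` records and a
    ``patients`` CSV). Artifacts (report JSON, cohort and change CSVs) are
    written to ``output_dir`` when given.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    excluded = {}
    if "synthgen" in cfg:
        block = cfg["synthgen"] or {}
        cohort_kwargs = dict(block.get("cohort", {}))
        cc = CohortConfig(**cohort_kwargs, seed=seed) if "seed" not in cohort_kwargs else CohortConfig(**cohort_kwargs)
        cohort = generate_cohort(cc)
        enrolled = len(cohort)
    elif "waveforms" in cfg:
        cohort, excluded = _cohort_from_waveforms(cfg)
        enrolled = len(cohort) + sum(excluded.values())
    else:
        raise ConfigError("config needs a 'synthgen' or 'waveforms' block")
    if len(cohort) == 0:
        raise ConfigError("zero analyzable patients")

    change_table = []
    for var in CHANGE_VARIABLES:
        if f"{var}_pre" not in cohort.columns:
            continue
        try:
            change_table.append(summarize_changes(cohort, var))
        except InsufficientDataError:
            continue

    hrqol: dict = {}
    associations: dict = {}
    if "hrqol_pre" in cohort.columns:
        pre = cohort["hrqol_pre"].to_numpy(float)
        post = cohort["hrqol_post"].to_numpy(float)
        ok = np.isfinite(pre) & np.isfinite(post)
        wil = compare_distributions(post[ok], pre[ok], design="paired", kind="rank")
        hrqol = {
            "pre_median": float(np.nanmedian(pre)),
            "pre_iqr": [float(np.nanpercentile(pre, 25)), float(np.nanpercentile(pre, 75))],
            "post_median": float(np.nanmedian(post)),
            "post_iqr": [float(np.nanpercentile(post, 25)), float(np.nanpercentile(post, 75))],
            "n_imputed_pre": int(np.isnan(pre).sum()),
            "n_imputed_post": int(np.isnan(post).sum()),
            "wilcoxon_p": wil.p_value,
        }
        # impute missing indices, pool each association across imputations
        # (association models need a reasonable cohort; small smoke runs
        # still get the change table and the medians above)
        m = int(cfg.get("m_imputations", 5)) if len(cohort) >= 20 else 0
        if m > 0:
            impute_cols = ["hrqol_pre", "hrqol_post"] + [
                f"delta_{v}" for v in CHANGE_VARIABLES if f"delta_{v}" in cohort.columns
            ]
            completed = mice_impute(cohort[impute_cols], m=m,
                                    iters=int(cfg.get("mice_iters", 10)), seed=seed,
                                    k_pmm=int(cfg.get("pmm_donors", 5)))
            for var in CHANGE_VARIABLES:
                col = f"delta_{var}"
                if col not in cohort.columns:
                    continue
                scale = -10.0 if var == "lvet" else 1.0
                fits = [
                    mixed_association(comp, predictor=col, scale=scale,
                                      model_form=cfg.get("model_form", "mixed"))
                    for comp in completed
                ]
                associations[var] = _result_dict(rubin_pool(fits))
                associations[var]["scale"] = scale

    cpi_contrasts: dict = {}
    if ("cpi_class" in cohort.columns and cohort["cpi_class"].nunique() == 2
            and len(cohort) >= 20):
        ind = (cohort["cpi_class"] == "normal").astype(float)
        work = cohort.assign(cpi_normal=ind)
        for var in ("sv", "svr"):
            col = f"delta_{var}"
            if col in work.columns:
                r = mixed_association(
                    work, outcome=(f"{var}_pre", f"{var}_post"),
                    predictor="cpi_normal", scale=1.0,
                )
                cpi_contrasts[var] = _result_dict(r)
        if "hrqol_pre" in work.columns:
            r = mixed_association(work, predictor="cpi_normal", scale=1.0)
            cpi_contrasts["hrqol"] = _result_dict(r)

    valv: dict = {}
    if ("valvuloplasty" in cohort.columns and cohort["valvuloplasty"].nunique() == 2
            and len(cohort) >= 20):
        ind = cohort["valvuloplasty"].astype(float)
        work = cohort.assign(bav=ind)
        for var in CHANGE_VARIABLES:
            if f"{var}_pre" not in work.columns:
                continue
            r = mixed_association(
                work, outcome=(f"{var}_pre", f"{var}_post"), predictor="bav", scale=1.0
            )
            valv[var] = _result_dict(r)
        if "elapsed_s" in cohort.columns:
            a = cohort.loc[cohort.valvuloplasty, "elapsed_s"]
            b = cohort.loc[~cohort.valvuloplasty, "elapsed_s"]
            valv["elapsed_s_difference"] = float(a.mean() - b.mean())

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = StudyReport(
        flow={"enrolled": enrolled, "excluded": excluded,
              "analyzed": len(cohort)},
        change_table=change_table,
        hrqol=hrqol,
        associations=associations,
        cpi_contrasts=cpi_contrasts,
        valvuloplasty_contrast=valv,
        provenance={"config_sha256": cfg_hash, "seed": seed, "version": __version__},
    )
    report.validate()

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        obs, truth = split_truth(cohort)
        obs.to_csv(out / "cohort.csv", index=False)
        if len(truth.columns) > 1:
            truth.to_csv(out / "cohort_truth.csv", index=False)
        pd.DataFrame(change_table).to_csv(out / "changes.csv", index=False)
    return report
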
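#!/usr/bin/env python
"""Generate the study's synthetic inputs: one full procedure waveform with
events (baseline, valvuloplasty, implantation) and a 97-patient cohort with
hidden ground truth. The cohort tables go to results/simulated/; the bulky
waveform CSV goes to scratch/."""
from pathlib import Path

from hemoqol.signal_io import write_waveform
from hemoqol.synthgen import CohortConfig, generate_cohort, generate_procedure_record, split_truth

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)
SCRATCH = ROOT / "scratch"
SCRATCH.mkdir(exist_ok=True)

record, truth = generate_procedure_record(bav=True, seed=1, patient_id="example")
write_waveform(record, SCRATCH / "example.csv")
print(f"waveform: {record.duration:.0f} s at {record.fs:.0f} Hz, events {record.events}")
print(f"  true pre LVET {truth['pre'].lvet_ms[0]:.0f} ms, post {truth['post'].lvet_ms[0]:.0f} ms; "
      f"matched z_ao {truth['pre'].z_ao:.3f} mmHg s/ml")

cohort = generate_cohort(CohortConfig(seed=1))
obs, hidden = split_truth(cohort)
obs.to_csv(OUT / "cohort.csv", index=False)
hidden.to_csv(OUT / "cohort_truth.csv", index=False)
print(f"cohort: {len(obs)} patients, {obs['hrqol_pre'].isna().sum()} missing pre indices, "
      f"{obs['hrqol_post'].isna().sum()} missing post")
print(f"wrote {SCRATCH}/example.csv and {OUT}/cohort.csv, cohort_truth.csv")
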
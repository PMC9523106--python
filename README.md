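# hemoqol

Beat-level arterial pulse-contour hemodynamics around transcatheter aortic
valve implantation (TAVI), EQ-5D-5L quality-of-life scoring, and the
statistics linking the two.

TAVI removes a left-ventricular outflow obstruction within seconds, and the
arterial pressure waveform records the ventricle's immediate response. This
package is for researchers analyzing such recordings: it extracts per-beat
variables from a continuous 200 Hz pressure trace — systolic/diastolic/mean
pressure, heart rate, left ventricular ejection time (LVET, foot to
dicrotic notch), dP/dt max, and pulse-contour stroke volume
SV = ∫(P − P_foot)dt / Z_ao over systole — and derives CO = SV·HR,
SVR = 80·(MAP − CVP)/CO, stroke work SV·MAP, and the cardiac power index
CPI = (MAP·CO/451)/BSA (low < 0.44 W·m⁻²). Health-related quality of life
is scored from EQ-5D-5L states with the Dutch tariff (index range −0.446 to
1). The statistical layer provides the paired change table, rank and exact
tests, Gaussian linear mixed models with a random intercept per patient
(reporting, e.g., index points per 10 ms LVET decrease), chained-equation
imputation with predictive mean matching and Rubin pooling, Little's MCAR
test, and exact noncentral-F power for multiple regression.

Because no patient data are distributable, the package ships a first-class
synthetic-data engine: a three-element Windkessel waveform generator with
known per-beat SV/LVET/HR truth, and a cohort generator calibrated to the
published pre-implantation summary statistics, immediate changes,
quality-of-life quantiles and missingness. Every pipeline stage is tested
against this ground truth.

## Worked example

Run the full synthetic study (a 97-patient cohort at the default
calibration, seed 1):

```sh
python analysis/03_cohort_study.py
```

which prints

```
analyzed 97 of 97 patients
variable       pre    post  change    %       p
sbp          136.1   148.5    12.4   10   0.000
...
lvet         328.0   310.1   -17.9   -6   0.000
dpdt_max     759.8  1194.4   434.6   70   0.000
sw          6436.8  7005.0   568.2   10   0.000
HRQoL index median 0.832 -> 0.849 (Wilcoxon p = 0.073; 9+1 imputed)
LVET association: +0.012 index points per 10 ms decrease (95% CI 0.005 to 0.020, p = 0.002)
valvuloplasty elapsed-time difference: 326 s
```

Each change row is the within-patient post-minus-pre mean with its paired-t
CI; the percent column is the mean of per-patient percent changes (hence
dP/dt's 70 % despite 435/760 ≈ 57 % — the convention matters under skew).
The association line is the pooled mixed-model interaction after imputing
the 10 missing indices: this seed's cohort realizes a positive index gain
per 10 ms LVET decrease, within sampling error of the generator's
configured +0.02. The other drivers — `analysis/01_simulate.py` (writes
example records and cohorts), `02_waveform_validation.py` (truth-recovery
errors of LVET/SV/HR on 100 records), `04_power_and_missingness.py` (power
curve; Little's-test calibration) — print similar one-screen summaries and
write their tables under `results/`.

The same machinery is scriptable:

```python
from hemoqol import generate_waveform, detect_beats, locate_fiducials, stroke_volume

record, truth = generate_waveform(sv=70, hr=75, lvet_ms=332, duration=30, seed=7)
feet = detect_beats(record)
fid = locate_fiducials(record, feet[:2])
print(stroke_volume(record, fid, truth.z_ao))   # ~70 ml
```

or from the shell: `hemoqol simulate`, `hemoqol analyze config.yaml`,
`hemoqol report out/report.json`.

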
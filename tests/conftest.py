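import numpy as np
import pytest

from hemoqol.synthgen import generate_procedure_record, generate_waveform


@pytest.fixture(scope="session")
def clean_record():
    """20-s waveform at the cohort's pre-implantation hemodynamics."""
    record, truth = generate_waveform(sv=70, hr=75, lvet_ms=332, duration=20, seed=101)
    return record, truth


@pytest.fixture(scope="session")
def procedure_record():
    """Full procedure timeline (10-min baseline, valvuloplasty, implantation)."""
    record, truth = generate_procedure_record(bav=True, seed=77, patient_id="fix01")
    return record, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
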
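import numpy as np
import pytest

import dilongqc as dq


@pytest.fixture(scope="session")
def default_params():
    return dq.GeneratorParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return dq.GeneratorParams(noise_sd=0.0, drift_amplitude=0.0, rt_jitter_sd=0.0)


@pytest.fixture(scope="session")
def midrange_concentrations():
    """All six analytes at the midpoint of their linear ranges (µg/mL)."""
    return {
        a: 0.5 * (c.linear_range[0] + c.linear_range[1])
        for a, c in dq.CALIBRATION.items()
    }


def process_study(seed, params=None):
    """Simulate the default 42-batch study and run baseline + detection."""
    params = params or dq.GeneratorParams()
    design = dq.default_design(seed=seed)
    chroms, truth, manifest = dq.generate_study(design, params=params)
    corrected = [dq.correct_baseline(c) for c in chroms]
    tables = [
        dq.assign_analytes(dq.detect_peaks(c), params.analyte_rts) for c in corrected
    ]
    return design, chroms, truth, manifest, corrected, tables


@pytest.fixture(scope="session")
def study42(default_params):
    """Processed default study at seed 42 (shared: it is deterministic)."""
    return process_study(42, default_params)
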
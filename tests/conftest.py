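import numpy as np
import pandas as pd
import pytest

from irsurv.preprocess import PreprocessConfig, concatenate_datasets, preprocess_patient
from irsurv.synthdata import SimulationConfig, make_axis, make_reference_spectra, simulate_cohort


@pytest.fixture(scope="session")
def full_axis():
    return make_axis(990.0, 3800.0, 6.0)


@pytest.fixture(scope="session")
def references(full_axis):
    return make_reference_spectra(full_axis)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient, 12×12-core synthetic cohort with a planted mask shift."""
    config = SimulationConfig(
        n_patients=12, core_size=12, effect_size=2.0, mask_shift=(2, 3), seed=123
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def preprocessed_small(small_cohort):
    """Fingerprint dataset + per-patient reports for the small cohort."""
    parts, reports = [], []
    for cube, mask in zip(small_cohort.cubes, small_cohort.masks):
        dataset, report = preprocess_patient(
            cube, mask, small_cohort.references, PreprocessConfig()
        )
        parts.append(dataset)
        reports.append(report)
    return concatenate_datasets(parts), reports


def survival_frame(times, events):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(len(times))],
            "time_months": np.asarray(times, float),
            "event": np.asarray(events, int),
        }
    )
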
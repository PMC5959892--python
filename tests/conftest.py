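import numpy as np
import pytest

from iknife import (
    SpectrumRecord, CohortTable, SyntheticConfig, generate_cohort, build_feature_matrix,
)
from iknife.synthetic import noiseless


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic scenario (seed 7): 3 classes x 10 patients x 2 x 3."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return build_feature_matrix(default_cohort)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(noiseless(SyntheticConfig(seed=7)))


@pytest.fixture(scope="session")
def small_config():
    """A reduced scenario for fast fits: 3 classes x 4 patients x 1 sample x 2 burns."""
    return SyntheticConfig(seed=11, patients_per_class=4, samples_per_patient=1,
                           burns_per_sample=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def toy_spectrum():
    return SpectrumRecord(
        mz=np.array([650.0, 699.52, 744.5, 900.25]),
        intensity=np.array([10.0, 100.0, 40.0, 5.0]),
        patient_id="P1", sample_id="S1", burn_id="B1", tissue_class="normal",
    )


def make_record(mz, intensity, burn="B1", patient="P1", sample="S1",
                tissue_class="normal", tumour_content=None):
    return SpectrumRecord(
        mz=np.asarray(mz, dtype=float), intensity=np.asarray(intensity, dtype=float),
        patient_id=patient, sample_id=sample, burn_id=burn,
        tissue_class=tissue_class, tumour_content=tumour_content,
    )
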
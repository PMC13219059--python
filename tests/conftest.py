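import numpy as np
import pandas as pd
import pytest

from petmpi.features import Lesion, LesionSet
from petmpi.synthetic import (
    GeneratorParams,
    cohort_feature_matrix,
    outcomes_frame,
    sample_cohort,
)


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(n_patients=83, seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return sample_cohort(default_params)


@pytest.fixture(scope="session")
def default_fm(default_cohort, default_params) -> pd.DataFrame:
    return cohort_feature_matrix(default_cohort, default_params)


@pytest.fixture(scope="session")
def default_outcomes(default_cohort) -> pd.DataFrame:
    return outcomes_frame(default_cohort)


@pytest.fixture
def two_lesion_set() -> LesionSet:
    """Worked two-lesion example: lesion A has voxels (0,0,0) SUV 4 and
    (4,0,0) SUV 6; lesion B the single voxel (0,30,0) SUV 8; voxel volume
    0.064 ml."""
    return LesionSet(
        patient_id="worked",
        lesions=[
            Lesion(lesion_id=1, coords_mm=np.array([[0.0, 0, 0], [4.0, 0, 0]]), suv=[4.0, 6.0]),
            Lesion(lesion_id=2, coords_mm=np.array([[0.0, 30.0, 0]]), suv=[8.0]),
        ],
        voxel_volume_ml=0.064,
    )
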
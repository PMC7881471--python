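import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hiernet.atlas import load_atlas
from hiernet.features import ROI_COLUMNS, SubjectMorphometry
from hiernet.synth import simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


def make_subject(
    thickness,
    thickness_sd=None,
    subject_id="S001",
    label="high",
    tiv=None,
    mean_thickness=None,
    total_area=None,
):
    """Hand-built subject with the given per-ROI thickness vector."""
    thickness = np.asarray(thickness, float)
    n = len(thickness)
    if thickness_sd is None:
        thickness_sd = np.full(n, 0.3)
    data = pd.DataFrame(
        {
            "gm_volume": np.full(n, 5000.0),
            "wm_volume": np.full(n, 4000.0),
            "csf_volume": np.full(n, 1500.0),
            "thickness_mean": thickness,
            "thickness_sd": np.asarray(thickness_sd, float),
            "surface_area": np.full(n, 2500.0),
        },
        index=pd.RangeIndex(1, n + 1, name="roi_index"),
    )[list(ROI_COLUMNS)]
    return SubjectMorphometry(
        subject_id=subject_id,
        label=label,
        data=data,
        tiv=tiv if tiv is not None else float(n * 10500.0),
        mean_thickness=mean_thickness if mean_thickness is not None else float(thickness.mean()),
        total_area=total_area if total_area is not None else float(n * 2500.0),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect 34+34 cohort (session-scoped: generation is reused)."""
    return simulate_cohort(seed=11)
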
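import numpy as np
import pandas as pd
import pytest

import flymort as fm


@pytest.fixture(scope="session")
def study_cohort():
    """One cohort at the full study design (14 isolines x 2 x 2 x 90)."""
    return fm.simulate_cohort(fm.CohortDesign(seed=12345), fm.GompertzFrailtyParams())


@pytest.fixture(scope="session")
def study_lifetable(study_cohort):
    return fm.build_lifetable(study_cohort)


@pytest.fixture(scope="session")
def study_fit(study_lifetable):
    return fm.fit_hazard_model(study_lifetable, "full")


@pytest.fixture(scope="session")
def study_boot(study_cohort, study_fit):
    return fm.bootstrap_refits(study_cohort, study_fit, n_boot=200, seed=777)


def make_records(ages, events, sex="female", treatment="control", isoline="iso01"):
    """Minimal records frame from parallel age/event lists."""
    n = len(ages)

    def _col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "fly_id": [f"f{i}" for i in range(n)],
            "isoline": _col(isoline),
            "sex": _col(sex),
            "treatment": _col(treatment),
            "observed_age": list(ages),
            "event": list(events),
        }
    )
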
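import numpy as np
import pytest

from farmstress.fuzzy_core import default_variables
from farmstress.inference import reference_profiles, reference_rulebase
from farmstress.survey_io import FactorProfile


@pytest.fixture(scope="session")
def variables():
    return default_variables()


@pytest.fixture(scope="session")
def rulebase():
    return reference_rulebase()


@pytest.fixture(scope="session")
def reference_table():
    """The packaged 11-respondent table: (profiles, printed scores, printed levels)."""
    return reference_profiles()


@pytest.fixture(scope="session")
def calibrated(rulebase, reference_table):
    """Breakpoint calibration of the reference FIS against the 11-profile
    table; computed once per session (it is a deterministic search)."""
    from farmstress.inference import calibrate_breakpoints

    profiles, _, levels = reference_table
    variables, hits = calibrate_breakpoints(rulebase, profiles, levels)
    return variables, hits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_profiles(array, ids=None, with_wrs=True):
    """Rows of (pcg, fin, scf, tech[, wrs]) -> FactorProfile list."""
    out = []
    for i, row in enumerate(np.atleast_2d(array)):
        out.append(
            FactorProfile(
                respondent_id=ids[i] if ids else f"r{i}",
                pcg=float(row[0]),
                fin=float(row[1]),
                scf=float(row[2]),
                tech=float(row[3]),
                wrs_observed=float(row[4]) if with_wrs and len(row) > 4 else None,
            )
        )
    return out


@pytest.fixture(scope="session")
def profile_factory():
    return make_profiles
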
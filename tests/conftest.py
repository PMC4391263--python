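import numpy as np
import pytest

from polgk.kinetic_model import RateConstants, TimeCourse
from polgk.global_fit import ExperimentSet, scheme1_course_model
from polgk.presets import DNTP_GRIDS_UM, rate_constants


@pytest.fixture(scope="session")
def s305r():
    return rate_constants("S305R")


@pytest.fixture(scope="session")
def wt():
    return rate_constants("WT")


@pytest.fixture(scope="session")
def p1073l():
    return rate_constants("P1073L")


def make_titration_set(rates: RateConstants, concs_uM, times,
                       e_total=100.0, d_total=75.0) -> ExperimentSet:
    """Noiseless single-turnover dNTP titration built directly from the
    forward model (bypasses the generators for oracle independence)."""
    courses, specs = [], []
    for c in concs_uM:
        spec = {"E_total": e_total, "D_total": d_total, "N": c * 1000.0}
        v = scheme1_course_model(rates.as_dict(), spec, times)
        courses.append(TimeCourse(times, v, "product26",
                                  {"series_value": c, "series_unit": "uM"}))
        specs.append(spec)
    return ExperimentSet(courses, "scheme1", specs, "dNTP")


@pytest.fixture(scope="session")
def s305r_noiseless_set(s305r):
    times = np.geomspace(0.01, 4.0, 10)
    return make_titration_set(s305r, DNTP_GRIDS_UM["S305R"], times)
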
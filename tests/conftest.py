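"""Shared fixtures: hand-written claims, survival fixtures, Table-1 rebuild."""

import numpy as np
import pandas as pd
import pytest

from emusurv.design import CONDITION_COLUMNS
from emusurv.simulate import default_code_lists


def _claim(bid, adm, dis, treat, dx, proc, age, enroll_start,
           sex="male", race="white", enroll_end="", death=""):
    return {
        "beneficiary_id": bid, "admission_date": adm, "discharge_date": dis,
        "treatment_date": treat, "diagnosis_codes": dx,
        "procedure_codes": proc, "age_at_admission": age, "sex": sex,
        "race": race, "enrollment_start": enroll_start,
        "enrollment_end": enroll_end, "death_date": death,
    }


@pytest.fixture
def codes():
    return default_code_lists()


@pytest.fixture
def ten_claims():
    """10 hand-written claims: 2 under-65, 1 conversion, 1 short-enrollment,
    2 claims of one beneficiary -> 5 eligible subjects."""
    rows = [
        _claim("A", "2012-03-01", "2012-03-08", "2012-03-02", "DX_RAAA",
               "PROC_EVAR", 72, "2010-01-01", death="2012-06-01"),
        _claim("B", "2011-05-10", "2011-05-20", "2011-05-11", "DX_RAAA",
               "PROC_OAR", 80, "2009-01-01"),
        _claim("C", "2013-02-01", "2013-02-06", "2013-02-01", "DX_RAAA",
               "PROC_EVAR", 60, "2011-01-01"),                       # under 65
        _claim("D", "2013-07-01", "2013-07-09", "2013-07-02", "DX_RAAA",
               "PROC_OAR", 64.5, "2011-01-01"),                      # under 65
        _claim("E", "2014-01-15", "2014-01-25", "2014-01-15",
               "DX_RAAA", "PROC_EVAR;PROC_OAR", 70, "2012-01-01"),   # conversion
        _claim("F", "2012-05-01", "2012-05-07", "2012-05-01", "DX_RAAA",
               "PROC_OAR", 75, "2012-01-01"),                 # short enrollment
        _claim("G", "2014-09-01", "2014-09-10", "2014-09-02", "DX_RAAA",
               "PROC_OAR", 68, "2010-06-01"),
        _claim("H", "2013-01-10", "2013-01-18", "2013-01-10", "DX_RAAA",
               "PROC_EVAR", 77, "2011-06-01"),
        _claim("H", "2013-06-01", "2013-06-09", "2013-06-01", "DX_RAAA",
               "PROC_EVAR", 77, "2011-06-01"),                # later claim of H
        _claim("I", "2015-03-01", "2015-03-11", "2015-03-02", "DX_RAAA",
               "PROC_OAR", 83, "2013-01-01"),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def fifty_row_survival():
    """Deterministic 50-row (Y, d, X, Z, w) survival fixture with ties-free
    times and non-unit weights."""
    rng = np.random.default_rng(5)
    n = 50
    x = rng.normal(size=(n, 3))
    z = rng.binomial(1, 0.5, n).astype(float)
    T = rng.exponential(1.0 / np.exp(0.4 * x[:, 0] - 0.5 * z))
    C = rng.exponential(2.0, n)
    Y = np.minimum(T, C)
    d = (T <= C).astype(float)
    w = rng.uniform(0.5, 3.0, n)
    return Y, d, x, z, w


@pytest.fixture(scope="session")
def table1_cohort():
    """Cohort table rebuilt from the reference cohort's published counts."""
    from emusurv.reference import reference_cohort
    return reference_cohort()
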
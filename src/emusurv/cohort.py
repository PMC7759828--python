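"""Cohort assembly: eligibility filters, outcome derivation, Table-1 reporting.

Turns claims-level records into the emulated-trial analysis cohort.  The
eligibility cascade mirrors the trial protocol: identify index hospitalizations
carrying a rupture diagnosis and exactly one of the two repair procedure code
sets within the enrollment window, then exclude, in order: age under 65 at the
index admission; conversion (both procedure code sets in the same index
hospitalization); concurrent excluded diagnoses; concurrent excluded
procedures; under 12 months of enrollment before the index admission; and for
beneficiaries with several eligible claims keep only the first.  Every step is
logged with excluded/remaining counts (conservation holds at each step).

Outcomes use the treatment date as time origin.  Short-term (perioperative)
mortality is death during the index hospitalization or within 30 days of
discharge, with survivors censored at discharge + 30 days.  Long-term
mortality censors at loss to follow-up (disenrollment) or the study end,
whichever comes first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITION_COLUMNS

__all__ = ["ExclusionLog", "apply_eligibility", "impute_treatment_date",
           "derive_outcomes", "drop_incomplete", "descriptive_table"]

PRIOR_ENROLLMENT_DAYS = 365  # calendar-day reading of "12 months"
PERIOP_WINDOW_DAYS = 30


@dataclass
class ExclusionLog:
    """Ordered per-criterion record of the eligibility cascade."""

    steps: list = field(default_factory=list)  # (label, excluded, remaining)

    def add(self, label: str, excluded: int, remaining: int) -> None:
        if self.steps and excluded + remaining != self.steps[-1][2]:
            raise ValueError("exclusion log violates count conservation")
        self.steps.append((label, int(excluded), int(remaining)))

    @property
    def final_count(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["criterion", "excluded", "remaining"])

    def to_json(self) -> str:
        return json.dumps([{"criterion": c, "excluded": e, "remaining": r}
                           for c, e, r in self.steps], indent=1)


def _codes(series: pd.Series) -> pd.Series:
    return series.fillna("").map(lambda s: set(filter(None, str(s).split(";"))))


def _parse_date(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series.replace("", pd.NA), format="%Y-%m-%d",
                          errors="coerce")


def apply_eligibility(claims: pd.DataFrame, codes: dict,
                      window=("2011-01-01", "2015-09-30")):
    """Apply the eligibility cascade; returns (eligible claims, ExclusionLog).

    ``codes`` needs keys ``rupture_dx``, ``evar_proc``, ``oar_proc``,
    ``excluded_dx``, ``excluded_proc`` (lists of code strings).
    """
    for key in ("rupture_dx", "evar_proc", "oar_proc", "excluded_dx",
                "excluded_proc"):
        if not codes.get(key):
            raise ValueError(f"code list {key!r} is missing or empty")
    log = ExclusionLog()
    claims = claims.reset_index(drop=True)
    n0 = len(claims)
    log.add("input claims", 0, n0)
    if n0 == 0:
        for label in ("unparseable dates", "no rupture diagnosis + repair "
                      "procedure in window", "age under 65 at diagnosis",
                      "conversion (both procedure sets)",
                      "concurrent excluded diagnosis",
                      "concurrent excluded procedure",
                      "under 12 months prior enrollment",
                      "later claim of same beneficiary"):
            log.add(label, 0, 0)
        return claims.copy(), log

    df = claims.copy()
    adm = _parse_date(df["admission_date"])
    parseable = adm.notna()
    log.add("unparseable dates", int((~parseable).sum()), int(parseable.sum()))
    df, adm = df[parseable], adm[parseable]

    dx = _codes(df["diagnosis_codes"])
    proc = _codes(df["procedure_codes"])
    rupture = set(codes["rupture_dx"])
    evar, oar = set(codes["evar_proc"]), set(codes["oar_proc"])
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    identified = (dx.map(lambda s: bool(s & rupture)).astype(bool)
                  & proc.map(lambda s: bool(s & evar) or bool(s & oar)).astype(bool)
                  & adm.between(lo, hi))
    log.add("no rupture diagnosis + repair procedure in window",
            int((~identified).sum()), int(identified.sum()))
    df, adm, dx, proc = df[identified], adm[identified], dx[identified], \
        proc[identified]

    keep = pd.to_numeric(df["age_at_admission"], errors="coerce") >= 65
    log.add("age under 65 at diagnosis", int((~keep).sum()), int(keep.sum()))
    df, adm, dx, proc = df[keep], adm[keep], dx[keep], proc[keep]

    conversion = proc.map(lambda s: bool(s & evar) and bool(s & oar)).astype(bool)
    log.add("conversion (both procedure sets)", int(conversion.sum()),
            int((~conversion).sum()))
    df, adm, dx, proc = df[~conversion], adm[~conversion], dx[~conversion], \
        proc[~conversion]

    bad_dx = dx.map(lambda s: bool(s & set(codes["excluded_dx"]))).astype(bool)
    log.add("concurrent excluded diagnosis", int(bad_dx.sum()),
            int((~bad_dx).sum()))
    df, adm, dx, proc = df[~bad_dx], adm[~bad_dx], dx[~bad_dx], proc[~bad_dx]

    bad_proc = proc.map(lambda s: bool(s & set(codes["excluded_proc"]))).astype(bool)
    log.add("concurrent excluded procedure", int(bad_proc.sum()),
            int((~bad_proc).sum()))
    df, adm = df[~bad_proc], adm[~bad_proc]

    estart = _parse_date(df["enrollment_start"])
    enrolled = estart.notna() & \
        (estart <= adm - pd.Timedelta(days=PRIOR_ENROLLMENT_DAYS))
    log.add("under 12 months prior enrollment", int((~enrolled).sum()),
            int(enrolled.sum()))
    df, adm = df[enrolled], adm[enrolled]

    # first eligible claim per beneficiary: admission date, then file order
    df = df.assign(_adm=adm)
    first = df.sort_values(["beneficiary_id", "_adm"],
                           kind="stable").groupby("beneficiary_id").head(1)
    dup = len(df) - len(first)
    log.add("later claim of same beneficiary", dup, len(first))
    out = first.sort_index().drop(columns=["_adm"]).reset_index(drop=True)
    return out, log


def impute_treatment_date(claims: pd.DataFrame):
    """Fill missing treatment dates with the admission date.

    Rationale: the condition is emergent, so treatment follows admission
    almost immediately.  Returns (claims, imputed fraction).
    """
    df = claims.copy()
    t = df["treatment_date"].astype("string").replace("", pd.NA)
    missing = t.isna()
    df["treatment_date"] = t.where(~missing, df["admission_date"])
    frac = float(missing.mean()) if len(df) else 0.0
    return df, frac


def derive_outcomes(claims: pd.DataFrame, codes: dict,
                    study_end: str = "2019-06-30") -> pd.DataFrame:
    """Build the analysis cohort table from eligible claims.

    Time origin is the treatment date.  Raises on death before treatment,
    naming the offending beneficiaries.
    """
    df = claims.reset_index(drop=True)
    treat = _parse_date(df["treatment_date"])
    if treat.isna().any():
        raise ValueError("treatment_date missing; run impute_treatment_date")
    discharge = _parse_date(df["discharge_date"])
    death = _parse_date(df["death_date"])
    eend = _parse_date(df["enrollment_end"])
    send = pd.Timestamp(study_end)

    bad = death.notna() & (death < treat)
    if bad.any():
        ids = df.loc[bad, "beneficiary_id"].tolist()[:10]
        raise ValueError(f"death before treatment for {int(bad.sum())} "
                         f"record(s), e.g. {ids}")

    proc = _codes(df["procedure_codes"])
    evar = set(codes["evar_proc"])
    Z = proc.map(lambda s: int(bool(s & evar)))

    long_censor = eend.fillna(send).clip(upper=send)
    d_long = (death.notna() & (death <= send)).astype(int)
    y_long = np.where(d_long == 1, (death - treat).dt.days,
                      (long_censor - treat).dt.days).astype(float)

    # short-term censoring cannot outlast the long-term follow-up: a subject
    # lost (or administratively censored) before discharge + 30 days stops
    # contributing then, keeping y_short <= y_long
    periop_end = discharge + pd.Timedelta(days=PERIOP_WINDOW_DAYS)
    d_short = (death.notna() & (death <= periop_end)
               & (death <= send)).astype(int)
    short_censor = periop_end.where(periop_end <= long_censor, long_censor)
    y_short = np.where(d_short == 1, (death - treat).dt.days,
                       (short_censor - treat).dt.days).astype(float)

    out = pd.DataFrame({
        "subject_id": df["beneficiary_id"],
        "treatment": Z.to_numpy(),
        "age": pd.to_numeric(df["age_at_admission"], errors="coerce"),
        "sex": df["sex"].astype("string").replace("", pd.NA),
        "race": df["race"].astype("string").replace("", pd.NA),
        "repair_year": treat.dt.year,
        "y_short": y_short, "d_short": d_short,
        "y_long": y_long, "d_long": d_long,
    })
    dxsets = _codes(df["diagnosis_codes"])
    cond_codes = codes.get("conditions", {})
    for c in CONDITION_COLUMNS:
        cset = set(cond_codes.get(c, [f"DX_{c.upper()}"]))
        out[c] = dxsets.map(lambda s: int(bool(s & cset)))
    return out


def drop_incomplete(cohort: pd.DataFrame):
    """Remove rows with any missing covariate; returns (cohort, n_removed)."""
    covars = ["age", "sex", "race", "repair_year", *CONDITION_COLUMNS]
    present = [c for c in covars if c in cohort.columns]
    mask = cohort[present].notna().all(axis=1)
    removed = int((~mask).sum())
    if removed == len(cohort) and len(cohort) > 0:
        import warnings
        warnings.warn("all rows removed: every record has missing covariates")
    return cohort[mask].reset_index(drop=True), removed


# ------------------------------------------------------------- descriptives

def _chi2_p(table: np.ndarray):
    """Pearson chi-squared on the full contingency table, no continuity
    correction; returns (stat, p) or (nan, nan) when expected counts vanish."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, np.nan
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: per-arm counts/percentages or mean (sd), with
    t-test (continuous) and chi-squared (categorical) p-values, plus
    unadjusted incidence of both outcomes.

    Percentage denominators for categorical covariates exclude missing values
    of that covariate; binary condition and outcome rows use the arm size.
    """
    arms = {1: cohort[cohort["treatment"] == 1],
            0: cohort[cohort["treatment"] == 0]}
    if min(len(a) for a in arms.values()) < 2:
        raise ValueError("need at least 2 subjects per arm")
    n1, n0 = len(arms[1]), len(arms[0])
    rows = []

    def _cat_rows(col, label=None):
        label = label or col
        sub1, sub0 = arms[1][col].dropna(), arms[0][col].dropna()
        levels = sorted(set(sub1.unique()) | set(sub0.unique()), key=str)
        tab = np.array([[int((sub1 == lv).sum()) for lv in levels],
                        [int((sub0 == lv).sum()) for lv in levels]]).T
        stat, p = _chi2_p(tab)
        for k, lv in enumerate(levels):
            c1, c0 = tab[k]
            rows.append({
                "variable": f"{label}={lv}", "kind": "categorical",
                "arm1_count": c1,
                "arm1_pct": 100.0 * c1 / len(sub1) if len(sub1) else np.nan,
                "arm0_count": c0,
                "arm0_pct": 100.0 * c0 / len(sub0) if len(sub0) else np.nan,
                "p_value": p if k == 0 else np.nan,
            })

    def _binary_row(col, label=None):
        label = label or col
        c1 = int(arms[1][col].sum())
        c0 = int(arms[0][col].sum())
        tab = [[c1, n1 - c1], [c0, n0 - c0]]
        stat, p = _chi2_p(np.array(tab))
        rows.append({"variable": label, "kind": "binary",
                     "arm1_count": c1, "arm1_pct": 100.0 * c1 / n1,
                     "arm0_count": c0, "arm0_pct": 100.0 * c0 / n0,
                     "p_value": p})

    # age: mean (sd), two-sample t-test
    a1 = arms[1]["age"].dropna().to_numpy(float)
    a0 = arms[0]["age"].dropna().to_numpy(float)
    if a1.std(ddof=1) == 0 and a0.std(ddof=1) == 0:
        p_age = np.nan
    else:
        p_age = float(stats.ttest_ind(a1, a0, equal_var=True).pvalue)
    rows.append({"variable": "age", "kind": "continuous",
                 "arm1_mean": a1.mean(), "arm1_sd": a1.std(ddof=1),
                 "arm0_mean": a0.mean(), "arm0_sd": a0.std(ddof=1),
                 "p_value": p_age})

    male1 = int((arms[1]["sex"] == "male").sum())
    male0 = int((arms[0]["sex"] == "male").sum())
    nm1 = int(arms[1]["sex"].notna().sum())
    nm0 = int(arms[0]["sex"].notna().sum())
    _, p_sex = _chi2_p(np.array([[male1, nm1 - male1], [male0, nm0 - male0]]))
    rows.append({"variable": "male", "kind": "binary",
                 "arm1_count": male1, "arm1_pct": 100.0 * male1 / nm1,
                 "arm0_count": male0, "arm0_pct": 100.0 * male0 / nm0,
                 "p_value": p_sex})

    _cat_rows("race")
    for c in CONDITION_COLUMNS:
        if c in cohort.columns:
            _binary_row(c)
    if "repair_year" in cohort.columns:
        _cat_rows("repair_year", "year")

    for col, label in (("d_long", "all-cause mortality"),
                       ("d_short", "perioperative mortality")):
        if col in cohort.columns:
            _binary_row(col, label)

    return pd.DataFrame(rows)
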
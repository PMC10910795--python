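"""Cohort construction: encounter merging, lab attachment, record selection.

Rules applied, in order:

* hospital encounters of one patient less than 24 h apart (next start minus
  previous end, strict) are pieced together into admissions;
* each admission collects the laboratory records drawn within 24 h *after*
  its start (closed window, one-sided);
* repeated measurements of one test within the window are reduced to the
  most abnormal record, where abnormality is the out-of-interval deviation
  normalized by the interval width;
* cohort filters: age >= 20 at draw, ICD codes truncated to level 3, tests
  kept only if measured in >= 20% of admissions, outcomes kept only with
  enough unique patients, and a separate fitting mask excluding records of
  patients who died within 28 days of the draw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRATUM_FIELDS = ["test_name", "specimen", "unit", "lab_id", "sex", "age_group"]


class EmptyCohortError(ValueError):
    """A filter removed every row; surfaced instead of silently succeeding."""


def age_group_of(age) -> np.ndarray:
    lo = (np.asarray(age, dtype=int) // 10) * 10
    return np.array([f"[{a},{a + 10})" for a in np.atleast_1d(lo)]).reshape(np.shape(lo))


def truncate_code(code: str) -> str:
    """Collapse an ICD-10-like code to level 3 (e.g. 'I21.2' -> 'I21')."""
    return code.split(".")[0][:3]


def _split_codes(s) -> set[str]:
    if not isinstance(s, str) or not s:
        return set()
    return {c for c in s.split(";") if c}


def merge_encounters(encounters: pd.DataFrame, gap_hours: float = 24.0) -> pd.DataFrame:
    """Chain each patient's encounters into admissions.

    Encounters whose gap (next.start - previous running end) is strictly less
    than ``gap_hours`` belong to one admission; overlapping encounters are
    merged the same way.  Admission start/end are the min/max over members,
    codes the union.  Idempotent: merging the output again is a no-op.

    Returns a DataFrame with admission_id, patient_id, start, end, codes,
    death_date, age_at_start, n_encounters.
    """
    if len(encounters) == 0:
        return pd.DataFrame(columns=["admission_id", "patient_id", "start", "end",
                                     "codes", "death_date", "sex", "age_at_start", "n_encounters"])
    bad = encounters["start"] > encounters["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} encounters have start > end")
    enc = encounters.sort_values(["patient_id", "start", "end"], kind="mergesort").reset_index(drop=True)
    gap = pd.Timedelta(hours=gap_hours)

    new_patient = enc["patient_id"].ne(enc["patient_id"].shift())
    # running max of end within patient, shifted: the admission's frontier
    run_end = enc.groupby("patient_id", sort=False)["end"].cummax().shift()
    new_adm = new_patient | ((enc["start"] - run_end) >= gap)
    adm_id = new_adm.cumsum()

    grouped = enc.groupby(adm_id, sort=True)
    out = grouped.agg(
        patient_id=("patient_id", "first"),
        start=("start", "min"),
        end=("end", "max"),
        death_date=("death_date", "first"),
        sex=("sex", "first"),
        age_at_start=("age_at_start", "first"),
        n_encounters=("patient_id", "size"),
    ).reset_index(drop=True)
    out["codes"] = grouped["codes"].apply(
        lambda s: ";".join(sorted(set().union(*(_split_codes(x) for x in s))))).to_numpy()
    out.insert(0, "admission_id", [f"A{i:07d}" for i in range(len(out))])
    return out[["admission_id", "patient_id", "start", "end", "codes",
                "death_date", "sex", "age_at_start", "n_encounters"]]


def attach_labs(admissions: pd.DataFrame, records: pd.DataFrame,
                window_hours: float = 24.0) -> pd.DataFrame:
    """Assign each lab record to at most one admission.

    A record attaches iff same patient and ``admission.start <= timestamp <=
    admission.start + window`` (both ends closed); if two windows qualify the
    earliest admission wins.  Returns the records with an ``admission_id``
    column; unattached records are dropped (count logged).
    """
    if len(records) == 0:
        out = records.copy()
        out["admission_id"] = pd.Series(dtype=object)
        return out
    window = pd.Timedelta(hours=window_hours)
    rec = records.reset_index(drop=True)
    assigned = np.full(len(rec), None, dtype=object)

    adm_by_pat = {p: g.sort_values("start") for p, g in admissions.groupby("patient_id")}
    for pid, g in rec.groupby("patient_id", sort=False):
        adm = adm_by_pat.get(pid)
        if adm is None:
            continue
        starts = adm["start"].to_numpy()
        ids = adm["admission_id"].to_numpy()
        ts = g["timestamp"].to_numpy()
        pos = np.searchsorted(starts, ts, side="right") - 1
        for row_i, (t, k) in zip(g.index, zip(ts, pos)):
            # earliest qualifying admission: check the previous window first
            if k >= 1 and t <= starts[k - 1] + window:
                assigned[row_i] = ids[k - 1]
            elif k >= 0 and t <= starts[k] + window:
                assigned[row_i] = ids[k]
    out = rec.copy()
    out["admission_id"] = assigned
    n_dropped = int(pd.isna(out["admission_id"]).sum())
    if n_dropped:
        logger.info("attach_labs: dropped %d records outside any admission window", n_dropped)
    return out[out["admission_id"].notna()].reset_index(drop=True)


def select_most_abnormal(group: pd.DataFrame, bounds_fn) -> pd.Series:
    """Reduce one admission's repeated records of one test to a single record.

    ``bounds_fn(group) -> (lower, upper)`` arrays gives the applicable RI per
    record (standard or seasonally adjusted, depending on encoding version).
    If any record is out of interval, the record with the largest deviation
    ``|value - nearest bound| / (upper - lower)`` wins (a deep -1 beats a
    shallow +1); otherwise the last record by timestamp is returned.
    """
    lower, upper = bounds_fn(group)
    lower, upper = np.asarray(lower, float), np.asarray(upper, float)
    v = group["value"].to_numpy(float)
    flag = np.where(v > upper, 1, np.where(v < lower, -1, 0))
    if (flag != 0).any():
        width = upper - lower
        nearest = np.where(flag > 0, upper, lower)
        dev = np.where(flag != 0, np.abs(v - nearest) / width, -np.inf)
        # stable tie-break: earliest timestamp among equal deviations
        order = np.lexsort((group["timestamp"].to_numpy(), -dev))
        return group.iloc[order[0]]
    order = np.argsort(group["timestamp"].to_numpy(), kind="stable")
    return group.iloc[order[-1]]


@dataclass
class FilterReport:
    """Row counts removed by each cohort rule, in application order."""

    n_records_in: int = 0
    n_admissions_in: int = 0
    removed_records_age: int = 0
    removed_admissions_age: int = 0
    removed_records_coverage: int = 0
    tests_dropped: list = field(default_factory=list)
    tests_kept: list = field(default_factory=list)
    outcomes_dropped: list = field(default_factory=list)
    outcomes_kept: list = field(default_factory=list)
    records_excluded_from_fitting: int = 0
    n_records_out: int = 0
    n_admissions_out: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def apply_cohort_filters(
    records: pd.DataFrame,
    admissions: pd.DataFrame,
    outcome_codes: list[str],
    min_age: int = 20,
    coverage_frac: float = 0.20,
    min_patients: int = 1000,
    survival_days: int = 28,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], np.ndarray, FilterReport]:
    """Apply the cohort rules; returns filtered tables plus a FilterReport.

    ``records`` must already carry ``admission_id`` (see :func:`attach_labs`).
    Returns ``(records, admissions, kept_outcomes, fitting_mask, report)``
    where ``fitting_mask`` marks the records usable for seasonality fitting
    (drawn from patients surviving more than ``survival_days`` after the
    draw).  Rule order: age, code truncation, test coverage, outcome
    prevalence, survivor mask.
    """
    report = FilterReport(n_records_in=len(records), n_admissions_in=len(admissions))

    # (1) age >= min_age
    rec = records[records["age_at_draw"] >= min_age].copy()
    adm = admissions[admissions["age_at_start"] >= min_age].copy()
    report.removed_records_age = report.n_records_in - len(rec)
    report.removed_admissions_age = report.n_admissions_in - len(adm)
    rec = rec[rec["admission_id"].isin(adm["admission_id"])]
    if len(rec) == 0 or len(adm) == 0:
        raise EmptyCohortError("age filter removed every record/admission")

    # (2) truncate ICD codes to level 3
    adm["codes"] = adm["codes"].map(
        lambda s: ";".join(sorted({truncate_code(c) for c in _split_codes(s)})))
    outcome_codes = [truncate_code(c) for c in outcome_codes]

    # (3) test coverage: measured in >= coverage_frac of admissions
    n_adm = adm["admission_id"].nunique()
    cov = (rec.groupby("test_name")["admission_id"].nunique() / n_adm)
    kept_tests = sorted(cov[cov >= coverage_frac].index)
    report.tests_dropped = sorted(cov[cov < coverage_frac].index)
    report.tests_kept = kept_tests
    before = len(rec)
    rec = rec[rec["test_name"].isin(kept_tests)]
    report.removed_records_coverage = before - len(rec)
    if len(rec) == 0:
        raise EmptyCohortError("coverage filter removed every record")

    # (4) outcomes with >= min_patients unique patients
    code_sets = adm["codes"].map(_split_codes)
    kept_outcomes = []
    for code in outcome_codes:
        has = code_sets.map(lambda s, c=code: c in s)
        n_pat = adm.loc[has, "patient_id"].nunique()
        (kept_outcomes if n_pat >= min_patients else report.outcomes_dropped).append(code)
    report.outcomes_kept = kept_outcomes

    # (5) fitting mask: survived more than survival_days after the draw
    death = admissions.drop_duplicates("patient_id").set_index("patient_id")["death_date"]
    rec_death = rec["patient_id"].map(death)
    died_soon = rec_death.notna() & (
        (rec_death - rec["timestamp"]) <= pd.Timedelta(days=survival_days))
    fitting_mask = (~died_soon).to_numpy()
    report.records_excluded_from_fitting = int(died_soon.sum())

    report.n_records_out = len(rec)
    report.n_admissions_out = len(adm)
    return rec.reset_index(drop=True), adm.reset_index(drop=True), kept_outcomes, fitting_mask, report
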
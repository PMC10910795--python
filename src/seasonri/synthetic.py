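"""Synthetic EHR generator with per-stratum seasonal laboratory sinusoids.

Emulates the structure the downstream analysis assumes: long-format lab
records (patient, test + specimen, unit, lab ID, value, timestamp, sex, age),
hospital encounters with <24 h transfer splits, repeated measurements,
missingness, 28-day mortality, and admission-level diagnosis outcomes whose
probability depends on abnormality relative to the *seasonally true*
reference interval.  Lab values follow

    value = baseline_mean + baseline_sd * (s(week) + N(0, 1)),
    s(week) = beta0 + beta1 * cos(2*pi*(week - theta)/52)

so the normalized weekly means of a stratum converge to the generating
cosine, which is exactly the model the fitting stage estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seasonal import cosinor_value

HOURS = pd.Timedelta(hours=1)
STUDY_START = pd.Timestamp("2012-01-02")  # a Monday

LAB_COLUMNS = [
    "patient_id", "test_name", "specimen", "unit", "lab_id",
    "value", "timestamp", "sex", "age_at_draw",
]
ENCOUNTER_COLUMNS = ["patient_id", "start", "end", "codes", "death_date", "sex", "age_at_start"]


class CohortParseError(ValueError):
    """Malformed row in a cohort CSV; carries the 1-based file line number."""

    def __init__(self, path, line, message):
        self.path, self.line = str(path), line
        super().__init__(f"{path}:{line}: {message}")


def _require(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise ValueError(f"invalid SimConfig field '{fieldname}': {msg}")


@dataclass(frozen=True)
class TestSpec:
    """Ground truth for one synthetic laboratory test (one specimen + unit)."""

    test_name: str
    specimen: str = "plasma"
    unit: str = "mg/L"
    standard_ri: tuple[float, float] = (83.55, 116.45)
    baseline_mean: float = 100.0
    baseline_sd: float = 10.0
    true_beta0: float = 0.0
    true_beta1: float = 0.0
    true_theta: float = 0.0

    def __post_init__(self):
        lo, up = self.standard_ri
        _require(lo < up, "standard_ri", f"lower < upper required, got {self.standard_ri}")
        _require(self.baseline_sd > 0, "baseline_sd", "must be > 0")
        _require(-1.0 <= self.true_beta0 <= 1.0, "true_beta0", "must lie in [-1, 1]")
        _require(-1.0 <= self.true_beta1 <= 1.0, "true_beta1", "must lie in [-1, 1]")
        _require(0.0 <= self.true_theta < 52.0, "true_theta", "must lie in [0, 52)")

    def seasonal_shift(self, week):
        """De-normalized seasonal deviation (measurement units) at ``week``."""
        return self.baseline_sd * cosinor_value(self.true_beta0, self.true_beta1, self.true_theta, week)


@dataclass(frozen=True)
class OutcomeSpec:
    """Logistic admission-outcome model over per-test abnormality flags."""

    code: str
    intercept: float = -2.0
    weights: dict[str, float] = field(default_factory=dict)
    sex_weight: float = 0.0
    uses_seasonal_truth: bool = True


@dataclass
class SimConfig:
    n_patients: int = 2000
    years: int = 4
    tests: list[TestSpec] = field(default_factory=list)
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    sex_ratio: float = 0.54
    age_range: tuple[int, int] = (20, 89)
    encounter_rate: float = 0.6
    transfer_prob: float = 0.10
    missing_prob: float = 0.30
    repeat_prob: float = 0.10
    death_prob: float = 0.02
    filler_code_prob: float = 0.30
    subcode_prob: float = 0.50
    seed: int = 0

    def __post_init__(self):
        _require(self.n_patients >= 1, "n_patients", "must be >= 1")
        _require(self.years >= 1, "years", "must be >= 1")
        for name in ("sex_ratio", "transfer_prob", "missing_prob", "repeat_prob",
                     "death_prob", "filler_code_prob", "subcode_prob"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "probability must lie in [0, 1]")
        lo, hi = self.age_range
        _require(20 <= lo <= hi <= 100, "age_range", "must satisfy 20 <= lo <= hi <= 100")
        _require(self.encounter_rate > 0, "encounter_rate", "must be > 0")
        test_names = {t.test_name for t in self.tests}
        _require(len(test_names) == len(self.tests), "tests", "test names must be unique")
        for o in self.outcomes:
            unknown = set(o.weights) - test_names
            _require(not unknown, "outcomes", f"outcome {o.code} weights reference unknown tests {sorted(unknown)}")

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)


@dataclass
class TruthBundle:
    """Everything the generator knows: parameters, RI table, per-record flags."""

    config: SimConfig
    ri_table: pd.DataFrame          # test_name, specimen, unit, lab_id, sex, age_group, lower, upper
    record_truth: pd.DataFrame      # aligned with lab records: true_shift, true_flag, std_flag
    admission_truth: pd.DataFrame   # per generated admission: patient_id, start, outcome probs/labels

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {"seed": self.config.seed, "config": cfg}


def age_group_label(age) -> np.ndarray:
    """10-year band label for an age, e.g. 34 -> '[30,40)'."""
    lo = (np.asarray(age, dtype=int) // 10) * 10
    return np.char.add(np.char.add("[", lo.astype(str)), np.char.add(",", np.char.add((lo + 10).astype(str), ")")))


def build_ri_table(tests: list[TestSpec], ages=range(20, 100, 10), lab_id: str = "LAB1") -> pd.DataFrame:
    """Standard-RI table per test x sex x 10-year age group."""
    rows = []
    for t in tests:
        for sex in ("F", "M"):
            for lo_age in ages:
                rows.append({
                    "test_name": t.test_name, "specimen": t.specimen, "unit": t.unit,
                    "lab_id": lab_id, "sex": sex, "age_group": f"[{lo_age},{lo_age + 10})",
                    "lower": t.standard_ri[0], "upper": t.standard_ri[1],
                })
    return pd.DataFrame(rows)


def iso_week(timestamps: pd.Series) -> np.ndarray:
    """ISO week-of-year with week 53 folded into 52."""
    wk = timestamps.dt.isocalendar().week.to_numpy().astype(int)
    return np.minimum(wk, 52)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Generate (lab_records, encounters, truth) under ``config``.

    Bit-reproducible under a fixed seed: a single PCG64 stream drives every
    draw in a fixed order, and output tables are deterministically sorted.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    lab_id = "LAB1"

    # --- patients ------------------------------------------------------
    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    lo_age, hi_age = config.age_range
    age0 = rng.integers(lo_age, hi_age + 1, size=n)

    # --- admissions ----------------------------------------------------
    n_adm = rng.poisson(config.encounter_rate * config.years, size=n)
    pat_idx = np.repeat(np.arange(n), n_adm)
    m = pat_idx.size
    period_seconds = config.years * 52 * 7 * 86400
    start_offset = rng.integers(0, period_seconds, size=m)
    duration_h = 4.0 + rng.exponential(48.0, size=m)
    dur_s = (duration_h * 3600).astype(int)
    # Space one patient's admissions >= 48 h end-to-start so that distinct
    # generated admissions (and their transfer encounters, which may trail the
    # admission end by up to 23 h) never merge under the <24 h transfer rule.
    min_gap = 48 * 3600
    pos = 0
    for cnt in n_adm:
        if cnt > 1:
            sl = slice(pos, pos + cnt)
            o = np.sort(start_offset[sl])
            d = dur_s[sl]
            for j in range(1, cnt):
                floor_start = o[j - 1] + d[j - 1] + min_gap
                if o[j] < floor_start:
                    o[j] = floor_start
            start_offset[sl] = o
        pos += cnt
    start = STUDY_START + pd.to_timedelta(start_offset, unit="s")
    end = start + pd.to_timedelta(dur_s, unit="s")
    elapsed_years = start_offset / (365.25 * 86400)
    age_at_start = (age0[pat_idx] + elapsed_years).astype(int)

    adm = pd.DataFrame({
        "adm_idx": np.arange(m),
        "patient_id": patient_id[pat_idx],
        "pat_idx": pat_idx,
        "start": start,
        "end": end,
        "sex": sex[pat_idx],
        "age_at_start": age_at_start,
    })

    # --- lab records ---------------------------------------------------
    test_frames = []
    for t in config.tests:
        measured = rng.random(m) < (1.0 - config.missing_prob)
        repeated = measured & (rng.random(m) < config.repeat_prob)
        for pass_no in (0, 1):
            take = measured if pass_no == 0 else repeated
            k = int(take.sum())
            if k == 0:
                continue
            offs = rng.integers(0, 24 * 3600, size=k)
            ts = adm.loc[take, "start"].to_numpy() + offs.astype("timedelta64[s]")
            df = pd.DataFrame({
                "adm_idx": adm.loc[take, "adm_idx"].to_numpy(),
                "patient_id": adm.loc[take, "patient_id"].to_numpy(),
                "test_name": t.test_name, "specimen": t.specimen,
                "unit": t.unit, "lab_id": lab_id,
                "timestamp": ts,
                "sex": adm.loc[take, "sex"].to_numpy(),
                "age_at_draw": adm.loc[take, "age_at_start"].to_numpy(),
            })
            week = iso_week(df["timestamp"])
            shift = t.seasonal_shift(week)
            noise = rng.standard_normal(k)
            df["value"] = t.baseline_mean + shift + t.baseline_sd * noise
            df["week"] = week
            df["true_shift"] = shift
            lo, up = t.standard_ri
            df["true_flag"] = np.where(df["value"] > up + shift, 1, np.where(df["value"] < lo + shift, -1, 0))
            df["std_flag"] = np.where(df["value"] > up, 1, np.where(df["value"] < lo, -1, 0))
            width = up - lo
            near = np.where(df["value"] > (lo + up) / 2 + shift, up + shift, lo + shift)
            df["true_dev"] = np.abs(df["value"] - near) / width
            test_frames.append(df)

    if test_frames:
        labs = pd.concat(test_frames, ignore_index=True)
    else:
        labs = pd.DataFrame(columns=LAB_COLUMNS + ["adm_idx", "week", "true_shift",
                                                   "true_flag", "std_flag", "true_dev"])
    labs["timestamp"] = pd.to_datetime(labs["timestamp"]).dt.floor("s")

    # --- admission-level abnormality (most deviant record per test) -----
    def agg_flags(flag_col: str) -> pd.DataFrame:
        nz = labs[labs[flag_col] != 0]
        if nz.empty:
            return pd.DataFrame(columns=["adm_idx", "test_name", flag_col])
        best = (nz.sort_values(["adm_idx", "test_name", "true_dev"])
                  .drop_duplicates(["adm_idx", "test_name"], keep="last"))
        return best[["adm_idx", "test_name", flag_col]]

    true_flags = agg_flags("true_flag")
    std_flags = agg_flags("std_flag")

    # --- outcomes ------------------------------------------------------
    code_lists: list[list[str]] = [[] for _ in range(m)]
    outcome_rows = {}
    for o in config.outcomes:
        logit = np.full(m, o.intercept)
        logit += o.sex_weight * (adm["sex"].to_numpy() == "M")
        src = true_flags if o.uses_seasonal_truth else std_flags
        for test_name, w in o.weights.items():
            sub = src[src["test_name"] == test_name]
            fl = np.zeros(m)
            fl[sub["adm_idx"].to_numpy()] = sub.iloc[:, 2].to_numpy()
            logit += w * fl
        p = _sigmoid(logit)
        label = rng.random(m) < p
        suffix = rng.random(m) < config.subcode_prob
        digit = rng.integers(0, 10, size=m)
        for i in np.nonzero(label)[0]:
            code_lists[i].append(f"{o.code}.{digit[i]}" if suffix[i] else o.code)
        outcome_rows[f"p_{o.code}"] = p
        outcome_rows[f"y_{o.code}"] = label.astype(int)
    filler = rng.random(m) < config.filler_code_prob
    fdigit = rng.integers(0, 10, size=m)
    for i in np.nonzero(filler)[0]:
        code_lists[i].append(f"Z00.{fdigit[i]}")

    # --- deaths (within 28 days of a random admission) -------------------
    death_date = pd.Series(pd.NaT, index=range(n))
    has_adm = np.nonzero(n_adm > 0)[0]
    dies = has_adm[rng.random(has_adm.size) < config.death_prob]
    for p_i in dies:
        rows = adm.index[adm["pat_idx"] == p_i]
        pick = rows[rng.integers(0, len(rows))]
        death_date.iloc[p_i] = adm.loc[pick, "start"] + pd.to_timedelta(
            int(rng.integers(0, 28 * 86400)), unit="s")
    adm["death_date"] = death_date.to_numpy()[adm["pat_idx"].to_numpy()]
    adm["codes"] = [";".join(c) for c in code_lists]

    # --- encounters (transfer splits) ------------------------------------
    split = rng.random(m) < config.transfer_prob
    frac = rng.uniform(0.2, 0.8, size=m)
    gap_h = rng.uniform(1.0, 23.0, size=m)
    first = adm.copy()
    mid = adm["start"] + pd.to_timedelta((frac * duration_h * 3600).astype(int), unit="s")
    first.loc[split, "end"] = mid[split]
    first.loc[split, "codes"] = ""  # diagnoses registered on the discharge encounter
    second = adm.loc[split].copy()
    second["start"] = mid[split] + pd.to_timedelta((gap_h[split] * 3600).astype(int), unit="s")
    second["end"] = np.maximum(second["start"], second["end"])
    encounters = pd.concat([first, second], ignore_index=True)
    encounters = (encounters[ENCOUNTER_COLUMNS]
                  .sort_values(["patient_id", "start", "end"], kind="mergesort")
                  .reset_index(drop=True))
    for col in ("start", "end", "death_date"):
        encounters[col] = pd.to_datetime(encounters[col]).dt.floor("s")

    record_truth = labs[["adm_idx", "week", "true_shift", "true_flag", "std_flag", "true_dev"]].copy()
    lab_records = (labs[LAB_COLUMNS]
                   .sort_values(["patient_id", "test_name", "timestamp"], kind="mergesort"))
    record_truth = record_truth.loc[lab_records.index].reset_index(drop=True)
    lab_records = lab_records.reset_index(drop=True)

    ages = range((lo_age // 10) * 10, ((hi_age + config.years + 10) // 10) * 10, 10)
    truth = TruthBundle(
        config=config,
        ri_table=build_ri_table(config.tests, ages=ages, lab_id=lab_id),
        record_truth=record_truth,
        admission_truth=pd.DataFrame({"patient_id": adm["patient_id"], "start": adm["start"],
                                      **outcome_rows}),
    )
    return lab_records, encounters, truth


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_tests(beta1: float = 0.6, thetas=(2.0, 10.0, 28.0, 40.0)) -> list[TestSpec]:
    """Four seasonal test analogues with a central-90% standard RI.

    Amplitude 0.6 sd with a mean +/- 1.645 sd interval moves a substantial
    fraction of abnormality flags across a bound over the year, which is the
    regime the adjustment targets.
    """
    names = ["crp_like", "egfr_like", "hemoglobin_like", "leukocytes_like"]
    specs = []
    for name, th in zip(names, thetas):
        specs.append(TestSpec(
            test_name=name, specimen="plasma", unit="mg/L",
            standard_ri=(100.0 - 1.645 * 10.0, 100.0 + 1.645 * 10.0),
            baseline_mean=100.0, baseline_sd=10.0,
            true_beta0=0.0, true_beta1=beta1, true_theta=th,
        ))
    return specs


def default_outcomes(tests: list[TestSpec], n_outcomes: int = 1,
                     uses_seasonal_truth: bool = True) -> list[OutcomeSpec]:
    codes = [f"I{21 + i}" for i in range(n_outcomes)]
    return [OutcomeSpec(code=c, intercept=-2.0,
                        weights={t.test_name: 1.5 for t in tests},
                        sex_weight=0.5, uses_seasonal_truth=uses_seasonal_truth)
            for c in codes]


def default_config(seed: int = 0, n_patients: int = 2000, beta1: float = 0.6,
                   n_outcomes: int = 1, uses_seasonal_truth: bool = True,
                   age_range: tuple[int, int] = (20, 39)) -> SimConfig:
    tests = default_tests(beta1=beta1)
    return SimConfig(
        n_patients=n_patients, years=4, tests=tests,
        outcomes=default_outcomes(tests, n_outcomes, uses_seasonal_truth),
        age_range=age_range, seed=seed,
    )


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def write_cohort(records: pd.DataFrame, encounters: pd.DataFrame, path) -> None:
    """Write records.csv / encounters.csv (UTF-8, ISO-8601 timestamps)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = records[LAB_COLUMNS].copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"]).dt.strftime(TIME_FMT)
    rec.to_csv(path / "records.csv", index=False)
    enc = encounters[ENCOUNTER_COLUMNS].copy()
    for col in ("start", "end", "death_date"):
        enc[col] = pd.to_datetime(enc[col]).dt.strftime(TIME_FMT)
    enc.to_csv(path / "encounters.csv", index=False)


def _parse_times(df: pd.DataFrame, col: str, path) -> pd.Series:
    parsed = pd.to_datetime(df[col], format=TIME_FMT, errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col] != "")
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based, after header
        raise CohortParseError(path, line, f"unparseable timestamp in column '{col}': {df[col][bad].iloc[0]!r}")
    return parsed


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back what :func:`write_cohort` wrote; round-trip identical.

    Malformed numeric or timestamp fields raise :class:`CohortParseError`
    naming the file and 1-based line number.
    """
    path = Path(path)
    rpath, epath = path / "records.csv", path / "encounters.csv"
    rec = pd.read_csv(rpath, dtype={"patient_id": str}, keep_default_na=False)
    if len(rec):
        values = pd.to_numeric(rec["value"], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(rec.index[bad][0]) + 2
            raise CohortParseError(rpath, line, f"non-numeric value field: {rec['value'][bad].iloc[0]!r}")
        rec["value"] = values
        rec["timestamp"] = _parse_times(rec, "timestamp", rpath)
        rec["age_at_draw"] = rec["age_at_draw"].astype(int)
    else:
        rec = pd.DataFrame(columns=LAB_COLUMNS)
    enc = pd.read_csv(epath, dtype={"patient_id": str, "codes": str}, keep_default_na=False)
    if len(enc):
        for col in ("start", "end"):
            enc[col] = _parse_times(enc, col, epath)
        dd = enc["death_date"].replace("", pd.NA)
        enc["death_date"] = pd.to_datetime(dd, format=TIME_FMT, errors="raise")
        enc["age_at_start"] = enc["age_at_start"].astype(int)
    else:
        enc = pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    return rec[LAB_COLUMNS], enc[ENCOUNTER_COLUMNS]


def write_manifest(truth: TruthBundle, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth.manifest(), fh, indent=2, default=str)
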
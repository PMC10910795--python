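"""Abnormality-flag feature matrices for classification.

Each admission becomes one row; each included laboratory test one column,
holding +1 (above the reference interval), -1 (below) or 0 (within, or not
measured), plus a sex column (0 = female, 1 = male).  Version 1 flags
against the standard RI; version 2 against the seasonally adjusted RI at the
record's ISO week.  Columns are standardized (mean/variance fit on the
development split only) before modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .cohort import STRATUM_FIELDS, age_group_of
from .seasonal import AdjustedRI, SeasonalFit, StandardRI
from .synthetic import iso_week

logger = logging.getLogger(__name__)


def flag(value, lower, upper):
    """Abnormality flag: +1 above the interval, -1 below, 0 within.

    Values exactly on a bound count as normal (closed normal interval).
    Vectorized over all three arguments.
    """
    v = np.asarray(value, dtype=float)
    out = np.where(v > upper, 1, np.where(v < lower, -1, 0))
    return out if out.ndim else int(out)


class UnknownStratumError(KeyError):
    """ri_provider has no interval for a stratum present in the data."""


class RIProvider:
    """Week-indexed reference-interval lookup per stratum.

    Wraps a standard-RI table (one row per test/specimen/unit/lab/sex/age
    group) and, optionally, the per-stratum seasonal fits; ``version=1``
    always answers with the standard bounds, ``version=2`` with the adjusted
    bounds where the stratum's fit is significant.
    """

    def __init__(self, ri_table: pd.DataFrame,
                 adjusted: dict[tuple, AdjustedRI] | None = None):
        self._standard: dict[tuple, StandardRI] = {}
        for row in ri_table.itertuples(index=False):
            key = tuple(getattr(row, f) for f in STRATUM_FIELDS)
            self._standard[key] = StandardRI(float(row.lower), float(row.upper))
        self._adjusted = adjusted or {}

    def standard(self, key: tuple) -> StandardRI:
        try:
            return self._standard[key]
        except KeyError:
            raise UnknownStratumError(f"no standard RI for stratum {key!r}") from None

    def bounds(self, key: tuple, week, version: int):
        """(lower, upper) for a stratum at ``week`` under an encoding version."""
        base = self.standard(key)
        if version == 1:
            return base.lower, base.upper
        adj = self._adjusted.get(key)
        if adj is None:
            return base.lower, base.upper
        return adj.bounds(week)

    def bounds_for_records(self, records: pd.DataFrame, version: int):
        """Vectorized per-record bounds; raises on any unknown stratum."""
        weeks = records["week"].to_numpy() if "week" in records else iso_week(records["timestamp"])
        keys = list(zip(*(records[f] for f in STRATUM_FIELDS)))
        lower = np.empty(len(records))
        upper = np.empty(len(records))
        for i, (key, wk) in enumerate(zip(keys, weeks)):
            lower[i], upper[i] = self.bounds(key, wk, version)
        return lower, upper


def build_adjusted_lookup(fit_results: dict[tuple, tuple[SeasonalFit, float, float]],
                          ri_table: pd.DataFrame) -> dict[tuple, AdjustedRI]:
    """Combine per-stratum fits with the standard RI table into AdjustedRIs."""
    table = {}
    for row in ri_table.itertuples(index=False):
        key = tuple(getattr(row, f) for f in STRATUM_FIELDS)
        table[key] = StandardRI(float(row.lower), float(row.upper))
    out = {}
    for key, (fit, mean, sd) in fit_results.items():
        if key not in table:
            raise UnknownStratumError(f"fitted stratum {key!r} missing from the standard-RI table")
        out[key] = AdjustedRI(base=table[key], fit=fit, stratum_mean=mean, stratum_sd=sd)
    return out


@dataclass
class FeatureMatrix:
    """Admissions x (tests + sex) design matrix for one encoding version."""

    raw: pd.DataFrame          # pre-standardization entries, index = admission_id
    version: int
    test_columns: list[str]
    scaler: StandardScaler | None = field(default=None, repr=False)

    def fit_scaler(self, dev_index) -> "FeatureMatrix":
        """Fit column means/scales on the development rows only."""
        self.scaler = StandardScaler()
        dev = self.raw.loc[dev_index]
        self.scaler.fit(dev.to_numpy(float))
        zero_var = [c for c, s in zip(self.raw.columns, self.scaler.var_) if s == 0.0]
        if zero_var:
            warnings.warn(f"zero-variance feature columns pass through unscaled: {zero_var}",
                          stacklevel=2)
        return self

    def standardized(self, index=None) -> pd.DataFrame:
        if self.scaler is None:
            raise RuntimeError("call fit_scaler(dev_index) before standardized()")
        sub = self.raw if index is None else self.raw.loc[index]
        z = self.scaler.transform(sub.to_numpy(float))
        return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def add_stratum_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Attach week and age_group columns (stratum of the measurement)."""
    out = records.copy()
    if "week" not in out:
        out["week"] = iso_week(pd.to_datetime(out["timestamp"])) if len(out) else []
    if "age_group" not in out:
        out["age_group"] = age_group_of(out["age_at_draw"].to_numpy())
    return out


def build_matrix(admissions: pd.DataFrame, records: pd.DataFrame,
                 ri_provider: RIProvider, version: int,
                 test_columns: list[str] | None = None) -> FeatureMatrix:
    """Build the version-1 or version-2 feature matrix.

    Per admission and test, repeated records are reduced to the most abnormal
    one *under this version's bounds* (a record's flag depends on the bounds,
    so selection is version-specific), then flagged; unmeasured tests are
    imputed 0; sex is appended last (0 = F, 1 = M).  Deterministic given its
    inputs.
    """
    if version not in (1, 2):
        raise ValueError(f"version must be 1 or 2, got {version}")
    rec = add_stratum_columns(records)
    if test_columns is None:
        test_columns = sorted(rec["test_name"].unique())

    index = pd.Index(admissions["admission_id"], name="admission_id")
    mat = pd.DataFrame(0.0, index=index, columns=test_columns)

    if len(rec):
        lower, upper = ri_provider.bounds_for_records(rec, version)
        v = rec["value"].to_numpy(float)
        fl = np.where(v > upper, 1, np.where(v < lower, -1, 0))
        width = upper - lower
        nearest = np.where(fl > 0, upper, lower)
        dev = np.where(fl != 0, np.abs(v - nearest) / width, -np.inf)
        work = pd.DataFrame({
            "admission_id": rec["admission_id"].to_numpy(),
            "test_name": rec["test_name"].to_numpy(),
            "flag": fl, "dev": dev,
            "timestamp": rec["timestamp"].to_numpy(),
        })
        # most-abnormal selection: any flagged record beats unflagged ones;
        # among flagged, the largest normalized deviation wins; among all-
        # normal, the last by timestamp is the representative (flag 0 anyway).
        work = work.sort_values(["admission_id", "test_name", "dev", "timestamp"],
                                kind="mergesort")
        best = work.drop_duplicates(["admission_id", "test_name"], keep="last")
        best = best[best["admission_id"].isin(index)]
        pivot = best.pivot(index="admission_id", columns="test_name", values="flag")
        pivot = pivot.reindex(index=index, columns=test_columns).fillna(0.0)
        mat[:] = pivot.to_numpy(float)

    mat["sex"] = (admissions.set_index("admission_id").loc[index, "sex"] == "M").astype(float)
    return FeatureMatrix(raw=mat, version=version, test_columns=list(test_columns))


def outcome_vector(admissions: pd.DataFrame, code: str) -> pd.Series:
    """1 iff the level-3 code is registered at the admission."""
    y = admissions["codes"].map(lambda s: int(code in set(str(s).split(";"))))
    return pd.Series(y.to_numpy(), index=pd.Index(admissions["admission_id"], name="admission_id"),
                     name=code)
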
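"""End-to-end orchestration: simulate -> cohort -> fit -> encode -> evaluate.

One master seed fans out to per-stage seeds (recorded in the run manifest);
every stage writes its outputs into the run directory, so a failed run can
be resumed and a finished run is fully reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import features as feat_mod
from . import modeling, synthetic
from .explain import anova_by_level, level_tests_to_frame, mean_abs_shap, permutation_shap
from .seasonal import fdr_correct, fit_stratum_records, fits_to_frame, StratumUnfittableError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "fit", "encode", "evaluate", "explain", "report")


@dataclass
class CohortParams:
    window_hours: float = 24.0
    min_age: int = 20
    coverage_frac: float = 0.20
    min_patients: int = 1000
    survival_days: int = 28


@dataclass
class FitParams:
    alpha: float = 0.05
    min_weeks: int = 26
    significance_rule: str = "beta1_theta"
    aggregate: bool = True


@dataclass
class EvalParams:
    families: list[str] = field(default_factory=lambda: ["random_forest"])
    n_search: int = 40
    cv_folds: int = 5
    n_boots: int = 1000
    bca_boots: int = 10000
    dev_frac: float = 0.7
    #: optional per-family search-space overrides (family -> distributions)
    distributions: dict = field(default_factory=dict)


@dataclass
class ExplainParams:
    enabled: bool = False
    n_permutations: int = 50
    background_size: int = 100
    max_rows: int = 500
    family: str = "neural_net"


@dataclass
class PipelineConfig:
    sim: synthetic.SimConfig = field(default_factory=synthetic.default_config)
    cohort: CohortParams = field(default_factory=CohortParams)
    fit: FitParams = field(default_factory=FitParams)
    eval: EvalParams = field(default_factory=EvalParams)
    explain: ExplainParams = field(default_factory=ExplainParams)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + 7919 * STAGES.index(stage)) % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("sim", {})
        if isinstance(sim, dict):
            tests = [synthetic.TestSpec(**t) if isinstance(t, dict) else t
                     for t in sim.get("tests", [])]
            outcomes = [synthetic.OutcomeSpec(**o) if isinstance(o, dict) else o
                        for o in sim.get("outcomes", [])]
            sim = synthetic.SimConfig(**{**{k: v for k, v in sim.items()
                                            if k not in ("tests", "outcomes")},
                                         "tests": tests, "outcomes": outcomes})
            if isinstance(sim.age_range, list):
                sim.age_range = tuple(sim.age_range)
        kw = {"sim": sim, "seed": d.get("seed", 0)}
        for name, cls_ in (("cohort", CohortParams), ("fit", FitParams),
                           ("eval", EvalParams), ("explain", ExplainParams)):
            v = d.get(name, {})
            kw[name] = cls_(**v) if isinstance(v, dict) else v
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class StageError(RuntimeError):
    """A pipeline stage failed; the run directory holds a resumable checkpoint."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}; "
                         f"completed stages are checkpointed in the run directory")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def fit_strata(records: pd.DataFrame, fitting_mask: np.ndarray,
               params: FitParams) -> dict[tuple, tuple]:
    """Cosinor fit per stratum over the fitting subset of records.

    Returns stratum key -> (SeasonalFit, stratum_mean, stratum_sd); strata
    with too few points or zero variance are skipped with a logged reason.
    FDR correction is applied across strata, per parameter family.
    """
    rec = feat_mod.add_stratum_columns(records).loc[np.asarray(fitting_mask)]
    results: dict[tuple, tuple] = {}
    for key, g in rec.groupby(cohort_mod.STRATUM_FIELDS, sort=True):
        try:
            fit, mean, sd = fit_stratum_records(
                g["week"].to_numpy(), g["value"].to_numpy(), stratum=key,
                min_weeks=params.min_weeks, aggregate=params.aggregate)
        except StratumUnfittableError as exc:
            logger.info("stratum %s unfittable: %s", key, exc)
            continue
        results[key] = (fit, mean, sd)
    fits = [v[0] for v in results.values()]
    fdr_correct(fits, alpha=params.alpha, rule=params.significance_rule)
    return results


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Run every stage, writing outputs + manifest into ``outdir``.

    Returns the report dict (also written as report.json).  With
    ``resume=True``, stages whose outputs already exist are skipped, and the
    resumed run produces outputs identical to an uninterrupted one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "timings": {},
        "digests": {},
        "package_version": _version(),
    }
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") != manifest["config_hash"]:
            raise ValueError("cannot resume: config differs from the checkpointed run")
        manifest["timings"].update(prev.get("timings", {}))

    def done(stage):
        return resume and (outdir / f".{stage}.done").exists()

    def mark(stage, t0):
        manifest["timings"][stage] = round(time.time() - t0, 3)
        (outdir / f".{stage}.done").touch()

    # --- simulate ------------------------------------------------------
    t0 = time.time()
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=config.stage_seed("simulate"))
        records, encounters, truth = synthetic.simulate_cohort(sim_cfg)
        if not done("simulate"):
            synthetic.write_cohort(records, encounters, outdir)
            synthetic.write_manifest(truth, outdir / "truth.json")
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    mark("simulate", t0)

    # --- cohort --------------------------------------------------------
    t0 = time.time()
    try:
        admissions = cohort_mod.merge_encounters(encounters)
        attached = cohort_mod.attach_labs(admissions, records,
                                          window_hours=config.cohort.window_hours)
        outcome_codes = [o.code for o in config.sim.outcomes]
        attached, admissions, kept_outcomes, fitting_mask, filt_report = \
            cohort_mod.apply_cohort_filters(
                attached, admissions, outcome_codes,
                min_age=config.cohort.min_age,
                coverage_frac=config.cohort.coverage_frac,
                min_patients=config.cohort.min_patients,
                survival_days=config.cohort.survival_days)
        filt_report.to_json(outdir / "filter_report.json")
        admissions.to_csv(outdir / "admissions.csv", index=False)
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    mark("cohort", t0)

    # --- seasonal fit --------------------------------------------------
    t0 = time.time()
    try:
        fit_results = fit_strata(attached, fitting_mask, config.fit)
        fits_to_frame([v[0] for v in fit_results.values()]).to_csv(outdir / "fits.csv", index=False)
        adjusted = feat_mod.build_adjusted_lookup(fit_results, truth.ri_table)
        provider = feat_mod.RIProvider(truth.ri_table, adjusted)
    except Exception as exc:
        raise StageError("fit", exc) from exc
    mark("fit", t0)

    # --- encode --------------------------------------------------------
    t0 = time.time()
    try:
        fm1 = feat_mod.build_matrix(admissions, attached, provider, version=1)
        fm2 = feat_mod.build_matrix(admissions, attached, provider, version=2)
        dev_ids, test_ids = modeling.split_by_patient(
            admissions, dev_frac=config.eval.dev_frac, seed=config.stage_seed("encode"))
        fm1.fit_scaler(dev_ids)
        fm2.fit_scaler(dev_ids)
        n_cells_differ = int((fm1.raw.to_numpy() != fm2.raw.to_numpy()).sum())
        fm1.raw.to_csv(outdir / "features_v1.csv")
        fm2.raw.to_csv(outdir / "features_v2.csv")
    except Exception as exc:
        raise StageError("encode", exc) from exc
    mark("encode", t0)

    # --- evaluate ------------------------------------------------------
    t0 = time.time()
    try:
        groups = admissions.set_index("admission_id").loc[dev_ids, "patient_id"].to_numpy()
        results = []
        models_v2 = {}
        for code in kept_outcomes:
            y = feat_mod.outcome_vector(admissions, code)
            y_dev, y_test = y.loc[dev_ids].to_numpy(), y.loc[test_ids].to_numpy()
            X1_dev, X1_test = fm1.standardized(dev_ids).to_numpy(), fm1.standardized(test_ids).to_numpy()
            X2_dev, X2_test = fm2.standardized(dev_ids).to_numpy(), fm2.standardized(test_ids).to_numpy()
            for family in config.eval.families:
                spec = modeling.ModelSpec(
                    family=family, n_search=config.eval.n_search,
                    cv_folds=config.eval.cv_folds,
                    distributions=config.eval.distributions.get(family, {}))
                code_h = int(hashlib.sha256(code.encode()).hexdigest()[:8], 16) % 10007
                seed = (config.stage_seed("evaluate") + code_h) % (2**31 - 1)
                m1, _ = modeling.tune_and_fit(spec, X1_dev, y_dev, groups, seed=seed)
                m2, _ = modeling.tune_and_fit(spec, X2_dev, y_dev, groups, seed=seed)
                res = modeling.evaluate_pair(
                    m1, m2, X1_test, X2_test, y_test, outcome=code, family=family,
                    n_boots=config.eval.n_boots, bca_boots=config.eval.bca_boots,
                    seed=seed)
                results.append(res)
                if family == config.explain.family or len(config.eval.families) == 1:
                    models_v2[code] = (m2, X2_test)
        modeling.results_to_frame(results).to_csv(outdir / "comparison.csv", index=False)
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    mark("evaluate", t0)

    # --- explain (optional) -------------------------------------------
    t0 = time.time()
    explain_summary = {}
    if config.explain.enabled:
        try:
            rng = np.random.default_rng(config.stage_seed("explain"))
            for code, (model, X2_test) in models_v2.items():
                X2_dev = fm2.standardized(dev_ids)
                bg_idx = rng.choice(len(X2_dev), size=min(config.explain.background_size, len(X2_dev)),
                                    replace=False)
                test_df = fm2.standardized(test_ids)
                rows = test_df.iloc[:config.explain.max_rows]
                shap = permutation_shap(model.predict_proba, rows, X2_dev.iloc[bg_idx],
                                        n_permutations=config.explain.n_permutations,
                                        seed=config.stage_seed("explain"))
                shap.values.to_csv(outdir / f"shap_{code}.csv")
                summary = mean_abs_shap(shap, scaled=True)
                tests = anova_by_level(shap, fm2.raw.loc[rows.index])
                level_tests_to_frame(tests).to_csv(outdir / f"shap_levels_{code}.csv", index=False)
                explain_summary[code] = summary.to_dict()
        except Exception as exc:
            raise StageError("explain", exc) from exc
    mark("explain", t0)

    # --- report --------------------------------------------------------
    t0 = time.time()
    report = {
        "config_hash": manifest["config_hash"],
        "seed": config.seed,
        "n_admissions": int(len(admissions)),
        "n_patients": int(admissions["patient_id"].nunique()),
        "n_records": int(len(attached)),
        "kept_outcomes": kept_outcomes,
        "n_significant_strata": int(sum(v[0].significant for v in fit_results.values())),
        "n_strata": len(fit_results),
        "n_cells_differ": n_cells_differ,
        "comparisons": [
            {"outcome": r.outcome, "family": r.family,
             "auroc_v1": r.auroc_v1, "auroc_v2": r.auroc_v2,
             "auprc_v1": r.auprc_v1, "auprc_v2": r.auprc_v2,
             "median_diff": r.median_diff, "median_diff_auprc": r.median_diff_auprc,
             "bca_ci": list(r.bca_ci), "verdict": r.verdict}
            for r in results
        ],
        "net_gains": summarize_net_gains_rows(results),
        "mean_abs_shap": explain_summary,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    mark("report", t0)

    for p in sorted(outdir.iterdir()):
        if p.is_file() and not p.name.startswith("."):
            manifest["digests"][p.name] = _sha256(p)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def summarize_net_gains_rows(results) -> dict[str, float]:
    """Per family, summed median AUROC gains with non-significant diffs zeroed."""
    gains: dict[str, float] = {}
    for r in results:
        d = r.median_diff if r.verdict != "no_difference" else 0.0
        gains[r.family] = gains.get(r.family, 0.0) + d
    return {k: float(v) for k, v in gains.items()}


def summarize_net_gains(report: dict) -> pd.DataFrame:
    """Outcome x family table of median AUROC differences and significance.

    Non-significant entries are zeroed (they carry a ``significant=False``
    flag); the per-family totals match ``report['net_gains']``.
    """
    rows = []
    for c in report.get("comparisons", []):
        sig = c["verdict"] != "no_difference"
        rows.append({"outcome": c["outcome"], "family": c["family"],
                     "median_diff": c["median_diff"] if sig else 0.0,
                     "significant": sig, "verdict": c["verdict"]})
    if not rows:
        raise ValueError("report contains no comparisons")
    return pd.DataFrame(rows)


def sensitivity_config(seed: int, n_patients: int = 2000, beta1: float = 0.6,
                       n_boots: int = 200, bca_boots: int = 2000,
                       family: str = "random_forest") -> PipelineConfig:
    """Study conditions for the seasonal-truth sensitivity experiment.

    One seasonal-truth outcome over four tests with amplitude ``beta1``; a
    single classifier family with a compact forest search (3 configurations,
    3 patient-grouped folds) keeps the experiment desk-sized while the
    comparison machinery (paired boots, BCa) runs exactly as in the full
    pipeline.
    """
    sim = synthetic.default_config(seed=0, n_patients=n_patients, beta1=beta1,
                                   n_outcomes=1, uses_seasonal_truth=True,
                                   age_range=(20, 39))
    return PipelineConfig(
        sim=sim,
        cohort=CohortParams(min_patients=50),
        eval=EvalParams(
            families=[family], n_search=3, cv_folds=3,
            n_boots=n_boots, bca_boots=bca_boots,
            distributions={"random_forest": {
                "n_estimators": [60], "max_depth": [6, 10, None],
                "min_samples_leaf": [1, 5]}},
        ),
        seed=seed,
    )


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("seasonri")
    except Exception:  # pragma: no cover
        return "unknown"
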
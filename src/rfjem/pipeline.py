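"""End-to-end analysis: inputs -> exclusions -> exposure -> categories -> ORs.

For each cell of the analysis grid (outcome x field x method x metric x
lag/window label) the pipeline derives percentile cut-points from that
run's exposed controls, assigns categories, fits the stratified conditional
logistic model adjusted for education, and emits one odds-ratio row per
non-reference category plus a trend test.  Inestimable cells (empty
categories, non-convergence, no exposed controls) produce flagged rows, and
the run continues.  Output is deterministic given inputs and configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize, clogit, cohort, exposure
from .errors import InestimableRunError
from .jem import load_jem, median_prevalence_threshold

RESULT_COLUMNS = [
    "outcome", "field_kind", "method", "metric", "label", "category",
    "n_cases", "n_controls", "OR", "CI_low", "CI_high", "p_trend",
    "n_informative_strata", "converged",
]
CUTPOINT_COLUMNS = ["label", "field_kind", "method", "metric",
                    "p50", "p75", "p90", "n_exposed_controls"]

#: age bands above the sensitivity cut of 60 years at interview
_OVER_60_BANDS = ("60-64", "65-69", "70+")


@dataclass
class SensitivitySwitches:
    """Optional restrictions mirrored on the study's sensitivity analyses."""

    full_employment_window: bool = False  # worked all of [ref-4, ref-1]
    exclude_proxies: bool = False
    exclude_over_60: bool = False
    trim_top_percentile: bool = False  # drop > 99th pct of exposed controls
    exclude_preexisting: bool = False
    sex: str | None = None  # restrict to "male" / "female"
    glioma_grade: str | None = None  # restrict cases to "low" / "high"


@dataclass
class RunConfig:
    jem_path: str = "jem.csv"
    participants_path: str = "participants.csv"
    jobs_path: str = "jobs.csv"
    outcomes: tuple[str, ...] = ("glioma", "meningioma")
    fields: tuple[str, ...] = ("E", "H")
    methods: tuple[str, ...] = ("M1", "M2", "M3")
    metrics: tuple[str, ...] = ("cumulative", "twa")
    labels: tuple[str, ...] = exposure.PRIMARY_LABELS
    reference: str = "unexposed"  # or "low_exposed"
    clogit_method: str = "exact"
    sensitivity: SensitivitySwitches = dc_field(default_factory=SensitivitySwitches)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for axis, allowed in (
            (self.outcomes, cohort.CASE_STATUSES),
            (self.fields, ("E", "H")),
            (self.methods, exposure.METHODS),
            (self.labels, tuple(exposure.LABELS)),
            (self.metrics, ("cumulative", "twa")),
        ):
            if not axis:
                raise ValueError("every analysis axis needs at least one entry")
            bad = set(axis) - set(allowed)
            if bad:
                raise ValueError(f"unsupported values {sorted(bad)}; allowed {allowed}")
        if self.reference not in ("unexposed", "low_exposed"):
            raise ValueError(f"unknown reference choice {self.reference!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sens = SensitivitySwitches(**raw.pop("sensitivity", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcomes", "fields", "methods", "metrics", "labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sensitivity=sens, **raw)


@dataclass
class RunResult:
    results: pd.DataFrame
    cutpoints: pd.DataFrame
    profiles: pd.DataFrame
    ledger: cohort.ExclusionLedger
    log: list[str]


def sensitivity_filter(
    pdf: pd.DataFrame,
    jdf: pd.DataFrame,
    ref_years: pd.Series,
    switches: SensitivitySwitches,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the enabled subject-level restrictions; returns the kept subset.

    The full-employment predicate requires a (non-nonstandard) job spell to
    cover each of the four calendar years in [ref-4, ref-1].  Exposure
    trimming is applied per analysis cell, not here, because the 99th
    percentile is a property of each cell's exposed-control distribution.
    """
    keep = pd.Series(True, index=pdf.index)
    if switches.exclude_proxies:
        keep &= ~pdf["proxy"]
    if switches.exclude_over_60:
        keep &= ~pdf["age_group"].isin(_OVER_60_BANDS)
    if switches.exclude_preexisting:
        keep &= ~pdf["preexisting_condition"]
    if switches.sex is not None:
        keep &= pdf["sex"] == switches.sex
    if switches.glioma_grade is not None:
        keep &= (pdf["status"] == "control") | (pdf["grade"] == switches.glioma_grade)
    if switches.full_employment_window:
        employed = _fully_employed_pids(jdf, ref_years)
        keep &= pdf["pid"].isin(employed)
    out = pdf.loc[keep].reset_index(drop=True)
    if log is not None and len(out) != len(pdf):
        log.append(f"sensitivity filter kept {len(out)}/{len(pdf)} participants")
    n_cases = out["status"].isin(cohort.CASE_STATUSES).sum()
    n_controls = (out["status"] == "control").sum()
    if n_cases == 0 or n_controls == 0:
        raise InestimableRunError("sensitivity filter removed all cases or all controls")
    return out


def _fully_employed_pids(jdf: pd.DataFrame, ref_years: pd.Series) -> set[str]:
    real = jdf[~jdf["nonstandard"]
               & jdf["start_year"].notna() & jdf["end_year"].notna()]
    covered: dict[str, set[int]] = {}
    for row in real.itertuples(index=False):
        years = covered.setdefault(row.pid, set())
        years.update(range(int(row.start_year), int(row.end_year) + 1))
    out = set()
    for pid, ref in ref_years.items():
        need = set(range(int(ref) - 4, int(ref)))
        if need <= covered.get(pid, set()):
            out.add(pid)
    return out


def _fit_cell(values, exposed, y, strata, edu_X, reference, clogit_method,
              trim: bool):
    """Cut-points, categories, fit and trend for one analysis cell.

    Returns (rows, cutpoint_record); rows carry NaN ORs with a False
    converged flag when the cell is inestimable.
    """
    values = np.asarray(values, float)
    exposed = np.asarray(exposed, bool)
    y = np.asarray(y, bool)
    control_vals = values[~y & exposed]
    if trim and control_vals.size:
        cut = np.quantile(control_vals, 0.99)
        keep = ~(exposed & (values > cut))
        values, exposed, y = values[keep], exposed[keep], y[keep]
        strata = np.asarray(strata)[keep]
        edu_X = np.asarray(edu_X)[keep]
        control_vals = values[~y & exposed]
    cps = categorize.cutpoints(control_vals)
    cats = categorize.categorize(values, exposed, cps)
    if reference == "low_exposed":
        cats = categorize.rebase_reference(cats)
    levels = cats.non_reference_levels
    ind = cats.indicators()
    names = [f"cat{k}" for k in levels]
    estimable = ind.sum(axis=0) > 0
    X = np.hstack([ind[:, estimable], edu_X])
    fit = clogit.fit_clogit(
        X, y, strata, method=clogit_method,
        names=[n for n, e in zip(names, estimable) if e]
        + ["edu_medium_technical", "edu_university"],
    )
    try:
        trend = clogit.trend_test(cats.codes, y, strata, covariates=edu_X)
        p_trend = trend.p_value
    except Exception:
        p_trend = np.nan

    if fit.converged:
        ors = clogit.odds_ratios(fit).set_index("term")
    else:
        ors = pd.DataFrame(columns=["OR", "CI_low", "CI_high"])
    rows = []
    for k, name, ok in zip(levels, names, estimable):
        in_cat = cats.codes == k
        if fit.converged and ok and name in ors.index:
            o = ors.loc[name]
            orv, lo, hi = float(o["OR"]), float(o["CI_low"]), float(o["CI_high"])
            conv = True
        else:
            orv = lo = hi = np.nan
            conv = False
        rows.append({
            "category": k,
            "n_cases": int((in_cat & y).sum()),
            "n_controls": int((in_cat & ~y).sum()),
            "OR": orv, "CI_low": lo, "CI_high": hi,
            "p_trend": p_trend,
            "n_informative_strata": fit.n_informative_strata,
            "converged": conv,
        })
    cp_record = {"p50": cps.p50, "p75": cps.p75, "p90": cps.p90,
                 "n_exposed_controls": cps.n_exposed_controls}
    return rows, cp_record


def run_analysis(cfg: RunConfig) -> RunResult:
    """Run the full grid; see module docstring."""
    log: list[str] = []
    jem = load_jem(cfg.jem_path)
    pdf, jdf = cohort.load_cohort(cfg.participants_path, cfg.jobs_path)
    log.append(f"loaded {len(pdf)} participants, {len(jdf)} job spells")
    pdf, jdf, ledger = cohort.apply_exclusions(pdf, jdf)
    for label, counts in ledger.steps:
        log.append(f"excluded [{label}]: " + ", ".join(
            f"{s}={n}" for s, n in counts.items()))
    log.append("final: " + ", ".join(f"{s}={n}" for s, n in ledger.final.items()))
    ledger.validate()

    thresholds = None
    if "M2" in cfg.methods:
        thresholds = {fk: median_prevalence_threshold(jem, fk)
                      for fk in cfg.fields}
        log.append(f"method-2 prevalence thresholds: {thresholds}")

    all_results: list[dict] = []
    all_cutpoints: list[dict] = []
    all_profiles: list[pd.DataFrame] = []
    for outcome in cfg.outcomes:
        sub = pdf[(pdf["status"] == outcome) | (pdf["status"] == "control")]
        sub = sub.reset_index(drop=True)
        cases = sub[sub["status"] == outcome]
        if cases.empty:
            log.append(f"no {outcome} cases; outcome skipped")
            continue
        gap = cohort.median_diagnosis_interview_gap(cases)
        log.append(f"{outcome}: median diagnosis-interview gap {gap:.1f} years")
        ref = cohort.reference_years(sub, gap)
        sub = sensitivity_filter(sub, jdf, ref, cfg.sensitivity, log)
        ref = ref[ref.index.isin(set(sub["pid"]))]
        jobs = jdf[jdf["pid"].isin(set(sub["pid"]))]
        profiles = exposure.compute_profiles(
            sub, jobs, jem, ref, methods=cfg.methods, fields=cfg.fields,
            labels=cfg.labels, thresholds=thresholds,
        )
        all_profiles.append(profiles.assign(outcome=outcome))

        y_by_pid = (sub.set_index("pid")["status"] == outcome)
        strata_by_pid = (sub["age_group"] + "|" + sub["sex"] + "|"
                         + sub["region"]).set_axis(sub["pid"])
        edu_by_pid = sub.set_index("pid")["education"]

        for (fk, method, label), cell in profiles.groupby(
                ["field_kind", "method", "label"], sort=False):
            cell = cell.set_index("pid")
            pids = cell.index
            y = y_by_pid.loc[pids].to_numpy()
            strata = strata_by_pid.loc[pids].to_numpy()
            edu_X, _ = clogit.education_indicators(edu_by_pid.loc[pids])
            for metric in cfg.metrics:
                vals = cell[metric].to_numpy(float)
                exp_flags = cell["exposed"].to_numpy(bool)
                base = {"outcome": outcome, "field_kind": fk, "method": method,
                        "metric": metric, "label": label}
                try:
                    rows, cp = _fit_cell(
                        vals, exp_flags, y, strata, edu_X,
                        cfg.reference, cfg.clogit_method,
                        cfg.sensitivity.trim_top_percentile,
                    )
                except Exception as err:  # inestimable cell: flag row, continue
                    log.append(f"cell {base} inestimable: {err}")
                    for k in range(1, categorize.N_CATEGORIES):
                        all_results.append({**base, "category": k,
                                            "n_cases": 0, "n_controls": 0,
                                            "OR": np.nan, "CI_low": np.nan,
                                            "CI_high": np.nan, "p_trend": np.nan,
                                            "n_informative_strata": 0,
                                            "converged": False})
                    continue
                for r in rows:
                    all_results.append({**base, **r})
                all_cutpoints.append({"label": label, "field_kind": fk,
                                      "method": method, "metric": metric, **cp})

    results = pd.DataFrame(all_results, columns=RESULT_COLUMNS)
    cutpoints_df = pd.DataFrame(all_cutpoints, columns=CUTPOINT_COLUMNS)
    profiles_df = (pd.concat(all_profiles, ignore_index=True)
                   if all_profiles else pd.DataFrame())
    out = RunResult(results=results, cutpoints=cutpoints_df,
                    profiles=profiles_df, ledger=ledger, log=log)
    if cfg.outdir:
        _write_outputs(out, cfg.outdir)
    return out


def _write_outputs(res: RunResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.results.to_csv(outdir / "results.csv", index=False)
    res.cutpoints.to_csv(outdir / "cutpoints.csv", index=False)
    res.profiles.to_csv(outdir / "exposure_profiles.csv", index=False)
    res.ledger.to_frame().to_csv(outdir / "ledger.csv", index=False)
    (outdir / "run.log").write_text("\n".join(res.log) + "\n")
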
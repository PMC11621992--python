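"""Synthetic job-exposure matrices, job histories and case-control outcomes.

The real multi-country case-control data behind this kind of analysis are
not publicly deposited, so every pipeline stage here is exercised on
synthetic data whose marginal structure mirrors the study setting it
emulates: ~468 occupation codes of which ~62% carry exposure, job-level
exposure prevalence around 5% with a right-skewed (lognormal) intensity
distribution, strongly correlated E and H fields, careers averaging ~28
years, interviews in 2000-2004, and a case:control ratio near 1:1.5 within
strata of age band x sex x region.

Case status is drawn from a logistic model in the exposure category of a
configurable metric with known log odds ratios, so parameter-recovery and
calibration tests have a ground truth.  Participant-reported source-use
flags are noisy observations of true job-level exposure (configurable
sensitivity/specificity), which makes the three linkage methods produce the
expected prevalence ordering (all-jobs > prevalence-restricted >
self-reported).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import categorize, exposure
from .cohort import UNKNOWN_CODE
from .jem import Jem, JemEntry, write_jem

AGE_GROUPS = ("<35", "35-39", "40-44", "45-49", "50-54",
              "55-59", "60-64", "65-69", "70+")
#: (low age, high age) per band; the open bands are clamped to the study range.
AGE_BOUNDS = {
    "<35": (30, 34), "35-39": (35, 39), "40-44": (40, 44), "45-49": (45, 49),
    "50-54": (50, 54), "55-59": (55, 59), "60-64": (60, 64),
    "65-69": (65, 69), "70+": (70, 74),
}
AGE_WEIGHTS = (0.077, 0.085, 0.116, 0.136, 0.178, 0.186, 0.093, 0.080, 0.050)

REGIONS = ("Australia", "Canada", "France", "Germany",
           "Israel", "NewZealand", "UK")
REGION_WEIGHTS = (0.121, 0.117, 0.087, 0.283, 0.172, 0.026, 0.194)

EDUCATION_WEIGHTS = {"high_school_or_less": 0.539, "medium_technical": 0.187,
                     "university": 0.274}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study's conditions."""

    n_controls: int = 5601
    n_glioma: int = 2054
    n_meningioma: int = 1924
    n_isco_codes: int = 468
    frac_exposed_codes: float = 0.62
    prevalence_beta: tuple[float, float] = (1.0, 19.0)  # mean 5% job prevalence
    intensity_lognorm: tuple[float, float] = (-0.3, 1.2)  # (log-mean, log-sd)
    eh_log_correlation: float = 0.92  # Spearman E-H target ~0.9
    code_frequency_gamma: float = 22.0  # common jobs skew toward low prevalence
    mean_career_years: float = 27.6
    mean_jobs: float = 4.0
    overlap_prob: float = 0.10
    gap_prob: float = 0.20
    nonstandard_prob: float = 0.08
    interview_years: tuple[int, int] = (2000, 2004)
    true_log_or: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    effect_field: str = "E"
    effect_method: str = "M1"
    effect_label: str = "lag1"
    stratum_sd: float = 0.2
    proxy_prob: float = 0.05
    preexisting_prob: float = 0.01
    source_report_sensitivity: float = 0.90
    source_report_specificity: float = 0.97
    exclusion_rates: tuple[float, ...] = (0.046, 0.002, 0.005, 0.006, 0.007)

    def validate(self) -> None:
        fracs = [self.frac_exposed_codes, self.overlap_prob, self.gap_prob,
                 self.nonstandard_prob, self.proxy_prob, self.preexisting_prob,
                 self.source_report_sensitivity, self.source_report_specificity,
                 *self.exclusion_rates]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.prevalence_beta[0] <= 0 or self.prevalence_beta[1] <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.intensity_lognorm[1] <= 0:
            raise ValueError("lognormal sigma must be positive")
        if not -1.0 <= self.eh_log_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def generate_jem(cfg: SyntheticConfig, seed: int) -> Jem:
    """Draw a synthetic matrix: exposed codes get Beta prevalences and
    correlated lognormal E/H intensities; the rest are unexposed cells."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    codes = rng.choice(np.arange(1000, 10000), size=cfg.n_isco_codes,
                       replace=False)
    codes = [f"{c:04d}" for c in codes]
    exposed = rng.random(cfg.n_isco_codes) < cfg.frac_exposed_codes
    a, b = cfg.prevalence_beta
    prevalence = np.where(
        exposed, np.clip(rng.beta(a, b, cfg.n_isco_codes), 1e-4, 1.0), 0.0
    )
    mu, sigma = cfg.intensity_lognorm
    rho = cfg.eh_log_correlation
    cov = (sigma ** 2) * np.array([[1.0, rho], [rho, 1.0]])
    logs = rng.multivariate_normal([mu, mu], cov, size=cfg.n_isco_codes)
    intensity = np.where(exposed[:, None], np.exp(logs), 0.0)
    n_basis = 1 + rng.poisson(3, cfg.n_isco_codes)

    jem = Jem()
    for i, code in enumerate(codes):
        for k, fk in enumerate(("E", "H")):
            jem.add(JemEntry(isco88=code, field_kind=fk,
                             intensity=float(intensity[i, k]),
                             prevalence=float(prevalence[i]),
                             n_basis=int(n_basis[i])))
    return jem


def _job_code_weights(jem: Jem, gamma: float) -> tuple[list[str], np.ndarray]:
    """Sampling weights over occupation codes for job histories.

    Exposed and unexposed codes are held in proportion to their share of
    the matrix (most participants hold some nominally exposed job), but
    within the exposed codes the commonly held occupations skew toward low
    exposure prevalence (secretaries, salespersons ...): weight is
    ``exp(-gamma * prevalence)``, renormalized within the exposed block.
    """
    codes = jem.codes("E")
    prev = np.array([jem.prevalence(c, "E") for c in codes])
    exposed = prev > 0
    w = np.ones(len(codes))
    if exposed.any() and (~exposed).any():
        frac = exposed.mean()
        we = np.exp(-gamma * prev[exposed])
        w[exposed] = frac * we / we.sum()
        w[~exposed] = (1.0 - frac) / (~exposed).sum()
    elif exposed.any():
        we = np.exp(-gamma * prev[exposed])
        w[exposed] = we / we.sum()
    return codes, w / w.sum()


def _sample_history(rng, cfg: SyntheticConfig, codes, code_p,
                    birth_year: int, interview_year: int) -> list[dict]:
    """Sequential job spells from workforce entry to interview, with
    occasional gaps, overlaps and nonstandard periods."""
    start_age = int(rng.integers(16, 25))
    year = birth_year + start_age
    horizon = interview_year
    if year >= horizon:
        year = horizon - 1
    n_jobs = 1 + rng.poisson(max(cfg.mean_jobs - 1.0, 0.0))
    span = max(horizon - year, 1)
    mean_dur = max(span / n_jobs, 1.5)
    spells = []
    for _ in range(n_jobs):
        if year > horizon:
            break
        duration = 1 + rng.geometric(1.0 / mean_dur)
        end = min(year + duration - 1, horizon)
        nonstandard = rng.random() < cfg.nonstandard_prob
        code = None if nonstandard else str(rng.choice(codes, p=code_p))
        spells.append({"start_year": int(year), "end_year": int(end),
                       "isco88": code, "nonstandard": bool(nonstandard)})
        if rng.random() < cfg.overlap_prob:
            year = max(end - int(rng.integers(1, 4)), year) + 1
        elif rng.random() < cfg.gap_prob:
            year = end + 1 + int(rng.integers(1, 4))
        else:
            year = end + 1
    return spells


def _solve_intercept(lp_offsets: np.ndarray, target: float) -> float:
    """Scalar intercept making the mean case probability hit the target."""
    def mean_p(alpha):
        return expit(alpha + lp_offsets).mean() - target
    return brentq(mean_p, -20.0, 20.0)


def generate_cohort(
    cfg: SyntheticConfig, jem: Jem, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate participants, job histories and outcomes with known truth.

    True exposure is computed through the package's own exposure machinery
    (all-jobs linkage, configured field/metric/label, reference year =
    interview year) and drives a logistic disease model with the configured
    per-category log odds ratios.  Returns (participants, jobs, truth);
    the truth record carries everything a recovery test needs.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_total = cfg.n_controls + cfg.n_glioma + cfg.n_meningioma
    codes, code_p = _job_code_weights(jem, cfg.code_frequency_gamma)

    pids = [f"P{i:06d}" for i in range(n_total)]
    age_p = np.asarray(AGE_WEIGHTS) / np.sum(AGE_WEIGHTS)
    region_p = np.asarray(REGION_WEIGHTS) / np.sum(REGION_WEIGHTS)
    age_groups = rng.choice(AGE_GROUPS, size=n_total, p=age_p)
    ages = np.array([int(rng.integers(AGE_BOUNDS[g][0], AGE_BOUNDS[g][1] + 1))
                     for g in age_groups])
    sexes = np.where(rng.random(n_total) < 0.558, "female", "male")
    regions = rng.choice(REGIONS, size=n_total, p=region_p)
    educations = rng.choice(list(EDUCATION_WEIGHTS), size=n_total,
                            p=list(EDUCATION_WEIGHTS.values()))
    lo, hi = cfg.interview_years
    interviews = rng.integers(lo, hi + 1, size=n_total)

    job_rows: list[dict] = []
    for i, pid in enumerate(pids):
        birth = int(interviews[i]) - int(ages[i])
        for spell in _sample_history(rng, cfg, codes, code_p, birth,
                                     int(interviews[i])):
            code = spell["isco88"]
            prev = jem.prevalence(code, "E") if code else 0.0
            truly_exposed = bool(rng.random() < prev)
            if truly_exposed:
                reported = rng.random() < cfg.source_report_sensitivity
            else:
                reported = rng.random() > cfg.source_report_specificity
            job_rows.append({
                "pid": pid, **spell,
                "source_reported": bool(reported) and not spell["nonstandard"],
                "source_uncertain": False,
                "_truly_exposed": truly_exposed,
            })
    jdf = pd.DataFrame(job_rows)

    pdf = pd.DataFrame({
        "pid": pids,
        "status": "control",
        "diagnosis_year": pd.array([pd.NA] * n_total, dtype="Int64"),
        "interview_year": pd.array(interviews, dtype="Int64"),
        "age_group": age_groups,
        "sex": sexes,
        "region": regions,
        "education": educations,
        "proxy": rng.random(n_total) < cfg.proxy_prob,
        "grade": "na",
        "preexisting_condition": rng.random(n_total) < cfg.preexisting_prob,
    })

    # True exposure category via the package's own metric machinery.  The
    # effect is defined at reference year = interview - 1, matching what the
    # analysis reconstructs (diagnosis year for cases, interview minus the
    # cases' median diagnosis-interview gap for controls; the gap is 1 at
    # the median below).
    ref = pd.Series(interviews.astype(int) - 1, index=pids)
    jdf_typed = jdf.copy()
    jdf_typed["start_year"] = jdf_typed["start_year"].astype("Int64")
    jdf_typed["end_year"] = jdf_typed["end_year"].astype("Int64")
    profiles = exposure.compute_profiles(
        pdf, jdf_typed, jem, ref,
        methods=(cfg.effect_method,), fields=(cfg.effect_field,),
        labels=(cfg.effect_label,),
    )
    values = profiles.set_index("pid")["cumulative"].reindex(pids).to_numpy()
    exposed = values > 0
    if exposed.any():
        cps = categorize.cutpoints(values[exposed])
        cats = categorize.assign_categories(values, exposed, cps)
    else:
        cats = np.zeros(n_total, dtype=int)

    beta = np.asarray(cfg.true_log_or, dtype=float)
    lp = np.where(cats > 0, beta[np.maximum(cats - 1, 0)], 0.0)
    strata = pd.Series(
        [f"{a}|{s}|{r}" for a, s, r in zip(age_groups, sexes, regions)],
        index=pdf.index,
    )
    unique_strata = strata.unique()
    stratum_eff = dict(zip(unique_strata,
                           rng.normal(0.0, cfg.stratum_sd, len(unique_strata))))
    offsets = lp + strata.map(stratum_eff).to_numpy()
    target = (cfg.n_glioma + cfg.n_meningioma) / n_total
    alpha = _solve_intercept(offsets, target)
    p_case = expit(alpha + offsets)
    is_case = rng.random(n_total) < p_case
    glioma_share = cfg.n_glioma / max(cfg.n_glioma + cfg.n_meningioma, 1)
    tumor = np.where(rng.random(n_total) < glioma_share, "glioma", "meningioma")
    pdf.loc[is_case, "status"] = tumor[is_case]

    gaps = rng.choice([0, 1, 2], size=n_total, p=[0.15, 0.70, 0.15])
    diag = interviews - gaps
    pdf.loc[is_case, "diagnosis_year"] = diag[is_case]
    gli = pdf["status"] == "glioma"
    pdf.loc[gli, "grade"] = np.where(rng.random(int(gli.sum())) < 0.4,
                                     "low", "high")

    _inject_exclusions(rng, cfg, pdf, jdf)
    jdf = jdf[jdf["pid"].isin(set(pdf["pid"]))]  # no-op; keeps pids aligned
    jdf = jdf.drop(columns=["_truly_exposed"]).reset_index(drop=True)
    jdf["start_year"] = jdf["start_year"].astype("Int64")
    jdf["end_year"] = jdf["end_year"].astype("Int64")

    truth = {
        "true_log_or": list(beta),
        "alpha": float(alpha),
        "effect": {"field": cfg.effect_field, "method": cfg.effect_method,
                   "label": cfg.effect_label, "metric": "cumulative"},
        "category": {pid: int(c) for pid, c in zip(pids, cats)},
        "stratum": {pid: s for pid, s in zip(pids, strata)},
        "case_fraction_target": target,
    }
    return pdf, jdf, truth


def _inject_exclusions(rng, cfg: SyntheticConfig, pdf: pd.DataFrame,
                       jdf: pd.DataFrame) -> None:
    """Mutate a configured fraction of participants to violate each of the
    ordered exclusion criteria (mutually exclusive, first match wins)."""
    rates = cfg.exclusion_rates
    if not any(rates):
        return
    jobs_by_pid = jdf.groupby("pid").indices
    draws = rng.random((len(pdf), len(rates)))
    for i, row in enumerate(pdf.itertuples()):
        hit = next((k for k in range(len(rates)) if draws[i, k] < rates[k]), None)
        if hit is None:
            continue
        idx = jobs_by_pid.get(row.pid)
        if hit == 0:
            if idx is not None and len(idx):
                jdf.loc[jdf.index[idx[0]], "source_uncertain"] = True
        elif hit == 1:
            pdf.loc[row.Index, "education"] = "missing"
        elif hit == 2 and idx is not None and len(idx):
            jdf.loc[jdf.index[idx[0]], "end_year"] = None
        elif hit == 3 and idx is not None and len(idx):
            jdf.loc[jdf.index[list(idx)], "nonstandard"] = True
            jdf.loc[jdf.index[list(idx)], "isco88"] = None
            jdf.loc[jdf.index[list(idx)], "source_reported"] = False
        elif hit == 4 and idx is not None and len(idx):
            jdf.loc[jdf.index[idx[0]], "isco88"] = "UNKNOWN"
            jdf.loc[jdf.index[idx[0]], "nonstandard"] = False


def cohort_from_margins(margins: dict[str, dict[str, dict[str, int]]],
                        interview_year: int = 2002) -> pd.DataFrame:
    """Deterministic participant table matching given per-status marginal counts.

    ``margins[status][variable][level] = count``; every variable's counts
    must sum to the same group size.  Columns are filled independently
    (level blocks in the given order), which reproduces each variable's
    margin exactly — sufficient for summary-table checks, which look at one
    variable at a time.
    """
    frames = []
    for status, by_var in margins.items():
        sizes = {v: sum(c.values()) for v, c in by_var.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"margins for {status} disagree on group size: {sizes}")
        n = next(iter(sizes.values()))
        data = {"pid": [f"{status[:3]}{i:05d}" for i in range(n)],
                "status": status}
        for variable, counts in by_var.items():
            col: list[str] = []
            for level, k in counts.items():
                col.extend([level] * k)
            data[variable] = col
        df = pd.DataFrame(data)
        df["interview_year"] = interview_year
        df["diagnosis_year"] = (interview_year - 1 if status != "control"
                                else pd.NA)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col, default in (("age_group", "50-54"), ("sex", "female"),
                         ("region", "RegionA"),
                         ("education", "high_school_or_less"),
                         ("proxy", False), ("grade", "na"),
                         ("preexisting_condition", False)):
        if col not in out.columns:
            out[col] = default
    out["diagnosis_year"] = out["diagnosis_year"].astype("Int64")
    out["interview_year"] = out["interview_year"].astype("Int64")
    return out


def exclusion_scenario(
    initial: dict[str, int],
    excluded: dict[str, tuple[int, int, int, int, int]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic cohort in which exactly the given numbers of
    participants violate each of the five ordered exclusion criteria.

    ``initial`` gives group sizes per status; ``excluded[status]`` the
    count per criterion, in cascade order.  Remaining participants are
    clean.  Violators violate exactly one criterion each.
    """
    prows, jrows = [], []
    for status, n in initial.items():
        counts = excluded.get(status, (0, 0, 0, 0, 0))
        if sum(counts) > n:
            raise ValueError(f"more exclusions than participants for {status}")
        labels = [k for k, c in enumerate(counts) for _ in range(c)]
        labels += [None] * (n - len(labels))
        for i, crit in enumerate(labels):
            pid = f"{status[:3]}{i:05d}"
            prows.append({
                "pid": pid, "status": status,
                "diagnosis_year": 2001 if status != "control" else pd.NA,
                "interview_year": 2002, "age_group": "50-54", "sex": "female",
                "region": "RegionA",
                "education": "missing" if crit == 1 else "high_school_or_less",
                "proxy": False, "grade": "na", "preexisting_condition": False,
            })
            job = {"pid": pid, "start_year": 1980, "end_year": 2000,
                   "isco88": "2000", "nonstandard": False,
                   "source_reported": False, "source_uncertain": False}
            if crit == 0:
                job["source_uncertain"] = True
            elif crit == 2:
                job["end_year"] = pd.NA
            elif crit == 3:
                job["nonstandard"] = True
                job["isco88"] = pd.NA
            elif crit == 4:
                job["isco88"] = UNKNOWN_CODE
            jrows.append(job)
    pdf = pd.DataFrame(prows)
    jdf = pd.DataFrame(jrows)
    pdf["diagnosis_year"] = pdf["diagnosis_year"].astype("Int64")
    pdf["interview_year"] = pdf["interview_year"].astype("Int64")
    jdf["start_year"] = jdf["start_year"].astype("Int64")
    jdf["end_year"] = jdf["end_year"].astype("Int64")
    return pdf, jdf


def write_study(pdf: pd.DataFrame, jdf: pd.DataFrame, jem: Jem, truth: dict,
                outdir) -> dict[str, Path]:
    """Write jem.csv, participants.csv, jobs.csv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "jem": outdir / "jem.csv",
        "participants": outdir / "participants.csv",
        "jobs": outdir / "jobs.csv",
        "truth": outdir / "truth.json",
    }
    write_jem(jem, paths["jem"])
    pdf.to_csv(paths["participants"], index=False)
    jdf.to_csv(paths["jobs"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain mapping (e.g. parsed YAML), with
    tuple-valued fields accepted as lists."""
    cfg = SyntheticConfig()
    valid = set(asdict(cfg))
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    for k, v in d.items():
        current = getattr(cfg, k)
        if isinstance(current, tuple) and isinstance(v, (list, tuple)):
            v = tuple(v)
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
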
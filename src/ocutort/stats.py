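"""Cohort-level statistics for tortuosity studies.

Implements the study's analysis plan: per-site Mann-Whitney comparisons of
each tortuosity index between the affected (FD) and control groups and
between sexes, ordinary least squares regressions of tortuosity on age and
on systemic severity markers (GFR, maximum wall thickness), a per-metric
regression of conjunctival on retinal tortuosity, and demographic
summaries. Significance is assessed at alpha = 0.05 with no multiplicity
correction (the design always compares exactly two groups).

The unit of analysis defaults to the subject: segment values are averaged
within each eye, then eye means are averaged, avoiding pseudo-replication
from two correlated eyes. A per-eye mode is available through
:class:`StatsConfig`.

The Mann-Whitney test uses exact two-sided p-values by full enumeration of
rank assignments for small samples without ties (n1 + n2 <= 16 by
default), and a tie-corrected normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "SubjectRecord",
    "TestResult",
    "RegressionResult",
    "StatsConfig",
    "StudyReport",
    "aggregate_to_subject",
    "mann_whitney",
    "ols_regression",
    "summarize_demographics",
    "run_study",
    "load_fabry_cohort",
]

METRICS = ("soam", "pad", "i2e")
CONJ_SITES = ("conj_nasal", "conj_temporal", "conj_superior", "conj_inferior")


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject with group, demographics and optional covariates."""

    subject_id: str
    group: str  # "FD" | "control"
    sex: str  # "M" | "F"
    age: float
    gfr: Optional[float] = None  # mL/min
    mwt: Optional[float] = None  # mm (interventricular maximum wall thickness)
    nyha: Optional[int] = None  # NYHA class 1-4
    stroke: Optional[bool] = None
    phenotype: Optional[str] = None
    mutation: Optional[str] = None
    therapy: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in ("FD", "control"):
            raise ValueError(f"group must be 'FD' or 'control', got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.gfr is not None and not self.gfr > 0:
            raise ValueError("gfr must be positive when present")
        if self.nyha is not None and self.nyha not in (1, 2, 3, 4):
            raise ValueError("nyha must be in {1,2,3,4} when present")


@dataclass(frozen=True)
class TestResult:
    """Two-sample rank test outcome."""

    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx_tie_corrected"


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression y ~ x outcome."""

    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    aggregation: str = "subject"  # or "eye"
    exact_threshold: int = 16  # max n1+n2 for exact enumeration

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.aggregation not in ("subject", "eye"):
            raise ValueError("aggregation must be 'subject' or 'eye'")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midrank sums. For small samples without ties
    (n1 + n2 <= 16) the two-sided p-value is exact, obtained by
    enumerating all C(n1+n2, n1) rank assignments; two-sided p equals
    min(1, 2 * min(P(U <= u), P(U >= u))). Larger or tied samples use the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    return _mann_whitney(x, y)


def _mann_whitney(x, y, exact_threshold: int = 16) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate((x, y))
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(counts > 1))

    if not has_ties and n1 + n2 <= exact_threshold:
        p = _exact_two_sided_p(ranks, n1, u1)
        return TestResult(statistic=u1, p_value=p, n1=n1, n2=n2, method="exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        p = 1.0
    else:
        z = max(abs(u1 - mu) - 0.5, 0.0) / math.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(
        statistic=u1, p_value=p, n1=n1, n2=n2, method="normal_approx_tie_corrected"
    )


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact p by enumerating every assignment of n1 ranks to sample 1."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    le = ge = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
        total += 1
    one_sided = min(le, ge) / total
    return min(1.0, 2.0 * one_sided)


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a t-test on the slope."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        t_statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared) if np.isfinite(model.rsquared) else 0.0,
        n=int(x.size),
    )


def aggregate_to_subject(
    metrics: pd.DataFrame, mode: str = "subject"
) -> pd.DataFrame:
    """Collapse segment-level metric rows to the unit of analysis.

    ``mode='subject'`` averages segments within each eye, then averages
    eye means — one row per subject x site. ``mode='eye'`` stops at the
    eye level. Warns when a subject contributes a single eye at a site.
    """
    required = {"subject_id", "eye", "site", "segment_id", *METRICS}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    eye_means = (
        metrics.groupby(["subject_id", "site", "eye"], as_index=False)[list(METRICS)]
        .mean()
    )
    if mode == "eye":
        return eye_means
    if mode != "subject":
        raise ValueError("mode must be 'subject' or 'eye'")
    n_eyes = eye_means.groupby(["subject_id", "site"])["eye"].nunique()
    single = n_eyes[n_eyes < 2]
    for (sid, site) in single.index:
        warnings.warn(
            f"subject {sid} contributes a single eye at site {site}; "
            "using that eye's mean",
            stacklevel=2,
        )
    return (
        eye_means.groupby(["subject_id", "site"], as_index=False)[list(METRICS)]
        .mean()
    )


def summarize_demographics(records: Sequence[SubjectRecord]) -> Dict[str, dict]:
    """Per-group n, sex counts, mean/SD (n-1)/range of age."""
    if not records:
        raise ValueError("no subject records")
    out: Dict[str, dict] = {}
    for group in sorted({r.group for r in records}):
        ages = np.array([r.age for r in records if r.group == group], dtype=float)
        sexes = [r.sex for r in records if r.group == group]
        out[group] = {
            "n": int(ages.size),
            "n_male": sexes.count("M"),
            "n_female": sexes.count("F"),
            "age_mean": float(ages.mean()),
            "age_sd": float(ages.std(ddof=1)) if ages.size > 1 else None,
            "age_min": float(ages.min()),
            "age_max": float(ages.max()),
        }
    return out


@dataclass
class StudyReport:
    """Machine-readable container for every comparison in the study."""

    demographics: Dict[str, dict] = field(default_factory=dict)
    group_tests: List[dict] = field(default_factory=list)
    sex_tests: List[dict] = field(default_factory=list)
    regressions: List[dict] = field(default_factory=list)
    retina_conjunctiva: List[dict] = field(default_factory=list)
    skipped: List[dict] = field(default_factory=list)
    alpha: float = 0.05

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=_jsonify)

    def tests_frame(self) -> pd.DataFrame:
        """Flat table of all tests: comparison, site, metric, n1, n2, ..."""
        rows = []
        for r in self.group_tests + self.sex_tests:
            rows.append(
                {
                    "comparison": r["comparison"],
                    "site": r["site"],
                    "metric": r["metric"],
                    "n1": r["n1"],
                    "n2": r["n2"],
                    "statistic": r["statistic"],
                    "p_value": r["p_value"],
                    "method": r["method"],
                    "significant": r["significant"],
                }
            )
        for r in self.regressions + self.retina_conjunctiva:
            rows.append(
                {
                    "comparison": r["comparison"],
                    "site": r.get("site", ""),
                    "metric": r["metric"],
                    "n1": r["n"],
                    "n2": r["n"],
                    "statistic": r["t_statistic"],
                    "p_value": r["p_value"],
                    "method": "ols",
                    "significant": r["significant"],
                }
            )
        return pd.DataFrame(rows)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _skip(report: StudyReport, comparison: str, reason: str, **ctx) -> None:
    report.skipped.append({"comparison": comparison, "reason": reason, **ctx})


def run_study(
    metrics: pd.DataFrame,
    records: Sequence[SubjectRecord],
    config: StatsConfig = StatsConfig(),
) -> StudyReport:
    """Run the full comparison plan and return a :class:`StudyReport`.

    Comparisons (per tortuosity metric and ocular site): FD vs control
    Mann-Whitney; male vs female within each group; OLS of metric on age
    within each group; OLS on GFR and MWT within FD where recorded; plus
    a per-metric regression of mean conjunctival on retinal tortuosity.
    Missing covariates or empty strata are recorded as skipped, never
    dropped silently. p < alpha is flagged significant; no multiplicity
    adjustment is applied.
    """
    rec_by_id = {r.subject_id: r for r in records}
    unknown = set(metrics["subject_id"]) - set(rec_by_id)
    if unknown:
        raise ValueError(f"metric rows for subjects absent from records: {sorted(unknown)}")

    agg = aggregate_to_subject(metrics, mode=config.aggregation)
    agg = agg.merge(
        pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "sex": r.sex,
                    "age": r.age,
                    "gfr": r.gfr,
                    "mwt": r.mwt,
                }
                for r in records
            ]
        ),
        on="subject_id",
        how="left",
    )
    report = StudyReport(alpha=config.alpha)
    report.demographics = summarize_demographics(records)
    sites = sorted(agg["site"].unique(), key=lambda s: (s != "retina", s))

    for site in sites:
        at_site = agg[agg["site"] == site]
        for metric in METRICS:
            fd = at_site.loc[at_site["group"] == "FD", metric].dropna()
            ctl = at_site.loc[at_site["group"] == "control", metric].dropna()
            name = "FD_vs_control"
            if len(fd) and len(ctl):
                t = _mann_whitney(fd, ctl, exact_threshold=config.exact_threshold)
                report.group_tests.append(
                    {
                        "comparison": name, "site": site, "metric": metric,
                        "n1": t.n1, "n2": t.n2, "statistic": t.statistic,
                        "p_value": t.p_value, "method": t.method,
                        "significant": bool(t.p_value < config.alpha),
                    }
                )
            else:
                _skip(report, name, "empty group", site=site, metric=metric)

            for group in ("FD", "control"):
                sub = at_site[at_site["group"] == group]
                m = sub.loc[sub["sex"] == "M", metric].dropna()
                f = sub.loc[sub["sex"] == "F", metric].dropna()
                name = f"M_vs_F_{group}"
                if len(m) and len(f):
                    t = _mann_whitney(m, f, exact_threshold=config.exact_threshold)
                    report.sex_tests.append(
                        {
                            "comparison": name, "site": site, "metric": metric,
                            "n1": t.n1, "n2": t.n2, "statistic": t.statistic,
                            "p_value": t.p_value, "method": t.method,
                            "significant": bool(t.p_value < config.alpha),
                        }
                    )
                else:
                    _skip(report, name, "empty sex stratum", site=site, metric=metric)

            # regressions on age (both groups) and on systemic markers (FD)
            reg_plan = [("age", "FD"), ("age", "control"), ("gfr", "FD"), ("mwt", "FD")]
            for cov, group in reg_plan:
                sub = agg[(agg["site"] == site) & (agg["group"] == group)]
                sub = sub[[cov, metric]].dropna()
                name = f"{metric}_vs_{cov}_{group}"
                if len(sub) < 3:
                    _skip(report, name, f"fewer than 3 subjects with {cov}", site=site, metric=metric)
                    continue
                if np.ptp(sub[cov].to_numpy()) == 0:
                    _skip(report, name, f"constant covariate {cov}", site=site, metric=metric)
                    continue
                r = ols_regression(sub[cov], sub[metric])
                report.regressions.append(
                    {
                        "comparison": name, "site": site, "metric": metric,
                        "covariate": cov, "group": group,
                        "slope": r.slope, "intercept": r.intercept,
                        "slope_se": r.slope_se, "t_statistic": r.t_statistic,
                        "p_value": r.p_value, "r_squared": r.r_squared, "n": r.n,
                        "significant": bool(r.p_value < config.alpha),
                    }
                )

    # association between retinal and (mean) conjunctival tortuosity
    wide = agg.pivot_table(index="subject_id", columns="site", values=list(METRICS))
    for metric in METRICS:
        name = "conjunctiva_vs_retina"
        try:
            retina = wide[(metric, "retina")]
            conj_cols = [c for c in wide[metric].columns if c in CONJ_SITES]
            if not conj_cols:
                raise KeyError
        except KeyError:
            _skip(report, name, "retina or conjunctival sites absent", metric=metric)
            continue
        conj = wide[metric][conj_cols].mean(axis=1)
        both = pd.DataFrame({"retina": retina, "conj": conj}).dropna()
        if len(both) < 3 or np.ptp(both["retina"].to_numpy()) == 0:
            _skip(report, name, "insufficient paired data", metric=metric)
            continue
        r = ols_regression(both["retina"], both["conj"])
        report.retina_conjunctiva.append(
            {
                "comparison": name, "metric": metric,
                "slope": r.slope, "intercept": r.intercept,
                "slope_se": r.slope_se, "t_statistic": r.t_statistic,
                "p_value": r.p_value, "r_squared": r.r_squared, "n": r.n,
                "significant": bool(r.p_value < config.alpha),
            }
        )
    return report


def load_fabry_cohort() -> pd.DataFrame:
    """Load the packaged clinical table of the 11 FD patients.

    Columns: subject_id, group, sex, age, nyha, mwt (mm), gfr (mL/min),
    stroke, phenotype, cornea_verticillata, mutation, therapy — the
    published per-patient clinical findings of the case series.
    """
    with resources.files("ocutort.data").joinpath("fabry_cohort.csv").open() as fh:
        return pd.read_csv(fh)
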
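"""Disproportionality statistics: ROR, signal criteria, adjusted models.

The reporting odds ratio compares how disproportionately an outcome is
reported among exposed (interaction-group) reports against a comparator
(monotherapy) set.  With the 2x2 table

    =============  ==========  =============
    .              outcome     no outcome
    exposed        a           b
    comparator     c           d
    =============  ==========  =============

the point estimate, standard error and confidence interval are

    ROR = (a*d) / (b*c)
    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
    95% CI = exp(ln ROR +/- 1.96 * SE)

A signal requires a >= 3 and a CI lower bound strictly above 1.  Any zero
cell leaves the estimate undefined (no continuity correction is applied; the
a >= 3 rule already guards sparsity) and the signal flag false.

Adjusted odds ratios come from a maximum-likelihood logistic regression of
the outcome on the exposure indicator plus report-level covariates
(one-hot encoded with an explicit "missing" level).  The 1.96 multiplier is
used for all Wald intervals so crude and adjusted intervals are directly
comparable.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort

log = logging.getLogger(__name__)

Z95 = 1.96
#: Age bands used for baseline comparison and covariate adjustment.
AGE_BAND_EDGES = (0.0, 18.0, 60.0, 75.0, float("inf"))
AGE_BAND_LABELS = ("0-17", "18-59", "60-74", ">=75")

DEFAULT_COVARIATES = ("sex", "age_band", "reporter_type", "report_year")
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts underlying every ROR."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class RorResult:
    """Crude reporting odds ratio with Wald CI and the signal flag."""

    ror: float
    se_ln_ror: float
    ci_low: float
    ci_high: float
    a_count: int
    signal: bool
    stratum: tuple = ()
    table: Optional[ContingencyTable] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ror)


@dataclass(frozen=True)
class AdjustedResult:
    """Covariate-adjusted odds ratio from logistic regression."""

    aor: float
    ci_low: float
    ci_high: float
    covariates: tuple[str, ...]
    n_used: int
    converged: bool
    message: str = ""


def ror(table: ContingencyTable, stratum: tuple = ()) -> RorResult:
    """Crude ROR with Wald 95% CI; undefined (NaN) on any zero cell."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return RorResult(math.nan, math.nan, math.nan, math.nan,
                         a_count=a, signal=False, stratum=stratum, table=table)
    estimate = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ln = math.log(estimate)
    ci_low = math.exp(ln - Z95 * se)
    ci_high = math.exp(ln + Z95 * se)
    return RorResult(estimate, se, ci_low, ci_high, a_count=a,
                     signal=evaluate_signal_values(a, ci_low),
                     stratum=stratum, table=table)


def evaluate_signal_values(a_count: int, ci_low: float) -> bool:
    """Signal criterion: a >= 3 reports and CI lower bound strictly > 1."""
    return bool(a_count >= 3 and not math.isnan(ci_low) and ci_low > 1.0)


def evaluate_signal(result: RorResult) -> bool:
    return evaluate_signal_values(result.a_count, result.ci_low)


def _filter_mask(df: pd.DataFrame, spec: Mapping[str, str] | None) -> np.ndarray:
    mask = np.ones(len(df), dtype=bool)
    for key, value in (spec or {}).items():
        mask &= (df[key] == value).to_numpy()
    return mask


def make_table(cohort: Cohort, exposure_filter: Mapping[str, str] | None,
               outcome: str,
               comparator_filter: Mapping[str, str] | None = None,
               ) -> ContingencyTable:
    """Build the 2x2 table for one stratum and outcome.

    ``exposure_filter`` selects among interaction-group reports and
    ``comparator_filter`` among non-interaction (monotherapy) reports; the
    outcome column (``any_hemorrhage`` or ``ns_hemorrhage``) must already be
    present from event coding.  The two selections must be disjoint.
    """
    df = cohort.data
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not coded; run event coding first")
    exposed = (df["group"] == "interaction").to_numpy() & \
        _filter_mask(df, exposure_filter)
    comparator = (df["group"] == "non_interaction").to_numpy() & \
        _filter_mask(df, comparator_filter)
    if (exposed & comparator).any():
        raise ValueError("exposure and comparator filters select overlapping reports")
    flags = df[outcome].to_numpy(dtype=bool)
    a = int((exposed & flags).sum())
    b = int(exposed.sum()) - a
    c = int((comparator & flags).sum())
    d = int(comparator.sum()) - c
    return ContingencyTable(a, b, c, d)


def add_age_band(df: pd.DataFrame) -> pd.DataFrame:
    """Add the categorical ``age_band`` column derived from ``age_years``."""
    out = df.copy()
    band = pd.cut(pd.to_numeric(out["age_years"], errors="coerce"),
                  bins=AGE_BAND_EDGES, labels=AGE_BAND_LABELS,
                  right=False, include_lowest=True)
    out["age_band"] = band.astype(object).where(band.notna(), None)
    return out


def _design_matrix(records: pd.DataFrame, covariates: Sequence[str]
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Intercept + exposure + one-hot covariates with explicit missing level."""
    parts = {
        "const": np.ones(len(records)),
        "exposure": records["exposure"].to_numpy(dtype=float),
    }
    X = pd.DataFrame(parts, index=records.index)
    dropped = []
    for cov in covariates:
        col = records[cov].astype(object)
        col = col.where(pd.notna(col), "missing").astype(str)
        if col.nunique() < 2:
            dropped.append(cov)
            continue
        dummies = pd.get_dummies(col, prefix=cov, dtype=float)
        # reference level: drop the most frequent to keep the fit stable
        ref = col.value_counts().idxmax()
        dummies = dummies.drop(columns=f"{cov}_{ref}")
        X = pd.concat([X, dummies], axis=1)
    for name in list(X.columns):
        if name == "const":
            continue
        v = X[name].to_numpy()
        if v.min() == v.max():
            dropped.append(name)
            X = X.drop(columns=name)
    if dropped:
        warnings.warn(f"dropping constant design columns: {dropped}",
                      stacklevel=3)
    return X, dropped


def fit_logistic(records: pd.DataFrame,
                 covariates: Sequence[str] = (),
                 ) -> AdjustedResult:
    """Adjusted odds ratio of ``outcome`` on ``exposure`` by logistic MLE.

    ``records`` needs integer/boolean columns ``outcome`` and ``exposure``
    plus any requested covariate columns.  Categorical covariates are one-hot
    encoded with an explicit "missing" level; constant columns are dropped
    with a warning.  The fit is Newton-type maximum likelihood (tolerance
    1e-8, at most 100 iterations).  Non-convergence, or a coefficient beyond
    +/-15 in absolute value (a separation symptom), is reported via
    ``converged=False`` with a diagnostic message.

    Raises
    ------
    ValueError
        If the outcome is constant (no information about any odds ratio) or
        an exposure arm is empty.
    """
    import statsmodels.api as sm

    y = records["outcome"].to_numpy(dtype=float)
    if len(np.unique(records["exposure"].to_numpy())) < 2:
        raise ValueError("both exposure arms must be represented")
    if y.min() == y.max():
        raise ValueError("outcome is constant; odds ratios are undefined")
    X, _ = _design_matrix(records, covariates)

    message = ""
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, method="newton",
                                     maxiter=100, tol=1e-8)
        except Exception as exc:  # PerfectSeparationError and friends
            return AdjustedResult(math.nan, math.nan, math.nan,
                                  tuple(covariates), len(records),
                                  converged=False,
                                  message=f"fit failed: {exc}")
    if not fit.mle_retvals.get("converged", True):
        converged = False
        message = "maximum-likelihood iteration did not converge"
    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    if np.abs(params.to_numpy()).max() > SEPARATION_BOUND:
        converged = False
        worst = params.abs().idxmax()
        message = (f"possible separation: |coef[{worst}]| = "
                   f"{abs(params[worst]):.2f} > {SEPARATION_BOUND}")
    beta = params["exposure"]
    se = bse["exposure"]
    return AdjustedResult(
        aor=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        covariates=tuple(covariates),
        n_used=len(records),
        converged=converged,
        message=message,
    )


@dataclass
class BaselineTable:
    """Between-group baseline characteristics.

    ``continuous`` has one row per (variable, group) with n, mean, sd,
    median, q1, q3; ``categorical`` one row per (variable, level) with
    per-group counts and percentages of the non-missing totals (missing shown
    as its own level, excluded from the test); ``pvalues`` maps variable ->
    Welch-t (continuous) or Pearson chi-square (categorical) p-value;
    ``countries`` lists the top-3 reporting countries per group.
    """

    continuous: pd.DataFrame
    categorical: pd.DataFrame
    pvalues: dict[str, float]
    countries: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Publication-style long table with formatted cells."""
        rows = []
        for var in self.continuous["variable"].unique():
            sub = self.continuous[self.continuous["variable"] == var]
            cells = {}
            for r in sub.itertuples(index=False):
                cells[r.group] = (f"{r.median:.0f} ({r.q1:.0f}, {r.q3:.0f})")
            rows.append({"variable": var, "level": "median (Q1, Q3)",
                         **cells, "p": self.pvalues.get(var)})
        for (var, level), sub in self.categorical.groupby(
                ["variable", "level"], sort=False):
            r = sub.iloc[0]
            def fmt(n, pct):
                return f"{int(n):,}" if pd.isna(pct) else f"{int(n):,} ({pct:.1f}%)"
            rows.append({
                "variable": var, "level": level,
                "interaction": fmt(r["n_interaction"], r["pct_interaction"]),
                "non_interaction": fmt(r["n_non_interaction"],
                                       r["pct_non_interaction"]),
                "p": self.pvalues.get(var),
            })
        return pd.DataFrame(rows)


def _chi2_p(counts: pd.DataFrame) -> float:
    """Pearson chi-square p for a levels x groups count table."""
    table = counts.to_numpy(dtype=float)
    table = table[table.sum(axis=1) > 0]
    if (table.size == 0) or (table.sum(axis=0) == 0).any():
        return math.nan
    if table.shape[0] < 2:
        return 1.0  # a single represented level: proportions identical
    # identical proportions give statistic 0 -> p = 1
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p)


def baseline_table(cohort: Cohort) -> BaselineTable:
    """Table-style baseline comparison of the two analysis groups.

    Age is summarized as median (Q1, Q3) and mean +/- sd and compared with a
    Welch t-test; sex, age band, report year and reporter type are compared
    with Pearson chi-square tests on non-missing counts.
    """
    df = cohort.data
    if "age_band" not in df.columns:
        df = add_age_band(df)
    groups = {"interaction": df[df["group"] == "interaction"],
              "non_interaction": df[df["group"] == "non_interaction"]}
    for name, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"baseline table needs a non-empty {name} group")

    pvalues: dict[str, float] = {}

    cont_rows = []
    ages = {}
    for name, g in groups.items():
        x = pd.to_numeric(g["age_years"], errors="coerce").dropna()
        ages[name] = x
        cont_rows.append({
            "variable": "age_years", "group": name, "n": len(x),
            "mean": x.mean(), "sd": x.std(ddof=1),
            "median": x.median(), "q1": x.quantile(0.25),
            "q3": x.quantile(0.75),
        })
    if min(len(x) for x in ages.values()) >= 2:
        pvalues["age_years"] = float(sps.ttest_ind(
            ages["interaction"], ages["non_interaction"], equal_var=False).pvalue)
    else:
        pvalues["age_years"] = math.nan

    cat_rows = []
    cat_specs = {
        "age_band": list(AGE_BAND_LABELS),
        "sex": ["F", "M"],
        "report_year": sorted(df["report_year"].dropna().unique()),
        "reporter_type": ["physician", "pharmacist", "lawyer", "consumer",
                          "other_health_professional"],
    }
    for var, levels in cat_specs.items():
        counts = {}
        for name, g in groups.items():
            col = g[var]
            counts[name] = col.value_counts(dropna=True)
        totals = {name: counts[name].reindex(levels).fillna(0).sum()
                  for name in groups}
        for level in levels:
            row = {"variable": var, "level": str(level)}
            for name in groups:
                nlev = int(counts[name].get(level, 0))
                row[f"n_{name}"] = nlev
                row[f"pct_{name}"] = (100.0 * nlev / totals[name]
                                      if totals[name] else math.nan)
            cat_rows.append(row)
        miss_row = {"variable": var, "level": "missing"}
        for name, g in groups.items():
            miss_row[f"n_{name}"] = int(g[var].isna().sum())
            miss_row[f"pct_{name}"] = math.nan
        cat_rows.append(miss_row)
        count_table = pd.DataFrame(
            {name: [counts[name].get(level, 0) for level in levels]
             for name in groups}, index=[str(l) for l in levels])
        pvalues[var] = _chi2_p(count_table)

    country_rows = []
    for name, g in groups.items():
        top = g["country"].dropna().value_counts().head(3)
        for rank, (ctry, cnt) in enumerate(top.items(), start=1):
            country_rows.append({"group": name, "rank": rank,
                                 "country": ctry, "n": int(cnt)})
    return BaselineTable(
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
        pvalues=pvalues,
        countries=pd.DataFrame(country_rows,
                               columns=["group", "rank", "country", "n"]),
    )
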
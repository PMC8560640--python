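"""Cohort-level outcome analyses for transit-time biomarkers.

Implements the statistical pipeline applied to PTT/PBVi cohorts:

* group comparisons (t-test or Mann-Whitney after a normality screen,
  chi-square for categoricals);
* Spearman rank correlations;
* multivariable OLS of log_e(PTT) on clinical covariates;
* Cox proportional-hazards models reporting the hazard ratio per one
  standard deviation of the predictor, with Schoenfeld-residual
  diagnostics and an optional penalized sensitivity refit;
* Kaplan-Meier curves dichotomized at the cohort mean with a log-rank test;
* a sensitivity analysis censoring subjects revascularized within 90 days.

Ties in the Cox partial likelihood use the Efron approximation.  p-values
are reported unadjusted (no multiple-testing correction).  Death is treated
as censoring in the MACE analysis; competing-risks modeling is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.stats.diagnostic import kstest_normal

DAYS_PER_MONTH = 365.25 / 12.0

#: covariate set of the log-PTT regression
LOG_PTT_COVARIATES = (
    "la_area_index", "heart_rate", "age", "atrial_fibrillation",
    "lvef", "diabetes", "hypertension", "rest_mbf", "male",
)

#: adjustment set of the primary MACE Cox model
COX_COVARIATES = ("age", "male", "lvef", "diabetes", "hypertension", "lge_present")


# --------------------------------------------------------------------------
# descriptive comparisons and correlations
# --------------------------------------------------------------------------

def _is_binary(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def compare_groups(cohort: pd.DataFrame, group_col: str,
                   variables: list | None = None,
                   normality_alpha: float = 0.05) -> pd.DataFrame:
    """Compare two groups variable by variable.

    Continuous variables: two-tailed unpaired t-test when a Lilliefors
    (Kolmogorov-Smirnov) normality screen passes in both groups, otherwise
    a Mann-Whitney U test; summarized as median (IQR).  Binary variables:
    chi-square on the 2x2 table; summarized as n (%).  Groups smaller than
    3 subjects get descriptive output only (p = NaN).
    """
    groups = sorted(pd.unique(cohort[group_col].dropna()))
    if len(groups) != 2:
        raise ValueError(f"{group_col} must define exactly 2 groups, found {len(groups)}")
    g0 = cohort[cohort[group_col] == groups[0]]
    g1 = cohort[cohort[group_col] == groups[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (group_col, "id") and
                     pd.api.types.is_numeric_dtype(cohort[c])]
    too_small = min(len(g0), len(g1)) < 3

    rows = []
    for var in variables:
        a, b = g0[var].dropna(), g1[var].dropna()
        if _is_binary(cohort[var]):
            summ0 = f"{int(a.sum())} ({100 * a.mean():.1f}%)"
            summ1 = f"{int(b.sum())} ({100 * b.mean():.1f}%)"
            if too_small:
                test, p = "none", np.nan
            else:
                table = np.array([[a.sum(), len(a) - a.sum()],
                                  [b.sum(), len(b) - b.sum()]], dtype=float)
                if np.any(table.sum(axis=0) == 0):
                    # identical degenerate columns: no association testable
                    test, p = "chi-square", 1.0
                else:
                    _, p, _, _ = stats.chi2_contingency(table)
                    test = "chi-square"
        else:
            def iqr(x):
                q1, q3 = np.percentile(x, [25, 75])
                return f"{np.median(x):.2f} ({q1:.2f}-{q3:.2f})"
            summ0, summ1 = iqr(a), iqr(b)
            if too_small:
                test, p = "none", np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    normal = all(kstest_normal(np.asarray(x, dtype=float))[1] > normality_alpha
                                 for x in (a, b) if x.nunique() > 1)
                if normal:
                    _, p = stats.ttest_ind(a, b)
                    test = "t-test"
                else:
                    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    test = "mann-whitney"
        rows.append({"variable": var, f"group_{groups[0]}": summ0,
                     f"group_{groups[1]}": summ1, "test": test, "p_value": p})
    return pd.DataFrame(rows)


def correlate(cohort: pd.DataFrame, var_pairs: list) -> pd.DataFrame:
    """Spearman rank correlation for each (x, y) pair of column names."""
    rows = []
    for x, y in var_pairs:
        sub = cohort[[x, y]].dropna()
        if len(sub) < 10:
            raise ValueError(f"need at least 10 paired observations for ({x}, {y})")
        flagged = ""
        if sub[x].nunique() == 1 or sub[y].nunique() == 1:
            rho, p, flagged = np.nan, np.nan, "constant_variable"
        else:
            rho, p = stats.spearmanr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "rho": rho, "p_value": p, "flag": flagged})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# log-PTT multivariable regression
# --------------------------------------------------------------------------

@dataclass
class LinearModelResult:
    """Per-covariate estimates of the log-PTT OLS model."""

    table: pd.DataFrame  # beta, ci_low, ci_high, std_beta, p per covariate
    r2: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "n": self.n,
                "coefficients": self.table.to_dict(orient="index")}


def _name_collinear(X: pd.DataFrame) -> list:
    from scipy.linalg import qr
    _, r, piv = qr(X.to_numpy(), pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return [X.columns[i] for i in piv[rank:]]


class LogPTTRegression(BaseEstimator):
    """OLS of log_e(PTT) on clinical covariates.

    Reports unstandardized betas with 95% CI, standardized betas
    (beta * SD_x / SD_y) and the model r^2.  Complete cases must number at
    least ten per covariate; a rank-deficient design raises an error naming
    the collinear columns.
    """

    def __init__(self, covariates: tuple = LOG_PTT_COVARIATES,
                 outcome: str = "ptt", log_outcome: bool = True):
        self.covariates = covariates
        self.outcome = outcome
        self.log_outcome = log_outcome

    def fit(self, cohort: pd.DataFrame, y=None):
        cols = list(self.covariates) + [self.outcome]
        data = cohort[cols].dropna()
        k = len(self.covariates)
        if len(data) < 10 * k:
            raise ValueError(
                f"only {len(data)} complete cases for {k} covariates; need >= {10 * k}")
        X = data[list(self.covariates)].astype(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < k + 1:
            raise ValueError(f"rank-deficient design; collinear columns: {_name_collinear(X)}")
        yv = data[self.outcome].astype(float)
        if self.log_outcome:
            if (yv <= 0).any():
                raise ValueError("outcome must be positive for log transform")
            yv = np.log(yv)
        model = sm.OLS(yv, sm.add_constant(X)).fit()
        ci = model.conf_int(alpha=0.05)
        sd_y = float(np.std(yv, ddof=1))
        table = pd.DataFrame({
            "beta": model.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "std_beta": [
                model.params[c] * (float(X[c].std(ddof=1)) / sd_y) if c != "const" else np.nan
                for c in model.params.index
            ],
            "p_value": model.pvalues,
        })
        self.model_ = model
        self.result_ = LinearModelResult(table=table, r2=float(model.rsquared), n=len(data))
        return self


def fit_log_ptt_model(cohort: pd.DataFrame, covariates=LOG_PTT_COVARIATES,
                      **kwargs) -> LinearModelResult:
    """Functional wrapper over :class:`LogPTTRegression`."""
    return LogPTTRegression(covariates=covariates, **kwargs).fit(cohort).result_


# --------------------------------------------------------------------------
# Cox per-SD models
# --------------------------------------------------------------------------

@dataclass
class CoxModelResult:
    """Per-SD Cox model summary."""

    hr_per_sd: float
    ci95: tuple
    p_value: float
    model_chi_square: float
    predictor_sd: float
    schoenfeld_p: dict
    n: int
    n_events: int
    ties: str = "efron"
    firth_adjusted: dict | None = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "hr_per_sd": self.hr_per_sd, "ci95": list(self.ci95),
            "p_value": self.p_value, "model_chi_square": self.model_chi_square,
            "predictor_sd": self.predictor_sd, "schoenfeld_p": self.schoenfeld_p,
            "n": self.n, "n_events": self.n_events, "ties": self.ties,
            "firth_adjusted": self.firth_adjusted, "flags": list(self.flags),
        }


class CoxPerSD(BaseEstimator):
    """Cox proportional-hazards model with a per-SD scaled predictor.

    The predictor is divided by its cohort standard deviation (or a supplied
    ``scale_sd``) before fitting, so the reported hazard ratio is per one SD
    increase.  Proportionality is checked with a scaled Schoenfeld-residual
    test per covariate.  ``penalized_refit`` adds a sensitivity pass with an
    L2 penalty on the partial likelihood (guarding against bias at low event
    counts or separation); the penalty strength is recorded in the result.
    """

    def __init__(self, predictor: str = "ptt", covariates: tuple = COX_COVARIATES,
                 duration_col: str = "followup_time", event_col: str = "event",
                 scale_sd: float | None = None, penalized_refit: bool = False,
                 penalizer: float = 0.1):
        self.predictor = predictor
        self.covariates = covariates
        self.duration_col = duration_col
        self.event_col = event_col
        self.scale_sd = scale_sd
        self.penalized_refit = penalized_refit
        self.penalizer = penalizer

    def fit(self, cohort: pd.DataFrame, y=None):
        cols = [self.predictor, self.duration_col, self.event_col] + list(self.covariates)
        data = cohort[cols].dropna().astype(float)
        n_events = int(data[self.event_col].sum())
        if n_events == 0:
            raise ValueError("zero events; Cox model cannot be fitted")
        if n_events < 10:
            raise ValueError(f"only {n_events} events; need >= 10 for a stable fit")
        if data[self.predictor].nunique() == 1:
            raise ValueError(f"predictor {self.predictor!r} is constant")

        sd = float(self.scale_sd) if self.scale_sd is not None \
            else float(data[self.predictor].std(ddof=1))
        if sd <= 0:
            raise ValueError("predictor SD must be positive")
        scaled_col = f"{self.predictor}_per_sd"
        df = data.drop(columns=[self.predictor])
        df[scaled_col] = data[self.predictor] / sd

        flags = []
        cph = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col=self.duration_col, event_col=self.event_col)
            if any("convergence" in str(w.message).lower() for w in caught):
                flags.append("possible_separation_consider_penalized_refit")

        coef = float(cph.params_[scaled_col])
        ci = cph.confidence_intervals_.loc[scaled_col]
        schoen = proportional_hazard_test(cph, df, time_transform="rank")
        schoenfeld_p = {str(k): float(v) for k, v in schoen.p_value_as_dataframe()["p"].items()} \
            if hasattr(schoen, "p_value_as_dataframe") else \
            dict(zip(schoen.summary.index.get_level_values(0), schoen.summary["p"]))

        firth = None
        if self.penalized_refit:
            cph_pen = CoxPHFitter(penalizer=self.penalizer, l1_ratio=0.0)
            cph_pen.fit(df, duration_col=self.duration_col, event_col=self.event_col)
            ci_pen = cph_pen.confidence_intervals_.loc[scaled_col]
            firth = {
                "hr_per_sd": float(np.exp(cph_pen.params_[scaled_col])),
                "ci95": [float(np.exp(ci_pen.iloc[0])), float(np.exp(ci_pen.iloc[1]))],
                "penalty": "l2_partial_likelihood",
                "penalizer": self.penalizer,
            }

        self.fitter_ = cph
        self.result_ = CoxModelResult(
            hr_per_sd=float(np.exp(coef)),
            ci95=(float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
            p_value=float(cph.summary.loc[scaled_col, "p"]),
            model_chi_square=float(cph.log_likelihood_ratio_test().test_statistic),
            predictor_sd=sd,
            schoenfeld_p=schoenfeld_p,
            n=len(df), n_events=n_events,
            firth_adjusted=firth, flags=flags,
        )
        return self


def fit_cox_per_sd(cohort: pd.DataFrame, predictor: str = "ptt",
                   covariates: tuple = COX_COVARIATES, scale_sd=None,
                   **kwargs) -> CoxModelResult:
    """Functional wrapper over :class:`CoxPerSD`."""
    return CoxPerSD(predictor=predictor, covariates=covariates,
                    scale_sd=scale_sd, **kwargs).fit(cohort).result_


# --------------------------------------------------------------------------
# Kaplan-Meier and sensitivity analyses
# --------------------------------------------------------------------------

@dataclass
class KMResult:
    """Mean-dichotomized Kaplan-Meier comparison."""

    cutoff: float
    biomarker: str
    logrank_statistic: float
    logrank_p: float
    fitter_low: KaplanMeierFitter
    fitter_high: KaplanMeierFitter
    n_low: int
    n_high: int

    def survival_at(self, t: float) -> tuple:
        return (float(self.fitter_low.predict(t)), float(self.fitter_high.predict(t)))

    def plot(self, ax=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        self.fitter_low.plot_survival_function(ax=ax, show_censors=True)
        self.fitter_high.plot_survival_function(ax=ax, show_censors=True)
        ax.set_xlabel("follow-up (months)")
        ax.set_ylabel("event-free survival")
        ax.set_title(f"{self.biomarker} dichotomized at {self.cutoff:.3g} "
                     f"(log-rank p={self.logrank_p:.3g})")
        return ax


def km_dichotomized(cohort: pd.DataFrame, biomarker: str,
                    cutoff: float | None = None,
                    duration_col: str = "followup_time",
                    event_col: str = "event") -> KMResult:
    """Kaplan-Meier curves split at a biomarker cut-off (default: the mean).

    Product-limit estimates per stratum with censoring marks, compared by a
    two-group log-rank test.
    """
    data = cohort[[biomarker, duration_col, event_col]].dropna()
    cut = float(data[biomarker].mean()) if cutoff is None else float(cutoff)
    high = data[biomarker] > cut
    if high.all() or not high.any():
        raise ValueError(
            f"dichotomization at {cut:.4g} leaves an empty stratum; "
            "supply an explicit cutoff")
    lo_d, hi_d = data[~high], data[high]
    kmf_lo = KaplanMeierFitter(label=f"{biomarker} <= {cut:.3g}")
    kmf_lo.fit(lo_d[duration_col], lo_d[event_col])
    kmf_hi = KaplanMeierFitter(label=f"{biomarker} > {cut:.3g}")
    kmf_hi.fit(hi_d[duration_col], hi_d[event_col])
    lr = logrank_test(lo_d[duration_col], hi_d[duration_col],
                      lo_d[event_col], hi_d[event_col])
    return KMResult(cutoff=cut, biomarker=biomarker,
                    logrank_statistic=float(lr.test_statistic),
                    logrank_p=float(lr.p_value),
                    fitter_low=kmf_lo, fitter_high=kmf_hi,
                    n_low=len(lo_d), n_high=len(hi_d))


def sensitivity_censor_early_revasc(cohort: pd.DataFrame, window_days: float = 90.0,
                                    revasc_col: str = "early_revasc_days",
                                    duration_col: str = "followup_time",
                                    **cox_kwargs) -> CoxModelResult:
    """Refit the Cox model censoring subjects revascularized early.

    Subjects with ``early_revasc_days <= window_days`` are censored at the
    revascularization date (converted to months); the model specification is
    otherwise identical, so an empty censored subset reproduces the base fit
    exactly.
    """
    if revasc_col not in cohort.columns:
        raise ValueError(f"column {revasc_col!r} required for the sensitivity analysis")
    df = cohort.copy()
    revasc_months = df[revasc_col] / DAYS_PER_MONTH
    mask = df[revasc_col].notna() & (df[revasc_col] <= window_days) \
        & (revasc_months < df[duration_col])
    df.loc[mask, duration_col] = revasc_months[mask]
    df.loc[mask, cox_kwargs.get("event_col", "event")] = 0
    return fit_cox_per_sd(df, duration_col=duration_col, **cox_kwargs)
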
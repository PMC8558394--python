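"""CRP regression models.

Log-transformed CRP is modeled as a continuous outcome by OLS and clinically
elevated CRP (> 3 mg/L) as a binary outcome by maximum-likelihood logistic
regression. Models are built from a participant table with
``CRPLinearModel.from_dataframe(table, terms)`` / ``CRPLogisticModel...`` and
fitted with ``.fit()``, which returns a results object carrying estimates,
standard errors, p-values and a ``summary()`` table — the usual
model/results split. Reference levels: White ethnicity, female sex,
never-smoker, never/rarely insomnia.

Also here: the nested-model likelihood-ratio test, the acute-infection
sensitivity filter (CRP >= 10 mg/L removed), and grouped cohort summaries
with Welch two-sample tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    EmptyTableError,
    InputError,
    RankDeficiencyError,
    SeparationError,
)

#: Elevated-CRP clinical threshold (mg/L, strict >) and acute-infection
#: sensitivity threshold (mg/L, inclusive >=).
ELEVATED_THRESHOLD = 3.0
ACUTE_THRESHOLD = 10.0

CATEGORICAL_CODINGS = {
    "ethnicity": ("White", ["Black"]),
    "sex": ("female", ["male"]),
    "smoking": ("never", ["previous", "current", "prefer_not_to_answer"]),
    "insomnia": ("never_rarely", ["sometimes", "usually", "prefer_not_to_answer"]),
}

BASE_TERMS = ["ethnicity", "age_centered", "sex"]
INTERACTION_TERMS = BASE_TERMS + ["ethnicity:sex"]
FULLY_ADJUSTED_TERMS = BASE_TERMS + [
    "bmi", "insomnia", "mdd", "recruitment_year", "smoking", "pc1", "pc2", "townsend",
]

#: Model variables checked in the complete-case filter when present.
MODEL_VARIABLES = [
    "crp", "age", "sex", "ethnicity", "bmi", "townsend", "smoking",
    "insomnia", "mdd", "recruitment_year", "pc1", "pc2",
]


def prepare_analysis_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive analysis columns and apply the complete-case filter.

    Adds ``log_crp`` (natural log), ``age_centered`` (age minus cohort mean)
    and ``elevated`` (CRP strictly above 3 mg/L). Rows with a missing value in
    any model variable present in the table are dropped with a logged count.
    """
    cols = [c for c in MODEL_VARIABLES if c in raw.columns]
    if "crp" not in cols:
        raise InputError("prepare_analysis_table requires a crp column")
    table = raw.dropna(subset=cols).copy()
    n_dropped = len(raw) - len(table)
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "prepare_analysis_table dropped %d incomplete rows", n_dropped)
    if len(table) == 0:
        raise EmptyTableError("all rows dropped by the complete-case filter")
    if (table["crp"] <= 0).any():
        raise InputError("crp must be strictly positive")
    table["log_crp"] = np.log(table["crp"])
    table["age_centered"] = table["age"] - table["age"].mean()
    table["elevated"] = (table["crp"] > ELEVATED_THRESHOLD).astype(int)
    return table


def build_design(table: pd.DataFrame, terms) -> pd.DataFrame:
    """Build the design matrix (with intercept) for an ordered term list.

    Categorical terms expand to treatment-coded indicator columns named
    ``term[level]`` with the fixed reference levels above; ``a:b`` denotes a
    product of the two terms' columns.
    """
    cols = {"const": np.ones(len(table))}

    def term_columns(t):
        if t in CATEGORICAL_CODINGS:
            _, levels = CATEGORICAL_CODINGS[t]
            observed = set(table[t].unique())
            return {f"{t}[{lvl}]": (table[t] == lvl).to_numpy(float)
                    for lvl in levels if lvl in observed}
        if t not in table.columns:
            raise InputError(f"term {t!r} not found in table")
        return {t: table[t].to_numpy(float)}

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            for na, ca in term_columns(a).items():
                for nb, cb in term_columns(b).items():
                    cols[f"{na}:{nb}"] = ca * cb
        else:
            cols.update(term_columns(term))
    return pd.DataFrame(cols, index=table.index)


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    if np.linalg.matrix_rank(A) < X.shape[1]:
        # a column is flagged when it adds nothing beyond its predecessors
        bad, prev_rank = [], 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(A[:, : j + 1])
            if r == prev_rank:
                bad.append(X.columns[j])
            prev_rank = r
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear terms: {bad}", terms=bad
        )


@dataclass
class ModelFit:
    """Coefficient table and fit statistics of a fitted model."""

    outcome_name: str
    family: str                     # "linear" or "logistic"
    terms: list
    estimates: np.ndarray
    standard_errors: np.ndarray
    statistics: np.ndarray          # t (linear) or Wald z (logistic)
    p_values: np.ndarray
    n_obs: int
    log_likelihood: float
    r_squared: float | None = None
    term_spec: list = field(default_factory=list)

    def __post_init__(self):
        k = len(self.terms)
        for v in (self.estimates, self.standard_errors, self.statistics, self.p_values):
            if len(v) != k:
                raise InputError("coefficient vectors have unequal lengths")
        if self.n_obs <= k:
            raise InputError("n_obs must exceed the number of terms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.estimates,
            "std_error": self.standard_errors,
            "statistic": self.statistics,
            "p_value": self.p_values,
        })

    def forest_frame(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.estimates,
            "ci_low": self.estimates - z * self.standard_errors,
            "ci_high": self.estimates + z * self.standard_errors,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __getitem__(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])


class _ResultsMixin:
    """Shared results surface over a statsmodels results object."""

    def __init__(self, model, sm_results, fit: ModelFit):
        self.model = model
        self._sm = sm_results
        self.fit_table = fit
        self.params = pd.Series(fit.estimates, index=fit.terms)
        self.bse = pd.Series(fit.standard_errors, index=fit.terms)
        self.pvalues = pd.Series(fit.p_values, index=fit.terms)
        self.nobs = fit.n_obs
        self.llf = fit.log_likelihood

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    def summary(self):
        return self._sm.summary()

    def to_frame(self) -> pd.DataFrame:
        return self.fit_table.to_frame()


class CRPLinearResults(_ResultsMixin):
    def __init__(self, model, sm_results, fit: ModelFit):
        super().__init__(model, sm_results, fit)
        self.rsquared = fit.r_squared
        self.resid = np.asarray(sm_results.resid)


class CRPLogisticResults(_ResultsMixin):
    def __init__(self, model, sm_results, fit: ModelFit):
        super().__init__(model, sm_results, fit)
        self.fittedvalues = np.asarray(sm_results.predict())


class _ModelBase:
    """Common constructor: outcome vector plus an ordered term specification."""

    outcome: str = "log_crp"

    def __init__(self, endog, exog: pd.DataFrame, terms, outcome_name=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.term_spec = list(terms)
        self.outcome_name = outcome_name or self.outcome
        if len(self.endog) != len(exog):
            raise InputError("endog and exog lengths differ")
        _check_rank(exog)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, terms=None, outcome=None):
        outcome = outcome or cls.outcome
        terms = list(terms) if terms is not None else list(BASE_TERMS)
        if outcome not in table.columns:
            raise InputError(f"outcome column {outcome!r} not in table "
                             "(run prepare_analysis_table first)")
        X = build_design(table, terms)
        return cls(table[outcome].to_numpy(), X, terms, outcome_name=outcome)


class CRPLinearModel(_ModelBase):
    """OLS model of log CRP on an ordered term specification."""

    outcome = "log_crp"

    def fit(self) -> CRPLinearResults:
        res = sm.OLS(self.endog, self.exog).fit()
        fit = ModelFit(
            outcome_name=self.outcome_name,
            family="linear",
            terms=list(self.exog.columns),
            estimates=np.asarray(res.params),
            standard_errors=np.asarray(res.bse),
            statistics=np.asarray(res.tvalues),
            p_values=np.asarray(res.pvalues),
            n_obs=int(res.nobs),
            log_likelihood=float(res.llf),
            r_squared=float(res.rsquared),
            term_spec=self.term_spec,
        )
        return CRPLinearResults(self, res, fit)


class CRPLogisticModel(_ModelBase):
    """Maximum-likelihood logistic model of a binary outcome (elevated CRP)."""

    outcome = "elevated"

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> CRPLogisticResults:
        y = self.endog
        if len(np.unique(y)) < 2:
            raise InputError("both outcome classes must be present")
        try:
            res = sm.Logit(y, self.exog).fit(disp=0, method="newton", tol=tol,
                                             maxiter=maxiter)
        except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as err:
            raise SeparationError(
                "perfect separation detected; consider a penalized (Firth-style) "
                "fit or removing the separating covariate"
            ) from err
        if not res.mle_retvals.get("converged", True):
            raise SeparationError(
                "logistic fit failed to converge (quasi-separation likely); "
                "consider a penalized fit"
            )
        fit = ModelFit(
            outcome_name=self.outcome_name,
            family="logistic",
            terms=list(self.exog.columns),
            estimates=np.asarray(res.params),
            standard_errors=np.asarray(res.bse),
            statistics=np.asarray(res.tvalues),
            p_values=np.asarray(res.pvalues),
            n_obs=int(res.nobs),
            log_likelihood=float(res.llf),
            term_spec=self.term_spec,
        )
        return CRPLogisticResults(self, res, fit)


def fit_linear_crp(table: pd.DataFrame, terms=None) -> ModelFit:
    """OLS of log CRP on ``terms`` (default: the base ethnicity+age+sex model)."""
    return CRPLinearModel.from_dataframe(table, terms).fit().fit_table


def fit_logistic_elevated(table: pd.DataFrame, terms=None) -> ModelFit:
    """Logistic fit of the elevated-CRP indicator on ``terms``."""
    return CRPLogisticModel.from_dataframe(table, terms).fit().fit_table


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if self.statistic < -1e-8:
            raise InputError("LRT statistic must be non-negative")
        self.statistic = max(self.statistic, 0.0)
        if self.df < 1:
            raise InputError("LRT df must be >= 1")


def likelihood_ratio_test(null_fit, alt_fit) -> LrtResult:
    """Likelihood-ratio test of nested fits (results objects or ModelFits)."""
    nf = getattr(null_fit, "fit_table", null_fit)
    af = getattr(alt_fit, "fit_table", alt_fit)
    if nf.outcome_name != af.outcome_name or nf.n_obs != af.n_obs:
        raise InputError("LRT requires the same outcome and observations")
    if not set(nf.terms) <= set(af.terms):
        raise InputError("models are not nested: null terms must be a subset")
    df = len(af.terms) - len(nf.terms)
    if df == 0:
        return LrtResult(0.0, 1, 1.0)
    statistic = 2.0 * (af.log_likelihood - nf.log_likelihood)
    return LrtResult(float(statistic), df, float(stats.chi2.sf(statistic, df)))


def sensitivity_exclude_acute(table: pd.DataFrame,
                              threshold: float = ACUTE_THRESHOLD) -> pd.DataFrame:
    """Remove acute-infection-range CRP (>= threshold mg/L, inclusive)."""
    if not threshold > 0:
        raise InputError("threshold must be positive")
    out = table[table["crp"] < threshold]
    if len(out) == 0:
        raise EmptyTableError("sensitivity filter removed every row")
    return out.copy()


def cohort_summary(table: pd.DataFrame, group_by: str = "ethnicity",
                   continuous=("age", "crp", "townsend", "bmi"),
                   categorical=("sex", "smoking", "insomnia")) -> dict:
    """Per-group descriptive table plus Welch two-sample tests.

    Returns ``{"summary": DataFrame, "tests": DataFrame}``. Welch t tests are
    run for CRP between the two levels of ``group_by`` and between sexes;
    tests are omitted for single-group input.
    """
    groups = [g for g in table[group_by].unique()]
    rows = []
    for g in sorted(groups):
        sub = table[table[group_by] == g]
        row = {group_by: g, "n": len(sub)}
        for c in continuous:
            if c in sub:
                row[f"{c}_mean"] = sub[c].mean()
                row[f"{c}_sd"] = sub[c].std()
        for c in categorical:
            if c in sub:
                freq = sub[c].value_counts(normalize=True)
                for lvl, p in freq.items():
                    row[f"{c}[{lvl}]_pct"] = 100.0 * p
        if "crp" in sub:
            row["elevated_crp_pct"] = 100.0 * (sub["crp"] > ELEVATED_THRESHOLD).mean()
        rows.append(row)
    summary = pd.DataFrame(rows)
    tests = []
    if len(groups) >= 2 and all(
        (table[group_by] == g).sum() >= 2 for g in groups
    ) and "crp" in table:
        a, b = sorted(groups)[:2]
        t, p = stats.ttest_ind(table.loc[table[group_by] == a, "crp"],
                               table.loc[table[group_by] == b, "crp"],
                               equal_var=False)
        tests.append({"contrast": f"crp: {a} vs {b}", "t": t, "p_value": p})
    if "sex" in table and table["sex"].nunique() == 2 and "crp" in table:
        t, p = stats.ttest_ind(table.loc[table["sex"] == "female", "crp"],
                               table.loc[table["sex"] == "male", "crp"],
                               equal_var=False)
        tests.append({"contrast": "crp: female vs male", "t": t, "p_value": p})
    return {"summary": summary, "tests": pd.DataFrame(tests)}
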
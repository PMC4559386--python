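"""Cohort-level statistics: EM imputation, hierarchical moderation OLS,
nested-model F-tests, gender group comparisons, and Holm-corrected
correlations.

The main analysis regresses each discounting outcome (ln k, beta, delta, and
the model-free impulsivity count) on a growing predictor set:

* model 1: the three memory scores (FNPA-PF, IGD-C1, IGD-C2);
* model 2: + gender, age, income, IQ;
* model 3: + the three gender x memory interactions, built by multiplying the
  gender code with mean-centred memory scores.

All coefficients are reported as standardized betas (every variable,
including the constructed interaction products, is z-scored before the fit).
The increment of model m over model m-1 is tested with the R-squared-change
F-test. Missing income is filled beforehand by multivariate-normal EM so all
participants enter the regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

MEMORY_SCORES = ["fnpa_pf", "igd_c1", "igd_c2"]
COVARIATES = ["gender_code", "age", "income", "iq"]
IMPUTE_COLUMNS = ["age", "iq", "income", "fnpa_pf", "igd_c1", "igd_c2"]

#: gender coding used throughout (the qualitative opposite-slopes pattern,
#: not coefficient signs, is the scientific claim)
GENDER_CODE = {"male": 0.0, "female": 1.0}


# ---------------------------------------------------------------------------
# EM imputation
# ---------------------------------------------------------------------------

def em_impute(
    table: pd.DataFrame,
    columns=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Fill missing numeric entries by multivariate-normal EM.

    Iterates expectation (conditional means and covariances of the missing
    entries given the observed ones) and maximization (update of the joint
    mean and covariance) until the imputed values move by less than ``tol``.
    Observed values are never altered.
    """
    if columns is None:
        columns = [c for c in IMPUTE_COLUMNS if c in table.columns]
    X = table[columns].to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return table.copy()
    if miss.all(axis=0).any():
        bad = [c for c, m in zip(columns, miss.all(axis=0)) if m]
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")

    n, p = X.shape
    col_means = np.nanmean(X, axis=0)
    X[miss] = np.take(col_means, np.where(miss)[1])

    for _ in range(max_iter):
        mu = X.mean(axis=0)
        centered = X - mu
        sigma = centered.T @ centered / n
        # E-step: per missingness pattern, conditional mean + covariance
        cond_cov_sum = np.zeros((p, p))
        X_new = X.copy()
        patterns = {}
        for i in range(n):
            patterns.setdefault(tuple(miss[i]), []).append(i)
        for pattern, rows in patterns.items():
            m = np.array(pattern)
            if not m.any():
                continue
            o = ~m
            S_oo = sigma[np.ix_(o, o)] + 1e-12 * np.eye(o.sum())
            S_mo = sigma[np.ix_(m, o)]
            B = np.linalg.solve(S_oo, S_mo.T).T  # regression of missing on observed
            C_mm = sigma[np.ix_(m, m)] - B @ S_mo.T
            for i in rows:
                X_new[i, m] = mu[m] + B @ (X[i, o] - mu[o])
            pad = np.zeros((p, p))
            pad[np.ix_(m, m)] = C_mm
            cond_cov_sum += len(rows) * pad
        delta = np.max(np.abs(X_new[miss] - X[miss]))
        X = X_new
        # M-step uses the completed data plus the conditional covariance of
        # the imputed entries (handled on the next iteration's moment update)
        mu = X.mean(axis=0)
        centered = X - mu
        sigma = (centered.T @ centered + cond_cov_sum) / n
        if delta < tol:
            break

    out = table.copy()
    for j, col in enumerate(columns):
        values = out[col].to_numpy(dtype=float)
        values[miss[:, j]] = X[miss[:, j], j]
        out[col] = values
    return out


# ---------------------------------------------------------------------------
# Hierarchical moderation OLS
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """One fitted model of the hierarchy, in standardized-beta form."""

    model_id: int
    outcome: str
    predictors: list
    coefficients: dict  # name -> (standardized beta, two-tailed p)
    fvalue: float
    df: tuple  # (df model, df residual)
    r2: float
    adj_r2: float
    p_model: float
    n: int
    delta_r2_test: dict | None = None  # {"F":, "df":, "p":} vs previous model

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "coefficients": {k: list(v) for k, v in self.coefficients.items()},
            "F": self.fvalue,
            "df": list(self.df),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "p_model": self.p_model,
            "n": self.n,
            "standardized": True,
        }
        if self.delta_r2_test is not None:
            d["delta_r2_test"] = {
                "F": self.delta_r2_test["F"],
                "df": list(self.delta_r2_test["df"]),
                "p": self.delta_r2_test["p"],
            }
        return d


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def build_design(table: pd.DataFrame) -> pd.DataFrame:
    """Standardized predictors for the model hierarchy.

    Interactions are gender code times mean-centred memory score, z-scored
    after the product is formed.
    """
    df = pd.DataFrame(index=table.index)
    gender = table["gender"].map(GENDER_CODE)
    if gender.isna().any():
        raise ValueError("gender must be 'male' or 'female'")
    raw = {
        "fnpa_pf": table["fnpa_pf"].to_numpy(float),
        "igd_c1": table["igd_c1"].to_numpy(float),
        "igd_c2": table["igd_c2"].to_numpy(float),
        "gender_code": gender.to_numpy(float),
        "age": table["age"].to_numpy(float),
        "income": table["income"].to_numpy(float),
        "iq": table["iq"].to_numpy(float),
    }
    for name, x in raw.items():
        if np.isnan(x).any():
            raise ValueError(f"missing values in {name}; impute first")
        df[name] = _zscore(x)
    for score in MEMORY_SCORES:
        x = raw[score]
        product = raw["gender_code"] * (x - x.mean())
        df[f"gender_x_{score}"] = _zscore(product)
    return df


MODEL_TERMS = {
    1: MEMORY_SCORES,
    2: MEMORY_SCORES + COVARIATES,
    3: MEMORY_SCORES + COVARIATES + [f"gender_x_{s}" for s in MEMORY_SCORES],
}


class HierarchicalInteractionOLS(BaseEstimator):
    """Three nested OLS models testing gender x memory moderation.

    ``fit(table, outcome)`` z-scores the outcome and predictors, fits the
    models, and stores a list of :class:`RegressionResult` in ``results_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, table: pd.DataFrame, outcome: str):
        design = build_design(table)
        n = len(table)
        max_p = len(MODEL_TERMS[3])
        if n <= max_p + 1:
            raise ValueError(f"need n > {max_p + 1} participants, got {n}")
        y = _zscore(table[outcome].to_numpy(float))

        self.results_ = []
        prev = None
        for model_id, terms in MODEL_TERMS.items():
            X = sm.add_constant(design[terms].to_numpy())
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("rank-deficient (collinear) design matrix")
            fit = sm.OLS(y, X).fit()
            coefs = {
                t: (float(fit.params[j + 1]), float(fit.pvalues[j + 1]))
                for j, t in enumerate(terms)
            }
            result = RegressionResult(
                model_id=model_id,
                outcome=outcome,
                predictors=list(terms),
                coefficients=coefs,
                fvalue=float(fit.fvalue),
                df=(int(fit.df_model), int(fit.df_resid)),
                r2=float(fit.rsquared),
                adj_r2=float(fit.rsquared_adj),
                p_model=float(fit.f_pvalue),
                n=n,
            )
            if prev is not None:
                result.delta_r2_test = delta_r2_f_test(result, prev, n)
            self.results_.append(result)
            prev = result
        return self

    def result(self, model_id: int) -> RegressionResult:
        return self.results_[model_id - 1]


def fit_model_hierarchy(table: pd.DataFrame, outcome: str) -> list:
    """Thin wrapper over :class:`HierarchicalInteractionOLS`."""
    return HierarchicalInteractionOLS().fit(table, outcome).results_


def delta_r2_f_test(full: RegressionResult, reduced: RegressionResult, n: int) -> dict:
    """F-test of the R-squared increment of nested OLS models.

    F = ((R2_full - R2_red)/q) / ((1 - R2_full)/(n - p_full - 1)) with q added
    terms, referred to F(q, n - p_full - 1).
    """
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    q = len(full.predictors) - len(reduced.predictors)
    if q == 0:
        raise ValueError("full model adds no terms")
    p_full = len(full.predictors)
    df_den = n - p_full - 1
    num = (full.r2 - reduced.r2) / q
    den = (1.0 - full.r2) / df_den
    F = num / den if den > 0 else np.inf
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df_den))
    return {"F": float(F), "df": (q, df_den), "p": p}


# ---------------------------------------------------------------------------
# Group comparisons, correlations, median splits
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test_name: str  # "t-test" or "mann-whitney"
    statistic: float
    p: float
    group_stats: dict = field(default_factory=dict)  # gender -> (mean, se, n)


def compare_groups(table: pd.DataFrame, variable: str, alpha: float = 0.05) -> GroupComparison:
    """Compare a variable between gender groups.

    Shapiro-Wilk within each group gates the test: both normal at ``alpha``
    gives a pooled-variance two-sample t-test, otherwise Mann-Whitney U.
    """
    groups = {
        g: table.loc[table["gender"] == g, variable].dropna().to_numpy(float)
        for g in ("male", "female")
    }
    if any(v.size == 0 for v in groups.values()):
        raise ValueError("both gender groups must be nonempty")
    if any(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError(f"variable {variable} is constant within a group")
    normal = all(stats.shapiro(v).pvalue > alpha for v in groups.values())
    m, f = groups["male"], groups["female"]
    if normal:
        res = stats.ttest_ind(m, f, equal_var=True)
        name = "t-test"
    else:
        res = stats.mannwhitneyu(m, f, alternative="two-sided")
        name = "mann-whitney"
    return GroupComparison(
        variable=variable,
        test_name=name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_stats={
            g: (float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)), int(v.size))
            for g, v in groups.items()
        },
    )


def holm_bonferroni(pvalues, alpha: float = 0.05):
    """Holm step-down decisions and adjusted p-values for one family."""
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return reject, p_adj


def memory_covariate_correlations(
    table: pd.DataFrame,
    covariates=("age", "iq", "income"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Memory-score x covariate correlations with per-covariate Holm control.

    Pearson r when both variables pass Shapiro-Wilk at ``alpha``, otherwise
    Spearman rho; two-tailed p-values; Holm-Bonferroni applied within each
    covariate's family of three tests.
    """
    rows = []
    for cov in covariates:
        fam = []
        for score in MEMORY_SCORES:
            x = table[score].to_numpy(float)
            y = table[cov].to_numpy(float)
            if np.isnan(x).any() or np.isnan(y).any():
                raise ValueError("correlations require a complete table")
            normal = (
                stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
            )
            if normal:
                r, p = stats.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = stats.spearmanr(x, y)
                method = "spearman"
            fam.append(
                {
                    "covariate": cov,
                    "memory_score": score,
                    "method": method,
                    "r": float(r),
                    "p": float(p),
                }
            )
        reject, p_adj = holm_bonferroni([f["p"] for f in fam], alpha=alpha)
        for f, rej, pa in zip(fam, reject, p_adj):
            f["p_holm"] = float(pa)
            f["significant"] = bool(rej)
            rows.append(f)
    return pd.DataFrame(rows)


def median_split_summary(table: pd.DataFrame, score: str, outcome: str) -> pd.DataFrame:
    """Mean and SE of an outcome per gender x high/low median-split cell.

    The split is at the within-sample median of ``score``; ties go to the low
    group.
    """
    med = table[score].median()
    split = np.where(table[score] <= med, "low", "high")
    out = []
    for gender in ("male", "female"):
        for level in ("low", "high"):
            mask = (table["gender"] == gender) & (split == level)
            vals = table.loc[mask, outcome].to_numpy(float)
            n = vals.size
            out.append(
                {
                    "score": score,
                    "outcome": outcome,
                    "gender": gender,
                    "split": level,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                }
            )
    return pd.DataFrame(out)
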
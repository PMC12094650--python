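"""Case-control and phenotype regression models for G×E analysis.

Four logistic model types relate case status to the polygenic score (G)
and an aggregate environmental score (E), always adjusted for age, sex and
education by default:

* genetic:       G + covariates
* environmental: E + covariates
* independent:   G + E + covariates
* interaction:   G + E + G×E + covariates

Continuous G and E are standardized before products are formed, so odds
ratios are per SD.  The module also provides Nagelkerke's pseudo-R²,
control-quantile dichotomization with subgroup odds-ratio tables
(low-G/low-E reference), Benjamini–Hochberg FDR, AIC/BIC, linear models
for symptom phenotypes, and a case-only gene–environment correlation
screen.

``fit_logistic`` is an iteratively reweighted least squares (Newton)
maximum-likelihood fit with the covariance taken as the inverse observed
information; separation is flagged by a coefficient-magnitude guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SubgroupORTable",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "build_design",
    "fit_model",
    "nagelkerke_r2",
    "dichotomize_by_control_quantile",
    "subgroup_or_table",
    "bh_fdr",
    "information_criteria",
    "fit_linear_phenotype",
    "ge_correlation_screen",
    "results_table",
]

DEFAULT_COVARIATES = ("age", "sex", "education")
MODEL_TYPES = ("genetic", "environmental", "independent", "interaction")


class SeparationError(RuntimeError):
    """Quasi-complete separation detected during a logistic fit."""


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge within the iteration budget."""


@dataclass
class ModelSpec:
    """Which terms enter a case-control model."""

    model_type: str = "interaction"
    outcome: str = "status"
    genetic_term: str = "prs_z"
    environmental_term: str = "pers_total_z"
    covariates: tuple = DEFAULT_COVARIATES
    covariate_interactions: tuple = ()  # covariates also crossed with G and E
    standardize: bool = True

    def __post_init__(self):
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")


@dataclass
class ModelFit:
    """Coefficients, covariance and likelihoods from a regression fit."""

    names: list
    params: np.ndarray
    cov: np.ndarray
    llf: float
    ll_null: float
    n: int
    converged: bool
    family: str = "binomial"  # or 'gaussian'

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = self.params.size
        if self.cov.shape != (k, k):
            raise ValueError("covariance dimensions do not match coefficients")
        if not np.allclose(self.cov, self.cov.T, atol=1e-6):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def k(self) -> int:
        return self.params.size

    def index(self, term: str) -> int:
        try:
            return self.names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in model") from None

    def se(self, term: str) -> float:
        i = self.index(term)
        return float(np.sqrt(self.cov[i, i]))

    def coef(self, term: str) -> float:
        return float(self.params[self.index(term)])

    def wald_p(self, term: str) -> float:
        z = self.coef(term) / self.se(term)
        return float(2.0 * norm.sf(abs(z)))

    def or_ci(self, term: str, level: float = 0.95):
        """(OR, low, high) Wald interval on the odds-ratio scale."""
        z = norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(term), self.se(term)
        return (float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))

    def table(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            b, s = self.coef(name), self.se(name)
            row = {"term": name, "estimate": b, "se": s, "p": self.wald_p(name)}
            if self.family == "binomial":
                row["or"], row["ci_low"], row["ci_high"] = self.or_ci(name)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic fitting (IRLS)
# ---------------------------------------------------------------------------


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * np.log(p) + n0 * np.log1p(-p))


def fit_logistic(
    X,
    y,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    maxiter: int = 100,
    separation_bound: float = 15.0,
) -> ModelFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges on max absolute coefficient change < ``tol``; the covariance
    is the inverse observed information at the optimum.  Any coefficient
    exceeding ``separation_bound`` in absolute value (on standardized
    predictors) raises :class:`SeparationError`.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])] if names is None else list(names)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError("outcome must be binary with both classes present")
    sd = X.std(axis=0)
    const_cols = np.flatnonzero(sd == 0)
    for c in const_cols:
        if names[c] not in ("const", "intercept") and not np.allclose(X[:, c], 1.0):
            raise ValueError(f"zero-variance predictor: {names[c]!r}")

    beta = np.zeros(k)
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        beta = beta + step
        if np.any(np.abs(beta) > separation_bound):
            raise SeparationError(
                f"coefficient magnitude exceeded {separation_bound}; data are "
                "(quasi-)separated"
            )
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")

    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ModelFit(
        names=names, params=beta, cov=cov, llf=llf, ll_null=_null_loglik(y),
        n=n, converged=True, family="binomial",
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _standardized(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"cannot standardize constant column {col.name!r}")
    return (x - x.mean()) / sd


def build_design(cohort: pd.DataFrame, spec: ModelSpec):
    """Design matrix and outcome for one of the four model types.

    Continuous G/E are standardized (when ``spec.standardize``) before the
    product term is formed.  Covariate×G and covariate×E columns are added
    for every covariate listed in ``spec.covariate_interactions``.
    Returns ``(X, y, term_names)`` with X a DataFrame including 'const'.
    """
    needed = [spec.outcome] + list(spec.covariates)
    if spec.model_type in ("genetic", "independent", "interaction"):
        needed.append(spec.genetic_term)
    if spec.model_type in ("environmental", "independent", "interaction"):
        needed.append(spec.environmental_term)
    for col in needed:
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")

    sub = cohort[list(dict.fromkeys(needed))].dropna()
    y = sub[spec.outcome].to_numpy(dtype=float)
    X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)

    g = e = None
    if spec.genetic_term in sub.columns and spec.model_type != "environmental":
        g = _standardized(sub[spec.genetic_term]) if spec.standardize else sub[
            spec.genetic_term
        ].to_numpy(dtype=float)
        X[spec.genetic_term] = g
    if spec.environmental_term in sub.columns and spec.model_type != "genetic":
        e = _standardized(sub[spec.environmental_term]) if spec.standardize else sub[
            spec.environmental_term
        ].to_numpy(dtype=float)
        X[spec.environmental_term] = e
    if spec.model_type == "interaction":
        X[f"{spec.genetic_term}:{spec.environmental_term}"] = g * e
    for cov in spec.covariates:
        X[cov] = sub[cov].to_numpy(dtype=float)
    for cov in spec.covariate_interactions:
        cv = sub[cov].to_numpy(dtype=float)
        if g is not None:
            X[f"{cov}:{spec.genetic_term}"] = cv * g
        if e is not None:
            X[f"{cov}:{spec.environmental_term}"] = cv * e
    return X, y, list(X.columns)


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Convenience wrapper: build the design and run the logistic fit."""
    X, y, names = build_design(cohort, spec)
    return fit_logistic(X, y, names)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def nagelkerke_r2(fit: ModelFit) -> float:
    """Normalized likelihood-ratio pseudo-R²:
    ``[1 - exp(2 (ll0 - ll1) / n)] / [1 - exp(2 ll0 / n)]``."""
    ll1, ll0, n = fit.llf, fit.ll_null, fit.n
    if ll1 < ll0 - 1e-6:
        raise ValueError("model log-likelihood below the null model")
    ll1 = max(ll1, ll0)
    num = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    den = 1.0 - np.exp(2.0 * ll0 / n)
    return float(num / den)


def information_criteria(fit: ModelFit):
    """(AIC, BIC) = (2k - 2 ll, k ln n - 2 ll)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    aic = 2.0 * fit.k - 2.0 * fit.llf
    bic = fit.k * np.log(fit.n) - 2.0 * fit.llf
    return float(aic), float(bic)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dichotomization and subgroup odds ratios
# ---------------------------------------------------------------------------


def dichotomize_by_control_quantile(values, control_mask, q: float = 0.75):
    """High/low split at the linear-interpolation quantile of controls.

    ``high`` is strictly greater than the threshold.  Default q = 0.75
    with 0.50 / 0.25 as sensitivity settings.
    """
    x = np.asarray(values, dtype=float)
    controls = x[np.asarray(control_mask, dtype=bool)]
    controls = controls[np.isfinite(controls)]
    if np.unique(controls).size < 2:
        raise ValueError("degenerate threshold: control values are identical")
    threshold = float(np.quantile(controls, q))
    return x > threshold, threshold


@dataclass
class SubgroupORTable:
    """Odds ratios of the four G/E subgroups vs the low/low reference."""

    cells: dict  # key -> {"n": int, "or": float, "ci": (lo, hi), "p": float}
    quantile: float
    fit: Optional[ModelFit] = None

    def __post_init__(self):
        if self.cells["low_low"]["or"] != 1.0:
            raise ValueError("reference cell OR must be exactly 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, c in self.cells.items():
            rows.append(
                {
                    "cell": key,
                    "n": c["n"],
                    "or": c["or"],
                    "ci_low": c["ci"][0] if c["ci"] is not None else np.nan,
                    "ci_high": c["ci"][1] if c["ci"] is not None else np.nan,
                    "p": c["p"] if c["p"] is not None else np.nan,
                    "quantile": self.quantile,
                }
            )
        return pd.DataFrame(rows)


def subgroup_or_table(
    cohort: pd.DataFrame,
    g_high,
    e_high,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "status",
    quantile: float = 0.75,
) -> SubgroupORTable:
    """One logistic fit with three subgroup indicators (low/low omitted)."""
    g_high = np.asarray(g_high, dtype=bool)
    e_high = np.asarray(e_high, dtype=bool)
    y = cohort[outcome].to_numpy(dtype=float)
    ind = {
        "high_low": g_high & ~e_high,
        "low_high": ~g_high & e_high,
        "high_high": g_high & e_high,
    }
    counts = {
        "low_low": int((~g_high & ~e_high).sum()),
        **{k: int(v.sum()) for k, v in ind.items()},
    }
    empty = [k for k, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty subgroup cell(s) {empty}; cell counts {counts}")

    X = pd.DataFrame({"const": np.ones(len(cohort))}, index=cohort.index)
    for key, v in ind.items():
        X[key] = v.astype(float)
    for cov in covariates:
        X[cov] = cohort[cov].to_numpy(dtype=float)
    fit = fit_logistic(X, y, list(X.columns))

    cells = {"low_low": {"n": counts["low_low"], "or": 1.0, "ci": None, "p": None}}
    for key in ("high_low", "low_high", "high_high"):
        orv, lo, hi = fit.or_ci(key)
        cells[key] = {"n": counts[key], "or": orv, "ci": (lo, hi), "p": fit.wald_p(key)}
    return SubgroupORTable(cells=cells, quantile=quantile, fit=fit)


# ---------------------------------------------------------------------------
# linear phenotype models
# ---------------------------------------------------------------------------


def fit_linear_phenotype(
    cohort: pd.DataFrame, spec: ModelSpec, phenotype: str
) -> ModelFit:
    """OLS interaction model for a continuous symptom phenotype."""
    spec2 = ModelSpec(
        model_type=spec.model_type,
        outcome=phenotype,
        genetic_term=spec.genetic_term,
        environmental_term=spec.environmental_term,
        covariates=spec.covariates,
        covariate_interactions=spec.covariate_interactions,
        standardize=spec.standardize,
    )
    X, y, names = build_design(cohort, spec2)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X.to_numpy()).fit()
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    return ModelFit(
        names=names,
        params=res.params,
        cov=res.cov_params(),
        llf=float(res.llf),
        ll_null=float(null.llf),
        n=int(res.nobs),
        converged=True,
        family="gaussian",
    )


# ---------------------------------------------------------------------------
# gene-environment correlation screen
# ---------------------------------------------------------------------------


def ge_correlation_screen(
    cases: pd.DataFrame,
    prs_col: str,
    domains: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Case-only logistic screen of each exposure domain on the PRS.

    Returns one row per domain with OR, 95% CI, p and BH-FDR adjusted p.
    Single-level domains are skipped with a warning.
    """
    if len(cases) == 0:
        raise ValueError("case subset is empty")
    rows = []
    for d in domains:
        sub = cases[[d, prs_col, *covariates]].dropna()
        y = sub[d].to_numpy(dtype=float)
        if np.unique(y).size < 2:
            warnings.warn(f"domain {d!r} has a single level; skipped")
            continue
        y = (y > np.min(y)).astype(float)  # ordinal domains: any exposure vs none
        X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
        X[prs_col] = sub[prs_col].to_numpy(dtype=float)
        for cov in covariates:
            X[cov] = sub[cov].to_numpy(dtype=float)
        fit = fit_logistic(X, y, list(X.columns))
        orv, lo, hi = fit.or_ci(prs_col)
        rows.append(
            {"domain": d, "n": fit.n, "or": orv, "ci_low": lo, "ci_high": hi,
             "p": fit.wald_p(prs_col)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_p"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def results_table(fits: dict, model_specs: dict) -> pd.DataFrame:
    """One row per term per model: estimate, SE, OR, CI, p, FDR-p plus
    Nagelkerke R², AIC, BIC and n.  ``fits`` maps model name -> ModelFit."""
    rows = []
    for name, fit in fits.items():
        aic, bic = information_criteria(fit)
        r2 = nagelkerke_r2(fit) if fit.family == "binomial" else np.nan
        tab = fit.table()
        for _, row in tab.iterrows():
            rows.append(
                {
                    "model_type": name,
                    "term": row["term"],
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "or": row.get("or", np.nan),
                    "ci_low": row.get("ci_low", np.nan),
                    "ci_high": row.get("ci_high", np.nan),
                    "p": row["p"],
                    "nagelkerke_r2": r2,
                    "aic": aic,
                    "bic": bic,
                    "n": fit.n,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_p"] = bh_fdr(out["p"].to_numpy())
    return out
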
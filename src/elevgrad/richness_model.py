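"""Species-richness modelling along the elevational gradient.

Spearman screening of covariates, a log-link quasipoisson GLM of per-site
richness (Poisson point estimates with a Pearson-estimated dispersion
inflating the standard errors), analysis-of-deviance F-tests between nested
fits, and backwards stepwise term elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "CountGLMFit",
    "DevianceTest",
    "StepwiseResult",
    "SingularDesignError",
    "spearman_correlation",
    "spearman_matrix",
    "fit_quasipoisson",
    "anova_f",
    "term_f_table",
    "backwards_stepwise",
]


class SingularDesignError(ValueError):
    """Model matrix is rank deficient (collinear or separated design)."""


@dataclass(frozen=True)
class DevianceTest:
    """One analysis-of-deviance F comparison."""

    term_tested: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "term": self.term_tested,
            "F": self.f_value,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p_value,
        }


@dataclass
class CountGLMFit:
    """A fitted quasipoisson (log-link) richness model.

    Coefficients are the Poisson maximum-likelihood estimates; ``dispersion``
    is the Pearson chi-square estimate of the quasi-likelihood scale and
    ``standard_errors`` are the Poisson errors inflated by its square root.
    """

    terms: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    dispersion: float
    null_deviance: float
    df_null: int
    residual_deviance: float
    df_residual: int
    n: int
    table: pd.DataFrame = field(repr=False)
    response: str = "richness"

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "dispersion": float(self.dispersion),
            "null_deviance": float(self.null_deviance),
            "df_null": int(self.df_null),
            "residual_deviance": float(self.residual_deviance),
            "df_residual": int(self.df_residual),
            "n": int(self.n),
        }


def spearman_correlation(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with its t-approximation p-value.

    Requires at least four paired observations; a constant vector leaves the
    correlation undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """All pairwise Spearman correlations among ``variables`` (long format)."""
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            rho, p = spearman_correlation(table[a], table[b])
            rows.append({"var_a": a, "var_b": b, "rho": rho, "p": p})
    return pd.DataFrame(rows)


def _design_matrix(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build the model matrix: intercept, treatment-coded factors, numeric terms."""
    columns = [np.ones(len(table))]
    names = ["Intercept"]
    for term in terms:
        col = table[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # treatment contrasts, first level reference
                columns.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
        else:
            columns.append(col.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(f"rank-deficient design for terms {terms}")
    return X, names


def fit_quasipoisson(
    table: pd.DataFrame, terms: list[str], response: str = "richness"
) -> CountGLMFit:
    """Fit the log-link quasipoisson GLM of ``response`` on ``terms``.

    Point estimates coincide with the Poisson GLM (IRLS); the dispersion is
    the Pearson chi-square divided by the residual degrees of freedom, and
    standard errors are scaled by its square root.  String/categorical terms
    enter as unordered factors with treatment contrasts (alphabetically
    first level as reference).
    """
    y = table[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("response must be non-negative counts")
    X, names = _design_matrix(table, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        result = model.fit(scale="X2", maxiter=200, tol=1e-10)
    if not getattr(result, "converged", True):
        raise RuntimeError(f"IRLS failed to converge for terms {terms}")
    coef = pd.Series(result.params, index=names)
    se = pd.Series(result.bse, index=names)
    return CountGLMFit(
        terms=list(terms),
        coefficients=coef,
        standard_errors=se,
        dispersion=float(result.scale),
        null_deviance=float(result.null_deviance),
        df_null=n - 1,
        residual_deviance=float(result.deviance),
        df_residual=n - p,
        n=n,
        table=table,
        response=response,
    )


def anova_f(reduced: CountGLMFit, full: CountGLMFit, term: str = "") -> DevianceTest:
    """F-test comparing a reduced quasipoisson fit against a nesting full fit.

    F = ((dev_reduced − dev_full)/Δdf) / φ_full, referred to an F
    distribution on (Δdf, df_residual of the full model).  Identical models
    give F = 0, p = 1.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError(
            f"models are not nested: {reduced.terms} is not a subset of {full.terms}"
        )
    if reduced.n != full.n:
        raise ValueError("models fitted to different data")
    ddf = reduced.df_residual - full.df_residual
    if ddf == 0:
        return DevianceTest(term, 0.0, 1, full.df_residual, 1.0)
    ddev = reduced.residual_deviance - full.residual_deviance
    f = max(ddev, 0.0) / ddf / full.dispersion
    p = float(scipy.stats.f.sf(f, ddf, full.df_residual))
    return DevianceTest(term or "+".join(sorted(set(full.terms) - set(reduced.terms))),
                        f, ddf, full.df_residual, p)


def term_f_table(fit: CountGLMFit, kind: str = "sequential") -> list[DevianceTest]:
    """Per-term analysis-of-deviance F-tests for a fitted model.

    ``kind='sequential'`` adds terms in the model's stated order (type-I
    deviance drops); ``kind='deletion'`` tests each term by dropping it from
    the full model.  Either way F is scaled by the full model's dispersion.
    """
    if kind not in {"sequential", "deletion"}:
        raise ValueError(f"unknown test kind {kind!r}")
    tests: list[DevianceTest] = []
    if kind == "sequential":
        previous = fit_quasipoisson(fit.table, [], response=fit.response)
        for i, term in enumerate(fit.terms):
            current = fit_quasipoisson(fit.table, fit.terms[: i + 1], response=fit.response)
            ddf = previous.df_residual - current.df_residual
            ddev = previous.residual_deviance - current.residual_deviance
            f = max(ddev, 0.0) / ddf / fit.dispersion
            p = float(scipy.stats.f.sf(f, ddf, fit.df_residual))
            tests.append(DevianceTest(term, f, ddf, fit.df_residual, p))
            previous = current
    else:
        for term in fit.terms:
            reduced = fit_quasipoisson(
                fit.table, [t for t in fit.terms if t != term], response=fit.response
            )
            tests.append(anova_f(reduced, fit, term=term))
    return tests


@dataclass
class StepwiseResult:
    """Final fit plus the full elimination trace."""

    final: CountGLMFit
    trace: list[dict]

    def to_dict(self) -> dict:
        return {"final": self.final.to_dict(), "trace": self.trace}


def backwards_stepwise(
    table: pd.DataFrame,
    full_terms: list[str],
    alpha: float = 0.05,
    variant: str = "deviance_guarded",
    deviance_budget: float = 2.0,
    response: str = "richness",
) -> StepwiseResult:
    """Backwards stepwise elimination driven by single-deletion F-tests.

    At each step the term whose deletion F-test has the largest p-value
    above ``alpha`` is removed and the model refitted; the comparison of the
    reduced model against the previous step's model is recorded.  Under the
    default ``deviance_guarded`` variant a removal is additionally forbidden
    (and the procedure stops) when the scaled deviance increase would exceed
    ``deviance_budget`` per degree of freedom — a guard that keeps terms
    whose removal worsens the deviance materially even when individually
    non-significant.  ``variant='strict_alpha'`` applies the p-value rule
    alone.
    """
    if variant not in {"deviance_guarded", "strict_alpha"}:
        raise ValueError(f"unknown stepwise variant {variant!r}")
    current = fit_quasipoisson(table, list(full_terms), response=response)
    trace: list[dict] = []
    while current.terms:
        deletions = term_f_table(current, kind="deletion")
        candidates = [t for t in deletions if t.p_value > alpha]
        if not candidates:
            trace.append({"action": "stop", "reason": "all terms significant",
                          "terms": list(current.terms)})
            break
        drop = max(candidates, key=lambda t: t.p_value)
        reduced = fit_quasipoisson(
            table, [t for t in current.terms if t != drop.term_tested], response=response
        )
        scaled_increase = (
            (reduced.residual_deviance - current.residual_deviance)
            / current.dispersion
            / drop.df_num
        )
        if variant == "deviance_guarded" and scaled_increase > deviance_budget:
            trace.append({
                "action": "stop",
                "reason": "deviance budget exceeded",
                "term": drop.term_tested,
                "scaled_deviance_increase_per_df": scaled_increase,
                "budget": deviance_budget,
                "terms": list(current.terms),
            })
            break
        comparison = anova_f(reduced, current, term=drop.term_tested)
        trace.append({
            "action": "remove",
            "term": drop.term_tested,
            "deletion_test": drop.to_dict(),
            "anova_vs_previous": comparison.to_dict(),
            "deviance_before": current.residual_deviance,
            "deviance_after": reduced.residual_deviance,
        })
        current = reduced
    if not current.terms:
        warnings.warn("stepwise elimination reached the intercept-only model", stacklevel=2)
    return StepwiseResult(final=current, trace=trace)
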
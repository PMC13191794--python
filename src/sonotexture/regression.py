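"""Gamma log-link regression of blood loss with mean-ratio reporting.

Blood loss in millilitres is continuous and strictly positive, so it is
modelled as Gamma-distributed with a log link: E[y | x] = exp(Xβ).  An
exponentiated coefficient exp(βⱼ) is a mean ratio (MR) — the
multiplicative change in expected blood loss per unit of xⱼ (for a
binary predictor, present vs. absent).

Model building mirrors the usual screening workflow: univariable fits
first, variables with p < 0.05 enter the multivariable model, and the
final model is chosen by AIC-based stepwise search over the screened
candidate set.  Benjamini–Hochberg FDR correction is applied to the
final model's p-values.

Fitting is delegated to statsmodels (IRLS); on top of the fit the
dispersion φ is the Pearson estimator, and log-likelihood/AIC use the
moment plug-in shape 1/φ, re-evaluated per candidate model, with
AIC = −2·loglik + 2·(#coefficients + 1).  Only relative AICs matter for
the stepwise search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .types import OUTCOME_COL

__all__ = [
    "GammaFit",
    "MeanRatioEstimate",
    "fit_gamma_log",
    "mean_ratios",
    "univariate_screen",
    "stepwise_aic",
    "fdr_adjust",
]


@dataclass(frozen=True)
class GammaFit:
    """A fitted Gamma log-link model."""

    terms: tuple[str, ...]  # includes "Intercept" first
    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    deviance: float
    loglik: float
    aic: float
    n: int
    fitted_mean: np.ndarray
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected blood loss for new rows (mL)."""
        mat = _design(X, [t for t in self.terms if t != "Intercept"])
        return np.exp(mat.to_numpy() @ self.beta)


@dataclass(frozen=True)
class MeanRatioEstimate:
    term: str
    mr: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    p_fdr: float | None = None


def _design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for t in terms:
        X[t] = pd.to_numeric(data[t], errors="raise").astype(float)
    return X


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Gamma log-likelihood with moment plug-in shape k = 1/φ."""
    k = 1.0 / phi
    return float(
        np.sum(
            k * np.log(k / mu)
            + (k - 1.0) * np.log(y)
            - k * y / mu
            - special.gammaln(k)
        )
    )


def fit_gamma_log(data: pd.DataFrame, terms: list[str], outcome: str = OUTCOME_COL) -> GammaFit:
    """Fit E[y] = exp(β₀ + Σ βⱼ xⱼ) by IRLS with Gamma variance.

    ``terms`` are column names of ``data``; an intercept is always
    included.  Raises on non-positive outcomes or a rank-deficient
    design; non-convergence is reported via the ``converged`` flag.
    """
    y = data[outcome].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("outcome must be strictly positive")
    X = _design(data, list(terms))
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if len(y) <= mat.shape[1]:
        raise ValueError("need more subjects than coefficients")

    model = sm.GLM(y, mat, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=100, tol=1e-8, scale="X2")  # Pearson dispersion
    mu = np.asarray(res.fittedvalues)
    p = mat.shape[1]
    phi = float(res.scale)
    loglik = _gamma_loglik(y, mu, phi)
    aic = -2.0 * loglik + 2.0 * (p + 1)
    return GammaFit(
        terms=tuple(X.columns),
        beta=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        dispersion=phi,
        deviance=float(res.deviance),
        loglik=loglik,
        aic=aic,
        n=len(y),
        fitted_mean=mu,
        converged=bool(res.converged),
    )


def mean_ratios(fit: GammaFit, include_intercept: bool = False) -> list[MeanRatioEstimate]:
    """MR = exp(β) with 95% Wald CIs and two-sided z p-values."""
    out = []
    for i, term in enumerate(fit.terms):
        if term == "Intercept" and not include_intercept:
            continue
        b = float(fit.beta[i])
        se = float(fit.se[i])
        z = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            MeanRatioEstimate(
                term=term,
                mr=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p_value=p,
                beta=b,
                se=se,
            )
        )
    return out


def univariate_screen(
    data: pd.DataFrame,
    variables: list[str],
    outcome: str = OUTCOME_COL,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Fit each variable alone (with intercept); keep those with p < alpha.

    Per the screening role of this step, p-values are NOT adjusted for
    multiplicity here.  Constant variables are skipped with a log entry.
    An empty candidate set is a valid result.
    """
    import logging

    rows = []
    candidates = []
    for var in variables:
        x = pd.to_numeric(data[var], errors="coerce")
        if x.nunique(dropna=True) < 2:
            logging.getLogger("sonotexture").info("skipping constant variable %s", var)
            continue
        fit = fit_gamma_log(data, [var], outcome=outcome)
        (est,) = mean_ratios(fit)
        rows.append(
            dict(variable=var, mr=est.mr, ci_low=est.ci_low, ci_high=est.ci_high, p=est.p_value)
        )
        if est.p_value < alpha:
            candidates.append(var)
    report = pd.DataFrame(rows, columns=["variable", "mr", "ci_low", "ci_high", "p"])
    return candidates, report


def stepwise_aic(
    data: pd.DataFrame,
    candidates: list[str],
    outcome: str = OUTCOME_COL,
    direction: str = "both",
) -> GammaFit:
    """AIC-based stepwise search over the screened candidate set.

    Starts from the full candidate model and repeatedly applies the
    single add/drop move that lowers AIC most, stopping at a local
    minimum.  Deterministic: candidate order is lexicographic and ties
    favour the first move in that order.  An intercept-only model is a
    valid endpoint.
    """
    if direction not in ("both", "backward"):
        raise ValueError("direction must be 'both' or 'backward'")
    pool = sorted(candidates)
    current = list(pool)
    best = fit_gamma_log(data, current, outcome=outcome)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for term in current:
            trial = [t for t in current if t != term]
            moves.append((fit_gamma_log(data, trial, outcome=outcome).aic, trial))
        if direction == "both":
            for term in pool:
                if term not in current:
                    trial = sorted(current + [term])
                    moves.append((fit_gamma_log(data, trial, outcome=outcome).aic, trial))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic < best.aic - 1e-10:
            current = best_terms
            best = fit_gamma_log(data, current, outcome=outcome)
        else:
            break
    return best


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
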
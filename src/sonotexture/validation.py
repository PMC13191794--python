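"""Internal validation: discrimination, optimism correction, calibration, ICC.

Discrimination of the continuous blood-loss prediction is summarized at
the two hemorrhage thresholds (> 500 mL and > 1000 mL, strict
inequalities) by the AUC — the Mann–Whitney concordance of predicted
blood loss between events and non-events, with ties counted 0.5.  The
AUC variance uses DeLong's placement-value estimator; correlated AUCs
from two models on the same subjects are compared with DeLong's paired
test.  Internal validation follows the bootstrap optimism recipe: refit
the same model (fixed term set) on each resample, score it on the
resample and on the original data, and subtract the mean difference
from the apparent AUC.  Calibration is the least-squares line of
observed on predicted blood loss (ideal slope 1, intercept 0) with a
bootstrap bias correction.  Reader reliability uses the two-way
random-effects, absolute-agreement, single-measure ICC with the Koo–Li
interpretation bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import fit_gamma_log
from .types import OUTCOME_COL

logger = logging.getLogger("sonotexture")

__all__ = [
    "rmse",
    "roc_auc",
    "delong_paired_test",
    "optimism_bootstrap",
    "calibration",
    "icc_agreement",
    "AUCResult",
    "BootstrapValidation",
    "CalibrationResult",
    "ReliabilityReport",
    "validate_model",
    "ValidationReport",
]

THRESHOLDS_ML = (500.0, 1000.0)


def rmse(observed, predicted) -> float:
    """Root mean squared error, millilitres."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values (V10 for positives, V01 for negatives)."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives, ties at 0.5
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return float(v10.mean()), v10, v01


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def roc_auc(predicted, events) -> AUCResult:
    """AUC with DeLong variance and a 95% Wald CI clipped to [0, 1]."""
    score = np.asarray(predicted, dtype=float)
    ev = np.asarray(events, dtype=bool)
    pos, neg = score[ev], score[~ev]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    auc, v10, v01 = _placements(pos, neg)
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0
    )
    se = float(np.sqrt(max(var, 0.0)))
    return AUCResult(
        auc=auc,
        se=se,
        ci_low=float(max(auc - 1.96 * se, 0.0)),
        ci_high=float(min(auc + 1.96 * se, 1.0)),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def delong_paired_test(pred_a, pred_b, events) -> tuple[float, float]:
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns (z, two-sided p).  A zero-variance difference (e.g. the two
    predictors rank subjects identically) yields z = 0, p = 1.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if a.shape != b.shape or a.shape != ev.shape:
        raise ValueError("predictors and events must be aligned")
    auc_a, v10a, v01a = _placements(a[ev], a[~ev])
    auc_b, v10b, v01b = _placements(b[ev], b[~ev])
    m, n = int(ev.sum()), int((~ev).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least two subjects per class")
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if not np.allclose(a, b):
            logger.warning("degenerate zero-variance AUC difference; p set to 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class BootstrapValidation:
    apparent_auc: float
    optimism: float
    corrected_auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_redrawn: int
    seed: int


def _auc_only(score: np.ndarray, ev: np.ndarray) -> float:
    pos, neg = score[ev], score[~ev]
    return _placements(pos, neg)[0]


def optimism_bootstrap(
    data: pd.DataFrame,
    terms: list[str],
    threshold_ml: float,
    n_boot: int = 1000,
    seed: int = 0,
    outcome: str = OUTCOME_COL,
) -> BootstrapValidation:
    """Harrell-style optimism correction of the apparent AUC.

    The model recipe (the term set) is held fixed; each iteration refits
    the coefficients on a bootstrap draw of subjects, computes the AUC
    on the draw (optimistic) and on the original sample, and records the
    difference.  corrected = apparent − mean(optimism).  The 95% CI is
    the 2.5/97.5 percentile band of the bootstrap test AUCs.  Resamples
    with a single outcome class are redrawn (count reported).
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    y = data[outcome].to_numpy(dtype=float)
    events = y > threshold_ml
    if events.all() or not events.any():
        raise ValueError("both outcome classes must be present")
    fit = fit_gamma_log(data, terms, outcome=outcome)
    apparent = _auc_only(fit.fitted_mean, events)

    rng = np.random.default_rng(seed)
    n = len(data)
    optimisms = np.empty(n_boot)
    test_aucs = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            ev_b = events[idx]
            if ev_b.any() and not ev_b.all():
                break
            n_redrawn += 1
        boot = data.iloc[idx]
        try:
            # wild resamples can push IRLS through transient overflows;
            # the converged fit is still usable for ranking subjects
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit_b = fit_gamma_log(boot, terms, outcome=outcome)
        except ValueError:  # rank-deficient draw: skip, count as no optimism
            optimisms[b] = 0.0
            test_aucs[b] = apparent
            continue
        auc_boot = _auc_only(fit_b.fitted_mean, ev_b)
        auc_orig = _auc_only(fit_b.predict(data), events)
        optimisms[b] = auc_boot - auc_orig
        test_aucs[b] = auc_orig
    mean_opt = float(optimisms.mean())
    lo, hi = np.percentile(test_aucs, [2.5, 97.5])
    if n_redrawn:
        logger.info("redrew %d single-class bootstrap resamples", n_redrawn)
    return BootstrapValidation(
        apparent_auc=apparent,
        optimism=mean_opt,
        corrected_auc=apparent - mean_opt,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    slope_corrected: float
    intercept_corrected: float
    n_boot: int
    seed: int


def calibration(observed, predicted, n_boot: int = 1000, seed: int = 0) -> CalibrationResult:
    """Calibration line of observed on predicted blood loss (mL scale).

    Apparent slope/intercept come from ordinary least squares; the
    bias-corrected line subtracts the mean bootstrap optimism
    (bootstrap estimate minus apparent) of each parameter.  Ideal
    reference: slope 1, intercept 0.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 10:
        raise ValueError("need at least 10 subjects")
    if np.var(pred) == 0:
        raise ValueError("zero-variance predictions cannot be calibrated")
    slope, intercept = np.polyfit(pred, obs, 1)
    rng = np.random.default_rng(seed)
    n = obs.size
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.var(pred[idx]) > 0:
                break
        boots[b] = np.polyfit(pred[idx], obs[idx], 1)
    opt = boots.mean(axis=0) - np.array([slope, intercept])
    return CalibrationResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_corrected=float(slope - opt[0]),
        intercept_corrected=float(intercept - opt[1]),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_raters: int


def _koo_li_band(icc: float) -> str:
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ReliabilityReport:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete subjects × raters matrix.  The point
    estimate and the F-based confidence interval follow the standard
    ANOVA mean-squares formulation (McGraw & Wong's ICC(A,1)); the
    qualitative band follows Koo & Li (< 0.50 poor, 0.50–0.75 moderate,
    0.75–0.90 good, ≥ 0.90 excellent).
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = Y.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if np.isnan(Y).any():
        raise ValueError("ratings matrix must be complete")

    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom > 0 else 1.0

    # F-based CI for ICC(A,1) with Satterthwaite denominator df
    if mse == 0:
        lo = hi = icc
    else:
        fj = msc / mse
        df2 = (n - 1) * (k - 1)
        vn = df2 * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = float(n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = float(n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
        lo, hi = max(min(lo, icc), -1.0), min(max(hi, icc), 1.0)
    return ReliabilityReport(
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        band=_koo_li_band(icc),
        n_subjects=n,
        n_raters=k,
    )


@dataclass(frozen=True)
class ValidationReport:
    rmse_ml: float
    per_threshold: dict[float, dict]
    calibration: CalibrationResult
    n_boot: int
    seed: int


def validate_model(
    data: pd.DataFrame,
    terms: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    outcome: str = OUTCOME_COL,
    thresholds: tuple[float, ...] = THRESHOLDS_ML,
) -> ValidationReport:
    """Full internal validation of one fitted model recipe."""
    fit = fit_gamma_log(data, terms, outcome=outcome)
    y = data[outcome].to_numpy(dtype=float)
    report: dict[float, dict] = {}
    for i, thr in enumerate(thresholds):
        events = y > thr
        apparent = roc_auc(fit.fitted_mean, events)
        boot = optimism_bootstrap(
            data, terms, thr, n_boot=n_boot, seed=seed + i, outcome=outcome
        )
        report[thr] = {
            "auc": apparent.auc,
            "auc_ci_low": apparent.ci_low,
            "auc_ci_high": apparent.ci_high,
            "optimism": boot.optimism,
            "auc_corrected": boot.corrected_auc,
            "auc_corrected_ci_low": boot.ci_low,
            "auc_corrected_ci_high": boot.ci_high,
        }
    cal = calibration(y, fit.fitted_mean, n_boot=n_boot, seed=seed)
    return ValidationReport(
        rmse_ml=rmse(y, fit.fitted_mean),
        per_threshold=report,
        calibration=cal,
        n_boot=n_boot,
        seed=seed,
    )
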
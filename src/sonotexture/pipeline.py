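"""End-to-end model building: features + clinical data → three models.

Mirrors the study's modelling structure:

* Model 1 — radiomic candidates only,
* Model 2 — clinical/sonographic candidates only,
* Model 3 — the union (integrated model),

each built by the same recipe: univariable Gamma log-link screening
(p < 0.05), AIC-based stepwise selection over the screened candidates,
FDR correction of the final model's p-values, then internal validation
(RMSE, AUC at the 500/1000 mL thresholds, bootstrap optimism
correction, calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regression import (
    GammaFit,
    fdr_adjust,
    fit_gamma_log,
    mean_ratios,
    stepwise_aic,
    univariate_screen,
)
from .selection import select_features
from .types import OUTCOME_COL
from .validation import ValidationReport, validate_model

__all__ = ["ModelResult", "build_model", "run_study"]


@dataclass
class ModelResult:
    name: str
    candidates: list[str]
    screen_report: pd.DataFrame
    fit: GammaFit
    effects: pd.DataFrame  # term, MR, CI, p, p_fdr
    validation: ValidationReport | None = None


def build_model(
    data: pd.DataFrame,
    variables: list[str],
    name: str = "model",
    alpha: float = 0.05,
    validate: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> ModelResult:
    """Screen → stepwise → FDR → (optionally) validate one variable set."""
    candidates, screen = univariate_screen(data, variables, alpha=alpha)
    if candidates:
        fit = stepwise_aic(data, candidates)
    else:
        fit = fit_gamma_log(data, [])
    estimates = mean_ratios(fit)
    effects = pd.DataFrame(
        dict(
            term=[e.term for e in estimates],
            mr=[e.mr for e in estimates],
            ci_low=[e.ci_low for e in estimates],
            ci_high=[e.ci_high for e in estimates],
            p=[e.p_value for e in estimates],
        )
    )
    if len(effects):
        effects["p_fdr"] = fdr_adjust(effects["p"].to_numpy())
    else:
        effects["p_fdr"] = []
    validation = None
    if validate and len(fit.terms) > 1:
        validation = validate_model(data, [t for t in fit.terms if t != "Intercept"],
                                    n_boot=n_boot, seed=seed)
    return ModelResult(
        name=name,
        candidates=candidates,
        screen_report=screen,
        fit=fit,
        effects=effects,
        validation=validation,
    )


def run_study(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    k_top: int = 15,
    seed: int = 0,
    validate: bool = True,
    n_boot: int = 1000,
    selection_kwargs: dict | None = None,
) -> dict[str, ModelResult]:
    """Run the full three-model comparison.

    ``features`` is the radiomic feature table with the outcome column;
    ``clinical`` holds the clinical/sonographic covariates (no outcome
    needed — the outcome travels with the features).
    """
    selected, _ = select_features(features, k=k_top, seed=seed, **(selection_kwargs or {}))
    radiomic_vars = [c for c in selected.columns if c != OUTCOME_COL]
    clinical_vars = [c for c in clinical.columns if c != OUTCOME_COL]
    data = selected.join(clinical[clinical_vars], how="inner")

    out = {}
    out["radiomics"] = build_model(
        data, radiomic_vars, name="radiomics", validate=validate, n_boot=n_boot, seed=seed
    )
    out["clinical"] = build_model(
        data, clinical_vars, name="clinical", validate=validate, n_boot=n_boot, seed=seed
    )
    out["integrated"] = build_model(
        data, radiomic_vars + clinical_vars, name="integrated",
        validate=validate, n_boot=n_boot, seed=seed,
    )
    return out
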
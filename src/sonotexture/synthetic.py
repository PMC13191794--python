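"""Synthetic textured-ROI cohorts with known ground truth.

The study population this emulates is women with placenta previa or a
low-lying placenta: ~107 subjects, one 5 × 5 mm ROI per tissue
(placenta, PUM, FM) per gestational window (20w, 30w), binary clinical
covariates, and a strictly positive postpartum blood loss in millilitres
with median around 400 mL (IQR roughly 300–700) and event rates near
48% (> 500 mL) and 15% (> 1000 mL).

Texture is simulated as a stationary correlated Gaussian field:
unit-variance white noise smoothed with a Gaussian kernel whose scale is
the correlation length, optionally passed through a monotone exponential
tilt that controls skewness, then affinely mapped to the target
mean/standard deviation on the 8-bit gray scale and clipped.

Planted effects act through per-subject latent z-scores of the generator
parameters: for each tissue × window, a subject draws one standard
normal deviation per parameter; the rendered patch uses
``base + scale · z`` while the outcome's linear predictor uses the z
itself.  Feature extraction therefore sees an attenuated, noisy version
of the planted signal — parameter-recovery checks must use tolerance
bands.  Blood loss is Gamma with shape ``gamma_shape`` and mean
``exp(β₀ + Σ βⱼ xⱼ)``.

All randomness flows from one integer seed through independent
per-subject/per-patch child streams (numpy ``SeedSequence.spawn``), so
every fixture is reproducible patch-by-patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import ImagePatch, TISSUES, WINDOWS

__all__ = [
    "TextureParams",
    "CohortSpec",
    "SyntheticSubject",
    "make_texture_patch",
    "simulate_cohort",
    "write_cohort",
]

PARAM_NAMES = ("mean_intensity", "intensity_sd", "correlation_length", "skew_strength")


@dataclass(frozen=True)
class TextureParams:
    """Base generator parameters for one tissue × window."""

    mean_intensity: float = 120.0
    intensity_sd: float = 30.0
    correlation_length: float = 2.0
    skew_strength: float = 0.0


def _default_texture_params() -> dict[str, TextureParams]:
    # tissue-specific base echogenicity; placenta brighter and coarser
    out: dict[str, TextureParams] = {}
    base = {
        "placenta": TextureParams(140.0, 28.0, 2.5, 0.2),
        "PUM": TextureParams(100.0, 25.0, 1.8, 0.0),
        "FM": TextureParams(90.0, 22.0, 1.5, 0.0),
    }
    for tissue in TISSUES:
        for window in WINDOWS:
            out[f"{tissue}_{window}"] = base[tissue]
    return out


def _default_betas() -> dict[str, float]:
    # clinical effects on the log-mean scale, from the emulated cohort;
    # texture effects are per SD of the latent generator parameter
    return {
        "previous_cesarean": float(np.log(1.96)),
        "previa_enrollment": float(np.log(1.37)),
        "resolution": float(np.log(0.54)),
        "placenta_30w_skew_strength": 0.30,
        "PUM_30w_correlation_length": -0.25,
        "placenta_20w_mean_intensity": -0.20,
    }


def _default_prevalences() -> dict[str, float]:
    return {
        "previous_cesarean": 16 / 107,
        "previa_enrollment": 38 / 107,
        "resolution": 85 / 107,
    }


#: per-parameter scale of subject-level deviations (additive, except
#: correlation_length which is multiplicative exp(0.25 z) to stay > 0)
JITTER = {
    "mean_intensity": 10.0,
    "intensity_sd": 4.0,
    "correlation_length": 0.25,
    "skew_strength": 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a synthetic cohort."""

    n_subjects: int = 107
    patch_size_px: int = 64
    tissues: tuple[str, ...] = TISSUES
    windows: tuple[str, ...] = WINDOWS
    texture_params: dict[str, TextureParams] = field(default_factory=_default_texture_params)
    clinical_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    beta: dict[str, float] = field(default_factory=_default_betas)
    beta0: float = float(np.log(650.0))
    gamma_shape: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        for key, tp in self.texture_params.items():
            if tp.correlation_length <= 0:
                raise ValueError(f"correlation_length must be positive ({key})")
        for name, p in self.clinical_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        valid = set(self.clinical_prevalences)
        for tissue in self.tissues:
            for window in self.windows:
                valid.update(f"{tissue}_{window}_{p}" for p in PARAM_NAMES)
        unknown = set(self.beta) - valid
        if unknown:
            raise ValueError(f"beta refers to unknown features: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    patches: dict[str, ImagePatch]
    covariates: dict[str, float]
    latents: dict[str, float]
    blood_loss_ml: float

    def __post_init__(self) -> None:
        if self.blood_loss_ml <= 0:
            raise ValueError("blood loss must be strictly positive")


def make_texture_patch(
    mean_intensity: float,
    intensity_sd: float,
    correlation_length: float,
    skew_strength: float,
    size_px: int = 64,
    seed: int | np.random.Generator = 0,
    tissue: str = "placenta",
    window: str = "20w",
    subject_id: str = "synthetic",
    pixel_spacing_mm: tuple[float, float] | None = None,
) -> ImagePatch:
    """Render one correlated-Gaussian-field patch.

    A unit white-noise field is Gaussian-smoothed at scale
    ``correlation_length`` (pixels), re-standardized, exponentially
    tilted by ``skew_strength`` (sign controls skew direction),
    standardized again, mapped to ``mean_intensity`` ± ``intensity_sd``
    and clipped to [0, 255].  Deterministic given the seed.
    """
    if size_px < 8:
        raise ValueError("size_px must be at least 8")
    if intensity_sd < 0:
        raise ValueError("intensity_sd must be non-negative")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    if correlation_length >= size_px:
        raise ValueError("correlation_length must be smaller than the patch")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((size_px, size_px))
    z = gaussian_filter(z, sigma=correlation_length, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    if skew_strength != 0.0 and intensity_sd > 0:
        # monotone increasing tilt whose skewness carries the sign of s
        # (plain exp(s z) is right-skewed for either sign)
        z = np.expm1(skew_strength * z) / skew_strength
        zsd = z.std()
        z = (z - z.mean()) / zsd if zsd > 0 else np.zeros_like(z)
    if intensity_sd == 0:
        gray = np.full((size_px, size_px), float(mean_intensity))
    else:
        gray = mean_intensity + intensity_sd * z
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    if pixel_spacing_mm is None:
        s = 5.0 / size_px  # 5 x 5 mm ROI
        pixel_spacing_mm = (s, s)
    return ImagePatch(
        pixels=pixels,
        tissue=tissue,
        window=window,
        subject_id=subject_id,
        pixel_spacing_mm=pixel_spacing_mm,
    )


def _subject_linear_predictor(spec: CohortSpec, covs: dict[str, float], latents: dict[str, float]) -> float:
    lp = spec.beta0
    for name, b in spec.beta.items():
        x = covs.get(name)
        if x is None:
            x = latents[name]
        lp += b * x
    return lp


def simulate_cohort(spec: CohortSpec, render_images: bool = True) -> list[SyntheticSubject]:
    """Draw a full synthetic cohort from ``spec``.

    With ``render_images=False`` the patches dict is left empty (latents,
    covariates and outcomes only) — useful for statistical calibration
    studies that do not touch the image pipeline.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    width = len(str(spec.n_subjects - 1))
    subjects: list[SyntheticSubject] = []
    for idx, child in enumerate(children):
        sid = f"S{idx:0{width}d}"
        sub_rng = np.random.default_rng(child)
        covs = {
            name: float(sub_rng.random() < prob)
            for name, prob in spec.clinical_prevalences.items()
        }
        latents: dict[str, float] = {}
        patches: dict[str, ImagePatch] = {}
        for tissue in spec.tissues:
            for window in spec.windows:
                key = f"{tissue}_{window}"
                base = spec.texture_params[key]
                z = {p: float(sub_rng.standard_normal()) for p in PARAM_NAMES}
                for p in PARAM_NAMES:
                    latents[f"{key}_{p}"] = z[p]
                if render_images:
                    params = dict(
                        mean_intensity=base.mean_intensity + JITTER["mean_intensity"] * z["mean_intensity"],
                        intensity_sd=max(base.intensity_sd + JITTER["intensity_sd"] * z["intensity_sd"], 1.0),
                        correlation_length=base.correlation_length
                        * float(np.exp(JITTER["correlation_length"] * z["correlation_length"])),
                        skew_strength=base.skew_strength + JITTER["skew_strength"] * z["skew_strength"],
                    )
                    patches[key] = make_texture_patch(
                        **params,
                        size_px=spec.patch_size_px,
                        seed=sub_rng,
                        tissue=tissue,
                        window=window,
                        subject_id=sid,
                    )
        lp = _subject_linear_predictor(spec, covs, latents)
        mean = float(np.exp(lp))
        loss = float(sub_rng.gamma(spec.gamma_shape, mean / spec.gamma_shape))
        loss = max(loss, 1e-6)  # Gamma is a.s. positive; guard float underflow
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                patches=patches,
                covariates=covs,
                latents=latents,
                blood_loss_ml=loss,
            )
        )
    return subjects


def cohort_frames(subjects: list[SyntheticSubject]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(covariates+outcome, latent z-scores) DataFrames indexed by subject."""
    cov = pd.DataFrame(
        {**s.covariates, "blood_loss_ml": s.blood_loss_ml}
        for s in subjects
    )
    cov.index = pd.Index([s.subject_id for s in subjects], name="subject_id")
    lat = pd.DataFrame([s.latents for s in subjects])
    lat.index = cov.index
    return cov, lat


def write_cohort(subjects: list[SyntheticSubject], spec: CohortSpec, out_dir: str | Path) -> None:
    """Write a cohort to disk: PNGs, ROI sidecar, covariates, ground truth."""
    from PIL import Image

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    roi_rows = []
    for s in subjects:
        for key, patch in s.patches.items():
            fname = f"{s.subject_id}_{key}.png"
            Image.fromarray(patch.pixels, mode="L").save(img_dir / fname)
            roi_rows.append(
                dict(
                    subject_id=s.subject_id,
                    image_path=f"images/{fname}",
                    tissue=patch.tissue,
                    window=patch.window,
                    x=0,
                    y=0,
                    width=patch.pixels.shape[1],
                    height=patch.pixels.shape[0],
                    spacing_row_mm=patch.pixel_spacing_mm[0],
                    spacing_col_mm=patch.pixel_spacing_mm[1],
                )
            )
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    cov, _ = cohort_frames(subjects)
    cov.to_csv(out / "clinical.csv")
    truth = {
        "beta0": spec.beta0,
        "beta": dict(spec.beta),
        "gamma_shape": spec.gamma_shape,
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
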
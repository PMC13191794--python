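"""Core data containers shared across the pipeline.

The pipeline works on rectangular grayscale regions of interest (ROIs)
cropped from obstetric ultrasound images.  Each ROI is labelled with the
tissue it samples — placenta, placental underlying myometrium (PUM) or
free myometrium (FM) — and the gestational window of the scan (20 or 30
weeks).  Feature tables are plain pandas DataFrames, one row per subject,
with columns named ``{tissue}_{window}_{source}_{feature}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TISSUES = ("placenta", "PUM", "FM")
WINDOWS = ("20w", "30w")

#: column holding the outcome in feature tables, millilitres
OUTCOME_COL = "blood_loss_ml"


@dataclass(frozen=True)
class ImagePatch:
    """One grayscale ROI with its acquisition metadata.

    Parameters
    ----------
    pixels
        2-D integer array of gray values in [0, 255].
    tissue
        One of :data:`TISSUES`.
    window
        One of :data:`WINDOWS`.
    subject_id
        Identifier linking the patch to a cohort row.
    pixel_spacing_mm
        Physical size of one pixel, (row, col), millimetres.
    """

    pixels: np.ndarray
    tissue: str
    window: str
    subject_id: str
    pixel_spacing_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("patch must be a 2-D array of at least 2x2 pixels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}; expected one of {WINDOWS}")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px))

    @property
    def key(self) -> str:
        return f"{self.tissue}_{self.window}"


@dataclass(frozen=True)
class RoiRecord:
    """A rectangular ROI inside an image file.

    Coordinates are 0-based with the half-open convention: the crop is
    ``image[y:y+height, x:x+width]``.
    """

    subject_id: str
    image_path: str
    tissue: str
    window: str
    x: int
    y: int
    width: int
    height: int
    pixel_spacing_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("ROI must be at least 2x2 pixels")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.tissue not in TISSUES or self.window not in WINDOWS:
            raise ValueError("tissue/window outside the closed vocabulary")


def feature_name(tissue: str, window: str, source: str, feature: str) -> str:
    """Canonical feature-column name, e.g. ``PUM_30w_glcm_imc1``."""
    return f"{tissue}_{window}_{source}_{feature}"
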
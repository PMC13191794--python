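"""Image/table I/O: ROI cropping, feature-table assembly, cohort summary.

Images are 8-bit grayscale PNG or uncompressed monochrome DICOM.  RGB
inputs are reduced to luminance with the fixed Rec.601 weights; 16-bit
pixel data are linearly rescaled to [0, 255].  ROI rectangles come from
a sidecar CSV (0-based, half-open coordinates) — manual delineation of
the regions is out of scope here, the table is the contract.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .texture import GLCMConfig, extract_features
from .types import ImagePatch, RoiRecord, OUTCOME_COL

logger = logging.getLogger("sonotexture")

__all__ = [
    "load_image",
    "load_patch",
    "expected_roi_px",
    "read_rois",
    "build_feature_table",
    "cohort_summary",
]

REC601 = np.array([0.299, 0.587, 0.114])


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or DICOM file into an 8-bit grayscale array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValueError("only monochrome DICOM pixel data is supported")
    else:
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[..., :3] @ REC601
    if arr.max() > 255:  # 16-bit data: linear rescale into 8-bit range
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def load_patch(roi: RoiRecord, root: str | Path = ".") -> ImagePatch:
    """Crop one ROI rectangle out of its image, exactly (no resampling)."""
    img = load_image(Path(root) / roi.image_path)
    h, w = img.shape
    if roi.x + roi.width > w or roi.y + roi.height > h:
        raise ValueError(
            f"ROI ({roi.x},{roi.y},{roi.width},{roi.height}) outside {w}x{h} image "
            f"for subject {roi.subject_id}"
        )
    crop = img[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width]
    return ImagePatch(
        pixels=crop.copy(),
        tissue=roi.tissue,
        window=roi.window,
        subject_id=roi.subject_id,
        pixel_spacing_mm=roi.pixel_spacing_mm,
    )


def expected_roi_px(pixel_spacing_mm: float, roi_mm: float = 5.0) -> int:
    """Expected ROI side length in pixels for a square ROI of ``roi_mm``."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    return max(int(round(roi_mm / pixel_spacing_mm)), 2)


def read_rois(path: str | Path) -> list[RoiRecord]:
    """Parse the ROI sidecar CSV into records."""
    df = pd.read_csv(path)
    required = {"subject_id", "image_path", "tissue", "window", "x", "y", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        spacing = (
            (float(row.spacing_row_mm), float(row.spacing_col_mm))
            if "spacing_row_mm" in df.columns
            else (0.1, 0.1)
        )
        records.append(
            RoiRecord(
                subject_id=str(row.subject_id),
                image_path=str(row.image_path),
                tissue=str(row.tissue),
                window=str(row.window),
                x=int(row.x),
                y=int(row.y),
                width=int(row.width),
                height=int(row.height),
                pixel_spacing_mm=spacing,
            )
        )
    return records


def build_feature_table(
    rois: list[RoiRecord],
    root: str | Path = ".",
    config: GLCMConfig | None = None,
    outcome: pd.Series | None = None,
) -> pd.DataFrame:
    """Load every ROI, extract features, and assemble the subject table.

    Deterministic: the same files always give a bit-identical table.
    """
    by_subject: dict[str, list[ImagePatch]] = {}
    for roi in rois:
        by_subject.setdefault(roi.subject_id, []).append(load_patch(roi, root))
    rows = {sid: extract_features(patches, config) for sid, patches in sorted(by_subject.items())}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    if outcome is not None:
        table[OUTCOME_COL] = outcome.reindex(table.index)
        if (table[OUTCOME_COL] <= 0).any():
            raise ValueError("blood loss must be strictly positive")
    return table


def cohort_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Descriptive statistics with a normality screen per variable.

    Continuous variables are tested against a normal distribution with
    parameters fitted from the sample (Kolmogorov–Smirnov; note the
    Lilliefors caveat — fitted parameters make the nominal KS p-value
    conservative).  Normal-looking variables (p ≥ alpha) are summarized
    as mean ± SD, the rest as median (IQR).  Binary variables are
    reported as % (n/N).  Zero-variance columns are flagged degenerate
    and not tested.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for col in table.columns:
        x = pd.to_numeric(table[col], errors="coerce").dropna().to_numpy(dtype=float)
        n = x.size
        if n == 0:
            continue
        uniq = np.unique(x)
        if uniq.size == 1:
            rows.append(dict(variable=col, kind="degenerate", summary=f"constant = {uniq[0]:g}",
                             ks_p=np.nan))
            continue
        if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
            k = int(x.sum())
            rows.append(dict(variable=col, kind="binary",
                             summary=f"{100 * k / n:.2f}% ({k}/{n})", ks_p=np.nan))
            continue
        mu, sd = x.mean(), x.std(ddof=1)
        ks_p = float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)
        if ks_p >= alpha:
            summary = f"{mu:.2f} (±{sd:.2f})"
            kind = "normal"
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summary = f"{med:.2f} ({q1:.2f}/{q3:.2f})"
            kind = "non-normal"
        rows.append(dict(variable=col, kind=kind, summary=summary, ks_p=ks_p))
    return pd.DataFrame(rows).set_index("variable")
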
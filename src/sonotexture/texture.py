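"""First-order and gray-level co-occurrence (Haralick) texture features.

An ROI is summarized in two passes.  First-order statistics describe the
intensity histogram while ignoring spatial arrangement: mean, median,
standard deviation, skewness, excess kurtosis, and the Shannon entropy of
the quantized histogram.  Second-order statistics derive from the
gray-level co-occurrence matrix (GLCM): the joint distribution p(i, j) of
quantized levels of pixel pairs separated by a fixed displacement.  The
GLCM is computed symmetrically at distance 1 for the four standard
directions (0°, 45°, 90°, 135°), normalized per direction, and averaged;
the classical Haralick descriptors are then evaluated on the averaged
matrix.  All entropies are in bits, with 0·log 0 := 0.

Degenerate inputs (constant patches) are handled with explicit
conventions rather than exceptions, so batch extraction never aborts on a
flat ROI: correlation and the information measures of correlation default
to 0 when a required denominator vanishes, and the variance of a
point-mass difference distribution is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .types import ImagePatch, TISSUES, WINDOWS, feature_name

__all__ = [
    "GLCMConfig",
    "GrayLevelCooccurrence",
    "FirstOrderFeatures",
    "HaralickFeatures",
    "quantize",
    "compute_glcm",
    "first_order",
    "haralick",
    "extract_features",
    "FIRST_ORDER_NAMES",
    "HARALICK_NAMES",
]

#: the four standard direction angles, radians (skimage convention)
DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization and co-occurrence parameters.

    ``sum_variance_mode`` selects between the corrected modern convention
    (moments of the sum distribution about the sum average, the default)
    and the original-publication variant that centres on sum entropy.
    """

    levels: int = 32
    distance: int = 1
    angles: tuple[float, ...] = DEFAULT_ANGLES
    symmetric: bool = True
    sum_variance_mode: str = "corrected"  # or "original"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.levels > 256:
            raise ValueError("more than 256 levels is not supported")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.sum_variance_mode not in ("corrected", "original"):
            raise ValueError("sum_variance_mode must be 'corrected' or 'original'")


def quantize(pixels: np.ndarray, levels: int = 32) -> np.ndarray:
    """Quantize a gray patch into ``levels`` equal-width bins of its own range.

    Min–max binning is applied per ROI: the patch's observed range is
    split into ``levels`` equal-width bins, so features become invariant
    to affine shifts of the gray scale.  A constant patch maps entirely
    to level 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    if levels > 256:
        raise ValueError("more than 256 levels is not supported")
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros(px.shape, dtype=np.uint8)
    q = np.floor((px - lo) / (hi - lo) * levels).astype(np.int64)
    # the maximum falls on the right edge of the last bin
    np.clip(q, 0, levels - 1, out=q)
    return q.astype(np.uint8)


@dataclass(frozen=True)
class GrayLevelCooccurrence:
    """Normalized co-occurrence probabilities with derived distributions.

    ``p`` is the direction-averaged G×G probability matrix.  ``p_x`` and
    ``p_y`` are its marginals, ``p_sum[k]`` the distribution of i+j
    (k = 0..2G−2) and ``p_diff[d]`` the distribution of \\|i−j\\|
    (d = 0..G−1).
    """

    p: np.ndarray
    levels: int
    distance: int
    angles: tuple[float, ...]
    symmetric: bool
    per_direction: np.ndarray  # G×G×n_angles, each slice normalized

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("GLCM probabilities must sum to 1")
        if (p < -1e-15).any():
            raise ValueError("GLCM probabilities must be non-negative")

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def p_sum(self) -> np.ndarray:
        G = self.levels
        i, j = np.indices((G, G))
        out = np.zeros(2 * G - 1)
        np.add.at(out, (i + j).ravel(), self.p.ravel())
        return out

    @property
    def p_diff(self) -> np.ndarray:
        G = self.levels
        i, j = np.indices((G, G))
        out = np.zeros(G)
        np.add.at(out, np.abs(i - j).ravel(), self.p.ravel())
        return out


def compute_glcm(qpatch: np.ndarray, config: GLCMConfig | None = None) -> GrayLevelCooccurrence:
    """Co-occurrence matrix of a quantized patch, averaged over directions.

    Pair counts are accumulated per direction (symmetrically by default,
    i.e. each ordered pair counted in both orders), normalized to
    probabilities per direction, then averaged across directions.
    """
    cfg = config or GLCMConfig()
    q = np.asarray(qpatch)
    if q.ndim != 2 or min(q.shape) < 2:
        raise ValueError("quantized patch must be 2-D, at least 2x2")
    if q.min() < 0 or q.max() >= cfg.levels:
        raise ValueError("quantized values outside [0, levels)")
    if cfg.distance >= max(q.shape):
        raise ValueError("patch too small for the requested displacement")

    counts = graycomatrix(
        q.astype(np.uint8),
        distances=[cfg.distance],
        angles=list(cfg.angles),
        levels=cfg.levels,
        symmetric=cfg.symmetric,
        normed=False,
    )[:, :, 0, :].astype(np.float64)

    totals = counts.sum(axis=(0, 1))
    if (totals == 0).any():
        raise ValueError("no valid pixel pairs for at least one direction")
    per_dir = counts / totals
    p = per_dir.mean(axis=2)
    return GrayLevelCooccurrence(
        p=p,
        levels=cfg.levels,
        distance=cfg.distance,
        angles=tuple(cfg.angles),
        symmetric=cfg.symmetric,
        per_direction=per_dir,
    )


@dataclass(frozen=True)
class FirstOrderFeatures:
    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis_excess: float
    shannon_entropy: float
    degenerate: bool = False


@dataclass(frozen=True)
class HaralickFeatures:
    asm: float
    contrast: float
    correlation: float
    variance: float
    idm: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float
    difference_variance: float
    difference_entropy: float
    imc1: float
    imc2: float
    degenerate: bool = False


FIRST_ORDER_NAMES = tuple(f.name for f in dc_fields(FirstOrderFeatures) if f.name != "degenerate")
HARALICK_NAMES = tuple(f.name for f in dc_fields(HaralickFeatures) if f.name != "degenerate")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order(patch: ImagePatch | np.ndarray, levels: int = 32) -> FirstOrderFeatures:
    """Histogram statistics of the raw gray values.

    Moments use the denominator-n (population) convention; kurtosis is
    excess kurtosis.  Shannon entropy is that of the ``levels``-bin
    quantized histogram, in bits.  A constant patch is flagged degenerate
    with skewness, kurtosis and entropy defined as 0.
    """
    px = np.asarray(patch.pixels if isinstance(patch, ImagePatch) else patch, dtype=np.float64)
    if px.size < 4:
        raise ValueError("need at least 4 pixels")
    x = px.ravel()
    mean = float(x.mean())
    median = float(np.median(x))
    m2 = float(((x - mean) ** 2).mean())
    sd = float(np.sqrt(m2))
    if m2 == 0.0:
        return FirstOrderFeatures(mean, median, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - 3.0
    q = quantize(px, levels)
    h = np.bincount(q.ravel(), minlength=levels) / q.size
    return FirstOrderFeatures(mean, median, sd, skew, kurt, _entropy_bits(h))


def haralick(glcm: GrayLevelCooccurrence, sum_variance_mode: str = "corrected") -> HaralickFeatures:
    """Classical Haralick descriptors of a normalized GLCM.

    All entropies are Shannon entropies in bits.  The information
    measures of correlation use HX, HY, HXY, HXY1, HXY2 in bits; by the
    Gibbs inequality HXY1 ≥ HXY, so imc1 ≤ 0 for any non-degenerate
    matrix.
    """
    p = glcm.p
    G = glcm.levels
    i = np.arange(G, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = glcm.p_x
    py = glcm.p_y
    p_sum = glcm.p_sum
    p_diff = glcm.p_diff

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())

    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    degenerate = sig_x == 0.0 or sig_y == 0.0
    if degenerate:
        correlation = 0.0
    else:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))

    variance = float(((i - mu_x) ** 2 * px).sum())  # "sum of squares: variance"
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    k = np.arange(2 * G - 1, dtype=np.float64)
    sum_average = float((k * p_sum).sum())
    sum_entropy = _entropy_bits(p_sum)
    if sum_variance_mode == "corrected":
        sum_variance = float(((k - sum_average) ** 2 * p_sum).sum())
    else:  # original-publication form, centred on sum entropy
        sum_variance = float(((k - sum_entropy) ** 2 * p_sum).sum())

    entropy = _entropy_bits(p.ravel())

    d = np.arange(G, dtype=np.float64)
    mu_d = float((d * p_diff).sum())
    difference_variance = float(((d - mu_d) ** 2 * p_diff).sum())
    difference_entropy = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    hxy = entropy
    # cross entropies against the independence product px*py
    prod = np.outer(px, py)
    mask = (p > 0) & (prod > 0)
    hxy1 = float(-(p[mask] * np.log2(prod[mask])).sum())
    mask2 = prod > 0
    hxy2 = float(-(prod[mask2] * np.log2(prod[mask2])).sum())

    denom = max(hx, hy)
    imc1 = 0.0 if denom == 0.0 else float((hxy - hxy1) / denom)
    arg = 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    return HaralickFeatures(
        asm=asm,
        contrast=contrast,
        correlation=correlation,
        variance=variance,
        idm=idm,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        entropy=entropy,
        difference_variance=difference_variance,
        difference_entropy=difference_entropy,
        imc1=imc1,
        imc2=imc2,
        degenerate=degenerate,
    )


def extract_features(
    patches: list[ImagePatch] | dict[str, ImagePatch],
    config: GLCMConfig | None = None,
) -> pd.Series:
    """Feature row for one subject: first-order + Haralick per tissue/window.

    Returns a Series indexed by ``{tissue}_{window}_{fo|glcm}_{feature}``
    covering every tissue × window combination; combinations without a
    patch are NaN (missing, never silently zero).  Duplicate
    tissue/window patches for one subject are an error.
    """
    cfg = config or GLCMConfig()
    if isinstance(patches, dict):
        patch_list = list(patches.values())
    else:
        patch_list = list(patches)

    by_key: dict[str, ImagePatch] = {}
    for patch in patch_list:
        if patch.key in by_key:
            raise ValueError(f"duplicate patch for {patch.key}")
        by_key[patch.key] = patch

    values: dict[str, float] = {}
    for tissue in TISSUES:
        for window in WINDOWS:
            patch = by_key.get(f"{tissue}_{window}")
            if patch is None:
                for name in FIRST_ORDER_NAMES:
                    values[feature_name(tissue, window, "fo", name)] = np.nan
                for name in HARALICK_NAMES:
                    values[feature_name(tissue, window, "glcm", name)] = np.nan
                continue
            fo = first_order(patch, levels=cfg.levels)
            glcm = compute_glcm(quantize(patch.pixels, cfg.levels), cfg)
            har = haralick(glcm, sum_variance_mode=cfg.sum_variance_mode)
            for name in FIRST_ORDER_NAMES:
                values[feature_name(tissue, window, "fo", name)] = getattr(fo, name)
            for name in HARALICK_NAMES:
                values[feature_name(tissue, window, "glcm", name)] = getattr(har, name)
    return pd.Series(values)
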
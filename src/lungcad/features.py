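"""Hand-crafted nodule descriptors: texture, shape, intensity, semantic.

Texture comes from gray-level co-occurrence matrices (GLCM): the joint
probability ``p(i, j)`` of quantized level pairs at a spatial offset, from
which the Haralick-style statistics contrast, correlation, homogeneity and
entropy are computed.  Shape descriptors are measured on the binary nodule
mask (area, best-fit-ellipse aspect ratio, isoperimetric roundness and
circularity, traced-boundary perimeter).  Intensity descriptors are
first-order statistics of the masked region.  Semantic attributes mirror the
radiologist vocabulary: size bin, diameter, spiculation score, lobe location
and a coarse morphology category.

Conventions
-----------
* Coordinates are 0-based (row, column); mask and image share the grid.
* GLCM quantization: integer images whose maximum is below ``n_levels`` are
  used as-is, anything else is min-max quantized (over the masked region
  when a mask is given).
* The boundary used for circularity is an 8-connected Moore trace through
  pixel centers (ties broken clockwise from north); ``roundness`` instead
  uses the weighted Freeman perimeter estimate, which is less biased on
  smooth digital shapes.
* The spiculation score is an artifact convention: ``clamp01(1 - circularity)``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np
from skimage import measure

from .phantoms import NoduleSample

__all__ = [
    "Glcm",
    "FeatureConfig",
    "FeatureVector",
    "quantize_image",
    "compute_glcm",
    "texture_features",
    "shape_features",
    "intensity_features",
    "semantic_features",
    "extract_feature_vector",
    "trace_boundary",
    "isoperimetric_ratio",
    "DEFAULT_OFFSETS",
    "SIZE_BINS",
    "MORPHOLOGIES",
]

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
SIZE_BINS = ("<4 mm", "4-7 mm", "8-20 mm", ">20 mm")
MORPHOLOGIES = ("Smooth", "Lobulated", "Spiculated", "Irregular")

# morphology decision thresholds (documented artifact conventions)
SPICULATED_THRESHOLD = 0.45
SMOOTH_SPICULATION = 0.2
LOBULATED_ASPECT = 1.25


@dataclasses.dataclass(frozen=True)
class Glcm:
    matrix: np.ndarray
    offset: tuple[int, int]
    n_levels: int
    symmetric: bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must be non-negative and sum to 1")
        object.__setattr__(self, "matrix", m)


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    n_levels: int = 8
    offsets: tuple = DEFAULT_OFFSETS
    histogram_bins: int = 256
    include_sensor: bool = False


def quantize_image(image: np.ndarray, n_levels: int,
                   mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Quantize an image to ``n_levels`` gray levels.

    Integer images already within [0, n_levels) pass through unchanged;
    otherwise a min-max quantization (over the masked region if a mask is
    given) maps intensities to 0 .. n_levels-1.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 \
            and image.max() < n_levels:
        return image.astype(np.intp)
    ref = image[mask] if mask is not None else image
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def compute_glcm(image: np.ndarray, offset: tuple[int, int] = (0, 1),
                 n_levels: int = 8, symmetric: bool = True,
                 mask: Optional[np.ndarray] = None) -> Glcm:
    """Co-occurrence probabilities of level pairs at offset ``(di, dj)``.

    When a mask is given, only pairs with both pixels inside the mask count.
    """
    di, dj = offset
    if di == 0 and dj == 0:
        raise ValueError("offset must be nonzero")
    q = quantize_image(image, n_levels, mask)
    h, w = q.shape
    if abs(di) >= h or abs(dj) >= w:
        raise ValueError("offset larger than the image")

    src = q[max(0, -di):h - max(0, di), max(0, -dj):w - max(0, dj)]
    dst = q[max(0, di):h + min(0, di), max(0, dj):w + min(0, dj)]
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        msrc = m[max(0, -di):h - max(0, di), max(0, -dj):w - max(0, dj)]
        mdst = m[max(0, di):h + min(0, di), max(0, dj):w + min(0, dj)]
        valid = msrc & mdst
        src, dst = src[valid], dst[valid]
    counts = np.bincount(src.ravel() * n_levels + dst.ravel(),
                         minlength=n_levels * n_levels
                         ).reshape(n_levels, n_levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for this offset")
    return Glcm(matrix=counts / total, offset=(di, dj), n_levels=n_levels,
                symmetric=symmetric)


def texture_features(glcm: Glcm) -> Dict[str, Optional[float]]:
    """Haralick-style statistics of a GLCM.

    ``correlation`` is ``None`` (undefined marker) when either marginal has
    zero standard deviation (e.g. a constant image).
    """
    p = glcm.matrix
    n = glcm.n_levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(np.sum(p * (i - j) ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(n) * pi))
    mu_j = float(np.sum(np.arange(n) * pj))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(n) - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        correlation: Optional[float] = None
    else:
        correlation = float(np.sum(p * (i - mu_i) * (j - mu_j))
                            / np.sqrt(var_i * var_j))
    return {"correlation": correlation, "contrast": contrast,
            "homogeneity": homogeneity, "entropy": entropy}


_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered 8-connected boundary pixel centers (Moore trace, clockwise).

    Returns an (n, 2) array of (row, col) coordinates of the outer boundary,
    starting at the topmost-leftmost pixel.  A single-pixel mask returns that
    pixel alone.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    start = tuple(np.argwhere(padded)[0])
    boundary = [start]
    # backtrack begins at the pixel west of the start
    prev_dir = 6
    cur = start
    while True:
        found = False
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            ni, nj = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if padded[ni, nj]:
                nxt = (ni, nj)
                prev_dir = (d + 4) % 8  # direction back to cur
                found = True
                break
        if not found:  # isolated pixel
            break
        if nxt == start and len(boundary) > 1:
            break
        boundary.append(nxt)
        cur = nxt
        if len(boundary) > 4 * padded.size:  # safety, unreachable
            raise RuntimeError("boundary trace failed to terminate")
    return np.asarray(boundary) - 1  # undo padding offset


def isoperimetric_ratio(area: float, perimeter: float) -> float:
    """The isoperimetric shape factor 4*pi*A / P^2 (1 for a continuous disk)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter ** 2


def shape_features(mask: np.ndarray, spacing_mm: float = 1.0) -> Dict[str, float]:
    """Area, aspect ratio, roundness, perimeter, circularity of a nodule mask.

    ``area`` (mm^2) and ``perimeter`` (mm) are physical; the three ratios are
    dimensionless.  ``perimeter`` is the closed Euclidean length of the Moore
    boundary trace; ``roundness`` uses the Freeman perimeter estimate.
    Single-pixel and degenerate masks report ratios of 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_px = int(mask.sum())
    area_px = float(n_px)
    area = area_px * spacing_mm ** 2

    boundary = trace_boundary(mask)
    if len(boundary) < 2:
        q_px = 0.0
    else:
        closed = np.vstack([boundary, boundary[:1]])
        # the pixel-center polygon traces the region's r - 1/2 contour and
        # underestimates the true boundary by ~2*pi*(1/2); correct by +pi
        q_px = float(np.sum(np.hypot(*np.diff(closed, axis=0).T))) + np.pi

    l_px = float(measure.perimeter(mask, neighborhood=4))

    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    major = props.axis_major_length
    aspect = float(major / minor) if minor > 0 else 1.0

    circularity = isoperimetric_ratio(area_px, q_px) if q_px > 0 else 1.0
    roundness = isoperimetric_ratio(area_px, l_px) if l_px > 0 else 1.0
    return {"area": area, "aspect_ratio": aspect, "roundness": roundness,
            "perimeter": q_px * spacing_mm, "circularity": circularity}


def intensity_features(image: np.ndarray, mask: np.ndarray,
                       n_bins: int = 256) -> Dict[str, float]:
    """First-order statistics of the masked region.

    Moments (mean, variance, skewness, kurtosis) are central moments of the
    region intensities — the 3rd and 4th are *not* standardized, matching the
    histogram-moment definitions the rest of the pipeline uses.  Uniformity
    is the histogram energy sum(H^2) over ``n_bins`` equal-width bins;
    smoothness is ``1 - 1/(1 + variance)`` and therefore scale-dependent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    values = np.asarray(image, dtype=float)[mask]
    mean = float(values.mean())
    centered = values - mean
    variance = float(np.mean(centered ** 2))
    skewness = float(np.mean(centered ** 3))
    kurtosis = float(np.mean(centered ** 4))
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        uniformity = 1.0
    else:
        counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
        probs = counts / counts.sum()
        uniformity = float(np.sum(probs ** 2))
    smoothness = 1.0 - 1.0 / (1.0 + variance)
    return {"uniformity": uniformity, "mean": mean, "variance": variance,
            "kurtosis": kurtosis, "skewness": skewness, "smoothness": smoothness}


def semantic_features(mask: np.ndarray, spacing_mm: float,
                      location_hint: Optional[bool] = None) -> Dict[str, object]:
    """Radiologist-style attributes derived from the mask geometry.

    Size bins follow the clinical cut-points <4, 4-7, 8-20, >20 mm with
    boundary diameters assigned to the lower bin.  Morphology combines the
    spiculation score and aspect ratio: Spiculated above 0.45 spiculation,
    Smooth/Lobulated below 0.2 (split on aspect ratio 1.25), Irregular
    in between.  ``upper_lobe`` is metadata passed through unchanged.
    """
    if spacing_mm is None or spacing_mm <= 0:
        raise ValueError("a positive pixel spacing is required")
    shp = shape_features(mask, spacing_mm)
    diameter_mm = 2.0 * np.sqrt(shp["area"] / np.pi)
    if diameter_mm <= 4.0:
        size_bin = SIZE_BINS[0]
    elif diameter_mm <= 7.0:
        size_bin = SIZE_BINS[1]
    elif diameter_mm <= 20.0:
        size_bin = SIZE_BINS[2]
    else:
        size_bin = SIZE_BINS[3]
    spiculation = float(np.clip(1.0 - shp["circularity"], 0.0, 1.0))
    if spiculation >= SPICULATED_THRESHOLD:
        morphology = "Spiculated"
    elif spiculation < SMOOTH_SPICULATION:
        morphology = "Lobulated" if shp["aspect_ratio"] >= LOBULATED_ASPECT \
            else "Smooth"
    else:
        morphology = "Irregular"
    return {"size_bin": size_bin, "diameter_mm": float(diameter_mm),
            "spiculation": spiculation, "upper_lobe": location_hint,
            "morphology": morphology}


@dataclasses.dataclass
class FeatureVector:
    texture: Dict[str, Optional[float]]
    shape: Dict[str, float]
    intensity: Dict[str, float]
    semantic: Dict[str, object]
    sensor: Optional[np.ndarray] = None

    _TEXTURE = ("correlation", "contrast", "homogeneity", "entropy")
    _SHAPE = ("area", "aspect_ratio", "roundness", "perimeter", "circularity")
    _INTENSITY = ("uniformity", "mean", "variance", "kurtosis", "skewness",
                  "smoothness")
    _SEMANTIC = ("size_bin", "diameter_mm", "spiculation", "upper_lobe",
                 "morphology")

    def names(self) -> list[str]:
        names = [f"texture_{k}" for k in self._TEXTURE]
        names += [f"shape_{k}" for k in self._SHAPE]
        names += [f"intensity_{k}" for k in self._INTENSITY]
        names += [f"semantic_{k}" for k in self._SEMANTIC]
        if self.sensor is not None:
            names += [f"sensor_{i}" for i in range(len(self.sensor))]
        return names

    def to_array(self) -> np.ndarray:
        """Numeric encoding: categories become indices, None becomes NaN."""
        vals: list[float] = []
        for k in self._TEXTURE:
            v = self.texture[k]
            vals.append(np.nan if v is None else float(v))
        vals += [float(self.shape[k]) for k in self._SHAPE]
        vals += [float(self.intensity[k]) for k in self._INTENSITY]
        sem = self.semantic
        vals.append(float(SIZE_BINS.index(sem["size_bin"])))
        vals.append(float(sem["diameter_mm"]))
        vals.append(float(sem["spiculation"]))
        ul = sem["upper_lobe"]
        vals.append(np.nan if ul is None else float(bool(ul)))
        vals.append(float(MORPHOLOGIES.index(sem["morphology"])))
        if self.sensor is not None:
            vals += [float(v) for v in self.sensor]
        return np.asarray(vals)


def extract_feature_vector(sample: NoduleSample,
                           config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Full descriptor block for one sample.

    Texture features are averaged over the four standard offsets
    (0,1), (1,0), (1,1), (1,-1); an undefined correlation in any offset makes
    the averaged correlation undefined.
    """
    tex_acc: Dict[str, list] = {k: [] for k in FeatureVector._TEXTURE}
    for off in config.offsets:
        glcm = compute_glcm(sample.image, offset=off, n_levels=config.n_levels,
                            symmetric=True, mask=sample.mask)
        for k, v in texture_features(glcm).items():
            tex_acc[k].append(v)
    texture: Dict[str, Optional[float]] = {}
    for k, vs in tex_acc.items():
        texture[k] = None if any(v is None for v in vs) \
            else float(np.mean(vs))
    shape = shape_features(sample.mask, sample.spacing_mm)
    intensity = intensity_features(sample.image, sample.mask,
                                   n_bins=config.histogram_bins)
    semantic = semantic_features(sample.mask, sample.spacing_mm,
                                 location_hint=sample.upper_lobe)
    sensor = None
    if config.include_sensor and sample.sensor is not None:
        sensor = np.asarray(sample.sensor.values, dtype=float)
    return FeatureVector(texture=texture, shape=shape, intensity=intensity,
                         semantic=semantic, sensor=sensor)


def feature_table(samples: Sequence[NoduleSample],
                  config: FeatureConfig = FeatureConfig()):
    """Feature matrix as a DataFrame (one row per sample, plus the label)."""
    import pandas as pd

    rows, names = [], None
    for s in samples:
        fv = extract_feature_vector(s, config)
        if names is None:
            names = fv.names()
        rows.append(fv.to_array())
    df = pd.DataFrame(rows, columns=names)
    df["label"] = [s.label for s in samples]
    return df
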
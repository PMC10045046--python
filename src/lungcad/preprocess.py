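"""Intensity normalization and entropy-based redundant-frame elimination.

Normalization is a Z-score (population standard deviation) followed by an
affine rescale to [0, 1]; a plain Z-score does not land in the unit interval,
so the rescale reconciles the standardization step with the unit-range
contract the rest of the pipeline assumes.  Constant images map to 0.5.

Frame redundancy is measured on 256-bin normalized intensity histograms
with the Kullback-Leibler divergence (relative entropy, log base 2, bits)
or its square root.  Scanning the ordered slice sequence, a frame is
dropped when its divergence from the last *kept* frame falls below a
threshold, so runs of near-duplicates collapse to a single representative.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.special import rel_entr

__all__ = [
    "IntensityHistogram",
    "FrameDistance",
    "zscore_normalize",
    "frame_histogram",
    "relative_entropy",
    "eliminate_redundant_frames",
]

#: floor applied to zero histogram bins so the divergence is finite
KL_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class IntensityHistogram:
    probs: np.ndarray
    n_bins: int
    value_range: tuple[float, float]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if p.shape != (self.n_bins,):
            raise ValueError("probs length must equal n_bins")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability vector")
        object.__setattr__(self, "probs", p)


@dataclasses.dataclass(frozen=True)
class FrameDistance:
    d_re: float
    d_srre: float


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Z-score (population std) then min-max rescale to [0, 1].

    The result is invariant to positive affine transforms of the input;
    constant images map to all 0.5.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    std = image.std()
    if std == 0:
        return np.full_like(image, 0.5)
    z = (image - image.mean()) / std
    span = z.max() - z.min()
    if span == 0:  # numerically constant after standardization
        return np.full_like(image, 0.5)
    return (z - z.min()) / span


def frame_histogram(frame: np.ndarray, n_bins: int = 256,
                    value_range: Optional[tuple[float, float]] = None) -> IntensityHistogram:
    """Normalized equal-width intensity histogram (values at hi fall in the last bin)."""
    frame = np.asarray(frame, dtype=float)
    if value_range is None:
        lo, hi = float(frame.min()), float(frame.max())
        if lo == hi:
            hi = lo + 1.0
    else:
        lo, hi = value_range
    if not lo < hi:
        raise ValueError("range must satisfy lo < hi")
    counts, _ = np.histogram(frame, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    if total == 0:
        raise ValueError("all pixels fall outside the histogram range")
    return IntensityHistogram(probs=counts / total, n_bins=n_bins,
                              value_range=(lo, hi))


def relative_entropy(p: IntensityHistogram, q: IntensityHistogram,
                     sqrt_variant: bool = False) -> FrameDistance:
    """KL divergence D(P||Q) in bits, with epsilon-floored bins, and its sqrt.

    Zero bins on either side are floored at 1e-12 and the vectors
    renormalized, which keeps the divergence finite and non-negative; tiny
    negative rounding residues are clamped to zero.
    """
    if p.n_bins != q.n_bins:
        raise ValueError("histograms must have the same number of bins")
    pa = np.maximum(p.probs, KL_EPS)
    qa = np.maximum(q.probs, KL_EPS)
    pa = pa / pa.sum()
    qa = qa / qa.sum()
    d_re = float(rel_entr(pa, qa).sum() / np.log(2.0))
    d_re = max(d_re, 0.0)
    return FrameDistance(d_re=d_re, d_srre=float(np.sqrt(d_re)))


def eliminate_redundant_frames(frames: Sequence[np.ndarray], threshold: float,
                               n_bins: int = 256,
                               value_range: Optional[tuple[float, float]] = None,
                               use_sqrt: bool = False) -> list[int]:
    """Scan frames in time order and keep those that differ from the last kept one.

    Frame ``i`` is dropped when its (square-root) relative entropy from the
    last kept frame is below ``threshold``; the first frame is always kept.
    Returns the kept indices (a subsequence containing 0).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    if value_range is None:
        lo = min(float(np.min(f)) for f in frames)
        hi = max(float(np.max(f)) for f in frames)
        if lo == hi:
            hi = lo + 1.0
        value_range = (lo, hi)
    hists = [frame_histogram(f, n_bins=n_bins, value_range=value_range) for f in frames]
    kept = [0]
    for i in range(1, len(frames)):
        d = relative_entropy(hists[kept[-1]], hists[i])
        dist = d.d_srre if use_sqrt else d.d_re
        if dist >= threshold:
            kept.append(i)
    return kept
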
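"""Temperature quantization and the nine ROI texture features.

The feature extractor mirrors a classical thermography texture analysis:
mean and variance are computed on the raw temperatures; the map is then
rounded to 0.1 °C, min-shifted and scaled to non-negative integer levels
(one level = 0.1 °C), from which skewness, kurtosis, Shannon entropy and
four gray-level co-occurrence statistics (contrast, homogeneity, energy,
correlation) at a horizontal offset of 20 pixels are derived.

Conventions (documented so fixtures are portable):

* rounding to 0.1 °C is half-away-from-zero (MATLAB-style ``round``);
* variance and central moments are population (÷N) moments; kurtosis is
  the Pearson (non-excess) form with normal reference value 3;
* entropy is in bits (log base 2);
* the co-occurrence matrix tallies ordered pairs in a single direction
  (asymmetric), normalized to total mass 1;
* zero-variance degenerate cases define skewness, kurtosis and GLCM
  correlation as 0, so downstream clustering never sees NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FEATURE_NAMES, ROI, crop, validate_map

#: °C per quantization level.
PRECISION = 0.1

#: Default co-occurrence offset: (row delta, col delta) = 20 px horizontally.
DEFAULT_OFFSET = (0, 20)


@dataclass(frozen=True)
class QuantizedMap:
    """Integer-level map: ``levels * 0.1 + offset_c`` recovers rounded °C."""

    levels: np.ndarray  # 2-D int64, min exactly 0
    offset_c: float  # rounded ROI minimum in °C
    precision: float = PRECISION

    @property
    def n_levels(self) -> int:
        return int(self.levels.max()) + 1


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize(values: np.ndarray) -> QuantizedMap:
    """Quantize temperatures to integer levels of 0.1 °C.

    Each pixel is rounded to one decimal place, the ROI minimum of the
    rounded values is subtracted, and the shifted values are scaled by 10
    and cast to integers.
    """
    arr = validate_map(values)
    deci = _round_half_away(arr * 10.0).astype(np.int64)  # rounded deci-°C, exact
    dmin = deci.min()
    return QuantizedMap(levels=deci - dmin, offset_c=dmin / 10.0)


def moments(values: np.ndarray, roi: ROI | None = None) -> tuple[float, float]:
    """Mean (°C) and population variance (°C²) of the raw ROI temperatures."""
    arr = validate_map(values)
    if roi is not None:
        arr = crop(arr, roi)
    return float(arr.mean()), float(arr.var())


def shape_moments(q: QuantizedMap) -> tuple[float, float]:
    """Skewness m3/m2^1.5 and Pearson kurtosis m4/m2² of the level distribution.

    Both are 0 by definition for a constant (zero-variance) ROI.
    """
    x = q.levels.astype(np.float64).ravel()
    m = x.mean()
    d = x - m
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return 0.0, 0.0
    skew = np.mean(d**3) / m2**1.5
    kurt = np.mean(d**4) / m2**2
    return float(skew), float(kurt)


def entropy(q: QuantizedMap) -> float:
    """Shannon entropy in bits of the level-frequency histogram."""
    counts = np.bincount(q.levels.ravel())
    f = counts[counts > 0] / q.levels.size
    return float(-np.sum(f * np.log2(f)))


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized ordered-pair level co-occurrences at a fixed pixel offset."""

    p: np.ndarray  # n_levels × n_levels, entries ≥ 0, sum 1
    offset: tuple[int, int]
    n_pairs: int


def cooccurrence(
    q: QuantizedMap,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    symmetric: bool = False,
) -> CooccurrenceMatrix:
    """Co-occurrence matrix of level pairs at ``offset`` within the ROI.

    Pairs (q[r, c], q[r+dr, c+dc]) are tallied for every in-bounds
    position; they never cross the ROI boundary. With ``symmetric=True``
    each pair is counted in both directions.
    """
    dr, dc = offset
    rows, cols = q.levels.shape
    if rows <= abs(dr) or cols <= abs(dc):
        raise ValueError(
            f"ROI of shape ({rows}, {cols}) yields no pixel pairs at offset {offset}; "
            "use a larger ROI or a smaller offset"
        )
    a = q.levels[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
    b = q.levels[max(0, dr) :, max(0, dc) :][: a.shape[0], : a.shape[1]]
    n = q.n_levels
    counts = np.bincount((a * n + b).ravel(), minlength=n * n).reshape(n, n).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    return CooccurrenceMatrix(p=counts / n_pairs, offset=(dr, dc), n_pairs=n_pairs)


def glcm_stats(P: CooccurrenceMatrix) -> tuple[float, float, float, float]:
    """Contrast, homogeneity, energy and correlation of a normalized GLCM.

    correlation = Σ (i−μ_r)(j−μ_c) p(i,j) / (σ_r σ_c), defined as 0 when
    either marginal is degenerate.
    """
    p = np.asarray(P.p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or np.any(p < 0):
        raise ValueError("co-occurrence matrix must be square with non-negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"co-occurrence matrix is not normalized (sum {p.sum()!r})")
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(np.sum((i - j) ** 2 * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    energy = float(np.sum(p**2))
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    mu_r = float(np.sum(np.arange(n) * pr))
    mu_c = float(np.sum(np.arange(n) * pc))
    var_r = float(np.sum((np.arange(n) - mu_r) ** 2 * pr))
    var_c = float(np.sum((np.arange(n) - mu_c) ** 2 * pc))
    if var_r <= 0.0 or var_c <= 0.0:
        correlation = 0.0
    else:
        cov = float(np.sum((i - mu_r) * (j - mu_c) * p))
        correlation = cov / np.sqrt(var_r * var_c)
    return contrast, homogeneity, energy, correlation


def rebin(q: QuantizedMap, n_gray_levels: int) -> QuantizedMap:
    """Linearly re-bin quantized levels into ``n_gray_levels`` bins.

    Optional coarsening in the style of classical GLCM toolboxes; the
    default pipeline keeps the full 0.1 °C level range.
    """
    if n_gray_levels < 1:
        raise ValueError("n_gray_levels must be ≥ 1")
    n = q.n_levels
    if n <= n_gray_levels:
        return q
    binned = (q.levels * n_gray_levels) // n
    return QuantizedMap(levels=binned.astype(np.int64), offset_c=q.offset_c, precision=q.precision * n / n_gray_levels)


@dataclass(frozen=True)
class FeatureVector:
    """The nine ROI statistics, in the documented fixed order."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float
    contrast: float
    homogeneity: float
    energy: float
    correlation: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=np.float64)


def extract_features(
    values: np.ndarray,
    roi: ROI | None = None,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    symmetric: bool = False,
    n_gray_levels: int | None = None,
) -> FeatureVector:
    """Compute the nine-feature vector of one ROI.

    Mean/variance come from raw temperatures; the remaining seven
    statistics from the quantized level map.
    """
    arr = validate_map(values)
    if roi is not None:
        arr = crop(arr, roi)
    mean, variance = moments(arr)
    q = quantize(arr)
    skew, kurt = shape_moments(q)
    H = entropy(q)
    q_glcm = rebin(q, n_gray_levels) if n_gray_levels is not None else q
    P = cooccurrence(q_glcm, offset=offset, symmetric=symmetric)
    contrast, homogeneity, energy_, correlation = glcm_stats(P)
    return FeatureVector(mean, variance, skew, kurt, H, contrast, homogeneity, energy_, correlation)
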
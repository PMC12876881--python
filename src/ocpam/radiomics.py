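"""Radiomics texture features for single-organoid ROIs.

Exactly 32 features per organoid, computed on the original (non-
preprocessed) OCM intensities inside the segmentation mask: 9 first-order
histogram features, 13 grey-level co-occurrence matrix (GLCM) features and
10 grey-level run-length matrix (GLRLM) features.  Formulas follow the
pyradiomics documentation definitions.  Intensities are discretised into
``n_levels`` equal-width bins over the ROI's own range (32 by default),
which makes all level-based features invariant under positive affine
intensity transforms of the ROI.  GLCM/GLRLM use the 13 unique 3D
directions at distance 1, symmetric accumulation, and report the mean over
directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RadiomicsParams
from .core import LabelMask, Volume3D

__all__ = [
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "FEATURE_NAMES",
    "DIRECTIONS_3D",
    "DiscretizedROI",
    "TextureFeatureVector",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "extract_feature_vector",
]

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Variance", "Skewness", "Kurtosis",
    "Energy", "Entropy", "Uniformity", "Range",
)
GLCM_NAMES = (
    "Autocorrelation", "Joint Average", "Joint Energy", "Joint Entropy",
    "Contrast", "Correlation", "Inverse Difference Moment", "Sum Average",
    "Sum Entropy", "Difference Entropy", "Difference Variance",
    "Sum of Squares", "Cluster Tendency",
)
GLRLM_NAMES = (
    "Short Run Emphasis", "Long Run Emphasis", "Gray Level Non-Uniformity",
    "Run Length Non-Uniformity", "Run Length Non-Uniformity Normalized",
    "Run Percentage", "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis", "Gray Level Variance", "Run Entropy",
)
FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES  # 32 names

#: The 13 unique 3D offsets (one per opposite pair of the 26 neighbours).
DIRECTIONS_3D = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)


@dataclass
class DiscretizedROI:
    """Grey-level grid over one organoid's voxels.

    ``levels`` is an integer grid over the ROI bounding box with values in
    ``1..n_levels`` inside the ROI and 0 outside; ``raw`` holds the raw
    in-ROI intensities (1D) for the first-order moments.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    raw: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(
    vol: Volume3D | np.ndarray,
    roi: np.ndarray,
    n_levels: int = 32,
) -> DiscretizedROI:
    """Equal-width binning of in-ROI intensities from the ROI minimum to
    the ROI maximum into ``n_levels`` levels (cropped to the ROI bounding
    box).  A constant ROI maps every voxel to level 1."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    roi = np.asarray(roi, bool)
    if roi.shape != data.shape:
        raise ValueError("ROI mask must match the volume shape")
    if not roi.any():
        raise ValueError("empty ROI")
    idx = np.nonzero(roi)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    sub = np.asarray(data[sl], float)
    m = roi[sl]
    vals = sub[m]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(sub.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((sub - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
    else:
        lv = np.ones(sub.shape, dtype=np.int32)
    levels[m] = lv[m]
    return DiscretizedROI(levels=levels, mask=m, n_levels=n_levels, raw=vals)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def first_order_features(roi: DiscretizedROI) -> dict[str, float]:
    """The 9 first-order histogram features.

    Moments (Mean, Median, Variance, Skewness, Kurtosis, Range) and Energy
    are computed on the raw in-ROI intensities; Entropy and Uniformity on
    the discretised level histogram (base-2).  Kurtosis is the un-excess
    ``m4/m2²`` convention; skewness and kurtosis of a constant ROI are 0.
    """
    x = roi.raw
    mean = float(x.mean())
    centred = x - mean
    m2 = float((centred**2).mean())
    m3 = float((centred**3).mean())
    m4 = float((centred**4).mean())
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    hist = np.bincount(roi.levels[roi.mask], minlength=roi.n_levels + 1)[1:]
    p = hist / hist.sum()
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Variance": m2,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x**2).sum()),
        "Entropy": _entropy(p),
        "Uniformity": float((p**2).sum()),
        "Range": float(x.max() - x.min()),
    }


def _shifted_pairs(levels, mask, offset):
    """Index arrays of in-ROI voxel pairs at the given offset."""
    sl_src, sl_dst = [], []
    for o, n in zip(offset, levels.shape):
        if abs(o) >= n:
            return None
        if o >= 0:
            sl_src.append(slice(0, n - o))
            sl_dst.append(slice(o, n))
        else:
            sl_src.append(slice(-o, n))
            sl_dst.append(slice(0, n + o))
    sl_src, sl_dst = tuple(sl_src), tuple(sl_dst)
    valid = mask[sl_src] & mask[sl_dst]
    if not valid.any():
        return None
    return levels[sl_src][valid], levels[sl_dst][valid]


def _glcm_matrix(roi: DiscretizedROI, offset) -> Optional[np.ndarray]:
    pairs = _shifted_pairs(roi.levels, roi.mask, offset)
    if pairs is None:
        return None
    i, j = pairs
    ng = roi.n_levels
    counts = np.zeros((ng, ng))
    np.add.at(counts, (i - 1, j - 1), 1.0)
    counts = counts + counts.T  # symmetric co-occurrence
    return counts / counts.sum()


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    mu_y = mu_x  # symmetric
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # diagonal (i+j) and cross-diagonal (|i-j|) distributions
    p_sum = np.zeros(2 * ng + 1)  # index k = i+j, valid 2..2Ng
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_diff = np.zeros(ng)  # index k = |i-j|, valid 0..Ng-1
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2 * ng + 1)
    kd = np.arange(ng)
    diff_avg = float((kd * p_diff).sum())

    if sig_x > 0:
        corr = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sig_x * sig_x))
    else:
        corr = 1.0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "Joint Average": mu_x,
        "Joint Energy": float((p**2).sum()),
        "Joint Entropy": _entropy(p.ravel()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "Inverse Difference Moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Sum Average": float((ks * p_sum).sum()),
        "Sum Entropy": _entropy(p_sum),
        "Difference Entropy": _entropy(p_diff),
        "Difference Variance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "Sum of Squares": float(((ii - mu_x) ** 2 * p).sum()),
        "Cluster Tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
    }


def glcm_features(
    roi: DiscretizedROI,
    distance: int = 1,
    directions: Sequence[tuple[int, int, int]] = DIRECTIONS_3D,
) -> dict[str, float]:
    """The 13 GLCM features, averaged over directions.

    Per direction, symmetric co-occurrence counts between in-ROI voxel
    pairs at ``distance * direction`` are normalised to a probability
    matrix; directions with no valid pair are skipped.
    """
    per_dir = []
    for d in directions:
        offset = tuple(distance * c for c in d)
        p = _glcm_matrix(roi, offset)
        if p is not None:
            per_dir.append(_glcm_features_one(p))
    if not per_dir:
        raise ValueError("no in-ROI voxel pairs in any direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _glrlm_matrix(roi: DiscretizedROI, direction) -> np.ndarray:
    """Grey-level x run-length counts of maximal runs along one direction.

    Runs break at the ROI boundary.  Implemented as a vectorised chain
    walk: run starts are voxels with no same-level in-ROI predecessor, and
    all runs are advanced in lockstep.
    """
    lv, m = roi.levels, roi.mask
    shape = lv.shape
    d = np.asarray(direction)

    # same-level predecessor map
    prev_same = np.zeros(shape, bool)
    sl_src, sl_dst = [], []
    for o, n in zip(direction, shape):
        if o >= 0:
            sl_src.append(slice(0, n - o) if o < n else slice(0, 0))
            sl_dst.append(slice(o, n) if o < n else slice(0, 0))
        else:
            sl_src.append(slice(-o, n) if -o < n else slice(0, 0))
            sl_dst.append(slice(0, n + o) if -o < n else slice(0, 0))
    sl_src, sl_dst = tuple(sl_src), tuple(sl_dst)
    if all(s.stop != s.start for s in sl_src):
        prev_same[sl_dst] = (
            m[sl_dst] & m[sl_src] & (lv[sl_dst] == lv[sl_src])
        )
    starts = m & ~prev_same
    pos = np.argwhere(starts)
    run_levels = lv[tuple(pos.T)]
    lengths = np.ones(len(pos), dtype=np.int64)
    cur = pos
    alive = np.arange(len(pos))
    while alive.size:
        nxt = cur[alive] + d
        inb = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
        cont = np.zeros(alive.size, bool)
        if inb.any():
            t = tuple(nxt[inb].T)
            cont[inb] = m[t] & (lv[t] == run_levels[alive[inb]])
        lengths[alive[cont]] += 1
        cur[alive[cont]] += d
        alive = alive[cont]
    ng = roi.n_levels
    max_len = int(lengths.max()) if lengths.size else 1
    P = np.zeros((ng, max_len))
    np.add.at(P, (run_levels - 1, lengths - 1), 1.0)
    return P


def _glrlm_features_one(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, lmax = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, lmax + 1)[None, :]
    nr = P.sum()
    p = P / nr
    row = P.sum(axis=1)  # per grey level
    col = P.sum(axis=0)  # per run length
    mu_g = float((p * i).sum())
    return {
        "Short Run Emphasis": float((P / j**2).sum() / nr),
        "Long Run Emphasis": float((P * j.astype(float) ** 2).sum() / nr),
        "Gray Level Non-Uniformity": float((row**2).sum() / nr),
        "Run Length Non-Uniformity": float((col**2).sum() / nr),
        "Run Length Non-Uniformity Normalized": float((col**2).sum() / nr**2),
        "Run Percentage": float(nr / n_voxels),
        "Low Gray Level Run Emphasis": float((P / i.astype(float) ** 2).sum() / nr),
        "High Gray Level Run Emphasis": float((P * i.astype(float) ** 2).sum() / nr),
        "Gray Level Variance": float((p * (i - mu_g) ** 2).sum()),
        "Run Entropy": _entropy(p.ravel()),
    }


def glrlm_features(
    roi: DiscretizedROI,
    directions: Sequence[tuple[int, int, int]] = DIRECTIONS_3D,
) -> dict[str, float]:
    """The 10 GLRLM features, averaged over directions."""
    per_dir = []
    for d in directions:
        P = _glrlm_matrix(roi, d)
        if P.sum() > 0:
            per_dir.append(_glrlm_features_one(P, roi.n_voxels))
    if not per_dir:
        raise ValueError("empty ROI: no runs in any direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


@dataclass
class TextureFeatureVector:
    """The 32 named radiomics features for one organoid ROI."""

    label: int
    values: dict[str, float]
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must hold exactly the 32 named features")
        arr = np.array(list(self.values.values()), float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("all 32 features must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], float)

    def to_flat(self) -> dict:
        rec = {"label": self.label, "day": self.day}
        rec.update(self.values)
        return rec


def extract_feature_vector(
    vol: Volume3D,
    mask: LabelMask,
    label: int,
    params: Optional[RadiomicsParams] = None,
) -> TextureFeatureVector:
    """Extract the full 32-feature vector for one labelled organoid from
    the original (non-preprocessed) OCM volume.

    The blocks are concatenated in fixed order: first-order, GLCM, GLRLM.
    ROIs smaller than ``min_roi_voxels`` are rejected.
    """
    params = params or RadiomicsParams()
    roi_mask = mask.labels == label
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError(f"label {label} not present in mask")
    if n < params.min_roi_voxels:
        raise ValueError(
            f"ROI of {n} voxels below the minimum of {params.min_roi_voxels}"
        )
    roi = discretize(vol, roi_mask, params.n_levels)
    if params.mode == "2d":
        dirs_2d = ((0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1))
        glcm = glcm_features(roi, params.distance, dirs_2d)
        glrlm = glrlm_features(roi, dirs_2d)
    else:
        glcm = glcm_features(roi, params.distance)
        glrlm = glrlm_features(roi)
    values = {}
    values.update(first_order_features(roi))
    values.update({k: glcm[k] for k in GLCM_NAMES})
    values.update({k: glrlm[k] for k in GLRLM_NAMES})
    ordered = {k: values[k] for k in FEATURE_NAMES}
    return TextureFeatureVector(label=label, values=ordered, day=mask.day)
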
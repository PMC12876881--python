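"""Organoid segmentation: preprocessing, a pluggable backend, and mask
summaries.

Preprocessing is percentile histogram normalisation/stretching plus median
noise reduction.  The default ``classical`` backend thresholds the
preprocessed volume, closes and fills the foreground, labels 26-connected
components and splits touching organoids by marker-based watershed on the
Euclidean distance transform.  An ``external-mask`` backend validates and
relabels a mask produced elsewhere (e.g. by a learned network) to the same
contract, so every downstream stage is backend-agnostic.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .config import SegmentationParams
from .core import LabelMask, OrganoidRecord, Volume3D

__all__ = [
    "preprocess_volume",
    "segment_organoids",
    "filter_components",
    "summarize_mask",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def preprocess_volume(vol: Volume3D, params: Optional[SegmentationParams] = None) -> Volume3D:
    """Percentile-clip, stretch to [0, 1] and median-denoise a volume.

    The affine stretch makes the result invariant to positive intensity
    scaling of the input.  A constant volume has no usable histogram and
    returns zeros with a warning.
    """
    params = params or SegmentationParams()
    data = np.asarray(vol.data, dtype=float)
    lo = np.percentile(data, params.low_percentile)
    hi = np.percentile(data, params.high_percentile)
    if hi <= lo:
        warnings.warn("constant volume: preprocessing returns zeros")
        return vol.with_data(np.zeros_like(data))
    stretched = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    if params.denoise_size > 1:
        stretched = ndimage.median_filter(stretched, size=params.denoise_size)
    return vol.with_data(stretched)


def _split_touching(binary: np.ndarray, spacing, min_sep_um: float) -> np.ndarray:
    """Label 26-connected components, splitting merged organoids.

    Markers are the distance-transform maxima cores (regions above 60% of
    each component's peak distance); cores closer than ``min_sep_um`` are
    merged, so near-spherical single organoids are never over-split.
    """
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return labels.astype(np.int32)
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for sl, comp_idx in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == comp_idx
        edt = ndimage.distance_transform_edt(comp, sampling=spacing)
        edt = ndimage.gaussian_filter(edt, 1.0)
        cores = edt > 0.6 * edt.max()
        core_labels, n_cores = ndimage.label(cores, structure=_CONN26)
        if n_cores > 1:
            # enforce the minimum marker separation: merge cores whose
            # centroids are closer than min_sep_um (keep the deepest)
            cents = np.array(
                ndimage.center_of_mass(cores, core_labels, range(1, n_cores + 1))
            ) * np.asarray(spacing)
            depths = ndimage.maximum(edt, core_labels, range(1, n_cores + 1))
            keep = list(range(n_cores))
            for i in sorted(range(n_cores), key=lambda i: -depths[i]):
                if i not in keep:
                    continue
                for j in list(keep):
                    if j != i and np.linalg.norm(cents[i] - cents[j]) < min_sep_um:
                        if depths[j] <= depths[i]:
                            keep.remove(j)
            remap = np.zeros(n_cores + 1, dtype=np.int32)
            for new, old in enumerate(sorted(keep), start=1):
                remap[old + 1] = new
            core_labels = remap[core_labels]
            n_cores = len(keep)
        if n_cores > 1:
            split = watershed(-edt, markers=core_labels, mask=comp)
            for c in range(1, n_cores + 1):
                out[sl][split == c] = next_label
                next_label += 1
        else:
            out[sl][comp] = next_label
            next_label += 1
    return out


def segment_organoids(
    vol: Volume3D,
    params: Optional[SegmentationParams] = None,
    backend: str = "classical",
    external_mask: Optional[np.ndarray] = None,
) -> LabelMask:
    """Produce a :class:`LabelMask` of individual organoids.

    ``classical``: global threshold (Otsu by default) on the preprocessed
    volume, morphological closing + hole filling, 26-connected labelling
    and watershed splitting of touching organoids, then small-object
    removal and size-ordered relabelling.

    ``external-mask``: validate and relabel a user-supplied integer mask
    (e.g. the output of a learned segmentation network) to the same
    contract.
    """
    params = params or SegmentationParams()
    if backend == "external-mask":
        if external_mask is None:
            raise ValueError("external-mask backend requires external_mask")
        ext = np.asarray(external_mask)
        if ext.shape != vol.shape:
            raise ValueError("external mask shape must match the volume")
        if not np.issubdtype(ext.dtype, np.integer):
            raise ValueError("external mask must be integer-labelled")
        mask = LabelMask(labels=ext.astype(np.int32), spacing=vol.spacing, day=vol.day)
        return filter_components(mask, params.min_volume_um3)
    if backend != "classical":
        raise ValueError(f"unknown backend {backend!r}")

    data = np.asarray(vol.data, dtype=float)
    if params.threshold_method == "otsu":
        if np.ptp(data) == 0:
            warnings.warn("empty foreground: returning empty mask")
            return LabelMask(
                labels=np.zeros(vol.shape, np.int32), spacing=vol.spacing, day=vol.day
            )
        thr = threshold_otsu(data)
    else:
        thr = params.fixed_threshold
    binary = data > thr
    if not binary.any():
        warnings.warn("empty foreground: returning empty mask")
        return LabelMask(
            labels=np.zeros(vol.shape, np.int32), spacing=vol.spacing, day=vol.day
        )
    binary = ndimage.binary_closing(binary, structure=_CONN26)
    binary = ndimage.binary_fill_holes(binary)
    labels = _split_touching(binary, vol.spacing, params.split_marker_distance_um)
    mask = LabelMask(labels=labels, spacing=vol.spacing, day=vol.day)
    return filter_components(mask, params.min_volume_um3)


def filter_components(mask: LabelMask, min_volume_um3: float) -> LabelMask:
    """Drop components below ``min_volume_um3``; relabel contiguously in
    decreasing size order (largest organoid becomes label 1)."""
    labels = mask.labels
    n = mask.n_labels
    if n == 0:
        return LabelMask(labels=labels.copy(), spacing=mask.spacing, day=mask.day)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    volumes = counts * mask.voxel_volume
    keep = np.nonzero(volumes >= min_volume_um3)[0] + 1
    order = keep[np.argsort(-volumes[keep - 1], kind="stable")]
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabelMask(labels=remap[labels], spacing=mask.spacing, day=mask.day)


def summarize_mask(mask: LabelMask) -> list[OrganoidRecord]:
    """Per-label volume (µm³), intensity-free centroid (µm) and half-open
    voxel bounding box."""
    n = mask.n_labels
    if n == 0:
        return []
    labels = mask.labels
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    objects = ndimage.find_objects(labels)
    spacing = np.asarray(mask.spacing)
    records = []
    for lab in range(1, n + 1):
        if counts[lab - 1] == 0:
            continue
        sl = objects[lab - 1]
        bbox = tuple((s.start, s.stop) for s in sl)
        records.append(
            OrganoidRecord(
                label=lab,
                centroid=tuple(np.asarray(centroids[lab - 1]) * spacing),
                volume=float(counts[lab - 1] * mask.voxel_volume),
                bbox=bbox,
                day=mask.day,
            )
        )
    return records
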
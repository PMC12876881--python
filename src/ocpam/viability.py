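"""Fluorescence-derived viability ground truth.

Live (acridine-orange-like) and dead (propidium-iodide-like) channels are
binarised by contrast-limited adaptive histogram equalisation followed by
global Otsu thresholding.  The viability score of an organoid is the
number of live pixels divided by the number of live plus dead pixels
inside its region, and a 50% cut-off assigns the HIGH/LOW status (exactly
50% counts as LOW; pixels positive in both channels count once as dead —
the conventional dead-stain dominance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu

from .config import ViabilityParams
from .core import LabelMask, Volume3D

__all__ = ["ViabilityLabel", "binarize_channel", "viability_score",
           "assign_status", "score_organoids"]


@dataclass
class ViabilityLabel:
    """Per-organoid live/dead pixel counts, score and status."""

    organoid_id: int
    live_pixels: int
    dead_pixels: int
    score: Optional[float] = None  # live / (live + dead); None if unscorable
    status: Optional[str] = None  # HIGH | LOW, set by assign_status
    unscorable: bool = False

    def to_flat(self) -> dict:
        return {
            "organoid_id": self.organoid_id,
            "live_pixels": self.live_pixels,
            "dead_pixels": self.dead_pixels,
            "score": "" if self.score is None else self.score,
            "status": self.status or ("UNSCORABLE" if self.unscorable else ""),
        }


def binarize_channel(
    img: Volume3D,
    params: Optional[ViabilityParams] = None,
) -> np.ndarray:
    """CLAHE (tile-wise) then a global Otsu threshold on the equalised
    image.  Returns a boolean mask; a constant image yields an empty mask
    with a warning."""
    params = params or ViabilityParams()
    data = np.asarray(img.data, dtype=float)
    rng_ = np.ptp(data)
    if rng_ == 0:
        warnings.warn("constant image: returning empty mask")
        return np.zeros(data.shape, dtype=bool)
    norm = (data - data.min()) / rng_
    kernel = [max(2, int(round(s * params.clahe_tile_fraction))) for s in data.shape]
    # CLAHE needs tiles smaller than the image; degenerate axes fall back
    kernel = [min(k, s) for k, s in zip(kernel, data.shape)]
    squeeze = data.shape[0] == 1
    if squeeze:
        eq = equalize_adapthist(
            norm[0], kernel_size=kernel[1:], clip_limit=params.clahe_clip_limit
        )[np.newaxis]
    else:
        eq = equalize_adapthist(
            norm, kernel_size=kernel, clip_limit=params.clahe_clip_limit
        )
    thr = threshold_otsu(eq)
    return eq > thr


def viability_score(
    live_mask: np.ndarray,
    dead_mask: np.ndarray,
    roi: np.ndarray,
    organoid_id: int = 0,
    double_positive: str = "dead",
) -> ViabilityLabel:
    """Score = live / (live + dead) restricted to the ROI.

    Pixels positive in both channels are counted once, as dead by default.
    When the ROI contains no stained pixel at all the label is flagged
    UNSCORABLE instead of receiving a score.
    """
    live_mask = np.asarray(live_mask, bool)
    dead_mask = np.asarray(dead_mask, bool)
    roi = np.asarray(roi, bool)
    if live_mask.shape != dead_mask.shape or live_mask.shape != roi.shape:
        raise ValueError("masks and ROI must share one shape")
    both = live_mask & dead_mask
    if double_positive == "dead":
        live = live_mask & ~both
        dead = dead_mask
    else:
        live = live_mask
        dead = dead_mask & ~both
    n_live = int(np.count_nonzero(live & roi))
    n_dead = int(np.count_nonzero(dead & roi))
    if n_live + n_dead == 0:
        return ViabilityLabel(
            organoid_id=organoid_id, live_pixels=0, dead_pixels=0,
            score=None, unscorable=True,
        )
    return ViabilityLabel(
        organoid_id=organoid_id,
        live_pixels=n_live,
        dead_pixels=n_dead,
        score=n_live / (n_live + n_dead),
    )


def assign_status(label: ViabilityLabel, cutoff: float = 0.5) -> ViabilityLabel:
    """HIGH iff score strictly above the cut-off, else LOW; a score of
    exactly the cut-off is LOW.  Unscorable labels pass through."""
    if label.unscorable or label.score is None:
        return label
    label.status = "HIGH" if label.score > cutoff else "LOW"
    return label


def score_organoids(
    live_img: Volume3D,
    dead_img: Volume3D,
    mask: LabelMask,
    params: Optional[ViabilityParams] = None,
) -> list[ViabilityLabel]:
    """Binarise both channels once, then score and status every organoid
    in the mask."""
    params = params or ViabilityParams()
    live_bin = binarize_channel(live_img, params)
    dead_bin = binarize_channel(dead_img, params)
    out = []
    for lab in range(1, mask.n_labels + 1):
        roi = mask.labels == lab
        vl = viability_score(
            live_bin, dead_bin, roi, organoid_id=lab,
            double_positive=params.double_positive,
        )
        out.append(assign_status(vl, params.cutoff))
    return out
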
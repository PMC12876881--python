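"""Shared data model for the OC-PAM analysis pipeline.

All volumes are indexed ``(z, y, x)`` with 0-based voxel indices; bounding
boxes are half-open index ranges per axis.  Physical coordinates are
``index * spacing`` in micrometres, with the origin at the centre of voxel
``(0, 0, 0)``.  No stage of the pipeline mutates its input volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Modality",
    "Volume3D",
    "LabelMask",
    "OrganoidRecord",
]


class Modality:
    """String tags for the imaging modality of a :class:`Volume3D`."""

    OCM = "OCM"
    PAM = "PAM"
    FLM_LIVE = "FLM_LIVE"
    FLM_DEAD = "FLM_DEAD"
    PHANTOM = "PHANTOM"

    ALL = (OCM, PAM, FLM_LIVE, FLM_DEAD, PHANTOM)


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing components must be > 0, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """A 3D intensity grid with voxel spacing in micrometres.

    Parameters
    ----------
    data:
        3D scalar array indexed ``(z, y, x)``; intensities must be finite
        and non-negative.
    spacing:
        ``(dz, dy, dx)`` voxel size in µm, all strictly positive.
    modality:
        One of :class:`Modality` (``OCM``, ``PAM``, ``FLM_LIVE``,
        ``FLM_DEAD``, ``PHANTOM``).
    day:
        Integer acquisition day, or ``None`` when not part of a series.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = Modality.OCM
    day: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("volume must have extent >= 1 on every axis")
        self.spacing = _check_spacing(self.spacing)
        if self.modality not in Modality.ALL:
            raise ValueError(f"unknown modality {self.modality!r}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")
        if self.day is not None:
            self.day = int(self.day)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def field_um(self) -> tuple[float, float, float]:
        """Physical extent of the grid per axis in µm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def with_data(self, data: np.ndarray, modality: Optional[str] = None) -> "Volume3D":
        """A new volume sharing this one's metadata with different data."""
        return Volume3D(
            data=data,
            spacing=self.spacing,
            modality=self.modality if modality is None else modality,
            day=self.day,
        )


@dataclass
class LabelMask:
    """Integer-labelled 3D grid aligned to a source :class:`Volume3D`.

    Label 0 is background; labels ``1..K`` are organoids and form a
    contiguous set.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    day: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)
        if self.day is not None:
            self.day = int(self.day)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def check_contiguous(self) -> None:
        """Raise if the labels are not exactly the set {0..K}."""
        present = np.unique(self.labels)
        expected = np.arange(present[-1] + 1) if present.size else np.array([0])
        if present[0] != 0 or present.size != expected.size:
            raise ValueError("labels must form a contiguous set {0..K} including 0")


@dataclass
class OrganoidRecord:
    """Per-organoid summary used for matching and bookkeeping.

    ``centroid`` is in µm (z, y, x); ``volume`` in µm³; ``bbox`` is a
    half-open voxel index range per axis.
    """

    label: int
    centroid: tuple[float, float, float]
    volume: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("organoid volume must be > 0")

    def centroid_inside_bbox(self, spacing: Sequence[float]) -> bool:
        for c, (lo, hi), s in zip(self.centroid, self.bbox, spacing):
            if not (lo * s - 0.5 * s <= c <= hi * s):
                return False
        return True

    def to_flat(self) -> dict:
        """Flatten to a record suitable for CSV writing."""
        (z0, z1), (y0, y1), (x0, x1) = self.bbox
        return {
            "label": self.label,
            "day": self.day,
            "centroid_z_um": self.centroid[0],
            "centroid_y_um": self.centroid[1],
            "centroid_x_um": self.centroid[2],
            "volume_um3": self.volume,
            "bbox_z0": z0,
            "bbox_z1": z1,
            "bbox_y0": y0,
            "bbox_y1": y1,
            "bbox_x0": x0,
            "bbox_x1": x1,
        }
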
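"""OCM/PAM co-registration, melanin-positive cell detection and overlays.

Calibration is an axis-aligned affine (per-axis offset + scale) estimated
from a gold-pyramid phantom imaged by both modalities: the phantom's top
surface is extracted per lateral position in each modality, lateral scale
and offset come from the weighted moments of the surface height map, and
the axial pair from a least-squares fit of paired surface heights.
Melanin-positive cell centroids are found from the PAM peak amplitude
followed by thresholding at 87% of the peak (per depth line by default;
lines whose peak stays below the noise floor are skipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import matplotlib
from scipy import ndimage

from .core import Modality, Volume3D
from .recon import en_face_projection

__all__ = [
    "FusionCalibration",
    "AbsorberCentroid",
    "calibrate_fusion",
    "apply_calibration",
    "detect_absorbers",
    "fuse_overlay",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FusionCalibration:
    """Per-axis offset (µm) and scale mapping PAM coordinates onto the OCM
    frame: ``x_ocm = scale * x_pam + offset``."""

    offset_um: tuple[float, float, float]
    scale: tuple[float, float, float]
    residual_um: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError("scales must be > 0")
        if self.residual_um < 0:
            raise ValueError("residual must be >= 0")

    def inverse(self) -> "FusionCalibration":
        s = tuple(1.0 / c for c in self.scale)
        o = tuple(-off / sc for off, sc in zip(self.offset_um, self.scale))
        return FusionCalibration(offset_um=o, scale=s, residual_um=self.residual_um)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(
                {
                    "offset_um": list(self.offset_um),
                    "scale": list(self.scale),
                    "residual_um": self.residual_um,
                },
                fh,
                indent=1,
            )
        return path

    @classmethod
    def from_json(cls, path: str) -> "FusionCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            offset_um=tuple(d["offset_um"]),
            scale=tuple(d["scale"]),
            residual_um=float(d.get("residual_um", 0.0)),
        )


@dataclass
class AbsorberCentroid:
    """One detected melanin-positive component."""

    position_um: tuple[float, float, float]  # (z, y, x)
    peak_amplitude: float
    voxel_count: int


def _surface_map(vol: Volume3D, rel_floor: float = 0.5) -> np.ndarray:
    """Sub-voxel top-surface height (µm) per lateral position.

    Per depth line: lines whose peak is below ``rel_floor`` of the global
    peak are invalid (NaN); otherwise the height is the intensity-weighted
    centroid of the depth samples above half the line peak.
    """
    data = vol.data
    dz = vol.spacing[0]
    peaks = data.max(axis=0)
    floor = rel_floor * data.max()
    z = np.arange(data.shape[0])[:, None, None] * dz
    w = np.where(data >= 0.5 * peaks[None], data, 0.0)
    with np.errstate(invalid="ignore"):
        h = (w * z).sum(axis=0) / w.sum(axis=0)
    h = np.where(peaks >= floor, h, np.nan)
    return h


def calibrate_fusion(
    ocm_phantom: Volume3D,
    pam_phantom: Volume3D,
) -> FusionCalibration:
    """Estimate the axis-aligned affine mapping PAM onto the OCM frame.

    Surface height maps are extracted in both modalities; per lateral axis
    the scale is the square root of the ratio of the surface-weighted
    second moments and the offset aligns the weighted centroids; the axial
    scale/offset are a least-squares fit of paired heights sampled over
    the common lateral support.  The residual is the RMS height
    disagreement after the fit.
    """
    h_o = _surface_map(ocm_phantom)
    h_p = _surface_map(pam_phantom)
    if not np.isfinite(h_o).any() or not np.isfinite(h_p).any():
        raise ValueError("featureless volume: no surface detected")

    def lateral_fit(h, spacing):
        # weight by height above the flat plain; the 10% floor keeps noise
        # on the plain from biasing the moments (the plain's physical
        # extent differs between the two grids under the unknown scale)
        base = np.nanmedian(h)
        w = np.where(np.isfinite(h), np.clip(h - base, 0.0, None), 0.0)
        if w.max() > 0:
            w[w < 0.1 * w.max()] = 0.0
        tot = w.sum()
        if tot <= 0:
            raise ValueError("featureless volume: flat surface on all axes")
        cy = (w.sum(axis=1) * np.arange(h.shape[0]) * spacing[1]).sum() / tot
        cx = (w.sum(axis=0) * np.arange(h.shape[1]) * spacing[2]).sum() / tot
        vy = (w.sum(axis=1) * (np.arange(h.shape[0]) * spacing[1] - cy) ** 2).sum() / tot
        vx = (w.sum(axis=0) * (np.arange(h.shape[1]) * spacing[2] - cx) ** 2).sum() / tot
        return (cy, cx), (vy, vx), w

    (cy_o, cx_o), (vy_o, vx_o), w_o = lateral_fit(h_o, ocm_phantom.spacing)
    (cy_p, cx_p), (vy_p, vx_p), w_p = lateral_fit(h_p, pam_phantom.spacing)
    if vy_p <= 0 or vx_p <= 0:
        raise ValueError("scale unidentifiable: flat surface")
    s_y = float(np.sqrt(vy_o / vy_p))
    s_x = float(np.sqrt(vx_o / vx_p))
    o_y = float(cy_o - s_y * cy_p)
    o_x = float(cx_o - s_x * cx_p)

    # pair surface heights over the common lateral support for the z fit
    ny_o, nx_o = h_o.shape
    yy, xx = np.nonzero(np.isfinite(h_p) & (w_p > 0.05 * w_p.max()))
    y_map = (s_y * yy * pam_phantom.spacing[1] + o_y) / ocm_phantom.spacing[1]
    x_map = (s_x * xx * pam_phantom.spacing[2] + o_x) / ocm_phantom.spacing[2]
    inside = (y_map >= 0) & (y_map <= ny_o - 1) & (x_map >= 0) & (x_map <= nx_o - 1)
    yy, xx, y_map, x_map = yy[inside], xx[inside], y_map[inside], x_map[inside]
    if yy.size < 10:
        raise ValueError("insufficient lateral overlap between the phantoms")
    h_o_filled = np.where(np.isfinite(h_o), h_o, np.nanmedian(h_o))
    paired_o = ndimage.map_coordinates(
        h_o_filled, np.vstack([y_map, x_map]), order=1, mode="nearest"
    )
    paired_valid = np.isfinite(
        ndimage.map_coordinates(
            np.isfinite(h_o).astype(float), np.vstack([y_map, x_map]), order=1
        )
    ) & (
        ndimage.map_coordinates(
            np.isfinite(h_o).astype(float), np.vstack([y_map, x_map]), order=1
        )
        > 0.99
    )
    zp = h_p[yy, xx][paired_valid]
    zo = paired_o[paired_valid]
    if np.var(zp) <= 1e-12:
        raise ValueError("scale unidentifiable: flat surface along z")
    s_z, o_z = np.polyfit(zp, zo, 1)
    resid = zo - (s_z * zp + o_z)
    residual = float(np.sqrt(np.mean(resid**2)))
    return FusionCalibration(
        offset_um=(float(o_z), o_y, o_x),
        scale=(float(s_z), s_y, s_x),
        residual_um=residual,
    )


def apply_calibration(
    pam: Volume3D,
    calib: FusionCalibration,
    target: Volume3D,
) -> Volume3D:
    """Resample PAM onto the target OCM voxel grid under the affine map
    (linear interpolation; out-of-field voxels are zero)."""
    coords_1d = []
    for a in range(3):
        phys = np.arange(target.shape[a]) * target.spacing[a]
        pam_idx = (phys - calib.offset_um[a]) / calib.scale[a] / pam.spacing[a]
        coords_1d.append(pam_idx)
    grid = np.meshgrid(*coords_1d, indexing="ij")
    resampled = ndimage.map_coordinates(
        np.asarray(pam.data, float), np.stack(grid), order=1, mode="constant", cval=0.0
    )
    return Volume3D(
        data=resampled, spacing=target.spacing, modality=Modality.PAM, day=pam.day
    )


def _background_stats(data: np.ndarray, region: Optional[np.ndarray], shell: int = 2):
    if region is None:
        region = np.zeros(data.shape, bool)
        region[:shell], region[-shell:] = True, True
        region[:, :shell], region[:, -shell:] = True, True
        region[:, :, :shell], region[:, :, -shell:] = True, True
    vals = data[region]
    return float(vals.mean()), float(vals.std())


def detect_absorbers(
    pam: Volume3D,
    threshold_fraction: float = 0.87,
    scope: str = "per_aline",
    background_region: Optional[np.ndarray] = None,
    noise_sigma_mult: float = 5.0,
    min_voxels: int = 5,
) -> list[AbsorberCentroid]:
    """Melanin-positive cell centroids from PAM peak-amplitude thresholding.

    ``per_aline`` (default): within each depth line, voxels at or above
    ``threshold_fraction`` of that line's peak are kept; lines whose peak
    stays below the noise floor (background mean + ``noise_sigma_mult``
    SD; background defaults to a 2-voxel border shell) are skipped.
    ``global``: one threshold at the fraction of the volume's peak.
    Kept voxels are grouped into 26-connected components and each
    component of at least ``min_voxels`` voxels (an optically resolvable
    absorber spans several voxels; smaller clusters are noise) yields an
    intensity-weighted centroid.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    data = np.asarray(pam.data, float)
    mean_bg, sd_bg = _background_stats(data, background_region)
    floor = mean_bg + noise_sigma_mult * sd_bg
    if scope == "per_aline":
        peaks = data.max(axis=0)
        keep = (data >= threshold_fraction * peaks[None]) & (peaks[None] >= floor)
    elif scope == "global":
        peak = data.max()
        if peak < floor:
            return []
        keep = data >= threshold_fraction * peak
    else:
        raise ValueError(f"unknown scope {scope!r}")
    keep &= data >= floor
    if not keep.any():
        return []
    labels, n = ndimage.label(keep, structure=_CONN26)
    if n == 0:
        return []
    spacing = np.asarray(pam.spacing)
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(data), labels, idx)
    peaks_c = ndimage.maximum(data, labels, idx)
    coms = np.asarray(ndimage.center_of_mass(data, labels, idx))
    out = []
    for i in range(n):
        if counts[i] < min_voxels:
            continue
        out.append(
            AbsorberCentroid(
                position_um=tuple(float(c * s) for c, s in zip(coms[i], spacing)),
                peak_amplitude=float(peaks_c[i]),
                voxel_count=int(counts[i]),
            )
        )
    return out


def fuse_overlay(
    ocm: Volume3D,
    pam_on_ocm_grid: Volume3D,
    centroids: Optional[Sequence[AbsorberCentroid]] = None,
    db_floor: float = -40.0,
    alpha: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Fused en-face overlay and two-channel fused volume.

    OCM is rendered greyscale (standard-deviation projection, log scale);
    PAM on a warm colormap (maximum projection, log scale), alpha-
    composited where the PAM projection carries signal.  Returns
    ``(rgb_image, fused_volume)`` with the fused volume holding both
    channels stacked as ``(2, z, y, x)``.
    """
    if ocm.shape != pam_on_ocm_grid.shape:
        raise ValueError("OCM and resampled PAM must share one grid")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ocm_db = en_face_projection(ocm, "STD", log_compress=True, db_floor=db_floor)
        pam_lin = en_face_projection(pam_on_ocm_grid, "MAX", log_compress=False)
        pam_db = en_face_projection(
            pam_on_ocm_grid, "MAX", log_compress=True, db_floor=db_floor
        )
    gray = (ocm_db - db_floor) / (-db_floor)
    rgb = np.stack([gray] * 3, axis=-1)
    if pam_lin.max() > 0:
        pam_norm = (pam_db - db_floor) / (-db_floor)
        pam_fg = pam_norm > 0.25  # signal meaningfully above the dB floor
        warm = matplotlib.colormaps["hot"](pam_norm)[..., :3]
        a = alpha * pam_fg[..., None]
        rgb = (1.0 - a) * rgb + a * warm
    fused_volume = np.stack([np.asarray(ocm.data), np.asarray(pam_on_ocm_grid.data)])
    return np.clip(rgb, 0.0, 1.0), fused_volume
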
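"""Spectral-domain OCM A-line reconstruction and en-face projections.

The reconstruction follows the standard spectral-domain chain: background
subtraction, resampling from wavelength to uniformly spaced wavenumber,
software compensation of residual dispersion, and an inverse Fourier
transform whose magnitude over positive optical depths is the image.  The
depth axis is scaled by the spectral span and the medium's refractive
index (1.38 for soft tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import hilbert

from .core import Modality, Volume3D

__all__ = ["SpectralFrame", "reconstruct_bscan", "en_face_projection"]


@dataclass
class SpectralFrame:
    """Raw spectrometer output for one B-scan.

    ``fringes`` is (lateral position x spectral sample); ``wavelength_nm``
    must be strictly monotonic; ``dispersion`` holds residual-dispersion
    phase polynomial coefficients, ``c_j`` multiplying ``(k - k0)^(j+2)``
    (quadratic term first).
    """

    fringes: np.ndarray
    wavelength_nm: np.ndarray
    background: np.ndarray
    dispersion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.fringes = np.atleast_2d(np.asarray(self.fringes, float))
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.background = np.asarray(self.background, float)
        d = np.diff(self.wavelength_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotonic")
        if self.background.shape[-1] != self.wavelength_nm.size:
            raise ValueError("background must match the spectral axis length")
        if self.fringes.shape[-1] != self.wavelength_nm.size:
            raise ValueError("fringes must match the spectral axis length")

    @property
    def n_samples(self) -> int:
        return self.wavelength_nm.size

    @property
    def n_alines(self) -> int:
        return self.fringes.shape[0]


def reconstruct_bscan(
    frame: SpectralFrame,
    n_medium: float = 1.38,
    interp: str = "cubic",
    lateral_spacing_um: float = 1.0,
) -> Volume3D:
    """Reconstruct one B-scan (depth x lateral) from a spectral frame.

    Per A-line: subtract the background spectrum, resample from wavelength
    onto a uniform wavenumber grid, remove the residual dispersion phase
    from the analytic signal, inverse-Fourier-transform and keep the
    magnitude over positive depths.

    Returns a :class:`Volume3D` of shape ``(n_depth, 1, n_lateral)`` whose
    z spacing is the depth pixel ``π / (Δk · n_medium)`` in µm.
    """
    wl = frame.wavelength_nm
    sig = frame.fringes - frame.background[np.newaxis, :]
    k = 2.0 * np.pi / (wl * 1e-3)  # rad/µm
    order = np.argsort(k)
    k_sorted = k[order]
    sig = sig[:, order]

    n = frame.n_samples
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], n)
    if interp == "cubic":
        resampled = CubicSpline(k_sorted, sig, axis=1)(k_uniform)
    elif interp == "linear":
        resampled = interp1d(k_sorted, sig, axis=1)(k_uniform)
    else:
        raise ValueError(f"unknown interpolation {interp!r}")

    analytic = hilbert(resampled, axis=1)
    if frame.dispersion:
        k0 = k_uniform.mean()
        phase = np.zeros(n)
        for j, c in enumerate(frame.dispersion):
            phase += c * (k_uniform - k0) ** (j + 2)
        analytic = analytic * np.exp(-1j * phase)[np.newaxis, :]

    # inverse transform to depth; the analytic signal's fringe phase is
    # +2·n·z·k, so the conjugate-exponent transform places z > 0 in the
    # first half of the axis
    depth_profile = np.fft.fft(analytic, axis=1) / n
    half = n // 2
    mag = np.abs(depth_profile[:, :half])  # (lateral, depth)

    dk = k_uniform[-1] - k_uniform[0]
    dz = np.pi / (dk * n_medium)  # µm per depth pixel
    data = mag.T[:, np.newaxis, :]  # (depth, 1, lateral)
    return Volume3D(
        data=data,
        spacing=(dz, lateral_spacing_um, lateral_spacing_um),
        modality=Modality.OCM,
    )


def en_face_projection(
    vol: Volume3D,
    method: str = "STD",
    log_compress: bool = False,
    db_floor: float = -40.0,
) -> np.ndarray:
    """Collapse the depth (z) axis by a statistic; optionally log-compress.

    ``method`` is one of ``STD`` (sample standard deviation), ``MAX`` or
    ``MEAN``.  Log compression maps ``x -> 20·log10(x / x_max)`` clipped at
    ``db_floor`` dB below the peak; an all-zero projection returns a floor
    image with a warning.
    """
    data = vol.data
    if method == "STD":
        img = data.std(axis=0, ddof=1) if data.shape[0] > 1 else np.zeros(data.shape[1:])
    elif method == "MAX":
        img = data.max(axis=0)
    elif method == "MEAN":
        img = data.mean(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    if not log_compress:
        return img
    peak = img.max()
    if peak <= 0:
        warnings.warn("all-zero projection: returning the dB floor image")
        return np.full_like(img, db_floor, dtype=float)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(img > 0, img / peak, np.nan))
    db = np.where(np.isnan(db), db_floor, db)
    return np.clip(db, db_floor, 0.0)
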
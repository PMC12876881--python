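"""Spectral-domain OCM reconstruction from synthetic interferograms.

Synthesises fringes for two point reflectors under an 845 nm / 131 nm
Gaussian source (the wavelength axis is nonlinear in wavenumber, so the
rescaling step matters), reconstructs the depth profile, and shows that
residual dispersion injected into the fringes is removed by the software
compensation.
"""

import dataclasses

import numpy as np

from ocpam.recon import reconstruct_bscan
from ocpam.synthetic import generate_interferogram

frame = generate_interferogram(
    reflector_depths_um=[100.0, 200.0], reflectivities=[1.0, 0.5], seed=0)
vol = reconstruct_bscan(frame, n_medium=1.38)
prof = vol.data[:, 0, 0].copy()
prof[:3] = 0  # ignore the DC bin
dz = vol.spacing[0]
print(f"depth pixel: {dz:.3f} µm (set by the spectral span and n=1.38)")
for z_true in (100.0, 200.0):
    i = int(round(z_true / dz))
    window = prof[i - 4:i + 5]
    peak = i - 4 + int(window.argmax())
    print(f"  reflector at {z_true:.0f} µm reconstructed at "
          f"{peak * dz:.1f} µm, amplitude {prof[peak]:.3f}")

# dispersion round trip: inject a quadratic phase, then compensate it
blurred = generate_interferogram([150.0], [1.0], seed=1, dispersion=(40.0,))
uncorrected = reconstruct_bscan(dataclasses.replace(blurred, dispersion=()))
corrected = reconstruct_bscan(blurred)


def fwhm(p):
    p = p.copy()
    p[:3] = 0
    pk = int(p.argmax())
    half = p[pk] / 2
    left = right = pk
    while left > 0 and p[left] > half:
        left -= 1
    while right < len(p) - 1 and p[right] > half:
        right += 1
    return (right - left) * dz


print(f"\nresidual dispersion blurs the peak: "
      f"{fwhm(uncorrected.data[:, 0, 0]):.1f} µm FWHM uncompensated vs "
      f"{fwhm(corrected.data[:, 0, 0]):.1f} µm after software compensation")

with np.errstate(divide="ignore"):
    db = np.clip(20.0 * np.log10(prof / prof.max()), -40.0, 0.0)
print(f"log-compressed depth profile: 0 dB at the strongest reflector, "
      f"{int((db > -40.0).sum())} of {db.size} depth pixels above the "
      f"-40 dB display floor")
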
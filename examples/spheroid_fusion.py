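"""OCM/PAM fusion and rare melanin-positive cell detection.

Calibrates the two modalities on a gold-pyramid phantom pair with a known
offset/scale, then detects sparsely mixed melanin-positive cells in a
spheroid PAM volume by 87%-of-peak per-line thresholding and compares the
detections with the generator's ground truth.
"""

import numpy as np
from scipy.spatial.distance import cdist

from ocpam.core import Volume3D
from ocpam.fusion import apply_calibration, calibrate_fusion, detect_absorbers
from ocpam.synthetic import generate_phantom_pair, generate_spheroid_pam

# --- phantom calibration ---------------------------------------------------
true_offset, true_scale = (10.0, 5.0, 0.0), (1.2, 1.0, 1.0)
ocm_ph, pam_ph, _ = generate_phantom_pair(true_offset, true_scale, seed=4)
cal = calibrate_fusion(ocm_ph, pam_ph)
print("phantom calibration (PAM -> OCM frame):")
print(f"  offset: true {true_offset} -> recovered "
      f"{tuple(round(o, 2) for o in cal.offset_um)} µm")
print(f"  scale:  true {true_scale} -> recovered "
      f"{tuple(round(s, 3) for s in cal.scale)}")
print(f"  residual surface disagreement: {cal.residual_um:.2f} µm RMS")

# resampling the PAM phantom into the OCM frame aligns the two surfaces
pam_reg = apply_calibration(pam_ph, cal, ocm_ph)
corr = np.corrcoef(ocm_ph.data.ravel(), pam_reg.data.ravel())[0, 1]
print(f"  voxelwise correlation after co-registration: {corr:.3f}")

# --- rare cell detection at 1% mixing --------------------------------------
ocm, pam, truth = generate_spheroid_pam(melanin_fraction=0.01, n_cells=400,
                                        seed=3)
cents = detect_absorbers(pam, threshold_fraction=0.87)
det = np.array([c.position_um for c in cents])
pos = truth.melanin_centers_um
D = cdist(pos, det) if len(det) else np.empty((len(pos), 0))
r = truth.extras["cell_radius_um"]
recall = (D.min(axis=1) <= r).mean() if len(det) else 0.0
print(f"\nspheroid with {len(pos)} melanin-positive of 400 cells (1% mixing):")
print(f"  detected {len(det)} absorber centroids, recall {100 * recall:.0f}% "
      f"(match radius = one cell radius, {r:.0f} µm)")

# --- control: no melanin, no signal ----------------------------------------
_, pam0, _ = generate_spheroid_pam(melanin_fraction=0.0, n_cells=400, seed=3)
print(f"  0% mixing control: {len(detect_absorbers(pam0))} detections "
      "(pure noise floor)")
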
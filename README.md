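# ocpam

Analysis pipeline for multimodal **optical coherence / photoacoustic
microscopy (OC-PAM)** of 3D cancer models — organoids and spheroids — for
researchers running label-free longitudinal drug-response studies.

Cancer organoids grown in matrix domes can be imaged volumetrically,
repeatedly and without staining by optical coherence microscopy (OCM).
This package turns those volumes into quantitative biology:

- **Segmentation & tracking** — individual organoids are segmented in each
  3D volume and linked across imaging days by attribute-based probability
  scoring (Gaussian centroid-distance kernel, volume-ratio kernel,
  bounding-box IoU), seeded from a middle-day reference volume and chained
  forward and backward in time. Organoid fusion events are detected from
  mask overlaps.
- **Growth kinetics** — per-organoid volume curves are normalised to the
  first observation and classified as rapid (≥ 2 decades of relative
  volume), medium (1–2 decades), weak (< 1 decade), or **DTP**
  (drug-tolerant persister): a biphasic plateau-then-regrowth trajectory,
  the signature of transiently arrested cells that resume proliferation
  after drug withdrawal.
- **Radiomics viability classification** — 32 texture features per
  organoid (9 first-order, 13 grey-level co-occurrence, 10 grey-level
  run-length) computed on the original OCM intensities inside the mask,
  feeding a gradient-boosted (XGBoost) classifier cross-validated against
  live/dead fluorescence ground truth (acridine-orange / propidium-iodide
  style staining, viability score = live/(live+dead) pixels, 50% cut-off).
  Tracked organoids are then scored label-free day by day; the *overall
  viability* of a track is the fraction of days predicted high-viability.
- **OCM/PAM fusion & rare-cell detection** — photoacoustic microscopy adds
  absorption contrast (melanin). The two modalities are co-registered with
  an axis-aligned affine (per-axis offset + scale) calibrated on a
  gold-coated pyramid phantom, and melanin-positive cells are located by
  thresholding each PAM depth line at 87% of its peak amplitude.
- **Spectral-domain reconstruction** — background subtraction, wavelength →
  wavenumber resampling, software dispersion compensation and inverse FFT,
  with standard-deviation / maximum / mean en-face projections on a dB
  scale.

Because raw study data of this kind is rarely public, the package ships a
first-class **synthetic-data module** (`ocpam.synthetic`) that emulates
every input with seeded randomness: speckled ellipsoidal organoids with
class-dependent growth trajectories and texture regimes, live/dead
fluorescence pairs, melanin-mixing spheroids, calibration phantom pairs
and point-reflector interferograms — each with ground truth for testing.

## Worked example

`examples/longitudinal_tracking.py` simulates a treated well, segments,
tracks and classifies growth:

```
simulated 24 organoids over days (3, 5, 7, 9)
  day  3: 24 organoids segmented
  day  5: 24 organoids segmented
  day  7: 24 organoids segmented
  day  9: 24 organoids segmented
24 tracks built (reference day = middle of the series)
growth classes: {'MEDIUM': 6, 'WEAK': 18}
DTP fraction: 0.0% (drug-tolerant-persister pattern: plateau then regrowth)
mean relative volume per day (normalised to first observation):
  day  3: 1.0x
  day  5: 1.97x
  day  7: 3.33x
  day  9: 4.51x
```

Every generated organoid was recovered and tracked; the well mixes
weak/no-growth organoids (relative volume stays under one decade) with
medium growers, and — as configured for this well — contains no persister.
`examples/viability_classification.py`, `examples/spheroid_fusion.py` and
`examples/spectral_reconstruction.py` walk through the other capabilities
the same way.

The `ocpam` command exposes the same pipeline from the shell
(`simulate | reconstruct | segment | track | growth | viability |
features | classify | fuse`), reading/writing TIFF volumes, CSV tables and
JSON manifests; see `ocpam --help`.

## Layout

| Module | Role |
| --- | --- |
| `ocpam.core`, `ocpam.io`, `ocpam.config` | data model (`Volume3D`, `LabelMask`, `OrganoidRecord`), TIFF/CSV/JSON I/O, YAML pipeline configuration |
| `ocpam.synthetic` | seeded generators for every pipeline input + ground truth |
| `ocpam.recon` | spectral-domain A-line reconstruction, en-face projections |
| `ocpam.segment` | preprocessing, classical + external-mask segmentation backends |
| `ocpam.tracking` | reference-day dual-branch matching, merge detection |
| `ocpam.growth` | relative growth, pattern classification, well summaries |
| `ocpam.viability` | CLAHE + Otsu channel binarisation, viability score and status |
| `ocpam.radiomics` | the 32-feature texture extractor (first-order / GLCM / GLRLM) |
| `ocpam.classify` | cross-validation, learning curve, importances, track scoring |
| `ocpam.fusion` | phantom calibration, resampling, absorber detection, overlays |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
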
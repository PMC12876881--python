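"""Synthetic inputs for the whole pipeline, with seeded randomness.

Generates longitudinal OCM organoid series with ground truth, paired
live/dead fluorescence renderings, melanin-mixing spheroid OCM/PAM pairs,
gold-pyramid calibration phantom pairs and spectral-domain interferograms.
Default geometry mirrors the imaging study being emulated: 2.52 µm step
size for longitudinal organoid imaging, 0.84 µm for spheroid imaging, a
1.38 soft-tissue refractive index, an 845 nm / 131 nm source.

Growth trajectories
-------------------
Four growth classes are generated, parameterised as per-interval volume
fold-changes over the imaging days (every other day from day 3):

* ``RAPID`` — ten-fold in the first interval, two to three decades by the
  fourth time point, unbroken growth thereafter.
* ``MEDIUM`` — slower expansion approaching (but not reaching) two decades
  at the end of the series.
* ``WEAK`` — limited growth, well below one decade.
* ``DTP`` (drug-tolerant persister) — biphasic: roughly ten-fold over the
  first two intervals, a plateau over the middle of the series, then rapid
  regrowth exceeding three decades of final relative volume.

The speckle model is multiplicative Rayleigh texture (standard OCT speckle
statistics) smoothed to a class-dependent correlation length; the
low-viability regime uses a shorter correlation length and a lower mean
backscatter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import LabelMask, Modality, Volume3D
from .recon import SpectralFrame

__all__ = [
    "GrowthClass",
    "OrganoidTruth",
    "SceneTruth",
    "DEFAULT_TRAJECTORIES",
    "DEFAULT_DAYS",
    "TEXTURE_REGIMES",
    "generate_organoid_timeseries",
    "generate_flm_pair",
    "generate_spheroid_pam",
    "generate_phantom_pair",
    "generate_interferogram",
]

GROWTH_CLASS_NAMES = ("RAPID", "MEDIUM", "WEAK", "DTP")

#: Imaging every other day from day 3, ten time points (21-day series).
DEFAULT_DAYS = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21)


@dataclass(frozen=True)
class GrowthClass:
    """A named growth pattern given as per-interval volume fold-changes."""

    name: str
    folds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in GROWTH_CLASS_NAMES:
            raise ValueError(f"unknown growth class {self.name!r}")
        if any(f <= 0 for f in self.folds):
            raise ValueError("all fold-changes must be > 0")
        if self.name == "DTP":
            self._check_biphasic()

    def _check_biphasic(self, f_plateau: float = 1.25) -> None:
        # need >= 2 consecutive plateau intervals followed by regrowth
        flat = [f <= f_plateau for f in self.folds]
        ok = False
        run = 0
        for i, is_flat in enumerate(flat):
            run = run + 1 if is_flat else 0
            if run >= 2 and any(not f for f in flat[i + 1 :]):
                ok = True
        if not ok:
            raise ValueError(
                "DTP trajectory needs >= 2 consecutive plateau intervals "
                "followed by regrowth"
            )

    def folds_for(self, n_intervals: int) -> np.ndarray:
        """Trajectory truncated/extended to ``n_intervals`` intervals."""
        f = list(self.folds)
        while len(f) < n_intervals:
            f.append(f[-1])
        return np.asarray(f[:n_intervals], dtype=float)


# Canonical 9-interval trajectories for the default 10-point series.
DEFAULT_TRAJECTORIES: dict[str, GrowthClass] = {
    # ten-fold in the first interval, ~200x by the 4th time point
    "RAPID": GrowthClass("RAPID", (10.0, 5.0, 4.0, 2.0, 1.8, 1.6, 1.5, 1.4, 1.3)),
    # approaches but stays under two decades at the end of the series
    "MEDIUM": GrowthClass("MEDIUM", (3.0, 2.5, 2.0, 1.8, 1.6, 1.3, 1.15, 1.1, 1.05)),
    # well under one decade overall
    "WEAK": GrowthClass("WEAK", (1.6, 1.4, 1.2, 1.1, 1.05, 1.02, 1.0, 1.0, 1.0)),
    # ~10x over two intervals, plateau over the series middle, rapid regrowth
    "DTP": GrowthClass("DTP", (3.5, 3.0, 1.05, 1.08, 1.05, 6.0, 5.0, 4.0, 3.0)),
}

#: Speckle regimes by viability class: (mean backscatter, correlation length
#: in voxels).  LOW viability: dimmer, finer-grained speckle.
TEXTURE_REGIMES: dict[str, tuple[float, float]] = {
    "HIGH": (0.55, 1.2),
    "LOW": (0.30, 0.4),
}


@dataclass
class OrganoidTruth:
    """Ground truth for one synthetic organoid across the series."""

    id: int
    growth_class: str
    viability: str  # HIGH | LOW
    texture_regime: str
    ellipsoids: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]]
    # day -> (center µm (z,y,x), semi-axes µm (z,y,x))

    def analytic_volume(self, day: int) -> float:
        """Exact ellipsoid volume in µm³ on the given day."""
        _, semi = self.ellipsoids[day]
        return 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2]

    def relative_trajectory(self, days: Sequence[int]) -> np.ndarray:
        v = np.array([self.analytic_volume(d) for d in days])
        return v / v[0]


@dataclass
class SceneTruth:
    """Everything the generators decided, for testing against."""

    days: tuple[int, ...]
    field_um: tuple[float, float, float]
    spacing_um: tuple[float, float, float]
    organoids: list[OrganoidTruth] = field(default_factory=list)
    cell_centers_um: Optional[np.ndarray] = None
    melanin_centers_um: Optional[np.ndarray] = None
    melanin_loads: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)

    def organoid(self, oid: int) -> OrganoidTruth:
        for o in self.organoids:
            if o.id == oid:
                return o
        raise KeyError(f"no organoid with id {oid}")

    def to_json(self, path: str) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "days": list(self.days),
            "field_um": list(self.field_um),
            "spacing_um": list(self.spacing_um),
            "organoids": [
                {
                    "id": o.id,
                    "growth_class": o.growth_class,
                    "viability": o.viability,
                    "texture_regime": o.texture_regime,
                    "ellipsoids": {
                        str(d): {"center_um": list(c), "semi_axes_um": list(s)}
                        for d, (c, s) in o.ellipsoids.items()
                    },
                }
                for o in self.organoids
            ],
            "cell_centers_um": arr(self.cell_centers_um),
            "melanin_centers_um": arr(self.melanin_centers_um),
            "melanin_loads": arr(self.melanin_loads),
            "extras": self.extras,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path


# ---------------------------------------------------------------------------
# longitudinal organoid series
# ---------------------------------------------------------------------------


def _pick_grid(field_um, n, cell_req_um):
    """Smallest axis-proportional grid of cells of extent >= cell_req_um."""
    g = [max(1, int(f // cell_req_um)) for f in field_um]
    if g[0] * g[1] * g[2] < n:
        raise ValueError(
            f"field too small: {field_um} µm fits {g[0] * g[1] * g[2]} organoids "
            f"of final extent {cell_req_um:.1f} µm, requested {n}"
        )
    return g


def _rayleigh_speckle(rng, shape, corr_len_vox: float) -> np.ndarray:
    """Strictly positive multiplicative speckle with mean 1."""
    f = rng.rayleigh(1.0, size=shape)
    if corr_len_vox > 0:
        f = gaussian_filter(f, corr_len_vox)
    return f / f.mean()


def generate_organoid_timeseries(
    n_organoids: int,
    days: Sequence[int] = DEFAULT_DAYS,
    class_mix: Optional[Mapping[str, float]] = None,
    field_um: tuple[float, float, float] = (600.0, 1200.0, 1200.0),
    spacing_um: tuple[float, float, float] = (2.52, 2.52, 2.52),
    seed: int = 0,
    viability_mix: float = 0.5,
    drift_um_per_day: float = 2.0,
    initial_semiaxis_um: tuple[float, float, float] = (5.0, 8.0, 0.2),
    fold_jitter: float = 0.02,
    separation_margin_um: float = 10.0,
    trajectories: Optional[Mapping[str, GrowthClass]] = None,
    background_noise: float = 0.012,
) -> tuple[list[Volume3D], list[LabelMask], SceneTruth]:
    """Generate a longitudinal OCM organoid scene with ground truth.

    Parameters
    ----------
    n_organoids:
        Number of organoids (>= 1).
    days:
        Ordered acquisition days (>= 2).
    class_mix:
        Probabilities over growth classes; default is the treated-well mix
        ``{WEAK: 0.55, MEDIUM: 0.25, RAPID: 0.12, DTP: 0.08}``.
    viability_mix:
        Probability of the HIGH-viability texture regime per organoid.
    initial_semiaxis_um:
        ``(min, max, anisotropy)``: base radius drawn uniformly in
        [min, max] µm, per-axis semi-axes scaled by ``1 ± anisotropy``.
    drift_um_per_day:
        Magnitude of the random centre drift per imaging day.
    fold_jitter:
        Log-normal jitter applied to each per-interval fold-change.

    Returns ``(volumes, masks, truth)``: one OCM :class:`Volume3D` and one
    ground-truth :class:`LabelMask` per day, plus the :class:`SceneTruth`.
    The masks carry stable ids (1..n) across days.
    """
    if n_organoids < 1:
        raise ValueError("n_organoids must be >= 1")
    days = tuple(int(d) for d in days)
    if len(days) < 2 or list(days) != sorted(set(days)):
        raise ValueError("days must be >= 2 strictly increasing integers")
    if class_mix is None:
        class_mix = {"WEAK": 0.55, "MEDIUM": 0.25, "RAPID": 0.12, "DTP": 0.08}
    probs = np.array([class_mix.get(c, 0.0) for c in GROWTH_CLASS_NAMES], float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_mix must sum to 1")
    trajectories = dict(DEFAULT_TRAJECTORIES, **(trajectories or {}))
    rng = np.random.default_rng(seed)

    n_int = len(days) - 1
    classes = rng.choice(GROWTH_CLASS_NAMES, size=n_organoids, p=probs / probs.sum())
    viability = np.where(rng.random(n_organoids) < viability_mix, "HIGH", "LOW")
    lo, hi, aniso = initial_semiaxis_um
    base_r = rng.uniform(lo, hi, size=n_organoids)
    axis_factors = rng.uniform(1 - aniso, 1 + aniso, size=(n_organoids, 3))

    folds = np.empty((n_organoids, n_int))
    for i, c in enumerate(classes):
        f = trajectories[c].folds_for(n_int)
        folds[i] = f * np.exp(rng.normal(0.0, fold_jitter, size=n_int))
    cum_fold = np.concatenate(
        [np.ones((n_organoids, 1)), np.cumprod(folds, axis=1)], axis=1
    )  # relative volume per day
    radial_scale = cum_fold ** (1.0 / 3.0)

    # placement on a jittered grid sized for the final-day extent
    drift_total = drift_um_per_day * n_int
    semi0 = base_r[:, None] * axis_factors  # (n, 3)
    max_final_semi = float((semi0 * radial_scale[:, -1][:, None]).max())
    cell_req = 2.0 * (max_final_semi + drift_total + separation_margin_um)
    grid = _pick_grid(field_um, n_organoids, cell_req)
    cell_ext = [f / g for f, g in zip(field_um, grid)]
    cells = [
        (iz, iy, ix)
        for iz in range(grid[0])
        for iy in range(grid[1])
        for ix in range(grid[2])
    ]
    chosen = rng.choice(len(cells), size=n_organoids, replace=False)
    slack = [max(0.0, (e - cell_req) / 2.0) for e in cell_ext]
    centers0 = np.empty((n_organoids, 3))
    for i, ci in enumerate(chosen):
        cc = cells[ci]
        for a in range(3):
            mid = (cc[a] + 0.5) * cell_ext[a]
            centers0[i, a] = mid + rng.uniform(-slack[a], slack[a])

    # per-day centres: bounded random walk inside the cell slack
    centers = np.empty((n_organoids, len(days), 3))
    centers[:, 0] = centers0
    for di in range(1, len(days)):
        step = rng.normal(0.0, drift_um_per_day / np.sqrt(3.0), size=(n_organoids, 3))
        centers[:, di] = centers[:, di - 1] + step
    # clip so every ellipsoid stays inside its cell (hence the field) always
    for i, ci in enumerate(chosen):
        cc = cells[ci]
        for a in range(3):
            lo_c = cc[a] * cell_ext[a] + cell_req / 2.0
            hi_c = (cc[a] + 1) * cell_ext[a] - cell_req / 2.0
            if hi_c < lo_c:
                lo_c = hi_c = (cc[a] + 0.5) * cell_ext[a]
            centers[i, :, a] = np.clip(centers[i, :, a], lo_c, hi_c)

    shape = tuple(int(round(f / s)) for f, s in zip(field_um, spacing_um))
    organoids: list[OrganoidTruth] = []
    for i in range(n_organoids):
        ell = {}
        for di, d in enumerate(days):
            semi = tuple(semi0[i] * radial_scale[i, di])
            ell[d] = (tuple(centers[i, di]), semi)
        organoids.append(
            OrganoidTruth(
                id=i + 1,
                growth_class=str(classes[i]),
                viability=str(viability[i]),
                texture_regime=str(viability[i]),
                ellipsoids=ell,
            )
        )
    truth = SceneTruth(
        days=days, field_um=tuple(field_um), spacing_um=tuple(spacing_um),
        organoids=organoids,
    )

    volumes, masks = [], []
    coords = [np.arange(n) * s for n, s in zip(shape, spacing_um)]
    for di, d in enumerate(days):
        data = np.abs(rng.normal(background_noise, background_noise / 2.5, size=shape))
        labels = np.zeros(shape, dtype=np.int32)
        for o in organoids:
            center, semi = o.ellipsoids[d]
            base, corr = TEXTURE_REGIMES[o.texture_regime]
            sl = []
            for a in range(3):
                i0 = max(0, int(np.floor((center[a] - semi[a]) / spacing_um[a])) - 1)
                i1 = min(shape[a], int(np.ceil((center[a] + semi[a]) / spacing_um[a])) + 2)
                sl.append(slice(i0, i1))
            zz = (coords[0][sl[0]] - center[0]) / semi[0]
            yy = (coords[1][sl[1]] - center[1]) / semi[1]
            xx = (coords[2][sl[2]] - center[2]) / semi[2]
            inside = (
                zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
            ) <= 1.0
            speck = _rayleigh_speckle(rng, inside.shape, corr)
            sub = data[tuple(sl)]
            sub[inside] = base * speck[inside]
            labels[tuple(sl)][inside] = o.id
        volumes.append(
            Volume3D(data=data, spacing=tuple(spacing_um), modality=Modality.OCM, day=d)
        )
        masks.append(LabelMask(labels=labels, spacing=tuple(spacing_um), day=d))
    return volumes, masks, truth


# ---------------------------------------------------------------------------
# fluorescence live/dead pair
# ---------------------------------------------------------------------------


def generate_flm_pair(
    mask: LabelMask,
    truth: Optional[SceneTruth] = None,
    live_fraction_by_class: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    live_fraction_by_label: Optional[Mapping[int, float]] = None,
    foreground: float = 180.0,
    background: float = 12.0,
) -> tuple[Volume3D, Volume3D]:
    """Render a live/dead channel pair over a label mask.

    Inside each organoid every voxel is assigned live with the Bernoulli
    probability of its viability class (acridine-orange-like channel) or
    dead otherwise (propidium-iodide-like channel); the two channels are
    spatially disjoint per voxel.  ``live_fraction_by_label`` overrides the
    class mapping per organoid id.
    """
    if mask.n_labels == 0:
        raise ValueError("mask is empty: no organoids to stain")
    if live_fraction_by_class is None:
        live_fraction_by_class = {"HIGH": 0.9, "LOW": 0.15}
    for p in live_fraction_by_class.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError("live fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = mask.shape
    live = np.abs(rng.normal(background, background / 3.0, size=shape))
    dead = np.abs(rng.normal(background, background / 3.0, size=shape))
    for lab in range(1, mask.n_labels + 1):
        voxels = mask.labels == lab
        n = int(voxels.sum())
        if n == 0:
            continue
        if live_fraction_by_label is not None and lab in live_fraction_by_label:
            p = float(live_fraction_by_label[lab])
        elif truth is not None:
            p = float(live_fraction_by_class[truth.organoid(lab).viability])
        else:
            p = float(next(iter(live_fraction_by_class.values())))
        is_live = rng.random(n) < p
        bright = foreground + rng.normal(0.0, foreground / 15.0, size=n)
        idx = np.nonzero(voxels)
        live[idx] = np.where(is_live, bright, live[idx])
        dead[idx] = np.where(~is_live, bright, dead[idx])
    mk = dict(spacing=mask.spacing, day=mask.day)
    return (
        Volume3D(data=live, modality=Modality.FLM_LIVE, **mk),
        Volume3D(data=dead, modality=Modality.FLM_DEAD, **mk),
    )


# ---------------------------------------------------------------------------
# melanin-mixing spheroid for OC-PAM
# ---------------------------------------------------------------------------


def generate_spheroid_pam(
    melanin_fraction: float,
    n_cells: int = 1000,
    spacing_um: tuple[float, float, float] = (0.84, 0.84, 0.84),
    seed: int = 0,
    cell_radius_um: float = 5.0,
    packing_fraction: float = 0.25,
    pam_noise: float = 0.01,
    blob_sigma_um: Optional[float] = None,
) -> tuple[Volume3D, Volume3D, SceneTruth]:
    """Co-culture spheroid: OCM shows the whole spheroid, PAM only the
    melanin-positive cells.

    Cell centres are placed with minimum separation of one cell diameter
    inside a sphere sized from ``n_cells`` and ``packing_fraction``.  The
    melanin-positive subset is the first ``round(f * n_cells)`` entries of
    a seed-fixed permutation, so positive sets are nested across mixing
    fractions at matched seeds.  PAM amplitude per cell is proportional to
    a log-normal per-cell melanin load; fraction 0 yields a pure noise
    floor.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= melanin_fraction <= 1.0:
        raise ValueError("melanin_fraction must lie in [0, 1]")
    rng_place = np.random.default_rng([seed, 1])
    rng_perm = np.random.default_rng([seed, 2])
    rng_load = np.random.default_rng([seed, 3])
    rng_noise = np.random.default_rng([seed, 4])

    cell_vol = 4.0 / 3.0 * np.pi * cell_radius_um**3
    radius = (n_cells * cell_vol / packing_fraction * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin = 4.0 * cell_radius_um
    field = tuple(2.0 * (radius + margin) for _ in range(3))
    center = np.array([f / 2.0 for f in field])

    # random sequential placement with a coarse hash grid
    min_sep = 2.0 * cell_radius_um
    cell_size = min_sep
    grid: dict[tuple[int, int, int], list[int]] = {}
    centers = np.empty((n_cells, 3))
    placed = 0
    attempts = 0
    max_attempts = 200 * n_cells
    while placed < n_cells and attempts < max_attempts:
        attempts += 1
        u = rng_place.normal(size=3)
        u /= np.linalg.norm(u)
        r = (radius - cell_radius_um) * rng_place.random() ** (1.0 / 3.0)
        p = center + u * r
        key = tuple(int(c // cell_size) for c in p)
        ok = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for j in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        if np.sum((centers[j] - p) ** 2) < min_sep**2:
                            ok = False
                            break
        if ok:
            centers[placed] = p
            grid.setdefault(key, []).append(placed)
            placed += 1
    if placed < n_cells:
        raise ValueError("could not place all cells; lower packing_fraction")

    n_pos = int(round(melanin_fraction * n_cells))
    perm = rng_perm.permutation(n_cells)
    pos_idx = perm[:n_pos]
    loads = rng_load.lognormal(mean=0.0, sigma=0.25, size=n_cells)

    shape = tuple(int(round(f / s)) for f, s in zip(field, spacing_um))
    coords = [np.arange(n) * s for n, s in zip(shape, spacing_um)]

    # OCM: full spheroid with speckle
    ocm = np.abs(rng_noise.normal(0.012, 0.005, size=shape))
    zz = (coords[0] - center[0]) ** 2
    yy = (coords[1] - center[1]) ** 2
    xx = (coords[2] - center[2]) ** 2
    inside = (
        zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    ) <= radius**2
    speck = _rayleigh_speckle(rng_noise, shape, 1.0)
    ocm[inside] = 0.5 * speck[inside]

    # PAM: noise floor plus Gaussian blobs at the positive cell centres
    pam = np.abs(rng_noise.normal(0.0, pam_noise, size=shape))
    sigma = blob_sigma_um if blob_sigma_um is not None else cell_radius_um / 2.0
    half = 3.0 * sigma
    for i in pos_idx:
        c = centers[i]
        sl, local = [], []
        for a in range(3):
            i0 = max(0, int(np.floor((c[a] - half) / spacing_um[a])))
            i1 = min(shape[a], int(np.ceil((c[a] + half) / spacing_um[a])) + 1)
            sl.append(slice(i0, i1))
            local.append(coords[a][i0:i1] - c[a])
        g = np.exp(
            -(
                local[0][:, None, None] ** 2
                + local[1][None, :, None] ** 2
                + local[2][None, None, :] ** 2
            )
            / (2.0 * sigma**2)
        )
        region = pam[tuple(sl)]
        np.maximum(region, loads[i] * g, out=region)

    truth = SceneTruth(
        days=(0, 0),
        field_um=field,
        spacing_um=tuple(spacing_um),
        cell_centers_um=centers,
        melanin_centers_um=centers[pos_idx] if n_pos else np.empty((0, 3)),
        melanin_loads=loads,
        extras={
            "melanin_fraction": melanin_fraction,
            "spheroid_radius_um": radius,
            "spheroid_center_um": center.tolist(),
            "cell_radius_um": cell_radius_um,
            "positive_indices": pos_idx.tolist(),
        },
    )
    sp = tuple(spacing_um)
    return (
        Volume3D(data=ocm, spacing=sp, modality=Modality.OCM),
        Volume3D(data=pam, spacing=sp, modality=Modality.PAM),
        truth,
    )


# ---------------------------------------------------------------------------
# gold pyramid calibration phantom
# ---------------------------------------------------------------------------


def generate_phantom_pair(
    true_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    true_scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    field_um: tuple[float, float, float] = (120.0, 240.0, 240.0),
    spacing_um: tuple[float, float, float] = (2.0, 2.0, 2.0),
    pyramid_height_um: float = 60.0,
    pyramid_halfwidth_um: float = 70.0,
    coating_um: float = 4.0,
    noise: float = 0.03,
) -> tuple[Volume3D, Volume3D, dict]:
    """Render the same gold-coated pyramid surface on an OCM grid and a
    PAM grid whose physical coordinates are ``scale * index * spacing +
    offset``.

    Returns ``(ocm_phantom, pam_phantom, truth)`` with ``truth`` holding
    the offset and scale that map PAM coordinates into the OCM frame.
    """
    scale = np.asarray(true_scale, float)
    offset = np.asarray(true_offset_um, float)
    if np.any(scale <= 0):
        raise ValueError("scales must be > 0")
    rng = np.random.default_rng(seed)
    shape = tuple(int(round(f / s)) for f, s in zip(field_um, spacing_um))
    zc = field_um[0] * 0.25
    yc, xc = field_um[1] / 2.0, field_um[2] / 2.0

    def surface_z(y, x):
        d = np.maximum(np.abs(y - yc), np.abs(x - xc))
        h = pyramid_height_um * np.clip(1.0 - d / pyramid_halfwidth_um, 0.0, None)
        return zc + h

    def render(transform_scale, transform_offset, rng_local):
        z = np.arange(shape[0]) * spacing_um[0]
        y = np.arange(shape[1]) * spacing_um[1]
        x = np.arange(shape[2]) * spacing_um[2]
        # physical coordinates of this grid's voxels
        pz = transform_scale[0] * z + transform_offset[0]
        py = transform_scale[1] * y + transform_offset[1]
        px = transform_scale[2] * x + transform_offset[2]
        zs = surface_z(py[:, None], px[None, :])  # (ny, nx)
        prof = np.exp(-((pz[:, None, None] - zs[None]) ** 2) / (2.0 * coating_um**2))
        return prof + np.abs(rng_local.normal(0.0, noise, size=shape))

    ocm = render((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), np.random.default_rng([seed, 11]))
    pam = render(scale, offset, np.random.default_rng([seed, 12]))
    truth = {"offset_um": tuple(offset), "scale": tuple(scale)}
    sp = tuple(spacing_um)
    return (
        Volume3D(data=ocm, spacing=sp, modality=Modality.PHANTOM),
        Volume3D(data=pam, spacing=sp, modality=Modality.PHANTOM),
        truth,
    )


# ---------------------------------------------------------------------------
# spectral interferograms
# ---------------------------------------------------------------------------


def generate_interferogram(
    reflector_depths_um: Sequence[float],
    reflectivities: Optional[Sequence[float]] = None,
    n_samples: int = 2048,
    center_wavelength_nm: float = 845.0,
    bandwidth_nm: float = 131.0,
    background_level: float = 10.0,
    seed: int = 0,
    n_medium: float = 1.38,
    noise: float = 0.01,
    dispersion: Sequence[float] = (),
    n_alines: int = 1,
) -> SpectralFrame:
    """Synthesise a spectral-domain fringe frame for point reflectors.

    The fringe per spectral sample is ``S(λ)·(background_level +
    Σ r·cos(2·k·z·n_medium + φ(k)))`` with a Gaussian source envelope
    ``S``, ``k = 2π/λ`` and an optional residual-dispersion phase
    polynomial ``φ(k) = Σ c_j (k − k₀)^(j+2)``.  The wavelength axis is
    uniform in λ, hence nonlinear in k, to exercise the rescaling step of
    the reconstruction.
    """
    depths = np.asarray(reflector_depths_um, float)
    if reflectivities is None:
        reflectivities = np.ones_like(depths)
    refl = np.asarray(reflectivities, float)
    if depths.shape != refl.shape:
        raise ValueError("depths and reflectivities must have equal length")
    rng = np.random.default_rng(seed)

    span = 2.5 * bandwidth_nm
    wl = np.linspace(
        center_wavelength_nm - span / 2.0, center_wavelength_nm + span / 2.0, n_samples
    )
    k = 2.0 * np.pi / (wl * 1e-3)  # rad/µm, decreasing in λ
    k_span = k.max() - k.min()
    z_max = np.pi * (n_samples / 2.0) / (k_span * n_medium)
    if depths.size and depths.max() >= z_max:
        raise ValueError(
            f"depth beyond Nyquist range: max depth {depths.max():.1f} µm >= "
            f"{z_max:.1f} µm for {n_samples} samples"
        )

    sigma_wl = bandwidth_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    envelope = np.exp(-((wl - center_wavelength_nm) ** 2) / (2.0 * sigma_wl**2))
    k0 = k.mean()
    phase_disp = np.zeros_like(k)
    for j, c in enumerate(dispersion):
        phase_disp += c * (k - k0) ** (j + 2)

    background = background_level * envelope
    fringes = np.empty((n_alines, n_samples))
    for a in range(n_alines):
        sig = np.zeros(n_samples)
        for z, r in zip(depths, refl):
            sig += r * np.cos(2.0 * k * z * n_medium + phase_disp)
        fringes[a] = background + envelope * sig + rng.normal(0.0, noise, n_samples)
    return SpectralFrame(
        fringes=fringes,
        wavelength_nm=wl,
        background=background,
        dispersion=tuple(dispersion),
    )
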
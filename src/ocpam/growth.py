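"""Per-organoid volume growth analysis and growth-pattern classification.

Volumes are normalised to the first observed time point, giving
dimensionless relative-volume curves.  Patterns are assigned by rule:

* ``DTP`` — a plateau (>= ``plateau_intervals`` consecutive intervals with
  per-interval fold-change <= ``f_plateau``) occurring after at least one
  growth interval, followed by a cumulative post-plateau fold-change of at
  least ``f_regrow`` (the biphasic "stalled-then-renewed" persister
  signature);
* otherwise by the final relative volume ``R``: ``RAPID`` when
  ``log10(R) >= 2``, ``MEDIUM`` when ``1 <= log10(R) < 2``, ``WEAK`` when
  ``log10(R) < 1``.

Missing days are carried as gaps and never interpolated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import GrowthThresholds
from .tracking import Track

__all__ = ["GrowthProfile", "WellSummary", "relative_growth",
           "classify_growth_pattern", "well_summary"]


@dataclass
class GrowthProfile:
    """One track's absolute and relative volume series."""

    track_id: int
    days: tuple[int, ...]  # observed days only
    volumes: tuple[float, ...]  # µm³
    relative: tuple[float, ...]  # normalised to the first observed day
    growth_class: Optional[str] = None

    def to_flat(self) -> dict:
        return {
            "track_id": self.track_id,
            "days": ";".join(str(d) for d in self.days),
            "final_relative_volume": self.relative[-1],
            "growth_class": self.growth_class or "",
        }


@dataclass
class WellSummary:
    days: tuple[int, ...]
    mean_relative: tuple[float, ...]
    std_relative: tuple[float, ...]
    n_per_day: tuple[int, ...]
    class_counts: dict[str, int] = field(default_factory=dict)
    dtp_percentage: float = 0.0  # percent, 3 significant figures


def relative_growth(
    track: Track,
    volumes: Optional[Mapping[int, float]] = None,
) -> GrowthProfile:
    """Relative-volume series for one track, normalised to the first
    observed volume.  Days with no observation are simply absent from the
    profile (gaps are never interpolated)."""
    volumes = dict(track.volumes if volumes is None else volumes)
    days = sorted(d for d in track.observed_days if d in volumes)
    vols = [float(volumes[d]) for d in days]
    obs = [(d, v) for d, v in zip(days, vols) if v > 0]
    if len(obs) < 2:
        raise ValueError("need >= 2 observed days with volume > 0")
    days = tuple(d for d, _ in obs)
    vols = tuple(v for _, v in obs)
    if vols[0] <= 0:
        raise ValueError("zero initial volume")
    rel = tuple(v / vols[0] for v in vols)
    return GrowthProfile(track_id=track.id, days=days, volumes=vols, relative=rel)


def classify_growth_pattern(
    profile: GrowthProfile,
    thresholds: Optional[GrowthThresholds] = None,
) -> str:
    """Assign exactly one growth class to a profile (see module docstring).

    The DTP rule is tested first; otherwise the class follows from the
    final relative volume.  The assignment is deterministic and total.
    """
    th = thresholds or GrowthThresholds()
    rel = np.asarray(profile.relative)
    folds = rel[1:] / rel[:-1]

    # find plateaus: maximal runs of consecutive flat intervals
    flat = folds <= th.f_plateau
    i = 0
    is_dtp = False
    while i < len(folds):
        if flat[i]:
            j = i
            while j < len(folds) and flat[j]:
                j += 1
            run_len = j - i
            had_growth_before = bool(np.any(~flat[:i]))
            if run_len >= th.plateau_intervals and had_growth_before and j < len(folds):
                regrow = rel[-1] / rel[j]  # cumulative fold after the plateau
                if regrow >= th.f_regrow:
                    is_dtp = True
                    break
            i = j
        else:
            i += 1
    if is_dtp:
        cls = "DTP"
    else:
        final_decades = np.log10(rel[-1]) if rel[-1] > 0 else -np.inf
        if final_decades >= th.rapid_log10:
            cls = "RAPID"
        elif final_decades >= th.medium_log10:
            cls = "MEDIUM"
        else:
            cls = "WEAK"
    profile.growth_class = cls
    return cls


def _sigfig(x: float, n: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


def well_summary(profiles: Sequence[GrowthProfile]) -> WellSummary:
    """Per-day mean relative-volume curve, growth-class counts and the
    drug-tolerant-persister percentage (3 significant figures)."""
    if not profiles:
        raise ValueError("need at least one profile")
    all_days = sorted({d for p in profiles for d in p.days})
    mean, std, n_per_day = [], [], []
    for d in all_days:
        vals = [
            p.relative[p.days.index(d)] for p in profiles if d in p.days
        ]
        mean.append(float(np.mean(vals)))
        std.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        n_per_day.append(len(vals))
    counts = Counter(p.growth_class or "UNCLASSIFIED" for p in profiles)
    dtp_pct = _sigfig(100.0 * counts.get("DTP", 0) / len(profiles))
    return WellSummary(
        days=tuple(all_days),
        mean_relative=tuple(mean),
        std_relative=tuple(std),
        n_per_day=tuple(n_per_day),
        class_counts=dict(counts),
        dtp_percentage=dtp_pct,
    )
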
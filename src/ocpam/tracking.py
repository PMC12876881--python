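"""Single-organoid tracking across imaging days.

Identities are established from a middle-day reference volume and a
dual-branch analysis: labels are matched between adjacent days (forward to
the last day and backward to the first) by attribute-based probability
scoring — a Gaussian kernel on centroid distance, a volume-ratio kernel
and a bounding-box IoU kernel, combined as a weighted sum — with a one-to-
one assignment maximising the total score over pairs above an acceptance
threshold.  Organoid fusion events are detected afterwards from mask
overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import TrackingParams
from .core import LabelMask, OrganoidRecord

__all__ = [
    "MatchScore",
    "Track",
    "select_reference_day",
    "score_pair",
    "match_day_pair",
    "build_tracks",
    "detect_merges",
]

MISSING = None  # day entry for a track not observed on that day


@dataclass(frozen=True)
class MatchScore:
    """Score components for one candidate label pair (all in [0, 1])."""

    pair: tuple[int, int]
    spatial: float
    volume: float
    bbox: float
    combined: float


@dataclass
class Track:
    """One organoid's identity across the imaging series.

    ``entries`` maps day -> label (or ``None`` for MISSING); ``volumes``
    maps day -> µm³.  Flags are tuples: ``("APPEARED", day)``,
    ``("LOST", day)``, ``("MERGED_INTO", other_track_id, day)``.
    """

    id: int
    entries: dict[int, Optional[int]] = field(default_factory=dict)
    volumes: dict[int, float] = field(default_factory=dict)
    flags: list[tuple] = field(default_factory=list)

    @property
    def observed_days(self) -> list[int]:
        return sorted(d for d, lab in self.entries.items() if lab is not None)

    def label_at(self, day: int) -> Optional[int]:
        return self.entries.get(day)

    def to_flat_rows(self) -> list[dict]:
        flags = ";".join(
            ":".join(str(x) for x in f) for f in sorted(self.flags, key=str)
        )
        return [
            {
                "track_id": self.id,
                "day": d,
                "label": "" if lab is None else lab,
                "volume_um3": self.volumes.get(d, ""),
                "flags": flags,
            }
            for d, lab in sorted(self.entries.items())
        ]


def select_reference_day(days: Sequence[int]) -> int:
    """The median imaging day; for an even count, the earlier of the two
    central days (e.g. day 9 of a 3..15 every-other-day series)."""
    days = sorted(days)
    if len(days) < 2:
        raise ValueError("need at least 2 imaging days")
    return days[(len(days) - 1) // 2]


def score_pair(
    a: OrganoidRecord,
    b: OrganoidRecord,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    sigma_d_um: float = 30.0,
) -> MatchScore:
    """Attribute-based probability score for matching ``a`` to ``b``.

    Spatial kernel ``exp(-d²/(2σ²))`` on centroid distance; volume kernel
    ``min(V)/max(V)``; bbox kernel = intersection-over-union of the voxel
    bounding boxes.  Combined score is the weighted sum.
    """
    if a.volume <= 0 or b.volume <= 0:
        raise ValueError("cannot score records with zero volume")
    d2 = sum((ca - cb) ** 2 for ca, cb in zip(a.centroid, b.centroid))
    spatial = float(np.exp(-d2 / (2.0 * sigma_d_um**2)))
    volume = min(a.volume, b.volume) / max(a.volume, b.volume)
    inter = 1.0
    vol_a = vol_b = 1.0
    for (a0, a1), (b0, b1) in zip(a.bbox, b.bbox):
        inter *= max(0, min(a1, b1) - max(a0, b0))
        vol_a *= a1 - a0
        vol_b *= b1 - b0
    union = vol_a + vol_b - inter
    bbox = inter / union if union > 0 else 0.0
    w = np.asarray(weights, float)
    combined = float(w @ [spatial, volume, bbox])
    return MatchScore(
        pair=(a.label, b.label), spatial=spatial, volume=volume, bbox=bbox,
        combined=combined,
    )


def match_day_pair(
    recs_a: Sequence[OrganoidRecord],
    recs_b: Sequence[OrganoidRecord],
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    sigma_d_um: float = 30.0,
    tau: float = 0.4,
) -> tuple[dict[int, int], set[int], set[int]]:
    """One-to-one matching between two days' records.

    Solved as an optimal bipartite assignment on the combined-score matrix
    (deterministic; ties resolved toward smaller label ids by the stable
    ordering of the inputs); pairs scoring below ``tau`` are rejected.

    Returns ``(correspondence a-label -> b-label, unmatched_a, unmatched_b)``.
    """
    recs_a = sorted(recs_a, key=lambda r: r.label)
    recs_b = sorted(recs_b, key=lambda r: r.label)
    if not recs_a or not recs_b:
        return {}, {r.label for r in recs_a}, {r.label for r in recs_b}
    scores = np.zeros((len(recs_a), len(recs_b)))
    for i, ra in enumerate(recs_a):
        for j, rb in enumerate(recs_b):
            scores[i, j] = score_pair(ra, rb, weights, sigma_d_um).combined
    rows, cols = linear_sum_assignment(scores, maximize=True)
    mapping = {}
    for i, j in zip(rows, cols):
        if scores[i, j] >= tau:
            mapping[recs_a[i].label] = recs_b[j].label
    unmatched_a = {r.label for r in recs_a} - set(mapping)
    unmatched_b = {r.label for r in recs_b} - set(mapping.values())
    return mapping, unmatched_a, unmatched_b


def build_tracks(
    records_by_day: Mapping[int, Sequence[OrganoidRecord]],
    params: Optional[TrackingParams] = None,
) -> list[Track]:
    """Link per-day records into tracks.

    One track is seeded per reference-day organoid and extended day-by-day
    forward to the last day and backward to the first via adjacent-day
    matching; chains that never touch the reference day become additional
    tracks.  Tracks not observed on the first series day are flagged
    ``APPEARED`` at their first observation; tracks not observed on the
    last day are flagged ``LOST`` at the first day they went missing.
    """
    params = params or TrackingParams()
    days = sorted(records_by_day)
    if len(days) < 2:
        raise ValueError("need at least 2 imaging days")
    ref = select_reference_day(days)
    by_day = {d: sorted(records_by_day[d], key=lambda r: r.label) for d in days}
    rec_index = {
        d: {r.label: r for r in recs} for d, recs in by_day.items()
    }

    forward: dict[int, dict[int, int]] = {}
    for da, db in zip(days[:-1], days[1:]):
        mapping, _, _ = match_day_pair(
            by_day[da], by_day[db], params.weights, params.sigma_d_um, params.tau
        )
        forward[da] = mapping
    backward = {
        db: {v: k for k, v in forward[da].items()}
        for da, db in zip(days[:-1], days[1:])
    }

    def chain_from(day: int, label: int) -> dict[int, int]:
        entries = {day: label}
        d, lab = day, label
        for da, db in zip(days[:-1], days[1:]):
            if da < day:
                continue
            nxt = forward[da].get(lab)
            if nxt is None:
                break
            entries[db] = nxt
            lab = nxt
        d, lab = day, label
        for da, db in zip(reversed(days[:-1]), reversed(days[1:])):
            if db > day:
                continue
            prev = backward[db].get(lab)
            if prev is None:
                break
            entries[da] = prev
            lab = prev
        return entries

    tracks: list[Track] = []
    claimed: set[tuple[int, int]] = set()
    seeds = [(ref, r.label) for r in by_day[ref]]
    for d in days:
        if d == ref:
            continue
        seeds.extend((d, r.label) for r in by_day[d])
    next_id = 1
    for day, label in seeds:
        if (day, label) in claimed:
            continue
        entries = chain_from(day, label)
        if any((d, lab) in claimed for d, lab in entries.items()):
            continue  # already covered by a longer chain through these nodes
        claimed.update(entries.items())
        track = Track(id=next_id)
        next_id += 1
        for d in days:
            track.entries[d] = entries.get(d)
        for d, lab in entries.items():
            track.volumes[d] = rec_index[d][lab].volume
        obs = track.observed_days
        if obs[0] > days[0]:
            track.flags.append(("APPEARED", obs[0]))
        if obs[-1] < days[-1]:
            lost_day = days[days.index(obs[-1]) + 1]
            track.flags.append(("LOST", lost_day))
        tracks.append(track)
    return tracks


def detect_merges(
    tracks: Sequence[Track],
    masks: Mapping[int, LabelMask],
    overlap_fraction: float = 0.5,
) -> list[Track]:
    """Flag organoid fusion events.

    When two or more prior-day labels each overlap at least
    ``overlap_fraction`` of their own voxels with a single current-day
    label, the smaller tracks are flagged ``MERGED_INTO`` the largest
    participant's track at that day.  Tracks are modified in place and
    returned.
    """
    days = sorted(masks)
    track_of = {
        (d, t.entries[d]): t for t in tracks for d in t.entries if t.entries[d]
    }
    for da, db in zip(days[:-1], days[1:]):
        la, lb = masks[da].labels, masks[db].labels
        na = int(la.max(initial=0))
        if na == 0:
            continue
        both = (la > 0) & (lb > 0)
        if not both.any():
            continue
        nb = int(lb.max(initial=0))
        joint = np.bincount(
            (la[both].astype(np.int64) - 1) * nb + (lb[both].astype(np.int64) - 1),
            minlength=na * nb,
        ).reshape(na, nb)
        sizes_a = np.bincount(la.ravel(), minlength=na + 1)[1:]
        frac = joint / np.maximum(sizes_a[:, None], 1)
        for b in range(1, nb + 1):
            donors = [a + 1 for a in range(na) if frac[a, b - 1] >= overlap_fraction]
            if len(donors) < 2:
                continue
            donor_sizes = {a: sizes_a[a - 1] for a in donors}
            survivor_label = max(donors, key=lambda a: (donor_sizes[a], -a))
            survivor_track = track_of.get((da, survivor_label))
            if survivor_track is None:
                continue
            for a in donors:
                if a == survivor_label:
                    continue
                t = track_of.get((da, a))
                if t is not None and t.id != survivor_track.id:
                    flag = ("MERGED_INTO", survivor_track.id, db)
                    if flag not in t.flags:
                        t.flags.append(flag)
    return list(tracks)
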
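"""TIFF volume and CSV table readers/writers.

Volumes travel as single- or multi-page TIFF stacks (pages stacked along
z); tabular outputs (organoid records, tracks, features) are CSV with a
header row and deterministic column order.  Round-trips are lossless for
integer grids and exact to float precision for float grids.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import LabelMask, Modality, Volume3D

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask", "write_table"]


def read_volume(
    path: str | os.PathLike,
    spacing: Sequence[float],
    modality: str = Modality.OCM,
    day: Optional[int] = None,
) -> Volume3D:
    """Read a TIFF stack into a :class:`Volume3D`.

    Pages are stacked along z.  A single-page TIFF becomes a volume with
    z-extent 1.  Raises on missing files, empty stacks, non-uniform page
    shapes and non-scalar (e.g. RGB) samples.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.size == 0:
        raise ValueError(f"empty stack: {path}")
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"expected scalar pages stacked along z, got array of ndim {data.ndim}"
        )
    return Volume3D(data=data, spacing=tuple(spacing), modality=modality, day=day)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> str:
    """Write a :class:`Volume3D` as a multi-page TIFF. Returns the path.

    The volume is validated (finite intensities) before any bytes are
    written, so a failed write never leaves a partial file behind.
    """
    path = os.fspath(path)
    data = np.asarray(vol.data)
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)):
            raise ValueError("refusing to write non-finite intensities")
        data = data.astype(np.float32, copy=False)
    tifffile.imwrite(path, data)
    return path


def write_mask(mask: LabelMask, path: str | os.PathLike) -> str:
    """Write a :class:`LabelMask` as a 16-bit (or 32-bit if needed) TIFF."""
    path = os.fspath(path)
    labels = mask.labels
    dtype = np.uint16 if mask.n_labels < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def read_mask(
    path: str | os.PathLike,
    spacing: Sequence[float],
    day: Optional[int] = None,
) -> LabelMask:
    """Read an integer label TIFF into a :class:`LabelMask`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    labels = tifffile.imread(path)
    if labels.size == 0:
        raise ValueError(f"empty stack: {path}")
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    return LabelMask(labels=labels.astype(np.int32), spacing=tuple(spacing), day=day)


def write_table(records: Sequence[dict], path: str | os.PathLike, columns=None) -> str:
    """Write flat records as CSV with a header row.

    All records must share one field set; the column order is the field
    order of the first record (or ``columns`` when given).  An empty
    sequence yields a header-only CSV when ``columns`` is provided, or an
    entirely empty file otherwise.
    """
    path = os.fspath(path)
    records = [r.to_flat() if hasattr(r, "to_flat") else dict(r) for r in records]
    if records:
        fields = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != fields:
                raise ValueError(
                    f"record {i} has fields {sorted(rec)} != {sorted(fields)}"
                )
        if columns is None:
            columns = fields
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False)
    return path
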
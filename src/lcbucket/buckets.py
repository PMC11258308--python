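"""Fixed three-dimensional bucketing of aligned peak lists.

The core of the whole pipeline: after alignment onto the shared
reference RT axis, each run's peaks are summed into a *fixed* grid of
(RT x m/z) buckets — fixed sizes, fixed origin, fixed ranges — so the
resulting feature vector has an identical schema for every run ever
processed, whichever instrument or batch it came from.  That schema
stability is what replaces cross-sample peak correspondence and lets
training tables grow incrementally.

m/z bucket sizes are adjusted for divisibility: the nominal size is
rounded to the nearest integer number of buckets spanning the block's
m/z range exactly (important for the MS2 isolation windows, whose
detection ranges are not multiples of the nominal sizes).  RT buckets
keep their nominal size; the last bucket may overhang the extent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import stable_hash
from .errors import SchemaMismatchError
from .peaks import ChromPeakList

__all__ = ["BucketGrid", "BucketVector", "make_grid", "bucketize", "schema_hash"]


@dataclass(frozen=True)
class BucketGrid:
    """One block's bucket geometry (use :func:`make_grid` to build)."""

    block: str                    # e.g. "RP-MS1", "RP-MS2"
    ms_level: int
    window_id: Optional[str]      # None for MS1 blocks
    rt_size: float
    mz_size: float                # nominal
    rt_origin: float
    rt_extent: float
    mz_range: tuple[float, float]
    effective_mz_size: float
    n_rt: int
    n_mz: int

    @property
    def key(self) -> tuple[int, Optional[str]]:
        """Peaks are routed to grids by (ms_level, window_id)."""
        return (self.ms_level, self.window_id)

    @property
    def label(self) -> str:
        return self.block if self.window_id is None else f"{self.block}|w={self.window_id}"

    def describe(self) -> dict:
        return {
            "block": self.block,
            "ms_level": self.ms_level,
            "window_id": self.window_id,
            "rt_size": self.rt_size,
            "mz_size": self.mz_size,
            "rt_origin": self.rt_origin,
            "rt_extent": self.rt_extent,
            "mz_range": list(self.mz_range),
            "effective_mz_size": self.effective_mz_size,
            "n_rt": self.n_rt,
            "n_mz": self.n_mz,
        }

    def feature_ids(self) -> list[str]:
        prefix = self.label
        return [f"{prefix}|rt={i:04d}|mz={j:05d}"
                for i in range(self.n_rt) for j in range(self.n_mz)]


def make_grid(
    block: str,
    rt_size: float,
    mz_size: float,
    rt_origin: float,
    rt_extent: float,
    mz_range: tuple[float, float],
    *,
    ms_level: int = 1,
    window_id: Optional[str] = None,
) -> BucketGrid:
    """Build a grid, applying the m/z divisibility adjustment.

    n_mz = round(width / mz_size) clamped to >= 1 and the effective m/z
    size is width / n_mz, so the buckets tile the m/z range exactly.
    n_rt = ceil(rt_extent / rt_size); RT buckets keep the nominal size.
    """
    if rt_size <= 0 or mz_size <= 0:
        raise ValueError("bucket sizes must be positive")
    lo, hi = mz_range
    width = hi - lo
    if width <= 0:
        raise ValueError(f"empty m/z range {mz_range}")
    n_mz = max(1, round(width / mz_size))
    n_rt = max(1, math.ceil((rt_extent - rt_origin) / rt_size))
    return BucketGrid(
        block=block, ms_level=ms_level, window_id=window_id,
        rt_size=float(rt_size), mz_size=float(mz_size),
        rt_origin=float(rt_origin), rt_extent=float(rt_extent),
        mz_range=(float(lo), float(hi)),
        effective_mz_size=width / n_mz, n_rt=n_rt, n_mz=n_mz,
    )


def _canonical(grids: Sequence[BucketGrid]) -> tuple[BucketGrid, ...]:
    return tuple(sorted(grids, key=lambda g: (g.block, g.window_id or "")))


def schema_hash(grids: Sequence[BucketGrid]) -> str:
    """Stable content hash of a grid set (order-independent)."""
    return stable_hash([g.describe() for g in _canonical(grids)])


@dataclass
class BucketVector:
    """One run's intensities on a grid set.

    ``data`` maps each grid's (ms_level, window_id) key to a dense
    (n_rt, n_mz) array; absent buckets are exact zeros.  Peaks falling
    outside their grid are dropped and tallied, so total input intensity
    is always ``total_intensity() + discarded_intensity``.
    """

    grids: tuple[BucketGrid, ...]
    data: dict[tuple[int, Optional[str]], np.ndarray]
    schema_id: str = ""
    discarded_intensity: float = 0.0
    discarded_count: int = 0

    def __post_init__(self):
        self.grids = _canonical(self.grids)
        if not self.schema_id:
            self.schema_id = schema_hash(self.grids)

    def total_intensity(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def feature_ids(self) -> list[str]:
        out = []
        for g in self.grids:
            out.extend(g.feature_ids())
        return out

    def values(self) -> np.ndarray:
        return np.concatenate([self.data[g.key].ravel() for g in self.grids])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values(), index=self.feature_ids())

    def copy(self) -> "BucketVector":
        return BucketVector(
            grids=self.grids,
            data={k: v.copy() for k, v in self.data.items()},
            schema_id=self.schema_id,
            discarded_intensity=self.discarded_intensity,
            discarded_count=self.discarded_count,
        )

    def equals(self, other: "BucketVector") -> bool:
        return (
            self.schema_id == other.schema_id
            and all(np.array_equal(self.data[g.key], other.data[g.key]) for g in self.grids)
        )

    def to_sparse_tsv(self, path, sidecar: bool = True) -> Path:
        """Sparse ``feature_id<TAB>intensity`` export + JSON schema sidecar."""
        path = Path(path)
        s = self.to_series()
        nz = s[s != 0.0]
        with open(path, "w") as fh:
            fh.write("feature_id\tintensity\n")
            for fid, val in nz.items():
                fh.write(f"{fid}\t{val!r}\n")
        if sidecar:
            meta = {
                "schema_id": self.schema_id,
                "grids": [g.describe() for g in self.grids],
                "discarded_intensity": self.discarded_intensity,
                "discarded_count": self.discarded_count,
            }
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
        return path


def bucketize(peaklist: ChromPeakList, grids: Sequence[BucketGrid]) -> BucketVector:
    """Sum a run's peak intensities into the fixed bucket grids.

    Each peak is assigned wholly by its (RT apex, m/z) point with
    half-open bucket intervals [low, high); the top m/z bucket is closed
    at the range's upper edge.  Peaks whose (ms_level, window_id) has a
    grid but fall outside it are dropped and tallied; peaks whose key has
    *no* grid raise :class:`SchemaMismatchError` unless the grid set
    contains no grid of that MS level at all (then they are ignored, so
    an MS1-only schema can consume a run acquired with MS2 scans).
    """
    grids = _canonical(grids)
    by_key: dict[tuple[int, Optional[str]], BucketGrid] = {}
    for g in grids:
        if g.key in by_key:
            raise SchemaMismatchError(f"duplicate grid for {g.key}")
        by_key[g.key] = g
    levels_present = {g.ms_level for g in grids}
    data = {g.key: np.zeros((g.n_rt, g.n_mz)) for g in grids}
    discarded = 0.0
    n_disc = 0
    for p in peaklist.peaks:
        key = (p.ms_level, p.window_id)
        grid = by_key.get(key)
        if grid is None:
            if p.ms_level not in levels_present:
                continue
            raise SchemaMismatchError(
                f"peak with ms_level={p.ms_level} window={p.window_id!r} has no grid"
            )
        lo, hi = grid.mz_range
        if p.rt < grid.rt_origin or p.mz < lo or p.mz > hi:
            discarded += p.intensity
            n_disc += 1
            continue
        ri = int(math.floor((p.rt - grid.rt_origin) / grid.rt_size))
        if ri >= grid.n_rt:
            discarded += p.intensity
            n_disc += 1
            continue
        if p.mz == hi:
            mi = grid.n_mz - 1
        else:
            mi = min(int(math.floor((p.mz - lo) / grid.effective_mz_size)), grid.n_mz - 1)
        data[key][ri, mi] += p.intensity
    return BucketVector(grids=grids, data=data,
                        discarded_intensity=discarded, discarded_count=n_disc)
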
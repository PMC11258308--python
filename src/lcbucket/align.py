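"""Reference-anchored retention-time alignment.

Every run is warped pairwise onto one fixed central reference run by
dynamic programming over a similarity matrix of m/z-binned scan profiles
(the obiwarp idea, re-implemented in simplified form): MS1 scans are
binned at ``bin_size`` Da over the MS1 range, every (sample scan,
reference scan) pair is scored by Pearson correlation (or covariance) of
its bin vectors, and an affine-gap alignment of the two scan sequences
yields matched scan pairs through which a monotone piecewise-linear warp
is interpolated.  "Local" mode leaves unaligned prefixes/suffixes
unpenalized (free end gaps); global mode charges them like any gap.

Because alignment is strictly pairwise against a persisted reference, a
run aligned alone is warped identically to the same run aligned within
any batch — the property that lets batches be processed separately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import AlignmentError
from .io import AcquisitionScheme, Run
from .peaks import ChromPeak, ChromPeakList

__all__ = [
    "AlignmentParams",
    "ReferenceProfile",
    "WarpFunction",
    "select_center",
    "build_reference",
    "align_run",
    "warp_peaklist",
]


@dataclass(frozen=True)
class AlignmentParams:
    """bin_size in Da; gap penalties are on the similarity scale
    (defaults follow obiwarp's published values for correlation
    similarity: open 0.3, extend 2.4)."""

    bin_size: float = 0.1
    local: bool = True
    gap_open: float = 0.3
    gap_extend: float = 2.4
    similarity: str = "correlation"  # or "covariance"

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.similarity not in ("correlation", "covariance"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


def _bin_profile(run: Run, bin_size: float, ms1_range: tuple[float, float]):
    """MS1 scans binned to a (n_scans, n_bins) intensity matrix."""
    lo, hi = ms1_range
    n_bins = int(round((hi - lo) / bin_size))
    scans = run.ms1_scans()
    rts = np.array([s.rt for s in scans])
    mat = np.zeros((len(scans), n_bins))
    for i, scan in enumerate(scans):
        idx = np.floor((scan.mz - lo) / bin_size).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(mat[i], idx[ok], scan.intensity[ok])
    return rts, mat


@dataclass
class ReferenceProfile:
    """The frozen central spectrum: binned MS1 profile + content hash.

    All future alignments must run against a byte-identical reference;
    the hash travels with every downstream artifact so incompatible
    feature tables can never be merged silently.
    """

    run_id: str
    rts: np.ndarray
    matrix: np.ndarray
    bin_size: float
    ms1_range: tuple[float, float]
    hash: str = ""

    def __post_init__(self):
        if not self.hash:
            h = hashlib.sha256()
            h.update(self.run_id.encode())
            h.update(np.float64(self.bin_size).tobytes())
            h.update(np.asarray(self.ms1_range, dtype=float).tobytes())
            h.update(np.ascontiguousarray(self.rts, dtype=float).tobytes())
            h.update(np.ascontiguousarray(self.matrix, dtype=float).tobytes())
            self.hash = h.hexdigest()

    def save(self, path) -> Path:
        """Persist as <path>.npz plus a JSON sidecar <path>.json."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), rts=self.rts, matrix=self.matrix)
        sidecar = {
            "run_id": self.run_id,
            "bin_size": self.bin_size,
            "ms1_range": list(self.ms1_range),
            "hash": self.hash,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "ReferenceProfile":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        ref = cls(run_id=meta["run_id"], rts=data["rts"], matrix=data["matrix"],
                  bin_size=meta["bin_size"], ms1_range=tuple(meta["ms1_range"]))
        if ref.hash != meta["hash"]:
            raise AlignmentError(f"reference artifact {path} is corrupt (hash mismatch)")
        return ref


@dataclass
class WarpFunction:
    """Monotone piecewise-linear map sample RT -> reference RT."""

    sample_rt: np.ndarray
    reference_rt: np.ndarray

    def __post_init__(self):
        self.sample_rt = np.asarray(self.sample_rt, dtype=float)
        self.reference_rt = np.asarray(self.reference_rt, dtype=float)
        if self.sample_rt.size < 2:
            raise AlignmentError("warp needs at least two matched scan pairs")
        if np.any(np.diff(self.sample_rt) <= 0) or np.any(np.diff(self.reference_rt) < 0):
            raise AlignmentError("warp knots are not monotone")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xs, ys = self.sample_rt, self.reference_rt
        y = np.interp(x, xs, ys)
        # linear extrapolation with the terminal segment slopes
        s0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
        s1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        y = np.where(x < xs[0], ys[0] + (x - xs[0]) * s0, y)
        y = np.where(x > xs[-1], ys[-1] + (x - xs[-1]) * s1, y)
        return y if y.ndim else float(y)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("sample_rt\treference_rt\n")
            for a, b in zip(self.sample_rt, self.reference_rt):
                fh.write(f"{a:.6f}\t{b:.6f}\n")
        return path


def select_center(peaklists: list[ChromPeakList]) -> str:
    """run_id of the peak list with the most MS1 peaks (ties: smallest id)."""
    if not peaklists:
        raise ValueError("no peak lists given")
    return min(peaklists, key=lambda pl: (-pl.ms1_count(), pl.run_id)).run_id


def build_reference(run: Run, params: AlignmentParams | None = None) -> ReferenceProfile:
    params = params or AlignmentParams()
    rts, mat = _bin_profile(run, params.bin_size, run.scheme.ms1_range)
    return ReferenceProfile(run_id=run.run_id, rts=rts, matrix=mat,
                            bin_size=params.bin_size, ms1_range=run.scheme.ms1_range)


def _similarity_matrix(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    """Row-by-row similarity of two (scans x bins) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    if mode == "correlation":
        an = np.linalg.norm(ac, axis=1, keepdims=True)
        bn = np.linalg.norm(bc, axis=1, keepdims=True)
        ac = np.divide(ac, an, out=np.zeros_like(ac), where=an > 0)
        bc = np.divide(bc, bn, out=np.zeros_like(bc), where=bn > 0)
        return ac @ bc.T
    return (ac @ bc.T) / max(a.shape[1] - 1, 1)


def _dp_align(S, gap_open, gap_extend, local):  # pragma: no cover - jitted
    """Affine-gap DP over the similarity matrix; returns matched pairs.

    States: M (diagonal match), Ix (gap in reference: sample scan
    skipped), Iy (gap in sample).  Local mode makes leading and trailing
    gaps free and ends at the best last-row/last-column M cell.
    """
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag-M 1 diag-Ix 2 diag-Iy 3 start
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 from M, 1 from Ix
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        if local:
            M[i, 0] = 0.0
        else:
            Ix[i, 0] = -gap_open - gap_extend * (i - 1)
            ptr_x[i, 0] = 1
    for j in range(1, m + 1):
        if local:
            M[0, j] = 0.0
        else:
            Iy[0, j] = -gap_open - gap_extend * (j - 1)
            ptr_y[0, j] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = S[i - 1, j - 1] + best
            ptr_m[i, j] = p
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            if a >= b:
                Ix[i, j] = a
                ptr_x[i, j] = 0
            else:
                Ix[i, j] = b
                ptr_x[i, j] = 1
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            if a >= b:
                Iy[i, j] = a
                ptr_y[i, j] = 0
            else:
                Iy[i, j] = b
                ptr_y[i, j] = 1
    # end point
    if local:
        ei, ej, best = n, m, M[n, m]
        for i in range(1, n + 1):
            if M[i, m] > best:
                best = M[i, m]
                ei, ej = i, m
        for j in range(1, m + 1):
            if M[n, j] > best:
                best = M[n, j]
                ei, ej = n, j
        state = 0
    else:
        ei, ej = n, m
        vals = (M[n, m], Ix[n, m], Iy[n, m])
        state = 0
        best = vals[0]
        if vals[1] > best:
            state, best = 1, vals[1]
        if vals[2] > best:
            state, best = 2, vals[2]
    pairs_i = []
    pairs_j = []
    i, j, st = ei, ej, state
    while i > 0 and j > 0:
        if st == 0:
            pairs_i.append(i - 1)
            pairs_j.append(j - 1)
            p = ptr_m[i, j]
            i -= 1
            j -= 1
            if local and p == 0 and (M[i, j] == 0.0) and (i == 0 or j == 0):
                break
            st = p
        elif st == 1:
            p = ptr_x[i, j]
            i -= 1
            st = 0 if p == 0 else 1
        else:
            p = ptr_y[i, j]
            j -= 1
            st = 0 if p == 0 else 2
    pairs_i.reverse()
    pairs_j.reverse()
    return pairs_i, pairs_j, best


try:  # JIT the quadratic DP when numba is present; fall back silently
    from numba import njit as _njit

    _dp_align_fast = _njit(cache=True)(_dp_align)
except Exception:  # pragma: no cover
    _dp_align_fast = _dp_align


def align_run(
    run: Run,
    ref: ReferenceProfile,
    params: AlignmentParams | None = None,
) -> tuple[Run, WarpFunction]:
    """Warp a run onto the reference RT axis.

    Returns the warped run (all scans, MS1 and MS2, mapped through the
    MS1-derived warp) and the warp itself.  Raises
    :class:`AlignmentError` when the similarity signal is degenerate.
    """
    params = params or AlignmentParams()
    if tuple(run.scheme.ms1_range) != tuple(ref.ms1_range):
        raise AlignmentError(
            f"run {run.run_id}: MS1 range {run.scheme.ms1_range} differs from "
            f"reference range {ref.ms1_range}"
        )
    rts, mat = _bin_profile(run, params.bin_size, ref.ms1_range)
    if mat.shape[0] < 2:
        raise AlignmentError(f"run {run.run_id}: fewer than two MS1 scans")
    S = _similarity_matrix(mat, ref.matrix, params.similarity)
    if not np.isfinite(S).all() or S.max() <= 0.05:
        raise AlignmentError(
            f"run {run.run_id}: no scan pair with usable similarity to "
            f"reference {ref.run_id}; alignment failed"
        )
    pi, pj, _score = _dp_align_fast(
        np.ascontiguousarray(S), params.gap_open, params.gap_extend, params.local
    )
    pi = np.asarray(pi, dtype=int)
    pj = np.asarray(pj, dtype=int)
    if pi.size < 2:
        raise AlignmentError(f"run {run.run_id}: degenerate alignment path")
    warp = WarpFunction(sample_rt=rts[pi], reference_rt=ref.rts[pj])
    new_rts = warp([s.rt for s in run.scans])
    # warping is monotone, so scan order is preserved
    warped = run.with_scan_rts(new_rts)
    return warped, warp


def warp_peaklist(pl: ChromPeakList, warp: WarpFunction) -> ChromPeakList:
    """Map every peak's RT fields through the warp."""
    peaks = [
        ChromPeak(mz=p.mz, rt=float(warp(p.rt)), rt_min=float(warp(p.rt_min)),
                  rt_max=float(warp(p.rt_max)), intensity=p.intensity,
                  ms_level=p.ms_level, window_id=p.window_id)
        for p in pl.peaks
    ]
    return ChromPeakList(run_id=pl.run_id, params=pl.params, peaks=peaks)
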
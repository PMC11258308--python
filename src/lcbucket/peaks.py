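"""Chromatographic peak detection on centroided scans.

A region-of-interest (ROI) detector in the centWave family: centroids in
consecutive scans whose m/z stays within a ppm tolerance of the chain's
running intensity-weighted mean are collected into ROIs, and each ROI is
split at local minima into candidate peaks that must pass a width window
around the expected chromatographic peak width and a signal-to-baseline
threshold.  The continuous-wavelet refinement stage of full centWave is
deliberately omitted: downstream bucketing consumes only (m/z, RT apex,
intensity), which this detector already pins down on centroided data.

When per-scan m/z noise is an appreciable fraction of the ppm tolerance,
single outlier centroids can fracture a chain into fragments.  A repair
pass therefore merges finished ROIs lying within twice the ppm tolerance
of each other — fragments of one compound by construction, since
resolvable compounds are many tolerances apart in m/z, while co-eluting
isomers merged this way are still separated afterwards by the
local-minimum peak split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import Run

__all__ = ["PeakDetectionParams", "ChromPeak", "ChromPeakList", "detect_peaks"]


@dataclass(frozen=True)
class PeakDetectionParams:
    """Detection tuning.

    peakwidth
        Expected chromatographic peak width (FWHM, seconds).  Candidate
        peaks are accepted when their measured FWHM lies in
        [0.5*peakwidth, 2*peakwidth].
    ppm
        m/z consistency tolerance for chaining centroids into an ROI.
    min_scans
        Minimum ROI length, in scans.
    snr_threshold
        Minimal apex-to-local-baseline ratio.
    intensity
        "area": trapezoidal integral over the peak (default);
        "apex": apex height.
    """

    peakwidth: float = 15.0
    ppm: float = 5.0
    min_scans: int = 5
    snr_threshold: float = 3.0
    intensity: str = "area"
    max_gap: int = 1  # scans an ROI may skip before being closed

    def __post_init__(self):
        if self.peakwidth <= 0 or self.ppm <= 0:
            raise ValueError("peakwidth and ppm must be positive")
        if self.min_scans < 3:
            raise ValueError("min_scans must be >= 3")
        if self.intensity not in ("area", "apex"):
            raise ValueError(f"unknown intensity mode {self.intensity!r}")


@dataclass(frozen=True)
class ChromPeak:
    """One detected chromatographic peak."""

    mz: float       # intensity-weighted mean of member centroids
    rt: float       # apex scan RT, seconds
    rt_min: float
    rt_max: float
    intensity: float
    ms_level: int = 1
    window_id: Optional[str] = None


@dataclass
class ChromPeakList:
    """Detected peaks for one run, sorted (ms_level, window, rt, mz)."""

    run_id: str
    params: PeakDetectionParams
    peaks: list[ChromPeak] = field(default_factory=list)

    def __len__(self):
        return len(self.peaks)

    def ms1_count(self) -> int:
        return sum(1 for p in self.peaks if p.ms_level == 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"run_id": self.run_id, "ms_level": p.ms_level,
              "window_id": p.window_id or "", "mz": p.mz, "rt": p.rt,
              "rt_min": p.rt_min, "rt_max": p.rt_max, "intensity": p.intensity}
             for p in self.peaks],
            columns=["run_id", "ms_level", "window_id", "mz", "rt",
                     "rt_min", "rt_max", "intensity"],
        )

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path


class _ROI:
    __slots__ = ("rts", "mzs", "ints", "weighted_mz_sum", "int_sum", "last_scan")

    def __init__(self, rt, mz, inten, scan_idx):
        self.rts = [rt]
        self.mzs = [mz]
        self.ints = [inten]
        self.weighted_mz_sum = mz * max(inten, 1e-12)
        self.int_sum = max(inten, 1e-12)
        self.last_scan = scan_idx

    @property
    def mean_mz(self):
        return self.weighted_mz_sum / self.int_sum

    def add(self, rt, mz, inten, scan_idx):
        self.rts.append(rt)
        self.mzs.append(mz)
        self.ints.append(inten)
        w = max(inten, 1e-12)
        self.weighted_mz_sum += mz * w
        self.int_sum += w
        self.last_scan = scan_idx


def _merge_two(a: _ROI, b: _ROI) -> _ROI:
    rts = a.rts + b.rts
    mzs = a.mzs + b.mzs
    ints = a.ints + b.ints
    order = np.argsort(rts, kind="stable")
    merged = None
    for k in order:
        if merged is None:
            merged = _ROI(rts[k], mzs[k], ints[k], 0)
        elif rts[k] == merged.rts[-1]:
            # same scan contributed to both fragments: combine the centroids
            w_old = max(merged.ints[-1], 1e-12)
            w_new = max(ints[k], 1e-12)
            merged.mzs[-1] = (merged.mzs[-1] * w_old + mzs[k] * w_new) / (w_old + w_new)
            merged.ints[-1] += ints[k]
            merged.weighted_mz_sum += mzs[k] * w_new
            merged.int_sum += w_new
        else:
            merged.add(rts[k], mzs[k], ints[k], 0)
    return merged


def _repair_chains(rois: list[_ROI], ppm: float) -> list[_ROI]:
    """Merge ROI fragments of one compound (centers within 2x ppm)."""
    if len(rois) < 2:
        return rois
    rois = sorted(rois, key=lambda r: r.mean_mz)
    out = [rois[0]]
    for nxt in rois[1:]:
        cur = out[-1]
        if nxt.mean_mz - cur.mean_mz <= 2.0 * ppm * 1e-6 * cur.mean_mz:
            out[-1] = _merge_two(cur, nxt)
        else:
            out.append(nxt)
    return out


def _fwhm(rts: np.ndarray, ints: np.ndarray, apex: int, lo: int, hi: int) -> float:
    """Full width at half maximum by linear interpolation within [lo, hi]."""
    half = ints[apex] / 2.0
    left = rts[lo]
    for i in range(apex, lo, -1):
        if ints[i - 1] < half <= ints[i]:
            frac = (half - ints[i - 1]) / (ints[i] - ints[i - 1])
            left = rts[i - 1] + frac * (rts[i] - rts[i - 1])
            break
    right = rts[hi]
    for i in range(apex, hi):
        if ints[i + 1] < half <= ints[i]:
            frac = (ints[i] - half) / (ints[i] - ints[i + 1])
            right = rts[i] + frac * (rts[i + 1] - rts[i])
            break
    return right - left


def _roi_peaks(roi: _ROI, params: PeakDetectionParams, ms_level: int,
               window_id: Optional[str]) -> list[ChromPeak]:
    rts = np.asarray(roi.rts)
    ints = np.asarray(roi.ints)
    mzs = np.asarray(roi.mzs)
    n = len(rts)
    if n < params.min_scans:
        return []
    # local maxima (boundary scans qualify), then split at minima between
    maxima = [i for i in range(n)
              if (i == 0 or ints[i] >= ints[i - 1])
              and (i == n - 1 or ints[i] > ints[i + 1])]
    if not maxima:
        return []
    bounds = [0]
    for a, b in zip(maxima, maxima[1:]):
        bounds.append(a + int(np.argmin(ints[a:b + 1])))
    bounds.append(n - 1)

    out = []
    for k, apex in enumerate(maxima):
        lo, hi = bounds[k], bounds[k + 1]
        if hi - lo + 1 < params.min_scans:
            continue
        width = _fwhm(rts, ints, apex, lo, hi)
        if not (0.5 * params.peakwidth <= width <= 2.0 * params.peakwidth):
            continue
        baseline = max(min(ints[lo], ints[hi]), 1e-12)
        if ints[apex] / baseline < params.snr_threshold:
            continue
        seg = slice(lo, hi + 1)
        w = np.maximum(ints[seg], 1e-12)
        mz = float(np.sum(mzs[seg] * w) / np.sum(w))
        if params.intensity == "area":
            value = float(np.trapezoid(ints[seg], rts[seg]))
        else:
            value = float(ints[apex])
        out.append(ChromPeak(mz=mz, rt=float(rts[apex]), rt_min=float(rts[lo]),
                             rt_max=float(rts[hi]), intensity=value,
                             ms_level=ms_level, window_id=window_id))
    return out


def detect_peaks(run: Run, params: PeakDetectionParams | None = None) -> ChromPeakList:
    """Detect chromatographic peaks, separately per MS level and window.

    A run shorter than ``min_scans`` scans yields an empty list with a
    warning rather than an error.
    """
    params = params or PeakDetectionParams()
    groups: dict[tuple[int, Optional[str]], list] = {}
    for scan in run.scans:
        groups.setdefault((scan.ms_level, scan.window_id), []).append(scan)

    peaks: list[ChromPeak] = []
    tol = params.ppm * 1e-6
    for (ms_level, window_id), scans in groups.items():
        if len(scans) < params.min_scans:
            warnings.warn(
                f"run {run.run_id}: only {len(scans)} scans for ms_level="
                f"{ms_level} window={window_id}; no peaks detected"
            )
            continue
        active: list[_ROI] = []
        closed: list[_ROI] = []
        for s_idx, scan in enumerate(scans):
            still_active = []
            for roi in active:
                if s_idx - roi.last_scan > params.max_gap + 1:
                    closed.append(roi)
                else:
                    still_active.append(roi)
            active = still_active
            taken = set()
            for mz, inten in zip(scan.mz, scan.intensity):
                best, best_d = None, None
                for ri, roi in enumerate(active):
                    if ri in taken or roi.last_scan == s_idx:
                        continue
                    d = abs(mz - roi.mean_mz)
                    if d <= tol * roi.mean_mz and (best_d is None or d < best_d):
                        best, best_d = ri, d
                if best is not None:
                    active[best].add(scan.rt, mz, inten, s_idx)
                    taken.add(best)
                else:
                    active.append(_ROI(scan.rt, mz, inten, s_idx))
        closed.extend(active)
        closed = _repair_chains(closed, params.ppm)
        for roi in closed:
            peaks.extend(_roi_peaks(roi, params, ms_level, window_id))

    peaks.sort(key=lambda p: (p.ms_level, p.window_id or "", p.rt, p.mz))
    return ChromPeakList(run_id=run.run_id, params=params, peaks=peaks)
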
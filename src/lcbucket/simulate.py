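"""Synthetic LC-HRMS run generator.

Emulates the features of real multi-instrument fingerprint data that the
downstream pipeline must cope with: class-specific marker compounds on a
shared background, per-instrument monotone retention-time distortion,
ppm-scale m/z jitter, log-normal intensity noise, and (optionally) the
vDIA isolation-window structure for fragment scans.

It deliberately does *not* model isotope patterns, adducts or chemical
noise floors — those do not change what the bucketing computations see.

Every run draws from an RNG seeded by a splitmix-mixed (seed, run index)
pair, so datasets are bit-reproducible and runs are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._util import splitmix64
from .errors import ConfigError
from .io import AcquisitionScheme, CentroidScan, IsolationWindow, Run, MANIFEST_COLUMNS

__all__ = [
    "RTDistortion",
    "CompoundSpec",
    "SimConfig",
    "SYNTH_MS1_SCHEME",
    "SYNTH_DIA_SCHEME",
    "simulate_run",
    "simulate_dataset",
    "make_compound_library",
    "example_config",
]

#: MS1-only scheme for synthetic experiments; compounds are drawn from a
#: narrow mass band so a 100-600 Da full scan covers them.
SYNTH_MS1_SCHEME = AcquisitionScheme(ms1_range=(100.0, 600.0))

#: Synthetic two-window vDIA scheme for fragment-handling tests.
SYNTH_DIA_SCHEME = AcquisitionScheme(
    ms1_range=(100.0, 600.0),
    windows=(
        IsolationWindow("w0225", 225.0, (50.0, 330.0)),
        IsolationWindow("w0475", 475.0, (50.0, 650.0)),
    ),
)


@dataclass(frozen=True)
class RTDistortion:
    """Monotone RT distortion rt' = a*rt + b + c*sin(2*pi*rt/p).

    The affine part models column ageing / flow differences between
    instruments; the smooth sinusoid models slow within-run drift.
    Monotonicity requires a > 2*pi*c/p.
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    p: float = 300.0
    max_shift: float = 60.0

    def __post_init__(self):
        if self.c and self.a <= 2.0 * math.pi * abs(self.c) / self.p:
            raise ConfigError(
                f"RT distortion not monotone: a={self.a} <= 2*pi*c/p="
                f"{2.0 * math.pi * abs(self.c) / self.p:.4f}"
            )

    def warp(self, rt):
        rt = np.asarray(rt, dtype=float)
        out = self.a * rt + self.b
        if self.c:
            out = out + self.c * np.sin(2.0 * np.pi * rt / self.p)
        return out


@dataclass(frozen=True)
class CompoundSpec:
    """A simulated compound: apex position, abundance and MS2 fragments.

    ``fragments`` is a tuple of (fragment m/z, relative intensity
    fraction) pairs emitted into the isolation window covering ``mz``.
    """

    mz: float
    rt: float
    mean_log_intensity: float = math.log(1e5)
    fragments: tuple[tuple[float, float], ...] = ()


@dataclass
class SimConfig:
    """Declarative description of a synthetic dataset.

    ``classes`` maps class label -> marker compounds; ``background``
    compounds appear in every run.  In the default "exclusive" marker
    mode a marker occurs only in runs of its own class; in "soft" mode it
    occurs everywhere and is ``soft_log_fold`` log-units more abundant in
    its own class (a harder, fold-change-based problem).
    """

    classes: dict[str, list[CompoundSpec]]
    background: list[CompoundSpec] = field(default_factory=list)
    n_samples_per_class: int = 30
    instruments: dict[str, RTDistortion] = field(
        default_factory=lambda: {"instA": RTDistortion(b=-10.0), "instB": RTDistortion(b=+10.0)}
    )
    mz_jitter_ppm: float = 3.0
    intensity_sigma: float = 0.3
    peak_sigma: float = 5.0  # chromatographic Gaussian sd, seconds
    scan_interval: float = 1.0  # seconds between MS1 scans
    rt_extent: float = 300.0  # run length, seconds
    scheme: AcquisitionScheme = field(default_factory=lambda: SYNTH_MS1_SCHEME)
    seed: int = 0
    method: str = "RP"
    polarity: str = "positive"
    marker_mode: str = "exclusive"  # or "soft"
    soft_log_fold: float = math.log(3.0)

    def validate(self):
        if self.n_samples_per_class < 1:
            raise ConfigError("n_samples_per_class must be >= 1")
        if self.marker_mode not in ("exclusive", "soft"):
            raise ConfigError(f"unknown marker_mode {self.marker_mode!r}")
        if not self.instruments:
            raise ConfigError("at least one instrument required")
        lo, hi = self.scheme.ms1_range
        for comp in self.all_compounds():
            if not lo <= comp.mz <= hi:
                raise ConfigError(f"compound m/z {comp.mz} outside MS1 range {self.scheme.ms1_range}")
            if comp.fragments and self.scheme.windows:
                win = self.scheme.window_for_precursor_mz(comp.mz)
                for fmz, frac in comp.fragments:
                    if not win.detect_range[0] <= fmz <= win.detect_range[1]:
                        raise ConfigError(
                            f"fragment {fmz} Da outside detect range of window {win.window_id}"
                        )
                    if not 0.0 <= frac <= 1.0:
                        raise ConfigError("fragment fraction outside [0, 1]")

    def all_compounds(self):
        out = list(self.background)
        for comps in self.classes.values():
            out.extend(comps)
        return out


def _compounds_for(cfg: SimConfig, class_label: str) -> list[tuple[CompoundSpec, float]]:
    """(compound, mean log intensity) pairs present in a run of a class.

    Iteration order is fixed (background, then classes sorted by label)
    so RNG draws are reproducible.
    """
    present: list[tuple[CompoundSpec, float]] = [(c, c.mean_log_intensity) for c in cfg.background]
    for label in sorted(cfg.classes):
        for comp in cfg.classes[label]:
            if cfg.marker_mode == "exclusive":
                if label == class_label:
                    present.append((comp, comp.mean_log_intensity))
            else:  # soft: present everywhere, boosted in its own class
                boost = cfg.soft_log_fold if label == class_label else 0.0
                present.append((comp, comp.mean_log_intensity + boost))
    return present


def _merge_centroids(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort centroids by m/z, summing any that collide within 1e-9 Da."""
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size > 1:
        keep = np.concatenate(([True], np.diff(mz) > 1e-9))
        if not keep.all():
            idx = np.cumsum(keep) - 1
            summed = np.zeros(keep.sum())
            np.add.at(summed, idx, inten)
            mz, inten = mz[keep], summed
    return mz, inten


def simulate_run(
    cfg: SimConfig,
    class_label: str,
    instrument_id: str,
    run_index: int,
    *,
    sample_id: Optional[str] = None,
    run_id: Optional[str] = None,
) -> Run:
    """Simulate one LC-MS run of a given class on a given instrument.

    Each present compound produces a Gaussian chromatographic peak
    (sd ``peak_sigma``, truncated at ±4 sd) centred at the
    instrument-distorted apex, one centroid per scan with independent
    per-scan m/z jitter.  Fragment centroids go to the MS2 scans of the
    window covering the precursor, scaled by their intensity fraction.
    """
    cfg.validate()
    if instrument_id not in cfg.instruments:
        raise ConfigError(f"unknown instrument {instrument_id!r}")
    distortion = cfg.instruments[instrument_id]
    rng = np.random.default_rng(splitmix64(cfg.seed, run_index))

    n_scans = int(math.floor(cfg.rt_extent / cfg.scan_interval)) + 1
    ms1_times = np.arange(n_scans) * cfg.scan_interval
    windows = cfg.scheme.windows
    # Interleave MS2 scans between consecutive MS1 scans, one per window
    # per cycle, offset by equal fractions of the scan interval.
    ms2_times = {
        w.window_id: ms1_times + (k + 1) * cfg.scan_interval / (len(windows) + 1)
        for k, w in enumerate(windows)
    }

    ms1_acc: list[list] = [[] for _ in range(n_scans)]
    ms2_acc: dict[str, list[list]] = {wid: [[] for _ in range(n_scans)] for wid in ms2_times}

    for comp, mli in _compounds_for(cfg, class_label):
        apex_rt = float(distortion.warp(comp.rt))
        amp = math.exp(mli + rng.normal(0.0, cfg.intensity_sigma))
        lo = apex_rt - 4.0 * cfg.peak_sigma
        hi = apex_rt + 4.0 * cfg.peak_sigma
        i0 = max(0, int(math.ceil(lo / cfg.scan_interval)))
        i1 = min(n_scans - 1, int(math.floor(hi / cfg.scan_interval)))
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        t = ms1_times[idx]
        profile = amp * np.exp(-0.5 * ((t - apex_rt) / cfg.peak_sigma) ** 2)
        eps = rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, size=idx.size)
        mzs = comp.mz * (1.0 + eps)
        for j, scan_i in enumerate(idx):
            ms1_acc[scan_i].append((mzs[j], profile[j]))
        if comp.fragments and windows:
            win = cfg.scheme.window_for_precursor_mz(comp.mz)
            times2 = ms2_times[win.window_id]
            t2 = times2[idx]
            prof2 = amp * np.exp(-0.5 * ((t2 - apex_rt) / cfg.peak_sigma) ** 2)
            for fmz, frac in comp.fragments:
                eps2 = rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, size=idx.size)
                fmzs = fmz * (1.0 + eps2)
                for j, scan_i in enumerate(idx):
                    ms2_acc[win.window_id][scan_i].append((fmzs[j], frac * prof2[j]))

    scans: list[CentroidScan] = []
    for i in range(n_scans):
        if ms1_acc[i]:
            mz = np.array([c[0] for c in ms1_acc[i]])
            inten = np.array([c[1] for c in ms1_acc[i]])
            mz, inten = _merge_centroids(mz, inten)
            scans.append(CentroidScan(rt=float(ms1_times[i]), ms_level=1, mz=mz, intensity=inten))
        for wid in ms2_acc:
            if ms2_acc[wid][i]:
                mz = np.array([c[0] for c in ms2_acc[wid][i]])
                inten = np.array([c[1] for c in ms2_acc[wid][i]])
                mz, inten = _merge_centroids(mz, inten)
                scans.append(
                    CentroidScan(rt=float(ms2_times[wid][i]), ms_level=2,
                                 mz=mz, intensity=inten, window_id=wid)
                )
    if not scans:
        raise ConfigError("simulation produced no scans (no compound within the run)")
    scans.sort(key=lambda s: s.rt)
    return Run(
        run_id=run_id or f"run{run_index:04d}",
        sample_id=sample_id or f"S{run_index:04d}",
        class_label=class_label,
        method=cfg.method,
        polarity=cfg.polarity,
        instrument_id=instrument_id,
        scans=scans,
        scheme=cfg.scheme,
    )


def simulate_dataset(cfg: SimConfig) -> tuple[list[Run], pd.DataFrame]:
    """Simulate n_samples_per_class runs per class plus a manifest.

    Instruments are assigned round-robin over the global sample counter,
    so each instrument measures an approximately equal share of every
    class — mirroring a lab splitting samples across machines.
    """
    cfg.validate()
    instruments = sorted(cfg.instruments)
    runs: list[Run] = []
    rows = []
    counter = 0
    for label in sorted(cfg.classes):
        for _ in range(cfg.n_samples_per_class):
            inst = instruments[counter % len(instruments)]
            run = simulate_run(cfg, label, inst, counter)
            runs.append(run)
            rows.append({
                "path": f"{run.run_id}.mzML",
                "sample_id": run.sample_id,
                "class_label": label,
                "method": cfg.method,
                "instrument_id": inst,
                "batch": "sim",
            })
            counter += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return runs, manifest


def make_compound_library(
    seed: int,
    *,
    n_classes: int = 3,
    markers_per_class: int = 5,
    n_background: int = 20,
    mz_range: tuple[float, float] = (110.0, 590.0),
    rt_range: tuple[float, float] = (30.0, 270.0),
    mean_log_intensity: float = math.log(1e5),
    min_mz_spacing: float = 0.5,
    class_labels: Optional[list[str]] = None,
) -> tuple[dict[str, list[CompoundSpec]], list[CompoundSpec]]:
    """Draw a reproducible compound library (markers + shared background).

    m/z positions are rejection-sampled to stay >= ``min_mz_spacing`` Da
    apart so distinct compounds can never fall inside one another's ppm
    tolerance during peak detection.
    """
    rng = np.random.default_rng(splitmix64(seed, 0xC0FFEE))
    labels = class_labels or [f"class{chr(ord('A') + i)}" for i in range(n_classes)]
    n_total = n_background + n_classes * markers_per_class
    mzs: list[float] = []
    while len(mzs) < n_total:
        cand = float(rng.uniform(*mz_range))
        if all(abs(cand - m) >= min_mz_spacing for m in mzs):
            mzs.append(cand)
    rts = rng.uniform(*rt_range, size=n_total)
    logi = mean_log_intensity + rng.normal(0.0, 0.4, size=n_total)
    comps = [CompoundSpec(mz=mzs[i], rt=float(rts[i]), mean_log_intensity=float(logi[i]))
             for i in range(n_total)]
    background = comps[:n_background]
    classes = {
        label: comps[n_background + i * markers_per_class:
                     n_background + (i + 1) * markers_per_class]
        for i, label in enumerate(labels)
    }
    return classes, background


def example_config(seed: int = 0, **overrides) -> SimConfig:
    """The reference synthetic study: 3 classes x 30 samples, 2 instruments
    offset by -10/+10 s, 5 exclusive markers per class over 20 shared
    background compounds, 3 ppm m/z jitter, 0.3 log-intensity sd."""
    lib_kwargs = {}
    for key in ("n_classes", "markers_per_class", "n_background", "mz_range",
                "rt_range", "class_labels"):
        if key in overrides:
            lib_kwargs[key] = overrides.pop(key)
    classes, background = make_compound_library(seed, **lib_kwargs)
    cfg = SimConfig(classes=classes, background=background, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
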
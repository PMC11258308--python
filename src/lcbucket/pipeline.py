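"""End-to-end composition: detect -> align -> bucketize -> normalize -> fuse.

Two entry points matter:

* :func:`process_batch` — process a training batch: detect peaks in all
  runs, elect the center run (most MS1 peaks) unless a reference is
  supplied, align every run against it, bucketize on the fixed grids and
  stack the normalized, fused vectors into a :class:`FeatureTable`.

* :func:`process_single` — process one new run against the *persisted*
  reference and schema only.  By construction this yields exactly the
  vector the run would get inside any batch, which is what makes
  routine one-sample-at-a-time classification possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .align import (AlignmentParams, ReferenceProfile, WarpFunction,
                    align_run, build_reference, select_center, warp_peaklist)
from .buckets import BucketGrid, BucketVector, bucketize, make_grid, schema_hash
from .errors import ConfigError, UserInputError
from .features import (FRAGMENT_BUCKET_SIZES, FeatureTable, FusionSpec,
                       assemble_sample, stack)
from .io import AcquisitionScheme, Run
from .normalize import (IstdSpec, NormalizationSpec, extract_istd_intensity,
                        normalize)
from .peaks import ChromPeakList, PeakDetectionParams, detect_peaks

__all__ = ["PipelineConfig", "build_grids", "process_batch", "process_single"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to turn raw runs into canonical feature vectors."""

    detection: PeakDetectionParams = field(default_factory=PeakDetectionParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    rt_size: float = 20.0            # MS1 bucket sizes
    mz_size: float = 2.0
    rt_origin: float = 0.0
    rt_extent: float = 300.0         # reference-axis extent covered by buckets
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    align: bool = True               # False: trust the raw RT axis
    istd: Optional[IstdSpec] = None

    def frag_sizes(self) -> Optional[tuple[float, float]]:
        if self.fusion.fragments == "no":
            return None
        return FRAGMENT_BUCKET_SIZES[self.fusion.fragments]


def build_grids(scheme: AcquisitionScheme, method: str,
                config: PipelineConfig) -> list[BucketGrid]:
    """MS1 grid (+ per-window MS2 grids when fragments are requested)."""
    grids = [make_grid(
        f"{method}-MS1", config.rt_size, config.mz_size, config.rt_origin,
        config.rt_extent, scheme.ms1_range, ms_level=1,
    )]
    sizes = config.frag_sizes()
    if sizes is not None:
        frag_rt, frag_mz = sizes
        if not scheme.windows:
            raise ConfigError(
                "fragment buckets requested but the acquisition scheme has no windows"
            )
        for w in scheme.windows:
            grids.append(make_grid(
                f"{method}-MS2", frag_rt, frag_mz, config.rt_origin,
                config.rt_extent, w.detect_range, ms_level=2, window_id=w.window_id,
            ))
    return grids


def _vector_for_run(
    run: Run,
    peaklist: ChromPeakList,
    reference: Optional[ReferenceProfile],
    config: PipelineConfig,
) -> tuple[pd.Series, str, Optional[WarpFunction]]:
    warp = None
    if config.align:
        assert reference is not None
        _, warp = align_run(run, reference, config.alignment)
        peaklist = warp_peaklist(peaklist, warp)
    grids = build_grids(run.scheme, run.method, config)
    vec = bucketize(peaklist, grids)
    istd_intensity = None
    if config.normalization.strategy == "ISTD_add":
        spec = config.normalization.istd or config.istd
        if spec is None:
            raise ConfigError("ISTD_add normalization requires an IstdSpec")
        istd_intensity = extract_istd_intensity(peaklist, spec)
    normed = normalize(vec, config.normalization, istd_intensity)
    blocks = _split_blocks(normed)
    fused, fused_schema = assemble_sample(blocks, config.fusion)
    return fused, fused_schema, warp


def _split_blocks(vec: BucketVector) -> dict[str, BucketVector]:
    """Split a multi-grid vector into per-block vectors for fusion."""
    out: dict[str, BucketVector] = {}
    for block in sorted({g.block for g in vec.grids}):
        grids = tuple(g for g in vec.grids if g.block == block)
        out[block] = BucketVector(grids=grids,
                                  data={g.key: vec.data[g.key] for g in grids})
    return out


def process_batch(
    runs: Sequence[Run],
    config: PipelineConfig,
    reference: Optional[ReferenceProfile] = None,
) -> tuple[FeatureTable, Optional[ReferenceProfile], dict[str, ChromPeakList]]:
    """Process a batch of runs into a feature table.

    When no reference is given, the run with the most MS1 peaks is
    elected center and frozen as the reference for every later batch.
    Returns (table, reference, raw peak lists by run_id).
    """
    if not runs:
        raise UserInputError("no runs to process")
    peaklists = {run.run_id: detect_peaks(run, config.detection) for run in runs}
    if config.align and reference is None:
        center_id = select_center(list(peaklists.values()))
        center_run = next(r for r in runs if r.run_id == center_id)
        reference = build_reference(center_run, config.alignment)
    rows = []
    fused_schema = None
    for run in runs:
        fused, fused_schema, _ = _vector_for_run(run, peaklists[run.run_id],
                                                 reference, config)
        rows.append((run.sample_id, run.class_label, fused))
    provenance = {
        "reference_hash": reference.hash if reference is not None else None,
        "reference_run": reference.run_id if reference is not None else None,
        "rt_size": config.rt_size, "mz_size": config.mz_size,
        "normalization": config.normalization.strategy,
        "fragments": config.fusion.fragments,
        "data_fusion": config.fusion.data_fusion,
    }
    table = stack(rows, fused_schema, provenance)
    return table, reference, peaklists


def process_single(
    run: Run,
    config: PipelineConfig,
    reference: Optional[ReferenceProfile],
) -> tuple[str, Optional[str], pd.Series, str]:
    """Process one run in isolation against the frozen reference.

    Returns (sample_id, class_label, fused vector, schema id) — exactly
    the row :func:`process_batch` would have produced for this run.
    """
    if config.align and reference is None:
        raise UserInputError("separate processing requires a persisted reference")
    peaklist = detect_peaks(run, config.detection)
    fused, fused_schema, _ = _vector_for_run(run, peaklist, reference, config)
    return run.sample_id, run.class_label, fused, fused_schema
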
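"""Factorial pipeline executor: one aligned dataset, many combinations.

Alignment is combination-independent, so the runs are detected and
warped once up front; per combination only bucketing, normalization,
fusion and forest training are re-run.  Bucket vectors are cached per
grid schema and normalized tables per (schema, normalization), which is
what makes 60- or 288-combination screens tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Sequence

from .align import build_reference, select_center, align_run, warp_peaklist
from .buckets import bucketize, schema_hash
from .classify import RFParams, train
from .errors import ConfigError
from .features import FusionSpec, assemble_sample, stack
from .normalize import NormalizationSpec, extract_istd_intensity
from .normalize import normalize as _normalize
from .peaks import detect_peaks
from .pipeline import PipelineConfig, build_grids, _split_blocks
from .io import Run

__all__ = ["factorial_pipeline"]


def factorial_pipeline(runs: Sequence[Run], base: PipelineConfig, *,
                       n_trees: int = 300):
    """Build a ``pipeline(combination, seed) -> oob_error`` closure.

    Recognized combination keys (all optional): ``rt_size``, ``mz_size``,
    ``normalization``, ``fragments``, ``data_fusion``.
    """
    peaklists = {r.run_id: detect_peaks(r, base.detection) for r in runs}
    if base.align:
        center = select_center(list(peaklists.values()))
        reference = build_reference(next(r for r in runs if r.run_id == center),
                                    base.alignment)
        aligned = {}
        for r in runs:
            _, warp = align_run(r, reference, base.alignment)
            aligned[r.run_id] = warp_peaklist(peaklists[r.run_id], warp)
    else:
        aligned = peaklists
    labels = {r.run_id: r.class_label for r in runs}
    samples = {r.run_id: r.sample_id for r in runs}
    order = [r.run_id for r in runs]
    scheme = runs[0].scheme
    method = runs[0].method

    bucket_cache: dict[str, dict] = {}
    istd_cache: dict[str, float] = {}

    def pipeline(combo: dict, seed: int) -> float:
        cfg = replace(
            base,
            rt_size=float(combo.get("rt_size", base.rt_size)),
            mz_size=float(combo.get("mz_size", base.mz_size)),
            normalization=NormalizationSpec(
                strategy=str(combo.get("normalization",
                                       base.normalization.strategy))),
            fusion=FusionSpec(
                fragments=str(combo.get("fragments", base.fusion.fragments)),
                data_fusion=str(combo.get("data_fusion", base.fusion.data_fusion)),
            ),
        )
        if cfg.fusion.data_fusion != "no":
            raise ConfigError("factorial executor handles single-method datasets only")
        grids = build_grids(scheme, method, cfg)
        key = schema_hash(grids)
        if key not in bucket_cache:
            bucket_cache[key] = {rid: bucketize(aligned[rid], grids) for rid in order}
        vectors = bucket_cache[key]
        rows = []
        fused_schema = None
        for rid in order:
            istd_intensity = None
            if cfg.normalization.strategy == "ISTD_add":
                spec = cfg.normalization.istd or base.istd
                if spec is None:
                    raise ConfigError("ISTD_add requires an IstdSpec in the base config")
                if rid not in istd_cache:
                    istd_cache[rid] = extract_istd_intensity(aligned[rid], spec)
                istd_intensity = istd_cache[rid]
            with warnings.catch_warnings():
                # empty RT rows are routine in sparse screens
                warnings.filterwarnings("ignore", message=".*empty RT bucket.*")
                normed = _normalize(vectors[rid], cfg.normalization, istd_intensity)
            fused, fused_schema = assemble_sample(_split_blocks(normed), cfg.fusion)
            rows.append((samples[rid], labels[rid], fused))
        table = stack(rows, fused_schema)
        bundle = train(table, RFParams(n_trees=n_trees, seed=seed))
        return bundle.oob_error

    return pipeline
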
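"""Fusion of normalized block vectors and feature-table assembly.

A sample's measurement can span up to four blocks — RP MS1, RP MS2
(fragment windows), HILIC MS1, HILIC MS2 — and the fusion spec decides
which are concatenated into the canonical feature vector:

* ``fragments``: include the RP MS2 windows (``yes_small`` = 5 s/5 Da
  buckets, ``yes_large`` = 80 s/20 Da, ``no``)
* ``data_fusion``: include HILIC MS1 (bucket sizes as RP MS1) and
  optionally HILIC MS2 (``yes_full``, ``yes_full_frag_small``,
  ``yes_full_frag_large``, ``no``)

Block order is canonical (RP-MS1, RP-MS2 windows ascending, HILIC-MS1,
HILIC-MS2 windows ascending) regardless of input order, and the combined
schema id hashes the fusion levels plus every block's grid schema, so
two tables agree on their features iff their schema ids agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import stable_hash
from .buckets import BucketVector
from .errors import ConfigError, SchemaMismatchError

__all__ = ["FusionSpec", "FeatureTable", "assemble_sample", "stack", "append_rows"]

FRAGMENT_LEVELS = ("yes_small", "yes_large", "no")
FUSION_LEVELS = ("yes_full", "yes_full_frag_small", "yes_full_frag_large", "no")

#: bucket (rt_size, mz_size) implied by the fragment factor levels
FRAGMENT_BUCKET_SIZES = {"yes_small": (5.0, 5.0), "yes_large": (80.0, 20.0)}


@dataclass(frozen=True)
class FusionSpec:
    fragments: str = "no"
    data_fusion: str = "no"
    primary_method: str = "RP"

    def __post_init__(self):
        if self.fragments not in FRAGMENT_LEVELS:
            raise ConfigError(f"fragments level {self.fragments!r} not in {FRAGMENT_LEVELS}")
        if self.data_fusion not in FUSION_LEVELS:
            raise ConfigError(f"data_fusion level {self.data_fusion!r} not in {FUSION_LEVELS}")
        if self.primary_method not in ("RP", "HILIC"):
            raise ConfigError(f"unknown method {self.primary_method!r}")

    @property
    def secondary_method(self) -> str:
        return "HILIC" if self.primary_method == "RP" else "RP"

    def required_blocks(self) -> list[str]:
        blocks = [f"{self.primary_method}-MS1"]
        if self.fragments != "no":
            blocks.append(f"{self.primary_method}-MS2")
        if self.data_fusion != "no":
            blocks.append(f"{self.secondary_method}-MS1")
        if self.data_fusion in ("yes_full_frag_small", "yes_full_frag_large"):
            blocks.append(f"{self.secondary_method}-MS2")
        return blocks


def assemble_sample(
    blocks: Mapping[str, BucketVector],
    spec: FusionSpec,
) -> tuple[pd.Series, str]:
    """Concatenate normalized block vectors into one canonical vector.

    ``blocks`` maps block labels ("RP-MS1", "RP-MS2", ...) to their
    normalized vectors; blocks not requested by the spec are ignored.
    Returns the fused feature series and the combined schema id.
    """
    required = spec.required_blocks()
    missing = [b for b in required if b not in blocks]
    if missing:
        raise SchemaMismatchError(f"fusion requires missing block(s): {missing}")
    pieces = []
    schema_parts = {"fragments": spec.fragments, "data_fusion": spec.data_fusion,
                    "primary_method": spec.primary_method, "blocks": {}}
    for label in required:
        vec = blocks[label]
        bad = [g.block for g in vec.grids if g.block != label]
        if bad:
            raise SchemaMismatchError(
                f"block {label!r}: vector carries grids for {sorted(set(bad))}"
            )
        pieces.append(vec.to_series())
        schema_parts["blocks"][label] = vec.schema_id
    fused = pd.concat(pieces)
    if fused.index.has_duplicates:
        raise SchemaMismatchError("duplicate feature ids after fusion")
    return fused, stable_hash(schema_parts)


@dataclass
class FeatureTable:
    """Samples x features matrix with labels and provenance.

    ``X`` is indexed by sample_id with feature ids as columns; ``y``
    holds class labels aligned to ``X``.  ``provenance`` records what is
    needed to reproduce/extend the table (reference hash, parameters).
    """

    X: pd.DataFrame
    y: pd.Series
    schema_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y indices differ")
        if self.X.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self):
        return len(self.X)

    @property
    def classes(self) -> list[str]:
        return sorted(self.y.unique())

    def to_csv(self, path) -> Path:
        path = Path(path)
        out = self.X.copy()
        out.insert(0, "class_label", self.y)
        out.to_csv(path, index_label="sample_id")
        meta = {"schema_id": self.schema_id, "provenance": self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="sample_id")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        y = df.pop("class_label")
        return cls(X=df, y=y, schema_id=meta["schema_id"], provenance=meta["provenance"])


def stack(
    rows: Sequence[tuple[str, Optional[str], pd.Series]],
    schema_id: str,
    provenance: Optional[dict] = None,
) -> FeatureTable:
    """Stack (sample_id, class_label, fused vector) rows into a table."""
    if not rows:
        raise ValueError("no rows to stack")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in rows")
    index = pd.Index(ids, name="sample_id")
    first = rows[0][2].index
    for sid, _, vec in rows[1:]:
        if not vec.index.equals(first):
            raise SchemaMismatchError(f"sample {sid}: feature ids differ from first row")
    X = pd.DataFrame([r[2].to_numpy() for r in rows], index=index, columns=first)
    y = pd.Series([r[1] for r in rows], index=index, name="class_label")
    return FeatureTable(X=X, y=y, schema_id=schema_id, provenance=provenance or {})


def append_rows(
    table: FeatureTable,
    rows: Sequence[tuple[str, Optional[str], pd.Series]],
    schema_id: str,
) -> FeatureTable:
    """Append new samples; refuses schema mismatches and duplicate ids."""
    if schema_id != table.schema_id:
        raise SchemaMismatchError(
            "cannot append: schema ids differ\n"
            f"  table: {table.schema_id}\n  rows:  {schema_id}"
        )
    new = stack(rows, schema_id)
    dup = set(new.X.index) & set(table.X.index)
    if dup:
        raise ValueError(f"duplicate sample_id(s) on append: {sorted(dup)}")
    if not new.X.columns.equals(table.X.columns):
        raise SchemaMismatchError("cannot append: feature ids differ")
    return FeatureTable(
        X=pd.concat([table.X, new.X]),
        y=pd.concat([table.y, new.y]),
        schema_id=table.schema_id,
        provenance=dict(table.provenance),
    )


def concat_tables(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Union of two tables with identical schemas (used by model extension)."""
    if a.schema_id != b.schema_id:
        raise SchemaMismatchError(
            f"cannot merge tables: schema ids differ\n  a: {a.schema_id}\n  b: {b.schema_id}"
        )
    dup = set(a.X.index) & set(b.X.index)
    if dup:
        raise ValueError(f"duplicate sample_id(s) in union: {sorted(dup)}")
    return FeatureTable(
        X=pd.concat([a.X, b.X]),
        y=pd.concat([a.y, b.y]),
        schema_id=a.schema_id,
        provenance=dict(a.provenance),
    )
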
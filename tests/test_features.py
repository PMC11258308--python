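"""Fusion and feature-table assembly: canonical order, schema safety."""

import numpy as np
import pandas as pd
import pytest

import lcbucket as lb
from lcbucket.buckets import BucketVector, make_grid
from lcbucket.errors import SchemaMismatchError
from lcbucket.features import (FusionSpec, append_rows, assemble_sample,
                               concat_tables, stack)


def _block_vector(block, n_rt=2, n_mz=3, fill=1.0, ms_level=1, window_id=None,
                  mz_range=(100.0, 600.0)):
    g = make_grid(block, 20.0, (mz_range[1] - mz_range[0]) / n_mz, 0.0,
                  20.0 * n_rt, mz_range, ms_level=ms_level, window_id=window_id)
    return BucketVector(grids=(g,), data={g.key: np.full((g.n_rt, g.n_mz), fill)})


def test_identity_fusion_returns_rp_ms1_vector():
    rp = _block_vector("RP-MS1", fill=3.0)
    fused, schema = assemble_sample({"RP-MS1": rp, "HILIC-MS1": _block_vector("HILIC-MS1")},
                                    FusionSpec(fragments="no", data_fusion="no"))
    pd.testing.assert_series_equal(fused, rp.to_series())
    assert schema


def test_block_order_is_canonical_not_input_order():
    blocks = {"HILIC-MS1": _block_vector("HILIC-MS1", fill=2.0),
              "RP-MS1": _block_vector("RP-MS1", fill=1.0)}
    spec = FusionSpec(fragments="no", data_fusion="yes_full")
    fused1, s1 = assemble_sample(blocks, spec)
    fused2, s2 = assemble_sample(dict(reversed(list(blocks.items()))), spec)
    pd.testing.assert_series_equal(fused1, fused2)
    assert s1 == s2
    assert fused1.index[0].startswith("RP-MS1")  # RP block leads


def test_missing_required_block_is_named():
    with pytest.raises(SchemaMismatchError, match="HILIC-MS1"):
        assemble_sample({"RP-MS1": _block_vector("RP-MS1")},
                        FusionSpec(data_fusion="yes_full"))


def test_long_term_optimal_fusion_feature_count():
    """RP MS1 20 s/2 Da + RP MS2 80 s/20 Da + HILIC MS1 20 s/2 Da +
    HILIC MS2 5 s/5 Da over the six-window scheme: the fused vector's
    length is exactly the sum of the per-block grid sizes."""
    scheme = lb.HONEY_VDIA_SCHEME
    extent = 600.0
    rp1 = lb.build_grids(scheme, "RP", lb.PipelineConfig(
        rt_size=20.0, mz_size=2.0, rt_extent=extent,
        fusion=FusionSpec(fragments="yes_large")))
    hi1 = lb.build_grids(scheme, "HILIC", lb.PipelineConfig(
        rt_size=20.0, mz_size=2.0, rt_extent=extent,
        fusion=FusionSpec(fragments="yes_small")))
    def vec(grids):
        data = {g.key: np.zeros((g.n_rt, g.n_mz)) for g in grids}
        return BucketVector(grids=tuple(grids), data=data)
    blocks = {
        "RP-MS1": vec([g for g in rp1 if g.block == "RP-MS1"]),
        "RP-MS2": vec([g for g in rp1 if g.block == "RP-MS2"]),
        "HILIC-MS1": vec([g for g in hi1 if g.block == "HILIC-MS1"]),
        "HILIC-MS2": vec([g for g in hi1 if g.block == "HILIC-MS2"]),
    }
    fused, _ = assemble_sample(blocks, FusionSpec(fragments="yes_large",
                                                  data_fusion="yes_full_frag_small"))
    expected = sum(g.n_rt * g.n_mz for g in rp1) + sum(g.n_rt * g.n_mz for g in hi1)
    assert len(fused) == expected
    assert not fused.index.has_duplicates


def _rows(ids, n_feat=4):
    rng = np.random.default_rng(0)
    idx = [f"f{i}" for i in range(n_feat)]
    return [(sid, "X", pd.Series(rng.uniform(size=n_feat), index=idx)) for sid in ids]


def test_append_grows_by_one_and_checks_schema():
    t = stack(_rows(["a", "b", "c"]), "schemaA")
    t2 = append_rows(t, _rows(["d"]), "schemaA")
    assert len(t2) == 4 and t2.schema_id == "schemaA"
    with pytest.raises(SchemaMismatchError, match="schema"):
        append_rows(t, _rows(["e"]), "schemaB")
    with pytest.raises(ValueError, match="duplicate"):
        append_rows(t, _rows(["a"]), "schemaA")


def test_incremental_equals_batch_stacking():
    rows = _rows(list("abcdef"))
    batch = stack(rows, "s")
    incremental = stack(rows[:2], "s")
    incremental = append_rows(incremental, rows[2:4], "s")
    incremental = append_rows(incremental, rows[4:], "s")
    pd.testing.assert_frame_equal(batch.X, incremental.X)
    pd.testing.assert_series_equal(batch.y, incremental.y)


def test_concat_tables_refuses_mismatch_and_duplicates():
    a = stack(_rows(["a", "b"]), "s")
    b = stack(_rows(["c"]), "s")
    assert len(concat_tables(a, b)) == 3
    with pytest.raises(SchemaMismatchError):
        concat_tables(a, stack(_rows(["d"]), "t"))
    with pytest.raises(ValueError, match="duplicate"):
        concat_tables(a, stack(_rows(["b"]), "s"))


def test_feature_table_csv_roundtrip(tmp_path):
    t = stack(_rows(["a", "b"]), "s")
    t.provenance["reference_hash"] = "deadbeef"
    p = t.to_csv(tmp_path / "feat.csv")
    back = lb.FeatureTable.from_csv(p)
    pd.testing.assert_frame_equal(back.X, t.X)
    assert back.schema_id == "s"
    assert back.provenance["reference_hash"] == "deadbeef"
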
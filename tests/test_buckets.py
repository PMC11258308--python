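"""Bucket grids and bucketing: geometry, conservation, oracle equality."""

import numpy as np
import pytest

import lcbucket as lb
from lcbucket.buckets import BucketGrid, bucketize, make_grid, schema_hash
from lcbucket.errors import SchemaMismatchError
from lcbucket.peaks import ChromPeak, ChromPeakList, PeakDetectionParams


def _peaklist(peaks):
    return ChromPeakList(run_id="t", params=PeakDetectionParams(), peaks=peaks)


def _peak(rt, mz, inten, ms_level=1, window_id=None):
    return ChromPeak(mz=mz, rt=rt, rt_min=rt - 1, rt_max=rt + 1, intensity=inten,
                     ms_level=ms_level, window_id=window_id)


def brute_force_bucketize(peaks, grid):
    """Independent oracle: loop over every (peak, bucket) pair testing
    half-open interval membership (top m/z edge closed)."""
    out = np.zeros((grid.n_rt, grid.n_mz))
    lo, hi = grid.mz_range
    for i in range(grid.n_rt):
        r0 = grid.rt_origin + i * grid.rt_size
        r1 = r0 + grid.rt_size
        for j in range(grid.n_mz):
            m0 = lo + j * grid.effective_mz_size
            m1 = m0 + grid.effective_mz_size
            for p in peaks:
                in_rt = r0 <= p.rt < r1
                in_mz = (m0 <= p.mz < m1) or (j == grid.n_mz - 1 and p.mz == hi)
                if in_rt and in_mz:
                    out[i, j] += p.intensity
    return out


# -------------------------------------------------------------------- grids


def test_ms1_grid_has_700_mass_buckets():
    g = make_grid("RP-MS1", 20.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    assert g.n_mz == 700
    assert g.effective_mz_size == 2.0


def test_fragment_window_divisibility_adjustment():
    g = make_grid("RP-MS2", 80.0, 20.0, 0.0, 600.0, (50.0, 225.0),
                  ms_level=2, window_id="w0150")
    assert g.n_mz == 9
    assert g.effective_mz_size == pytest.approx(175.0 / 9.0)
    assert g.n_mz * g.effective_mz_size == pytest.approx(175.0)


def test_single_bucket_grid():
    g = make_grid("X", 10.0, 10.0, 0.0, 5.0, (0.0, 10.0))
    assert g.n_mz == 1 and g.effective_mz_size == 10.0
    assert g.n_rt == 1


def test_rt_buckets_keep_nominal_size_with_overhang():
    g = make_grid("X", 20.0, 2.0, 0.0, 110.0, (100.0, 200.0))
    assert g.n_rt == 6  # 6 x 20 s >= 110 s


# ---------------------------------------------------------------- bucketize


def test_single_peak_assignment():
    g = make_grid("RP-MS1", 20.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    v = bucketize(_peaklist([_peak(10.0, 150.0, 100.0)]), [g])
    arr = v.data[g.key]
    assert arr[0, 25] == 100.0
    assert arr.sum() == 100.0


def test_two_peaks_summed_in_one_bucket():
    g = make_grid("RP-MS1", 20.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    v = bucketize(_peaklist([_peak(10.0, 150.3, 40.0), _peak(19.9, 151.9, 60.0)]), [g])
    arr = v.data[g.key]
    assert arr[0, 25] == 100.0
    assert (arr != 0).sum() == 1


def test_top_edge_closed_and_origin_drop():
    g = make_grid("RP-MS1", 20.0, 2.0, 10.0, 600.0, (100.0, 1500.0))
    v = bucketize(_peaklist([_peak(30.0, 1500.0, 5.0),   # top m/z edge
                             _peak(5.0, 200.0, 7.0)]),   # rt < origin
                  [g])
    assert v.data[g.key][1, g.n_mz - 1] == 5.0
    assert v.discarded_intensity == 7.0
    assert v.discarded_count == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 400
    peaks = [_peak(float(r), float(m), float(i))
             for r, m, i in zip(rng.uniform(-5, 320, n), rng.uniform(95, 610, n),
                                rng.uniform(0.1, 100, n))]
    g = make_grid("RP-MS1", 20.0, 10.0, 0.0, 300.0, (100.0, 600.0))
    v = bucketize(_peaklist(peaks), [g])
    np.testing.assert_array_equal(v.data[g.key], brute_force_bucketize(peaks, g))
    total = sum(p.intensity for p in peaks)
    assert v.total_intensity() + v.discarded_intensity == pytest.approx(total, rel=1e-12)


def test_monotone_coarsening():
    rng = np.random.default_rng(3)
    peaks = [_peak(float(r), float(m), 1.0)
             for r, m in zip(rng.uniform(0, 300, 2000), rng.uniform(100, 600, 2000))]
    pl = _peaklist(peaks)
    def nonzeros(rt_size, mz_size):
        g = make_grid("RP-MS1", rt_size, mz_size, 0.0, 300.0, (100.0, 600.0))
        return int((bucketize(pl, [g]).data[g.key] != 0).sum())
    for sizes in ([(5, 2), (20, 2), (80, 2)], [(20, 2), (20, 5), (20, 10), (20, 20)]):
        counts = [nonzeros(r, m) for r, m in sizes]
        assert counts == sorted(counts, reverse=True)


def test_separate_equals_batch_by_construction(tiny_table, tiny_dataset, tiny_cfg):
    table, reference, peaklists, config = tiny_table
    runs, _ = tiny_dataset
    run = runs[2]
    sid, label, vec, schema = lb.process_single(run, config, reference)
    assert schema == table.schema_id
    np.testing.assert_array_equal(vec.to_numpy(), table.X.loc[sid].to_numpy())


def test_unknown_window_peak_raises_but_ms2_ignored_without_ms2_grids():
    g1 = make_grid("RP-MS1", 20.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    g2 = make_grid("RP-MS2", 80.0, 20.0, 0.0, 600.0, (50.0, 225.0),
                   ms_level=2, window_id="w0150")
    ms2_peak = _peak(10.0, 100.0, 1.0, ms_level=2, window_id="w9999")
    with pytest.raises(SchemaMismatchError, match="w9999"):
        bucketize(_peaklist([ms2_peak]), [g1, g2])
    v = bucketize(_peaklist([ms2_peak]), [g1])  # MS1-only schema: MS2 ignored
    assert v.total_intensity() == 0.0


# -------------------------------------------------------------- schema hash


def test_schema_hash_order_independent_and_sensitive():
    g1 = make_grid("RP-MS1", 20.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    g2 = make_grid("RP-MS2", 80.0, 20.0, 0.0, 600.0, (50.0, 225.0),
                   ms_level=2, window_id="w0150")
    assert schema_hash([g1, g2]) == schema_hash([g2, g1])
    g1b = make_grid("RP-MS1", 80.0, 2.0, 0.0, 600.0, (100.0, 1500.0))
    assert schema_hash([g1, g2]) != schema_hash([g1b, g2])


def test_optimal_schema_hash_frozen():
    """The long-term-optimal grid set must hash identically everywhere."""
    config = lb.PipelineConfig(rt_size=20.0, mz_size=2.0, rt_extent=600.0,
                               fusion=lb.FusionSpec(fragments="yes_large"))
    grids = lb.build_grids(lb.HONEY_VDIA_SCHEME, "RP", config)
    assert schema_hash(grids) == (
        "413d868ecf64237663bdfec7507041de7a0696d39309ffcfde3a821ba4017360"
    )
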
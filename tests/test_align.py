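"""Alignment: center election, reference profiles, warp recovery."""

from dataclasses import replace

import numpy as np
import pytest

import lcbucket as lb
from lcbucket.align import _bin_profile
from lcbucket.errors import AlignmentError
from lcbucket.peaks import ChromPeak, ChromPeakList, PeakDetectionParams


def _fake_peaklist(run_id, n):
    peaks = [ChromPeak(mz=200.0 + i, rt=10.0 * i, rt_min=1.0, rt_max=20.0 * i + 1,
                       intensity=1.0) for i in range(n)]
    return ChromPeakList(run_id=run_id, params=PeakDetectionParams(), peaks=peaks)


def test_select_center_argmax_and_tie_rule():
    pls = [_fake_peaklist("A", 120), _fake_peaklist("B", 240), _fake_peaklist("C", 200)]
    assert lb.select_center(pls) == "B"
    assert lb.select_center([_fake_peaklist("B", 100), _fake_peaklist("A", 100)]) == "A"
    with pytest.raises(ValueError):
        lb.select_center([])


def test_reference_binning_geometry(noise_free_cfg):
    run = lb.simulate_run(noise_free_cfg, "classA", "ref", 0)
    # bin count over the full instrument range at the published bin size
    rts, mat = _bin_profile(run, 0.1, (100.0, 1500.0))
    assert mat.shape[1] == 14000
    # half-open edge rule: a centroid at 100.05 falls in bin [100.0, 100.1)
    scheme = lb.AcquisitionScheme(ms1_range=(100.0, 1500.0))
    one = lb.Run(run_id="r", sample_id="s", method="RP", instrument_id="i",
                 scans=[lb.CentroidScan(rt=0.0, ms_level=1, mz=[100.05], intensity=[7.0]),
                        lb.CentroidScan(rt=1.0, ms_level=1, mz=[100.05], intensity=[7.0])],
                 scheme=scheme)
    _, m2 = _bin_profile(one, 0.1, (100.0, 1500.0))
    assert m2[0, 0] == 7.0 and m2[0, 1:].sum() == 0.0


def test_reference_hash_deterministic_and_persistent(tmp_path, noise_free_cfg):
    run = lb.simulate_run(noise_free_cfg, "classA", "ref", 0)
    ref1 = lb.build_reference(run)
    ref2 = lb.build_reference(run)
    assert ref1.hash == ref2.hash
    ref1.save(tmp_path / "ref")
    loaded = lb.ReferenceProfile.load(tmp_path / "ref")
    assert loaded.hash == ref1.hash
    np.testing.assert_array_equal(loaded.matrix, ref1.matrix)


def test_self_alignment_is_identity(noise_free_cfg):
    run = lb.simulate_run(noise_free_cfg, "classA", "ref", 0)
    ref = lb.build_reference(run)
    _, warp = lb.align_run(run, ref)
    rts = np.array([s.rt for s in run.scans])
    assert np.abs(warp(rts) - rts).max() == 0.0


def test_constant_shift_recovered(noise_free_cfg):
    cfg = replace(noise_free_cfg,
                  instruments={"ref": lb.RTDistortion(), "sh": lb.RTDistortion(b=5.0)})
    base = lb.simulate_run(cfg, "classA", "ref", 0)
    shifted = lb.simulate_run(cfg, "classA", "sh", 0)
    ref = lb.build_reference(base)
    _, warp = lb.align_run(shifted, ref)
    comps = cfg.background + cfg.classes["classA"]
    errs = [abs(warp(c.rt + 5.0) - c.rt) for c in comps]
    assert np.median(errs) <= cfg.scan_interval


def test_smooth_distortion_recovered(noise_free_cfg):
    dist = lb.RTDistortion(a=1.01, b=3.0, c=2.0, p=300.0)
    cfg = replace(noise_free_cfg,
                  instruments={"ref": lb.RTDistortion(), "d": dist})
    base = lb.simulate_run(cfg, "classA", "ref", 0)
    warped_run = lb.simulate_run(cfg, "classA", "d", 0)
    ref = lb.build_reference(base)
    aligned, warp = lb.align_run(warped_run, ref)
    comps = cfg.background + cfg.classes["classA"]
    errs = [abs(warp(dist.warp(c.rt)) - c.rt) for c in comps]
    assert np.median(errs) <= 2.0
    # idempotence: realigning the aligned run moves scans < one interval
    _, warp2 = lb.align_run(aligned, ref)
    rts = np.array([s.rt for s in aligned.scans])
    assert np.abs(warp2(rts) - rts).max() <= cfg.scan_interval


def test_warp_monotone_and_extrapolates():
    warp = lb.WarpFunction(sample_rt=[10.0, 20.0, 30.0], reference_rt=[12.0, 21.0, 33.0])
    x = np.linspace(-10.0, 50.0, 301)
    y = warp(x)
    assert np.all(np.diff(y) >= 0)
    assert warp(0.0) == pytest.approx(12.0 - 10.0 * 0.9)  # terminal slope extrapolation
    with pytest.raises(AlignmentError, match="monotone"):
        lb.WarpFunction(sample_rt=[10.0, 5.0], reference_rt=[1.0, 2.0])


def test_alignment_pairwise_so_batch_context_irrelevant(tiny_dataset):
    runs, _ = tiny_dataset
    pls = [lb.detect_peaks(r) for r in runs]
    center = lb.select_center(pls)
    ref = lb.build_reference(next(r for r in runs if r.run_id == center))
    _, alone = lb.align_run(runs[1], ref)
    for _ in runs:  # "batch" loop: alignment must not look at other runs
        _, again = lb.align_run(runs[1], ref)
    np.testing.assert_array_equal(alone.sample_rt, again.sample_rt)
    np.testing.assert_array_equal(alone.reference_rt, again.reference_rt)


def test_disjoint_content_fails_loudly():
    scheme = lb.AcquisitionScheme(ms1_range=(100.0, 600.0))
    def flat_run(mz, rid):
        scans = [lb.CentroidScan(rt=float(t), ms_level=1, mz=[mz], intensity=[100.0])
                 for t in range(30)]
        return lb.Run(run_id=rid, sample_id=rid, method="RP", instrument_id="i",
                      scans=scans, scheme=scheme)
    ref = lb.build_reference(flat_run(500.0, "ref"))
    with pytest.raises(AlignmentError, match="alignment failed"):
        lb.align_run(flat_run(150.0, "sam"), ref)
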
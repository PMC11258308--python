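"""Normalization strategies: worked examples plus property tests."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lcbucket as lb
from lcbucket.buckets import BucketVector, bucketize, make_grid
from lcbucket.errors import UserInputError
from lcbucket.normalize import (SORBIC_ACID_NEG, SORBIC_ACID_POS, IstdSpec,
                                NormalizationSpec, extract_istd_intensity,
                                normalize)
from lcbucket.peaks import ChromPeak, ChromPeakList, PeakDetectionParams


def _vector(arr, block="RP-MS1"):
    arr = np.asarray(arr, dtype=float)
    g = make_grid(block, 20.0, (600.0 - 100.0) / arr.shape[1], 0.0,
                  20.0 * arr.shape[0], (100.0, 600.0))
    assert g.n_mz == arr.shape[1]
    return BucketVector(grids=(g,), data={g.key: arr.copy()})


def _arr(v):
    return next(iter(v.data.values()))


def test_tic_worked_example():
    v = normalize(_vector([[2.0, 3.0, 5.0]]), NormalizationSpec("TIC"))
    np.testing.assert_allclose(_arr(v), [[0.2, 0.3, 0.5]])


def test_bpc_rt_per_row_maxima():
    v = normalize(_vector([[2.0, 4.0], [10.0, 0.0]]), NormalizationSpec("BPC_RT"))
    np.testing.assert_allclose(_arr(v), [[0.5, 1.0], [1.0, 0.0]])


matrices = hnp.arrays(
    dtype=float, shape=st.tuples(st.integers(1, 6), st.integers(1, 8)),
    elements=st.floats(0.0, 1e6, allow_nan=False),
)


@settings(max_examples=60, derandomize=True)
@given(matrices)
def test_normalization_invariants(arr):
    v = _vector(arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tic = _arr(normalize(v, NormalizationSpec("TIC")))
        bpc = _arr(normalize(v, NormalizationSpec("BPC")))
        tic_rt = _arr(normalize(v, NormalizationSpec("TIC_RT")))
        bpc_rt = _arr(normalize(v, NormalizationSpec("BPC_RT")))
    if arr.sum() > 0:
        assert tic.sum() == pytest.approx(1.0)
        assert bpc.max() == pytest.approx(1.0)
    for i in range(arr.shape[0]):
        if arr[i].sum() > 0:
            assert tic_rt[i].sum() == pytest.approx(1.0)
            assert bpc_rt[i].max() == pytest.approx(1.0)
        else:
            assert tic_rt[i].sum() == 0.0


@settings(max_examples=40, derandomize=True)
@given(matrices, st.floats(1e-3, 1e3))
def test_scale_invariance_and_idempotence(arr, c):
    v = _vector(arr)
    scaled = _vector(arr * c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for strat in ("TIC", "BPC", "TIC_RT", "BPC_RT"):
            spec = NormalizationSpec(strat)
            np.testing.assert_allclose(_arr(normalize(scaled, spec)),
                                       _arr(normalize(v, spec)), rtol=1e-9, atol=1e-12)
        for strat in ("TIC", "BPC"):
            spec = NormalizationSpec(strat)
            once = normalize(v, spec)
            twice = normalize(once, spec)
            np.testing.assert_allclose(_arr(twice), _arr(once), rtol=1e-9, atol=1e-12)
        # ISTD scaling equivariance: normalize(c*v, c*istd) == normalize(v, istd)
        spec = NormalizationSpec("ISTD_add", istd=SORBIC_ACID_POS)
        np.testing.assert_allclose(
            _arr(normalize(scaled, spec, istd_intensity=5.0 * c)),
            _arr(normalize(v, spec, istd_intensity=5.0)), rtol=1e-9, atol=1e-12)


def test_all_zero_block_passes_through_with_warning():
    v = _vector(np.zeros((2, 3)))
    with pytest.warns(UserWarning, match="all-zero"):
        out = normalize(v, NormalizationSpec("TIC"))
    assert _arr(out).sum() == 0.0


def test_istd_missing_standard_is_hard_error():
    v = _vector([[1.0, 2.0]])
    spec = NormalizationSpec("ISTD_add", istd=SORBIC_ACID_POS)
    with pytest.raises(UserInputError, match="standard"):
        normalize(v, spec, istd_intensity=0.0)
    with pytest.raises(UserInputError):
        normalize(v, spec, istd_intensity=None)


def test_sorbic_acid_ion_targets_match_formula_oracle():
    """Cross-check the frozen targets against pyteomics' mass calculator."""
    from pyteomics import mass
    mono = mass.calculate_mass(formula="C6H8O2")
    proton = mass.calculate_mass(formula="H+")
    assert SORBIC_ACID_POS.target_mz == pytest.approx(mono + proton, abs=1e-4)
    assert SORBIC_ACID_NEG.target_mz == pytest.approx(mono - proton, abs=1e-4)
    assert SORBIC_ACID_POS.polarity == "positive"
    assert SORBIC_ACID_NEG.polarity == "negative"


def test_extract_istd_from_planted_infusion():
    """Signals planted at the standard's m/z across the run are summed."""
    target = SORBIC_ACID_POS.target_mz
    comps = [lb.CompoundSpec(mz=target, rt=rt, mean_log_intensity=math.log(5e4))
             for rt in (60.0, 150.0, 240.0)]
    cfg = lb.SimConfig(classes={"A": []}, background=comps, n_samples_per_class=1,
                       instruments={"i": lb.RTDistortion()}, mz_jitter_ppm=0.0,
                       intensity_sigma=0.0, rt_extent=300.0)
    run = lb.simulate_run(cfg, "A", "i", 0)
    pl = lb.detect_peaks(run)
    got = extract_istd_intensity(pl, SORBIC_ACID_POS)
    planted = 3 * 5e4 * cfg.peak_sigma * math.sqrt(2 * math.pi)
    assert got == pytest.approx(planted, rel=0.01)


def test_extract_istd_no_match_returns_zero():
    pl = ChromPeakList(run_id="r", params=PeakDetectionParams(), peaks=[
        ChromPeak(mz=200.0, rt=10.0, rt_min=9.0, rt_max=11.0, intensity=5.0)])
    assert extract_istd_intensity(pl, SORBIC_ACID_POS) == 0.0
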
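"""Shared fixtures: small synthetic datasets reused across test modules."""

from dataclasses import replace

import pytest

import lcbucket as lb


@pytest.fixture(scope="session")
def tiny_cfg():
    """2 classes x 3 samples, short runs: fast but exercises everything."""
    return replace(
        lb.example_config(11, n_classes=2, markers_per_class=2, n_background=6,
                          rt_range=(30.0, 170.0)),
        n_samples_per_class=3,
        rt_extent=200.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return lb.simulate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_table(tiny_cfg, tiny_dataset):
    runs, _ = tiny_dataset
    config = lb.PipelineConfig(rt_size=20.0, mz_size=2.0, rt_extent=tiny_cfg.rt_extent)
    table, reference, peaklists = lb.process_batch(runs, config)
    return table, reference, peaklists, config


@pytest.fixture()
def noise_free_cfg():
    """Single-instrument, zero-noise configuration for exact checks."""
    cfg = lb.example_config(5, n_classes=2, markers_per_class=2, n_background=4,
                            rt_range=(40.0, 260.0))
    return replace(cfg, mz_jitter_ppm=0.0, intensity_sigma=0.0,
                   instruments={"ref": lb.RTDistortion()})
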
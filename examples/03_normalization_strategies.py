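"""The five normalization strategies on one bucketed run.

TIC/BPC rescale a whole block by its intensity sum/maximum; TIC_RT and
BPC_RT do so within each retention-time bucket; ISTD_add divides by the
summed signal of an infused internal standard (sorbic acid).
"""

import numpy as np

import lcbucket as lb
from lcbucket.normalize import NormalizationSpec, SORBIC_ACID_POS, normalize

cfg = lb.example_config(seed=3, n_classes=2, markers_per_class=2, n_background=8)
run = lb.simulate_run(cfg, "classA", sorted(cfg.instruments)[0], 0)
peaks = lb.detect_peaks(run)
grid = lb.make_grid("RP-MS1", 20.0, 2.0, 0.0, cfg.rt_extent, cfg.scheme.ms1_range)
vec = lb.bucketize(peaks, [grid])
print(f"bucketed run: {int((vec.data[grid.key] != 0).sum())} occupied buckets, "
      f"total intensity {vec.total_intensity():.3g}")

for strategy in ("TIC", "BPC", "TIC_RT", "BPC_RT"):
    out = normalize(vec, NormalizationSpec(strategy)).data[grid.key]
    print(f"{strategy:7s}: sum={out.sum():10.4f}  max={out.max():.4f}")
print("TIC sums to 1, BPC peaks at 1; the _RT variants enforce the same "
      "per retention-time bucket, trading global scale for local contrast.")
print(f"\nISTD_add would divide by the sorbic acid signal at m/z "
      f"{SORBIC_ACID_POS.target_mz:.4f} ([M+H]+).")
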
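# Methods

This note documents the processing model, its tunable parameters, the
synthetic data the package is validated on, and the numerical and
design choices made where the literature leaves the details open.

## Processing model

A run enters as centroided mzML (profile data is rejected; centroiding
is the converter's job).  Scan times are normalized to seconds on
import because every downstream parameter is in seconds.  Processing
is strictly per-run:

1. **Peak detection** — an ROI detector in the centWave family.
   Centroids in consecutive scans chain into a region of interest while
   they stay within `ppm` (default 5) of the chain's running
   intensity-weighted mean m/z; chains may skip `max_gap` (default 1)
   scans.  Finished chains lying within 2×`ppm` of each other are
   merged before peak extraction: when per-scan m/z noise is an
   appreciable fraction of the tolerance, single outlier centroids can
   fracture one compound's chain, and resolvable compounds are many
   tolerances apart so the merge radius cannot conflate them
   (co-eluting isomers merged this way are still separated by the
   local-minimum split that follows).  Each ROI is split at local
   intensity minima; a candidate peak is kept if its interpolated FWHM
   lies in `[0.5, 2] × peakwidth` (default peakwidth 15 s) and its
   apex-to-boundary ratio reaches `snr_threshold` (default 3).  Peak
   intensity is the trapezoidal area over the peak region by default
   (`intensity="apex"` switches to apex height): a summed-intensity
   bucket is a total-ion quantity, so an integrated peak intensity is
   the consistent choice.  The continuous-wavelet refinement of full
   centWave is intentionally not reimplemented — bucketing consumes
   only (m/z, apex RT, intensity), which the ROI detector already
   determines on centroided data.

2. **Retention-time alignment** — pairwise against a frozen reference.
   MS1 scans are binned at `bin_size` (default 0.1 Da) over the MS1
   range; every (sample scan, reference scan) pair is scored by Pearson
   correlation of bin vectors (covariance available); an affine-gap
   dynamic program (open 0.3, extend 2.4 — the published defaults of
   obiwarp for correlation similarity) aligns the
   two scan sequences.  `local=True` (default) leaves unaligned
   prefixes/suffixes unpenalized, which is what lets a run with a
   shifted elution window align at all.  Matched scan pairs define a
   monotone piecewise-linear warp, extrapolated at the ends with the
   terminal segment slopes; MS2 scans and all peak RTs are mapped
   through the MS1-derived warp (MS1 carries the chromatographic
   information; aligning sparse MS2 profiles independently would only
   add noise).  Warped times may be slightly negative on the reference
   axis; bucketing counts such peaks into its discard tally.  The
   reference is elected once — the run with the most MS1 peaks, ties
   broken by smallest run id — and persisted with a content hash that
   every downstream artifact carries; alignment never re-elects a
   center, because the frozen reference is precisely what makes
   separately processed batches land on one axis.

3. **Bucketing** — the fixed grid.  For each block (RP-MS1, RP-MS2 per
   isolation window, HILIC-MS1, HILIC-MS2), `n_mz = round(width /
   mz_size)` buckets (clamped to ≥ 1) tile the block's m/z range
   exactly with effective size `width / n_mz`; this divisibility
   adjustment matters for the MS2 windows, whose detection ranges are
   not multiples of the nominal sizes (e.g. the 50–225 Da window at a
   nominal 20 Da resolves to 9 buckets of 175/9 ≈ 19.44 Da).  RT
   buckets keep their nominal size from a fixed origin (0 s on the
   reference axis), with `ceil(extent / rt_size)` buckets and the last
   allowed to overhang — a fixed origin and nominal RT size keep
   feature ids stable across batches, which is the whole point.
   Buckets are half-open `[low, high)` with the top m/z bucket closed
   so the grid covers its range; a peak is assigned wholly by its
   (apex RT, m/z) point, never split.  Peaks outside their grid are
   dropped and tallied, so input intensity always equals bucket sum
   plus discard tally.  A canonical-order content hash of the grid set
   is the schema id; tables and models refuse to mix schemas or
   reference hashes.

4. **Normalization** — five pure transforms on the bucket vector:
   TIC (divide by block sum), BPC (block maximum), TIC_RT / BPC_RT
   (sum / maximum within each RT bucket), ISTD_add (divide everything
   by the summed signal of the infused internal standard, sorbic acid:
   monoisotopic 112.05243 Da, [M+H]⁺ 113.05971 / [M−H]⁻ 111.04515,
   extraction tolerance ±0.005 Da ≈ 5 ppm at this mass with margin).
   Scope is per block by default — blocks come from different
   acquisitions with unrelated absolute scales — with a whole-vector
   option.  All-zero blocks or RT rows pass through with a warning;  a
   missing internal standard is a hard error.  The global-total
   reading of ISTD_add is implemented (bucket / total standard signal),
   and the strategy is retained although it screens as clearly inferior,
   so the full five-level comparison can be reproduced.

5. **Fusion and assembly** — normalized block vectors concatenate in
   canonical order (RP-MS1, RP-MS2 windows ascending, HILIC-MS1,
   HILIC-MS2 windows ascending) under a fusion spec: `fragments ∈
   {yes_small (5 s/5 Da), yes_large (80 s/20 Da), no}` for the primary
   method's MS2 blocks, `data_fusion ∈ {yes_full,
   yes_full_frag_small, yes_full_frag_large, no}` for the secondary
   method.  Blocks are concatenated as normalized, without re-scaling.
   Zero-variance features are retained — filtering would make the
   schema data-dependent and break incremental compatibility.  Feature
   ids are `block|w=<window>|rt=<idx>|mz=<idx>` with zero-padded
   indices for stable lexicographic order.

6. **Classification** — scikit-learn random forest behind the module
   surface: `n_trees` (500 in tests, 1000+ in acceptance runs, 5000 in
   production), `mtry = ⌊√p⌋`, `min_node_size = 1`, inverse-class-
   frequency case weights `w_i = 1/(k·n_class(i))` passed as sample
   weights so every class contributes equal total weight (the
   "proportional" reading is available but contradicts the purpose of
   compensating imbalance).  OOB error and the OOB confusion matrix
   (rows true, columns predicted) come from out-of-bag votes only;
   samples that were never out of bag are excluded with a warning.
   Prediction reports per-class tree-vote fractions.  Extension unions
   the training tables (duplicate sample ids refused), retrains from
   scratch with the same parameters and records the parent bundle
   hash — no online tree surgery, matching how the model is actually
   rebuilt in routine use.

7. **Factorial screening** — full-factorial expansion (last factor
   varying fastest), one pipeline execution per combination on a fixed
   aligned dataset with bucket-vector caching per grid schema, response
   = OOB error; failing combinations record NA with the error message
   and never abort the screen.  Factor analysis is a main-effects-only
   additive OLS ANOVA (the screening reports per-factor pairwise
   differences, so interactions are out of scope) followed by Tukey
   HSD on each factor using the additive model's residual mean square
   as the shared error term and studentized-range p-values — the
   behaviour of TukeyHSD applied to a multi-way aov.  Degenerate
   inputs: a factor with numerically zero between-level variance gets
   F = 0, p = 1; levels observed once flag the factor's pairs as
   unreliable.

## The synthetic data

The simulator emulates exactly the features the pipeline must survive:
class-specific marker compounds over a shared background; a monotone
per-instrument RT distortion `rt' = a·rt + b + c·sin(2πrt/p)`
(monotone iff `a > 2πc/p`, enforced); i.i.d. per-scan m/z jitter
`mz·(1+ε)`, `ε ~ N(0, ppm·10⁻⁶)`; per-run log-normal peak amplitudes
`exp(μ + N(0, σ))`; Gaussian chromatographic peaks (sd 5 s, truncated
at ±4 sd, one centroid per compound per scan); optional vDIA MS2
fragments emitted into the window covering the precursor, scaled by
their intensity fractions.  Two marker regimes: *exclusive* (markers
only in their own class — a separable problem) and *soft* (markers
everywhere, fold-change higher in their own class — a harder problem
used where headroom for improvement is needed).  Instruments are
assigned round-robin so each measures an approximately equal share of
every class.  Per-run RNG streams derive from (seed, run index) via a
splitmix64 finalizer chain, so datasets are bit-reproducible and runs
independent.

Deliberately not modelled: isotope patterns, adducts, chemical noise
floors, column bleed, detector saturation.  Passing tests therefore
demonstrate the *computational* properties of the workflow — schema
stability, alignment recovery, conservation, learning dynamics — not
that any particular food matrix is classifiable at a given accuracy;
real-matrix accuracy claims would need real data.

Synthetic experiments use an MS1 band of 100–600 Da with compounds in
110–590 Da (the full 100–1500 Da instrument scheme with its six
isolation windows — targets 150/250/350/450/750/1250 Da, detection
ranges 50–225 … 104–1555 Da — is a constant used wherever the real
geometry matters, e.g. grid arithmetic and fusion).  Reference scales:
the end-to-end study is 3 classes × 30 samples on two instruments
offset −10/+10 s, 5 markers/class over 20 background compounds, 3 ppm
jitter, σ = 0.3, 300 s runs at 1 scan/s; the continuous-learning study
is 3 classes with 5 initial + 10 extension + 8 held-out samples per
class in soft mode (fold 2.5, σ = 0.5), 200 s runs at 2 s intervals,
ten seeds; screening calibrations run 2-class, 6-per-class datasets at
the same reduced scale.

## Numerical choices

- Half-open bucket and profile-bin intervals, top m/z bucket closed.
- Chain-repair merge radius 2×ppm (rationale under peak detection).
- Warp knots from diagonal DP moves only; strictly increasing sample
  knots guaranteed by construction; linear end extrapolation.
- Alignment fails loudly when no scan pair reaches similarity 0.05.
- Intensity-weighted means use a 10⁻¹² weight floor so zero-intensity
  centroids cannot produce 0/0.
- ANOVA zero-effect guard: factor sum of squares below 10⁻¹² of total
  → F = 0, p = 1 (identical responses otherwise yield 0/0 noise).
- The DP inner loop is JIT-compiled with numba when importable, with
  an identical pure-Python fallback.

## Known limitations

- No numerical parity with the original xcms/obiwarp implementations
  is claimed: the peak detector omits the CWT stage and the aligner is
  a simplified re-implementation with the published gap defaults.
- Screening responses obtained from a single dataset share its
  sampling noise across combinations; the F-test's independence
  assumption then does not hold exactly and significance on one
  dataset should be read as screening, not confirmation.  The type-I
  calibration test therefore draws an independent null dataset per
  response, where the machinery is exact.
- ISTD_add assumes the standard's summed signal is comparable across
  runs; it is kept for completeness, not recommended.
- Case weights enter as scikit-learn sample weights (weighted impurity
  and OOB votes) rather than bootstrap sampling probabilities; the
  class-balancing effect is equivalent in expectation, the tree-level
  mechanics differ from weight-aware bootstrap draws.
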
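# Methods

This note records the models, algorithms, parameter conventions and design
choices behind `msikit`, in the spirit of the methods documentation of
mature scientific packages. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

An `MSIDataset` holds a feature × pixel intensity store, a pixel table
(`run`, `x`, `y` plus annotations) and a feature table keyed by m/z.
Coordinates are 0-based integers on a per-run grid; pixel order is
row-major within a run, runs concatenated in input order. On imzML export
coordinates are written 1-based, per the format convention, and converted
back on import. Missing annotations are typed missing values (`NaN`/`NA`),
never numeric sentinels. Every processing operation appends exactly one
provenance record (name, parameters, timestamp).

m/z queries resolve to the nearest feature; ties go to the lower m/z.
Overlapping ROI rectangles with different labels are an error rather than a
precedence rule, because silent precedence invites silent mislabeling.

## Chunked map-reduce

All dataset-level reductions (mean spectrum, TIC, reference-peak
statistics) run through `process_in_chunks`: a per-spectrum map, followed by
a pairwise (cascade) reduction inside each chunk and across chunks. With an
associative and commutative combiner the result depends on the chunking
only through floating-point rounding; the documented and tested tolerance
is 1e-12 relative across chunk sizes and worker counts (bit-exactness
across schedules is deliberately not promised). Peak memory is
O(chunk_size × features). Worker parallelism uses a thread pool; chunk
results are combined in deterministic chunk order.

## Preprocessing

- **Smoothing** — discrete convolution with a truncated Gaussian kernel,
  renormalized at the edges so no padding values are invented and constants
  are preserved exactly. The window is expressed in samples; an even window
  is rounded up to the next odd value and the adjustment is recorded in
  provenance (MALDI-TOF workflows often quote an even window such as 8 with
  kernel sd 2; we apply 9).
- **Baseline** — the index axis is split into equal-width blocks (a typical
  high-resolution TOF setting is 750 blocks); per-block medians are
  interpolated linearly at block centers with constant extrapolation, and
  the baseline-subtracted signal is clamped at zero, since negative
  residuals would poison TIC normalization.
- **TIC normalization** — each spectrum is scaled so its intensity sum
  equals the dataset mean TIC computed before scaling; all-zero spectra are
  left unchanged and flagged in a `tic_zero` pixel column. The operation is
  idempotent.
- **Resampling** — the shared axis is geometric, `m_{i+1} = m_i (1 + ppm·1e-6)`
  from the global minimum to the global maximum; a spectrum's value in a
  bin is the mean of its samples in `[m_i, m_{i+1})` (sum is available for
  centroided input). Bins tile the range with no gaps or overlaps.

## Mass-axis correction

Alignment warps each spectrum so its apexes line up with anchor peaks of
the mean spectrum. Anchors are the most intense local maxima (default 20)
of the mean spectrum; maxima below 5% of the spectrum maximum are excluded
as noise bumps — without this gate, weak anchors match random noise maxima
within the (generous, e.g. 200 ppm) tolerance and the warp distorts peak
flanks. Matched pairs define a piecewise-linear warp; outside the
control-point hull the correction tapers linearly to zero over a 5% margin,
keeping the warp continuous and strictly monotone while remaining the
identity far from the control points. Spectra with fewer than two matches
are left unwarped and flagged. Peak positions are refined by three-point
parabolic interpolation so residuals are not limited by the sampling step.

Re-calibration fits a linear model of mass error versus m/z through the
observed positions of known internal calibrants (at least two required;
four is a typical choice) and corrects the shared axis globally. The linear
model is applied after alignment, matching the usual processing order.
A mass error linear in m/z — which includes any constant-ppm drift — is
removed exactly up to apex-localization error.

## Peak detection and integration

Noise is estimated per block as either 1.4826·MAD (Gaussian-consistent
median absolute deviation) or the block mean absolute deviation (the
"simple" estimator; we define it this way explicitly since the name alone
underdetermines it), interpolated at block centers and floored at machine
epsilon. A sample is a peak iff it strictly exceeds every earlier neighbor
and is ≥ every later neighbor within ±window samples (plateaus report
their leftmost sample; fully flat windows never fire) and its intensity is
≥ snr × local noise. Peak sets are therefore monotone non-increasing in
the SNR threshold.

Reference peaks are detected on the mean spectrum; each reference carries
its detection frequency (fraction of spectra with a local maximum within
±tol ppm — local-maximum presence rather than nonzero area, which is
robust to baseline residue) and its mean intensity. Frequency filtering
keeps peaks with frequency ≥ min_freq and mean intensity > min_mean.

Integration (peak binning) takes the trapezoidal integral over axis samples
within ±tol ppm of each reference m/z. Overlapping windows are truncated at
the midpoint between adjacent references, preventing double counting; the
number of truncated windows is recorded in provenance. We use a fixed ±ppm
window (100–200 ppm are typical published settings) rather than
integration to local minima, and document that choice here.

## Spatial weights

Neighborhoods are Chebyshev (square) balls of radius r within one run, with
Euclidean distances inside — the square-window convention of spatially
aware MSI clustering. Gaussian weights are
`α_ii′ = exp(−d²/(2σ_r²))` with `σ_r = (2r+1)/4` (the radius is the only
published parameter; the kernel scale constant is recorded here and in the
config defaults). Adaptive weights multiply α by
`β_ii′ = exp(−δ_i′²/(2λ_i²))`, where δ is the Euclidean distance between
the neighbor's and the center's spectra and λ_i is the neighborhood maximum
of δ (floored at machine epsilon), so weights respect tissue boundaries.
Weights are normalized to sum to one per pixel; with identical spectra
everywhere the adaptive weights equal the Gaussian ones.

Ion-image rendering supports Gaussian smoothing (2-D kernel, same σ_r
scale, mask-normalized at missing pixels), adaptive/bilateral smoothing,
contrast suppression (clip at the 99th percentile, configurable, then
min-max), histogram equalization (rank-based, uniform [0,1]), and linear
(min-max) normalization — implemented as min-max; TIC-relative scaling is
the noted alternative. A constant image has a degenerate range and is
rendered as zeros with a flag.

## Spatial shrunken centroids

Model equations follow the nearest-shrunken-centroids family:

    d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0)),    m_k = √(1/n_k − 1/n)
    d′_kj = sign(d_kj) max(|d_kj| − s, 0)
    x̄′_kj = x̄_j + m_k (s_j + s0) d′_kj

with s_j the pooled within-class standard deviation, s0 the median of the
s_j. The −1/n convention matches the variance of (class mean − overall
mean). Spatial information enters through one mechanism only: the pixel
spectrum is replaced by its weighted neighborhood average before scoring,
identically in segmentation and prediction, so with r = 0 and s = 0 the
classifier reduces exactly to a diagonal-covariance nearest-centroid rule
(this equivalence is asserted against an independent oracle in the tests).
Class priors are updated from class sizes each iteration, floored at
1/(10n); scores include the −2 log π_k term; per-pixel probabilities are
∝ exp(−score/2).

Segmentation initializes labels by seeded k-means on a 10% pixel subsample
(standardized features), then alternates model computation and assignment;
ties in the arg-min go to the lowest class index and empty classes are
dropped. Convergence: fewer than tol = 1e-3 of labels changing, max 100
iterations. Label cycles (which can arise when spatial smoothing makes
region-boundary rows their own quasi-segments) are detected by hashing the
label vector; on a repeat the best-objective configuration seen is kept.
A list of shrinkage values is fitted as a warm-started path in ascending s,
each fit starting from the previous fit's labels — the standard
regularization-path treatment, which keeps the segmentation stable along
the grid and makes the surviving-feature count non-increasing in s.

Grouped cross-validation partitions the levels of a fold unit (e.g. tissue
cores) — never pixels — as evenly as possible after a seeded shuffle.
A per-fold rebinning hook lets reference peaks be rebuilt from each fold's
training spectra only. Accuracy is pixel-level, pooled over held-out folds;
ties are broken toward the smaller model (larger s, fewer components).

## Spatially-aware DGMM

Single-ion segmentation runs EM on a univariate Gaussian mixture whose
mixing proportions vary per pixel:
`π_ik = (Σ_i′ w_ii′ γ_i′k + a)/(1 + k a)` — spatial smoothing of the
responsibilities with Dirichlet pseudo-count a (default 1e-2). This
responsibility-smoothing form is the implemented variant of the spatial
prior. Component means initialize at the (2q−1)/(2k) quantiles with seeded
jitter; σ is floored at 1e-6 × intensity range (flagged when hit). Optional
deterministic annealing raises responsibilities to 1/T, T falling
geometrically from 2 to 1 with ratio 0.9. The log-likelihood is recorded
each E-step; it is non-decreasing in the non-annealed phase (asserted in
tests within 1e-9 relative — the π update is not a textbook EM step, so
this is verified rather than assumed). With r = 0 and a → 0 on
well-separated data the fit coincides with a standard Gaussian-mixture EM
(checked against an independent implementation in the tests).

## Class comparison, PLS-DA, PCA, co-localization

Class comparison is group-then-test: feature intensities are averaged per
biological group (sample / ROI / core), and a Welch (unequal-variance)
two-sample t-test compares group means across the two condition levels,
with Benjamini-Hochberg adjustment across features. Requiring ≥ 2 groups
per condition refuses pixel-level pseudoreplication by construction.
Zero-variance degeneracies are defined explicitly: equal means → t = 0,
p = 1.

PLS-DA regresses mean-centered intensities on the one-hot class matrix by
NIPALS PLS2 (scikit-learn's `PLSRegression`, scale=False) and predicts by
arg-max of the regressed class scores, ties to the first training class.
At full rank the fit coincides with ordinary least squares. PCA is the SVD
of the mean-centered matrix. Co-localization ranks features by Pearson
correlation of their pixel vectors with the query feature, the query
itself first at exactly 1.

## Phantom generator

The generator emulates the features of MALDI imaging data that the methods
above consume: a grid of labeled rectangular segments, per-segment Gaussian
peaks (m/z, amplitude, sd in Da) on a geometric constant-ppm axis (default
700–900 Da at 50 ppm sampling — a lipid-range window small enough to keep
tests fast), an exponentially decaying baseline, truncated-Gaussian
additive noise (intensities are nonnegative), per-pixel TIC factors,
per-spectrum constant-ppm shifts, and an optional global mass error linear
in m/z. Drift moves the m/z sampling positions (instrument-like), not the
intensities. Everything is deterministic given the mandatory seed.

What it does **not** emulate: isotope envelopes, matrix clusters,
correlated (pink) noise, detector saturation, irregular tissue outlines and
chemical gradients within a segment. Passing tests therefore demonstrate
the correctness of the algorithms under their stated models, not
performance on real tissue; the case-study accessions named in the
literature remain the appropriate integration check.

The centroided phantom variant plants group-mean intensities directly on a
small feature set, arranged as contiguous spatial bands, and is the
substrate for the segmentation/classification tests (e.g. four regions of
128 pixels on a 16 × 32 grid, one 10× enriched feature per region plus
graded weak features, noise sd 0.25 — strong but not trivial separation).

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen to exercise every code path at
desk scale: 2,000 pixels for chunk-invariance, 512 pixels for segmentation,
256 for DGMM, 200 cores × pixels for cross-validation, 1,000 simulations of
20 groups × 200 features for the type-I-error calibration. Tolerances:
chunking 1e-12 relative; oracle equivalences exact (SSC) or 1e-6/1e-8
(DGMM means, PLS vs OLS); peak-area closed form within 1%; re-calibration
residual < 10 ppm against a planted 150 ppm drift.

## Known limitations

- Processed-mode datasets must be resampled before any shared-axis
  operation; there is no on-the-fly per-spectrum interpolation.
- The re-calibration model is global and linear in m/z; per-spectrum
  lock-mass correction and physics-based (√-law) TOF calibration are out
  of scope.
- The DGMM is single-feature by design; multi-feature mixtures and Markov
  random-field priors are not implemented.
- No compression codecs, Analyze 7.5, mzML or vendor raw formats; no 3-D
  (z) coordinates; no on-disk database.
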
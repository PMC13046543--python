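# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `dynetfnc`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Data model and I/O

All algorithms consume a time-by-voxel matrix per subject (`BoldSeries`),
obtained by masking a 4-D NIfTI volume. Voxel ordering is the ascending
linear (C-order) index of the nonzero mask voxels — a pure function of the
mask, so outputs are reproducible across platforms. Data are stored float32
on disk and promoted to float64 in memory. By default each voxel's time
series is z-scored at load (`zscore=True`), the standard variance
normalization preceding ICA; pass `zscore=False` to retrieve raw stored
intensities (used by the round-trip tests). The grid is taken as given;
no resampling or other spatial preprocessing is performed — inputs are
assumed preprocessed (or synthetic).

## Synthetic data generator

The generator emulates a two-group resting-state study: M subjects
(default 24, half patients "TS", half controls "N"), T = 192 TRs at
TR = 2 s, on a 12×12×12 grid.

- **Spatial sources.** N compact difference-of-Gaussians blobs (center
  width = `blob_radius_vox`, surround 1.6×, zero integral), centers on a
  lattice with ≥ 3.5-radius separation, z-scaled over the mask. The
  zero-mean center-surround profile keeps pairwise source correlations well
  below the 0.2 artifact threshold even on small grids (a plain positive
  bump on a small grid acquires |r| ≈ 0.2 from the shared baseline). A grid
  too small for the requested count raises `PlacementError`.
- **State switching.** K distinct unit-diagonal correlation matrices
  (rank-one ±1 sign patterns, off-diagonals ±rho, default rho = 0.45, well
  separated for clustering). Each subject follows its own Markov dwell
  process: geometric segment lengths with mean `dwell_mean_trs`
  (default 40 TRs ≈ 80 s, a plausible resting-state dwell), segment states
  cycling through shuffled permutations of 1..K so every state occurs
  whenever the series holds ≥ K segments. Within a segment, time-course
  rows are zero-mean Gaussian with the segment covariance.
- **Spatial dynamics.** Per-window jitter multiplies the source maps by
  `1 + jitter · g`, with `g` a smooth unit-SD random field redrawn every 24
  TRs (the IVA window step). This gives IVA — which models per-window
  maps — signal that GICA's fixed-map model averages over.
- **Noise and SNR.** i.i.d. Gaussian noise per voxel-timepoint, scaled so
  empirical var(signal)/var(noise) equals the requested `snr`;
  `snr = inf` disables noise. No physiological, AR, or motion noise.
- **Planted effects.** (a) A group effect adds `group_delta_r` to one edge
  of one state's covariance for TS subjects (then projects back to unit-
  diagonal SPD, eigenvalue floor 0.05). (b) A clinical effect jitters that
  edge per subject (SD 0.12) and constructs the symptom score to correlate
  with the realized post-projection edge strengths at exactly the requested
  r (orthogonalized-noise construction), on the score scale mean 44.66,
  SD 17.96 (range of the motivating severity scale: 10–79); disease
  duration spans 1–12 months.

What passing tests on these data do **not** show: robustness to
physiological noise, motion, hemodynamic filtering of the state process,
non-Gaussian BOLD statistics, or realistic anatomy. The generator's role is
to verify that each estimator recovers exactly the structure it claims to
estimate.

## Group ICA (temporal route)

Subject temporal PCA (`n_subject_pcs`, default 120 at paper scale) →
concatenation → group PCA (`n_group_pcs`, default 100) → extended Infomax.
The ICA uses block-wise natural-gradient updates (block ≈ √V samples),
re-estimating sub-/super-Gaussian signs from kurtosis each pass; the
learning rate (0.05) decays ×0.9 when the per-pass weight change grows
(oscillation near a fixed point) and halves on blow-ups; convergence is a
maximum weight change < 1e-6 within 512 passes, otherwise the result
carries a not-converged flag. ICASSO reruns ICA from distinct seeds
(default 100), clusters pooled maps by 1−|r| with average linkage cut at
n_components, keeps each cluster's centrotype, and reports
iq = mean intra − mean extra similarity; clusters below `min_cluster`
(default 80) are kept but flagged unstable, never dropped. Back-
reconstruction is dual regression (the variant is not prescribed upstream;
dual regression is exact when data are a noiseless product of group maps
with any time courses). Maps carry a deterministic sign convention
(spatial skewness ≥ 0) and are z-scaled. Labeling takes the best
template |r| (ties broken by template order); below 0.2 → artifact; an
optional gray-matter screen flags components with < 0.5 of squared-map
energy inside gray matter. Spectral/temporal artifact features are not
implemented — the artifact screen is exactly these two rules.

## Temporal dynamic FNC

Rectangular (boxcar) sliding window, default width 18 TRs, step 1 TR — no
taper and no regularized covariance (a documented limitation: at paper
scale, 18 samples per window for ~54 components makes per-window
correlations noisy; on the synthetic problems N ≤ 10 so the plain Pearson
estimate is adequate). Window w covers rows [w·step, w·step+width).
Correlations are Fisher z-transformed before clustering and statistics.
Exemplars are strict local maxima of the per-window FC variance (endpoints
count against their single neighbor; constant sequences fall back to the
first global maximum). Two-stage k-means: k-means++ (n_init = 10, seeded)
on exemplars, then refinement over all windows from those centroids. For
k = "auto", the within/between cluster-distance ratio is evaluated on the
exemplars for k = 2..10 and the elbow is the point of maximum discrete
curvature. Occupancy metrics per subject and state: window count,
membership flag (≥ `min_windows`, default 10), and mean dwell (average
consecutive-run length). Both total windows and mean dwell are computed;
the statistical stage uses total windows as the "state duration" feature
(the upstream definition is ambiguous; this interpretation is flagged
here).

## IVA-GL (spatial route)

Windows: length 48 TRs, 50% overlap, validated so the last window ends
exactly at T (192 → L = 7); each window is demeaned and variance-normalized
per voxel. Whitening is strictly linear (no mean removal), so the SCV
identity y = (W P) x holds exactly. Both IVA stages minimize
Σₙ E[−log p(yₙ)] − Σ_d log|det W_d| by relative-gradient updates
ΔW = η (I − E[φ(y) yᵀ]) W with backtracking (a step is accepted only if the
cost does not increase; η halves otherwise, grows ×1.2 on success, cap 1);
convergence at max |I − E[φ yᵀ]| < 1e-6 within 1024 iterations, else a
flagged result. IVA-G uses the Gaussian score Σₙ⁻¹ yₙ (second-order,
exploits cross-dataset covariance); IVA-L the multivariate-Laplacian score
y/√(Σ_d y² + ε), ε = 1e-12. IVA-GL runs IVA-G from a seeded random
orthonormal start and refines with IVA-L initialized at the IVA-G rotations.
Signs are aligned within each SCV to the first dataset. Component count
defaults to 20 at paper scale (tests use ≤ 6). SDC screening ranks
components by best template |r| of the SCV-mean map and keeps the top
`keep` (default 9) — an automated stand-in for visual inspection,
documented as such.

Known estimator property (measured, see the decisions around the
acceptance suite): on image-like blob sources with flat background the
Laplacian-prior cost minimum is not exactly at the generating demixing, so
the joint ISI against the true window mixings plateaus near 0.2 even when
SCV mean maps correlate ≈ 0.88 with the generating sources. ISI is
therefore validated on sources actually drawn from the assumed priors
(where it reaches < 0.02), and recovery on image-like data is validated by
map correlation.

## Normalized mutual information

Equal-frequency (rank) binning with n_bins = max(8, ⌊V^{1/3}⌋) (requires
V ≥ 10·n_bins²), joint-histogram MI with Miller–Madow correction
I ← I + (m_x + m_y − m_xy − 1)/(2V), floored at 0, then
r* = √(1 − e^{−2I}). The floor makes analytically independent inputs
(factorizing joint histogram) report exactly 0; the mapping equals |ρ| for
bivariate Gaussians and stays in [0, 1). Rank binning makes the estimate
invariant to strictly monotone transforms of either map. Diagonal entries
are reported as 0 by convention. Edge variability is the sample SD
(n−1 denominator) across the L windows; group matrices are means of member
subjects' SD matrices. The KL-divergence-based map-change metric sometimes
discussed alongside this analysis has no defined estimator upstream and is
not implemented.

## Statistics

Two-sample t is pooled-variance (Student) by default with a Welch switch
(`equal_var=False`). Mann–Whitney U uses the exact null distribution (count
recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1)) for tie-free samples
with combined n ≤ 20, otherwise the normal approximation with tie
correction and continuity correction; fully tied input returns p = 1.
BH-FDR is the step-up procedure with monotone q-values (cumulative
minimum); rejection is q < α. For per-state comparisons, a subject's state
feature is the Fisher-z mean of its in-state window correlations; subjects
under the 10-window membership rule are excluded, states with < 2 members
in either group are skipped with a logged reason, and the FDR family is the
edges within one state (a global family is available via
`fdr_family="global"`). Clinical correlations are two-sided Pearson r,
applied only to features flagged significant by the group comparison. All
tests are two-sided. No covariate adjustment is performed.

## Pipeline and reproducibility

Stages simulate → gica → tdfnc → iva → sdfnc → stats run from one YAML
config; every stage persists its intermediates, so stage subcommands
compose byte-identically with `all`. One global seed is fanned out through
`numpy.random.SeedSequence([seed, stage_index])`. A manifest (version,
seed, full config, stage timings) is written on every run, including
failures. Config defaults equal the motivating study's stated settings.

## Problem sizes used in tests and acceptance

The shipped suites run on scaled-down problems chosen to exercise every
code path with stable statistics: cohorts of 6–24 subjects, 12³ grids,
4–6 components, 5–10 ICASSO runs, 100-replicate power runs at n = 12 per
group, and 200-replicate FDR calibration at 1000 edges. Paper-scale
defaults (100 components, 100 ICASSO runs) are exercised for their
parameter plumbing, not re-estimated in tests.

## Limitations

- No head-motion, slice-timing, drift, or physiological-noise simulation;
  no spatial normalization or resampling.
- Window-level Pearson estimates are unregularized.
- The artifact screen is template correlation + gray-matter energy only.
- Auto-k searches 2..10 and assumes an elbow exists; degenerate validity
  curves fall back to the minimum-ratio k among candidates.
- The MI estimator's histogram bias is only first-order corrected; very
  small V with many bins is rejected rather than estimated.
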
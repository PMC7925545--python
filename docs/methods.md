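# Methods

This note documents the statistical procedures implemented in `taphos3d`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic fixtures do and do not establish about real data.

## Data model

Marks live on triangulated bone meshes expressed in a canonical anatomical
frame per element: x runs longitudinally from the distal end (x = 0) to the
proximal end (humerus 250 mm, femur 280 mm, radius-ulna 300 mm, tibia
350 mm); y runs lateral → medial, z caudal → cranial.  Circular marks (tooth
pits, percussion marks) are one landmark; linear marks (scores, cut marks)
are three ordered landmarks, and only the middle point serves as the mark's
reference coordinate in all statistics.  Left-side material is mirrored
across the sagittal plane (y ↦ −y) before any bilateral comparison, so that
lateral/medial semantics coincide between sides.  Mirroring is this
package's convention for left/right co-registration; no claim is made that
it corrects for true antimeric shape asymmetry.  A recorded landmark is
considered valid when it lies within 2 mm of the mesh surface
(`SNAP_TOLERANCE_MM`): marks are placed by clicking on a rendered surface,
so larger offsets indicate a registration error, and `snap_to_surface`
projects them back (ties between equidistant faces go to the lowest face
index).  Intervals are half-open `[lo, hi)` throughout — segmentation and
binning — except the terminal interval, which closes so the bone end belongs
to the last bin.

## Observation window

Second-order statistics require a sampling window.  Marks lie on a curved
2D surface embedded in 3D, but the analysis treats them as a 3D point
process inside the axis-aligned bounding box of the reference points padded
by 1 mm (configurable).  This is a deliberate approximation: the "volume"
between the bone surface and the box boundary can never contain marks, so
absolute intensities and the F/G theoretical curves inherit a bias that is
*shared* by observed data and CSR simulations alike — envelope comparisons
remain internally consistent, but parameter values (e.g. λ) should not be
read as surface densities.  A surface-geodesic treatment is out of scope.

## Second-order estimators

All functions are evaluated on an r-grid of 512 equally spaced values
starting at 0 (default r_max = 0.25 × shortest window side, the usual
validity bound for translation corrections).

* **K3, translation correction.**
  `K̂(r) = λ⁻² Σ_{i≠j} 1(d_ij ≤ r) / V(W ∩ W_t)` with
  `V(W ∩ W_t) = Π_axes (side − |t_axis|)` for the pair offset `t`.  Pairs
  whose offset reaches a window side have an undefined weight and are
  excluded with a warning.  λ = n/V.
* **L3.**  `L(r) = (3K(r)/4π)^{1/3}`, so that CSR maps to the identity
  `L(r) = r`.  The cube root is the 3D analogue of the classical 2D
  square-root variance-stabilising transform; the identity requirement under
  CSR dictates the exponent in three dimensions.
* **G3, reduced-sample border correction.**
  `Ĝ(r) = #{i: d_i ≤ r, b_i ≥ r} / #{i: b_i ≥ r}` with `d_i` the
  nearest-neighbour distance and `b_i` the distance to the window boundary;
  reported as missing where the denominator vanishes.
* **F3, digital method.**  On a voxel grid (default 64 per axis) each voxel
  centre `u` has an empty-space distance `e(u)` to the nearest mark and a
  boundary distance `b(u)`;
  `F̂(r) = #{u: e(u) ≤ r, b(u) ≥ r} / #{u: b(u) ≥ r}`.  The CSR reference is
  `1 − exp(−λ·Vd(r))` with `Vd(r)` the *digital* ball volume (count of voxel
  -centre offsets with norm ≤ r times the voxel volume), so theory and
  estimator share one discretisation.
* **pcf3, kernel estimator.**
  `ĝ(r) = (4πr²λ²)⁻¹ Σ_{i≠j} κ_δ(r − d_ij) / V(W ∩ W_t)` with the
  Epanechnikov kernel `κ_δ(u) = (3/4δ)(1 − u²/δ²)` on `|u| ≤ δ` and default
  bandwidth `δ = 0.26 λ^{−1/3}` (the standard rule for this estimator
  family); undefined at r = 0.

**Envelopes.**  `nsim = 500` by default.  Simulations are CSR *conditioned
on the observed count* (a binomial process with the same n in the same
window); bounds are the pointwise min/max, i.e. a rank-1 two-sided envelope
whose pointwise exceedance probability under the null is `2/(nsim+1)` —
verified empirically at nsim = 39 (2/40 within binomial 3σ over 300
replicates).  For pcf envelopes the kernel bandwidth is computed once from
the observed pattern and held fixed across simulations.  Interpretation:
observed curve above the upper bound = clustering for K3/L3/G3/pcf3; the
reading is reversed for F3.

**Feature vector.**  Per pattern: the means of the observed K, F, G and pcf
curves over the finite entries of the r-grid, the mean nearest-neighbour
distance (mm), and λ.  Undefined entries (pcf at r = 0, exhausted G/F
denominators) are ignored, not imputed.

## Binned series and wavelet coherence

Longitudinal mark-frequency series use fixed binnings: humerus 25, femur
28, radius-ulna 30, tibia 35 bins over the canonical length — all 10-mm
bins — and 10 equal bins for the narrow cross-sectional axes, which are
reported as histograms only (their extent is too small to support scale
analysis, so coherence runs on the longitudinal axis alone).

Coherence of the left/right series pair follows the standard continuous
-wavelet formulation: analytic Morlet mother with ω₀ = 6; dyadic scales
`s_j = s0·2^{j·dj}` with `s0 = 2·dt`, `dj = 1/12`,
`J = ⌊log2(N·dt/s0)/dj⌋`; series are mean-centred and zero-padded to the
next power of two.  With `W_xy = W_x · conj(W_y)`,

    R²(s,t) = |S(s⁻¹ W_xy)|² / ( S(s⁻¹|W_x|²) · S(s⁻¹|W_y|²) )

where the smoothing operator `S` is a Gaussian along position with standard
deviation `s/√2` (implemented in the frequency domain; its normalisation
cancels in R²) followed by a boxcar over scale spanning `0.6/dj` scale steps
with fractional end weights.  Without smoothing R² would be identically 1;
with it, `wtc(x, x) = 1` exactly and swapping inputs negates the phase.
Phase is the argument of the smoothed cross-spectrum; **positive phase means
the first series leads** (a series shifted later by τ bins at period λ shows
phase `2πτ/λ`, verified analytically in the tests).  The cone of influence
is the e-folding scale `s_coi(t) = dt·min(t+½, N−t−½)/√2`; verdicts over
regions mostly outside the COI are flagged unreliable.

Counts are not detrended or variance-normalised before the CWT beyond mean
centring (configurable by preprocessing the series yourself); R² is
invariant to positive rescaling in any case.

**Significance.**  Pointwise 95th-percentile thresholds from `nrands = 300`
(default) surrogate pairs, each an AR(1) process matched to the
corresponding input's lag-1 autocorrelation and variance.  The type-I error
of this test under a white-noise null is ≈ 5% of in-COI cells (calibrated in
the acceptance suite with nrands = 100 over 50 replicates).  Descriptive
read-off thresholds ("strong" R² > 0.8, "moderate" > 0.6) are reporting
conventions, not tests.

## Bilateral PCA

PCA is fitted per element on the *pooled* mirrored-left + right 3D reference
coordinates (both sides must share one score plane for their ellipses to be
comparable), with explained-variance percentages reported for PC1/PC2.  Each
side's 95% ellipse is its 2D score covariance scaled by the χ² quantile with
2 df (5.991); coverage of ~95% of that side's scores is exact for Gaussian
clouds and verified by simulation.  Bilateral similarity is the Jaccard area
ratio area(∩)/area(∪) computed on 256-gon approximations (two unit circles
at distance 1 give 0.243, matching the closed-form lens area; note the
lens-to-single-circle ratio, 0.391, is a different — also defensible —
normalisation not used here).  Collinear mark sets have a degenerate
covariance and are rejected naming the offending side.

## Multi-element clustering

UPGMA (unweighted average linkage) on the Euclidean distance matrix of the
feature table, with a deterministic tie-break — merge the candidate pair
whose (min leaf label, max leaf label) is lexicographically smallest — so
the tree is invariant to input row order.  Trees export to Newick with leaf
branch length equal to the parent's merge height and internal branches equal
to height differences.  `cut_tree(k)` undoes the last k−1 merges.

**Scaling.**  The API default is `scaling="none"` (clustering on original
values).  The six features, however, span six orders of magnitude (K_obs
~10⁶, G_obs ~1), so unscaled Euclidean distance is effectively a one-column
(K) clustering.  On the bundled reference table, unscaled clustering at
k = 4 mixes element sides, whereas z-scored clustering recovers exactly four
bilateral element-pure clusters.  The worked example and the acceptance
suite therefore standardise the columns (`scaling="zscore"`), and we regard
the standardised analysis as the scientifically meaningful one; the
unstandardised mode remains available for sensitivity comparison.

The reference table's intensity column is kept in its scaled print units;
because the worked example standardises columns, the unknown absolute scale
has no effect on the clustering.

## Synthetic generators

* **Phantoms**: closed surfaces of revolution — a cylindrical shaft with
  ellipsoidal end caps flaring to `end_radius_factor × shaft_radius`
  (defaults 15 mm and 1.8) — sized to each element's canonical length.  They
  reproduce the gross geometry a window/binning pipeline needs (correct
  length, flared ends, watertight triangulation), *not* real bone anatomy:
  no crests, tubercles, curvature or antimeric asymmetry.
* **CSR / Thomas / hard-core** processes provide the null and the two
  canonical alternatives.  Thomas offspring falling outside the window are
  discarded (not wrapped) — adequate for fixtures; the induced edge bias is
  irrelevant to detection tests.  Hard-core uses sequential dart-throwing
  (fixed n is convenient for testing) rather than Matérn thinning.
* **Lion-like** patterns choose a longitudinal region (distal end / distal
  shaft / midshaft / proximal shaft / proximal end at 15/20/30/20/15% of
  length) by a per-element weight table, then sample uniformly on the
  phantom surface within it.  The default tables encode the qualitative
  felid pattern — heavy proximal ends, near-empty midshafts — and are
  declared fixtures: they are NOT estimates from any empirical dataset.

Consequently, passing tests demonstrate the *statistical machinery* is
correct and calibrated; they do not validate any substantive claim about
carnivore behaviour, which requires real mark coordinates.

## Problem sizes and numerical choices

The validation suites run at deliberately modest sizes chosen to exercise
every code path at stable Monte Carlo tolerances: CSR closed-form checks use
20 seeds of n = 150 in a 100×30×30 mm box with a 128-value r-grid and a
32-voxel F grid; envelope calibration uses 300 replicates of n = 20 at
nsim = 39; detection experiments use nsim = 99 envelopes over 20 seeds;
coherence calibration uses series of length 32 with 100 surrogates over 50
replicates.  Defaults for real analyses remain 512 r-values, nsim = 500,
nrands = 300, 64-voxel F grids.  Tolerances follow from the null
distributions (binomial 3σ bands for rates and coverages; 10%/0.05 bands for
curve agreement at these sample sizes).

Degenerate inputs are errors, not silent results: constant series for the
CWT, patterns with n < 2 for pair statistics, collinear sides for ellipses,
coarse (< 8³) F grids, hard-core packings that exhaust their proposal
budget.

## Known limitations

* The box window treats surface points as a volume process (above).
* Envelope tests are pointwise, not global rank envelopes; reading "above
  anywhere" as detection inflates the global type-I error, which is why the
  calibration is stated and tested pointwise at fixed r.
* AR(1) surrogates capture first-order autocorrelation only; count series
  with strong overdispersion may need tailored nulls.
* The Newick export encodes merge heights directly as depths (leaves sit at
  depth = their parent's merge height), which suits dendrogram comparison
  but is not an ultrametric in the height/2 convention some tools use.
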
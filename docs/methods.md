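# Methods

## Analysis model

The pipeline treats resting-state functional connectivity as a weighted,
undirected voxel graph. For one subject, the edge weight between voxels
*i* and *j* is the Pearson correlation of their cleaned BOLD series;
negative correlations are set to zero rather than removed from the edge
list (their interpretation is contested, and zeroing keeps the metric
sums defined over a fixed voxel set), and the diagonal is forced to zero
so self-connections never contribute. Three per-voxel raw sums are
computed from this matrix:

* weighted degree `WD_i = Σ_j adj(i,j)` over all grey-matter voxels
  (whole-brain scope);
* integration `I_i = Σ_{k ∉ net(i)} adj(i,k)` and segregation
  `S_i = Σ_{l ∈ net(i)} adj(i,l)` over isocortical voxels only, with
  network membership given by a seven-network parcellation (visual,
  somatomotor, dorsal attention, ventral attention/salience, limbic,
  frontoparietal, default mode).

The sums are deliberately not normalized by voxel count — they are
comparable across subjects because everyone shares one template grid, and
cross-subject scale is handled by the healthy-control normalization. The
identity `I + S = WD` (on the isocortex-restricted matrix) is exact by
construction and is enforced by tests to 1e-12.

### Preprocessing

Functional denoising operates on masked voxel series in a fixed order:
confound regression, band-pass filtering, then scrubbing/volume
selection. The confound design holds an intercept, 6 rigid motion
parameters with their backward derivatives, linear and quadratic trends,
and 5 principal components from each of two nuisance-tissue voxel sets
(lateral-ventricle and white-matter stand-ins; real tissue segmentation
is out of scope, so the sets are designated out-of-mask regions). The
band-pass is a zero-phase (forward-backward) 4th-order Butterworth,
0.01–0.08 Hz; the contract is the frequency response (pass-band amplitude
within ±10 %, ≥ 90 % attenuation at 2× the upper edge, no phase shift),
not the filter family. Framewise displacement uses the Power convention,
FD_t = Σ|Δtrans| + 50 mm · Σ|Δrot|, and a volume is scrubbed when the FD
of its incoming transition strictly exceeds 0.5 mm; only the terminating
volume is removed. Runs are concatenated after scrubbing and the first
120 surviving volumes retained; subjects with fewer than 120 are excluded
with reason "motion". Scrub-after-filter was chosen over
interpolate-before-filter as the minimal reading of the procedure; the
order is pinned by a regression test because the two do not commute.

### QC and normalization

Subject exclusion is two-stage and order-sensitive: motion first (the
120-volume rule), then a weighted-degree outlier rule — subjects whose
mean whole-brain WD falls outside the Tukey fences (quartiles by linear
interpolation, type 7; fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR, strict
comparison) over the remaining subjects are excluded. Age and sex (coded
0/1) are then removed per voxel by OLS fitted on the pooled included
sample — pooled rather than HC-only because the stated order ("removed
the effect … and then normalized") implies one model over participants;
an `hc_only` flag switches the convention. Finally every subject's map is
z-scored against the HC per-voxel mean and sample SD (n − 1 denominator).
Voxels with zero HC SD are flagged and zeroed for everyone.

### Group inference

Per voxel, the normalized value is regressed on an intercept, a group
indicator and nuisance covariates (SSRI/SNRI use by default; age and sex
are already removed upstream), and the group t statistic is mapped
through the t→normal quantile transform at the residual df.
Suprathreshold voxels (|z| > 1.96, positive and negative kept separate)
form clusters under 26-connectivity. The Monte Carlo clusterwise
correction is realized as a group-label permutation null: each of 10 000
iterations (defaults; the validation suites use 1000) permutes the group
indicator across the contrasted subjects while covariates stay attached
to their subjects, recomputes the t-map in closed form, and records the
maximum suprathreshold cluster extent over both signs. Corrected p uses
the +1 convention, p = (1 + #{null max ≥ extent}) / (1 + n_iter), so p is
never zero and the test is exact-level under exchangeability. Permutation
was chosen over smoothness-matched Gaussian-field simulation because it
is data-adaptive and needs no smoothness estimate; threshold, iteration
count and alpha follow the published parameters. Healthy controls never
enter a contrast; they only define the normalization scale. Thresholding
inside the permutation engine happens on the t scale at the t value
equivalent to the z threshold, which yields the identical suprathreshold
set without per-iteration quantile transforms. Intersection maps are
voxelwise ANDs of corrected masks across analyses or covariate
adjustments.

### Seeds and symptom correlations

One seed per hemisphere (hemispheres split at the affine x = 0 plane)
sits on the peak-z voxel of the corrected integration contrast inside the
intersection mask; ties break lexicographically on the grid coordinate.
The "3 mm spherical" ROI at 3 mm resolution is implemented as the
3×3×3 Chebyshev neighbourhood because the printed member count (27) is
taken as normative — a Euclidean 3 mm ball on a 3 mm grid would hold 7
voxels. Edge seeds are kept, truncated and logged. Seed-to-voxel maps are
Fisher-z transformed correlations of the seed-mean series with every
isocortical non-member voxel (|r| clipped to 1 − 1e−7 before atanh); the
group contrast reuses the clusterwise machinery, and the network
composition counts significant voxels with a *positive* group effect
(the reported direction is increased connectivity) over the six networks
other than the seed's own, the seed's network being defined by the peak
voxel's label.

Cluster-mean symptom correlations are Spearman (mid-ranks; p from the t
approximation at n − 2 df, exact permutation enumeration available behind
a flag for n ≤ 10), run for the documented cohort combinations — SDQ-20
and PHQ-15 within FND cohorts (mixed, motor, seizure), PHQ-15 only for
combined FND + PC samples — with 1.5·IQR outlier removal applied to the
connectivity variable only (per cluster × metric × cohort pair; the
symptom scores are not filtered) and Benjamini–Hochberg FDR within each
(cohort pair, metric) family. Missing scores drop pairwise.

## The synthetic generator

`voxelgraph.synthetic` emulates the covariance geometry the analysis
consumes, nothing more. The brain is the ellipsoid inscribed in the grid
(3 mm isotropic affine centred on x = 0); a balanced region-growing
partition gives seven spatially contiguous networks plus, by default, a
contiguous 10 % "non-isocortical" region labelled 0 that exercises the
whole-brain vs isocortical distinction. In-mask signals are multivariate
normal with correlation `base_within_corr` (default 0.3) on same-network
pairs and `base_between_corr` (default 0.1) otherwise — values in the
range typical of band-passed resting-state data. Effects add
`delta_corr` to edges touching a target region (between-network,
within-network, or all edges), optionally scaled per subject by a
standardized covariate (the monotone symptom link). Observation noise
(`noise_sd`, default 0.1) and a weak loading (0.07) on the first factor
of each of two out-of-mask nuisance blocks ("ventricle", "white matter" —
each 5 latent factors, the aCompCor targets) are added on top, so
confound regression removes something real. Motion tables carry
sub-threshold jitter plus a configurable number of 0.8 mm translation
steps (rotations held at zero — the simplest arithmetic that still
exercises scrubbing). Everything is deterministic under
(config seed, subject id).

Two design points deserve emphasis:

* **Feasibility of injected effects.** A uniform correlation increase of
  one region to all other-network voxels is not in general a valid
  correlation matrix — the perturbation has a negative eigenvalue of
  order delta·√(|region|·|targets|). When the target matrix loses
  positive semidefiniteness it is repaired by *constrained* alternating
  projections that pin the untouched edge class exactly (within-network
  entries for a between-network effect, and vice versa) and let the
  touched class absorb the adjustment. Consequently the realized delta
  can be smaller than requested (about half, at the validation geometry)
  and spills mildly onto other between-network edges, but the
  complementary metric is untouched by construction — which is precisely
  the dissociation the validation tests assert. `build_subject_target`
  exposes the realized matrix so tests can oracle against it.
* **Subject-level heterogeneity.** Each subject draws a global
  connectivity scale g ~ U(0.92, 1.0) and samples from gR + (1 − g)I
  (always PSD). This gives the healthy controls a between-subject SD
  beyond pure sampling noise, making the HC normalization scale
  meaningful.

Empirical correlations are attenuated relative to the target by
approximately g/(1 + noise_sd² + nuisance variance) — under the defaults
about 3–6 % — and tests that oracle empirical correlations either
account for this or switch the noise sources off.

What the generator does **not** emulate: haemodynamics, spatial
autocorrelation of scanner noise, physiological confounds, multi-site
effects, realistic anatomy. Passing tests therefore demonstrate the
statistical machinery — estimator correctness, error control, recovery
under the assumed covariance model — not robustness to the full
complexity of real fMRI.

## Validation suites and problem sizes

The reference results of the original design derive from restricted
clinical data, so validation is property-based, at sizes chosen to keep
the full suite in the minutes range on one CPU: the decomposition
identity over 200 random matrices of 50–500 voxels; the normalization
audit on a 30-HC cohort (10³ grid); familywise error over 500 null
cohorts of 30 + 30 subjects on a 12³ grid with 1000 permutations each
(null maps are generated directly at the normalized-map level as
unit-variance smoothed Gaussian fields, σ = 1 voxel — the mild smoothness
real z-maps carry, and the level at which group inference operates);
effect recovery with 30 subjects per group, a 100-voxel region and
delta 0.2; and symptom-correlation power/size over 500 replicates at
n = 100 with the generator's default link (population Spearman ρ ≈ 0.35).
`scripts/acceptance.py` recomputes all of these from a single seed.

## Numerical conventions and edge cases

Voxel coordinates are 0-based C-order indices; world space appears only
through the NIfTI affine. Zero-variance voxels get zero connectivity
rows and a QC listing. Rank-deficient confound or covariate designs drop
dependent (or constant) columns with a warning; a singular *contrast*
design aborts. Permutations that make the group column collinear with a
binary covariate are handled by pseudo-inverse (contributing a zero
t-map) rather than aborting the null. Quartiles are type 7 everywhere.
Cluster-extent ties and z-ties at seed peaks break deterministically
(extent sort is stable; peaks break lexicographically). With fewer than
4 subjects, outlier rules are skipped with a warning rather than
computed from unstable quartiles.

## Known limitations

Dense voxel×voxel matrices bound the practical mask size (a blocked
row-stream path exists for the correlation computation, but the metric
sums still materialize the matrix per subject); the generator's
block-constant covariance is far simpler than real connectomes; the
permutation null assumes exchangeability of the contrasted subjects
under the null (covariate imbalance is adjusted in the model, not in the
permutation scheme); and the realized size of large injected effects is
feasibility-limited as described above.
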
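# Methods

This note documents the models, numerical choices and validation strategy
behind `tbinet`, in the spirit of a package's methods appendix: what each
stage assumes, which knobs matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Hierarchical multimodal parcellation

**Model.**  ROIs are leaves of an average-linkage (UPGMA) dendrogram built on
a dissimilarity matrix: `1 − fc` for the functional tree and `1 − binary(sc)`
for the structural tree (a weighted option log1p-scales and min-max-
normalizes raw streamline counts first).  Cutting a tree at level *M* yields
a partition into exactly *M* modules; cuts are nested across levels by
construction (`scipy.cluster.hierarchy.cut_tree`).  Merge ties follow
scipy's deterministic nearest-neighbor-chain order, so the tree is a pure
function of its input.

**Cross-modularity.**  A level is scored by
`X(M) = (Q_s · Q_f · ⟨S⟩)^{1/3}`, clipped to 0 when any factor is
nonpositive.  `Q` is Newman's modularity evaluated (not optimized) on the
given cut.  The functional graph entering `Q_f` and the edge-set comparison
is the binary graph of the strongest correlations, **density-matched** to the
structural edge count: this puts the two modalities on a common footing and
makes `⟨S⟩ = 1` exact when both encode the same block structure.  `⟨S⟩` is
the symmetrized mean (both matching directions averaged) of each module's
best-match Sorensen similarity between intramodule edge sets; modules with
empty edge sets contribute 0.  The geometric mean is our combination rule for
"simultaneously accounting" for the three factors; the original atlas's exact
formula lives in external code we deliberately do not copy, so recovery on
synthetic block structure — not bit-identity with the published atlas — is
the validation surface.  Ties in `select_optimal_level` break toward the
smallest *M* (the coarser, more parsimonious parcellation).

## Group statistics

The design matrix uses cell-means coding (one indicator per group, no
intercept) followed by mean-centered covariates; contrasts are
`[1 0 …]` (control mean), `[0 1 …]` (TBI mean) and `[±1 ∓1 0 …]`
(directional differences).  The GLM contrast t equals the classical pooled
two-sample t when no covariates are present (asserted to 1e-10 against the
closed form).  Permutation p-values shuffle subject labels, refit the
covariates each time, and use the add-one estimator
`p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm)`, which cannot return zero;
the default is 1,000 permutations and features with `p ≥ 0.05` are flagged
as discarded.  Whether the original analysis pooled a maximal statistic
across modules is unknowable from the text; the per-module null with the
discard rule is implemented.

Hedges' effect size uses `g = J · t · √(1/n₁ + 1/n₂)` with
`J = 1 − 3/(4·df − 1)`; this reproduces the published effect-size values
from their printed t statistics to within one unit of the 4th decimal
(the residual is printed-t rounding).  The exact gamma-function correction
was evaluated and agrees less well, so the standard approximation is kept.
Published confidence-interval columns for these effect sizes are not
reproducible by any standard formula we tested (some do not bracket the
point estimate) and are ignored; intervals here are the normal approximation
`g ± 1.96·se(g)`, `se(g) = √((n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)))`.

`adjusted_association` residualizes both variables on the covariates by
default; the brain–behavior analysis residualizes the imaging descriptor
only ("corrected variance"), because the behavioral score enters raw in
that analysis' definition.  Both modes are exposed.

## Structural networks

SC matrices are binarized (1 where any streamline exists), the diagonal
forced to zero.  At a given level, inter-module weights count binary ROI
links crossing module boundaries; intra-module links are kept separately and
excluded from module degree (degree = links "ending in a different" module).
The handshake identity (degree sum = 2 × inter-module links) and exact
fine-to-coarse aggregation consistency are asserted in the tests.  The
structural motion covariate is the mean eddy-correction displacement; the
functional stages use mean framewise displacement.

## Module dynamics

The representative timecourse is the first principal component of the
module's voxel series (columns centered; sign fixed so the component
correlates nonnegatively with the module-mean timecourse — the sign is
otherwise arbitrary, which makes group tests on *skewness* convention-
dependent; variance, kurtosis and the peak count are sign-invariant).
Descriptors: sample variance (n−1), plain standardized 3rd/4th moments
(kurtosis of a Gaussian is 3, not 0), and the point-process count of frames
strictly above mean + 1 sample SD (Gaussian limit fraction 0.1587, asserted
at T = 10⁵).  Scrubbing replaces frames with FD > 0.5 mm by a natural cubic
spline through clean frames; flagged runs at either boundary are held at the
nearest clean value, since spline extrapolation there is unconstrained.  At
least 4 clean frames are required.

## Functional networks (MRC procedure)

Per module and subject, the voxel series is reduced to `n_pca` principal
components and unmixed by fixed-point ICA (logcosh contrast, symmetric
decorrelation — sklearn's FastICA) into `n_ica = C` unit-variance
timecourses, ordered by descending back-projection energy; everything is
deterministic given the seed (a non-converged fixed point is still a valid,
reproducible unmixing).  Spatial maps are the voxel-wise coefficients of a
*joint* multiple regression on all C components, so shared variance is
split by least squares rather than double-counted.  Pooled maps are
clustered by k-means with the 1 − Pearson-spatial-correlation distance,
realized exactly as Euclidean k-means on row-standardized maps
(`1 − corr(a,b) = ‖z_a − z_b‖²/2V`); k = 5 by default — the choice is a
config parameter because no selection criterion exists for it — with the
best of `n_restarts` initializations kept.  For group contrasts each
subject's maps within one MRC/module are averaged first, so a subject
contributes one observation (prevents pseudo-replication); subjects with no
maps in the MRC are dropped, and a whole group without maps is an error.

**Cluster-extent FWE.**  The null simulates i.i.d. Gaussian fields, smooths
them to the requested FWHM (periodic boundaries keep the field stationary),
restandardizes, thresholds at the voxel-forming p (two-sided by default;
0.005 unless configured), labels clusters under a 6-neighbor rule (18/26
available) and records the max cluster size; the reported minimum extent is
the smallest s with `P(max ≥ s) ≤ α`.  At FWHM = 0 the threshold matches an
independent-voxel brute-force oracle within ±1 voxel, and the achieved FWE
on null t-maps calibrates to 0.05 ± 0.03.  Directional difference contrasts
(`[1 −1 0 0]` vs `[−1 1 0 0]`) use one-sided forming thresholds — with
two-sided forming the two contrasts would produce identical |t| clusters and
could not be told apart.  Bit-compatibility with any particular external
cluster-simulation program is a non-goal; only the stated Monte-Carlo
contract is implemented.

## Posturography

iPL is the reciprocal of the total COP path length per 20-s, 100-Hz trial;
no vendor scaling is applied (published group means imply one, but every
analysis using iPL here is scale-invariant, so the unit choice is
inconsequential).  DC decomposes each displacement increment into its
component along the target direction and the orthogonal residual; on-target
movement sums absolute projections by default (`mode="net"` sums signed
projections — the vendor's internal definition is not public, and the choice
matters for oscillatory weight-shift paths, so it is switchable).  Only a
perfectly straight path scores 100%.  Aggregation: SOT — mean iPL over
non-fall trials within each of 4 conditions, then across conditions with
equal weights (the cross-condition rule is not specified anywhere; equal
weighting is the neutral choice); LOS — mean DC over 8 directions; RWS —
mean DC over 6 speed×direction trials.  A required condition with no usable
trial raises an error naming it.

## Synthetic cohort generator

**What it emulates.**  27 controls + 14 TBI with ages uniform on 8–19 y and
identically distributed motion in both groups (the matched design); 200 ROIs
in a nested 8-coarse/20-fine stochastic block model (within-fine p = 0.6,
within-coarse p = √(p_in·p_out) ≈ 0.17, across-coarse p = 0.05); FC from
module-coherent latent signals aligned with the SC blocks; voxel BOLD on a
24³ grid, T = 200 frames at TR = 3 s, with contiguous fine-module parcels,
supergaussian (Laplace, AR(1) ρ = 0.3) family and module latent signals and
per-voxel loadings set so the module-coherent share of voxel variance is
≈ 0.36 — which puts the cohort's PC1 explained-variance median inside the
28–54% band reported for real modules; five spatial-map families (fine
modules cycle through them); 100-Hz sway trajectories as mean-reverting
random walks (SOT), noisy ramps (LOS) and noisy sinusoids (RWS).

**Planted effects** (all in an `EffectSpec`, all recorded in the ground
truth): degree deficits in named coarse modules and a surplus in one
"prefrontal" fine module, realized by shifting the relevant Bernoulli edge
probabilities by exactly d standard deviations of the module-degree
distribution; a variance surplus realized by shifting the TBI log-amplitude
of the planted module's latent signal by half of d times the total
log-variance spread (subject heterogeneity s = 0.15 plus the finite-T
sampling term 2/T_eff, T_eff = T(1−ρ)/(1+ρ)); a TBI-only recruitment blob
(a sphere at the prefrontal parcel's centroid) whose voxels additionally
load on one family's latent signal; and a behavioral coupling parameterized
as the planted partial correlation (default −0.85) between the module's
*realized* PC1 variance and the target iPL, with sway step size solved from
the target path length (E‖step‖ = σ√(π/2) per 10-ms step).  Defaults: both
degree effects and the variance effect near d ≈ 1 and the study's cohort
sizes — chosen once as the regime the emulated findings describe.

**What it does not emulate.**  Biophysical BOLD (hemodynamic responses,
physiological noise spectra), realistic tractography error models,
distance-dependent connectivity, lesion heterogeneity, or vendor
posturography internals.  Passing tests therefore demonstrate that the
*inference machinery* is correct and calibrated under a faithful abstraction
of the study design — not that the pipeline would reproduce any particular
patient dataset.

## Validation scale and test design

The acceptance suite runs three tiers, sized to complete in minutes on one
CPU: (1) exact worked examples (effect sizes from printed t statistics, the
pooled-t balance example, the DC = 100% anchor); (2) calibration — 500
zero-effect cohorts at a reduced scale (24 ROIs, 6³ grid, 40 frames,
n_perm = 200) for the structural/dynamics/MRC stages, permutation-p
uniformity by KS test, and 200-rep cluster-extent FWE calibration on a 12³
grid; (3) planted-effect recovery on six replicate cohorts at the study's
cohort sizes with 120 ROIs, a 12³ grid and 150 frames — the package's
validation scale — asserting majority recovery of the deficit/surplus/
variance modules with the correct signs, the TBI-only surviving frontal
cluster, atlas-level recovery on block-structured pairs (≥ 19/20 seeds),
and the behavior coupling estimate within ±0.1 of the planted value.  All
stochastic tests run under fixed seeds chosen before their outcomes were
inspected.

## Known limitations

- The cross-modularity combination rule and the structural dissimilarity are
  documented stand-ins for choices the original atlas made in unpublished
  code; different rules shift X's absolute scale (comparisons across M are
  what matter here).
- Group tests on skewness inherit the PC sign convention.
- The permutation null is per-module; a pooled maximal-statistic variant
  would be stricter under many-module scans.
- The cluster-extent null assumes stationary Gaussian smoothness supplied as
  a parameter; estimating smoothness from residuals is not implemented.
- `run_pipeline` orchestrates synthetic cohorts end to end; real data enter
  through `tbinet.io` loaders and the stage functions directly rather than
  through the orchestrated config path.
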
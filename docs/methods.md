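# Methods

This note documents the models, algorithms, numerical choices and
limitations behind the package; the README shows how to run it.

## Problem setting

Registering a longitudinal infant cohort of diffusion tensor images (DTI)
to a common analysis space is hard because the brain changes rapidly in
size, shape and tissue properties over the first months of life.  Tensor
images carry white-matter orientation that scalar FA images lack, and a
*sample-specific* common space built from the data avoids the bias of a
fixed external atlas.  The package implements a two-level groupwise
scheme: scans are first clustered into homogeneous subgroups on an
image-similarity graph; each subgroup is registered groupwise to an
intermediate subgroup tensor template; the subgroup templates are then
registered to the final sample-specific common space; and each native
scan reaches the final space through its composed transform chain with a
single interpolation.

## Data model

A `TensorVolume` is a 3-D voxel grid of symmetric positive-definite 3x3
diffusion tensors (6 unique components in NIfTI lower-triangular order
`Dxx, Dxy, Dyy, Dxz, Dyz, Dzz`, units mm^2/s) with a voxel-to-world
affine (RAS+, 0-based indices).  Tensors are stored and manipulated in
the world frame; a dialect flag on the reader accepts DTI-TK-style
upper-triangular component files.  Eigenvalues are clamped to a floor of
1e-12 mm^2/s before any log-space or FA computation, so noise- or
interpolation-induced indefinite tensors never break the matrix
logarithm.  FA is `sqrt(3/2) * ||lambda - mean|| / ||lambda||`; MD is
`trace / 3`.

## Image similarity and clustering

Scans are rigidly pre-aligned to an initial target (the cohort medoid by
FA distance, translated so its MD center of mass sits at the grid
center — an automatic surrogate for manually nudging a template to a
standard origin).  The FA and MD maps of the aligned scans give pairwise
Euclidean distances `d_FA`, `d_MD`; the similarity of a pair is

    s(A, B) = 1 / d~_FA(A, B) + 1 / d~_MD(A, B)

with `d~` the distances normalized into (0, 1].  **Normalization
choice:** `normalize_distances` offers min-max normalization (with an
eps = 1e-6 floor) and division by the maximum.  The pipeline uses
division by the maximum: under min-max the closest FA pair and closest
MD pair sit exactly at the floor and receive reciprocal weights of ~1e6,
and those two edges alone dominate the graph's total weight, which
empirically destroys community recovery; dividing by the maximum keeps
weights at the natural dynamic range of the distances while still
mapping into (0, 1].

Louvain community detection (implemented in-package) maximizes weighted
Newman–Girvan modularity at resolution gamma (default 1) in the classic
two phases — greedy node moves, then community aggregation — repeated
until the modularity gain drops below 1e-9.  The node visit order is
shuffled by a user seed and equal-gain moves keep the current community,
so a given seed always reproduces the same partition.  Age-based binning
(half-open bins at 3 and 6 months by default) and the single-group
baseline are the comparison strategies.

## Registration engine

Pairwise registration minimizes the masked mean squared Frobenius
difference between fixed tensors and transformed-and-reoriented moving
tensors (the Euclidean tensor metric); scalar mode substitutes squared
FA differences.  Cost is evaluated only where the fixed image carries
signal (MD above 10% of its robust 95th-percentile maximum; FA above
0.01 in scalar mode), with the masked voxel set capped at 12,000 by
deterministic striding.  Optimization is a coordinate pattern search
with a halving step schedule inside a 3-level image pyramid (factors 4,
2, 1) — fully deterministic, no randomness anywhere in the engine.

* **Rigid (6 dof):** 3 Euler angles + 3 translations about the fixed
  signal center of mass, initialized by center-of-mass translation.
* **Affine (12 dof):** adds 3 log-scales and 3 shears through an RQ-style
  `L = R @ U` parameterization (U upper triangular, positive diagonal),
  initialized from the rigid result.
* **Deformable:** hierarchical piecewise-affine.  At level L the fixed
  domain splits into 2^L uniform blocks per axis; each block fits a local
  affine increment (translation-only once blocks get small) on the metric
  plus a quadratic penalty tying its corner displacements to
  already-estimated neighbors; block transforms are blended into a
  continuous displacement increment by a trilinear partition of unity
  over block centers; increments are composed across levels.  A level's
  increment is halved until the local Jacobian determinant stays above
  0.1 and the masked cost does not increase, so the per-level cost trace
  is non-increasing by construction.  The tie weight (0.05) and level
  schedule were fixed on the packaged phantom.

Tensor resampling interpolates componentwise on matrix logarithms
(log-Euclidean interpolation; guarantees PSD output) and reorients each
tensor by the finite-strain rotation — the rotation polar factor of the
local Jacobian of the forward map — which preserves eigenvalues (hence
FA and MD) exactly; only interpolation perturbs them.  Out-of-field
voxels become the isotropic floor tensor.  During deformable
*optimization* the incremental local rotations are second-order and
reorientation is deferred to resampling time.

## Template construction

`build_template` is align-then-average: per stage (rigid → affine →
deformable) and iteration, every native scan is registered to the
current target, warped through its full current chain (one
interpolation), and the target is replaced by the voxelwise
log-Euclidean mean of the aligned scans (arithmetic mean in scalar
mode).  Two iterations per stage are the default; improvements beyond
two are negligible, and the packaged desk-scale comparisons use one.
The two-level run applies this per subgroup (target: centered subgroup
medoid), then across subgroup templates (target: centered medoid
template), and composes chains so each native scan is interpolated once.
Size-1 subgroups pass through as their own template with a warning.
The FA-based baseline runs the same construction in scalar mode with a
single iteration per stage.

## Evaluation battery

All metrics use the FA > 0.25 mask on the average aligned FA map (0.05
and 0.1 are the configurable whole-brain / white-matter-enriched
alternatives):

* **Dyadic coherence** kappa = `1 - sqrt((b2 + b3) / (2 b1))` from the
  eigenvalues of the voxelwise mean dyadic tensor of the aligned
  principal eigenvectors; 0 for random orientations, 1 for perfect
  alignment; sign-blind by construction.
* **sigma_FA**: voxelwise coefficient of variation (sample SD / mean) of
  FA across scans.
* **NMI** between each aligned FA map and the cohort average, from a
  joint histogram over the mask (64 bins by default; the comparison
  driver uses 32, the sqrt-rule choice for its ~1e3-voxel desk-scale
  masks, since a 64x64 histogram filled by 1e3 samples is an
  undersmoothed estimator).  The symmetric-uncertainty form
  `2 I / (H_A + H_B)` is the default: it spans [0, 1] and *increases*
  with similarity, matching how the metric is used; the literal
  joint-to-marginal entropy ratio `H_AB / (H_A + H_B)` (which spans
  [0.5, 1] and decreases with similarity) is available behind a flag.
* **Jacobian determinant** of each scan's composed chain (central
  differences; constant for affine-only chains): voxelwise mean/SD maps
  and per-scan `|mean - 1|` deformation burden.  In the comparison
  driver the composed affine determinant is divided out first, so the
  burden measures registration-generated *nonlinear* deformation (the
  warp-field Jacobian); otherwise the cross-stage growth normalization
  (a ~2x affine volume change) dominates the statistic.

Method pairs are compared on per-scan NMI and `|mean Jacobian - 1|` by
pooled-variance two-sample two-tailed t-tests with Cohen's d, a seeded
10,000-resample bootstrap 95% CI on d, and Bonferroni correction for the
three method pairs.

## Synthetic cohorts

The phantom is an ellipsoidal "brain" (MD 1.0e-3 mm^2/s) carrying three
tract systems — a midline sagittal arc (corpus-callosum-like), two
lateral near-vertical bundles, and a horizontal bundle crossing them at
roughly 90 degrees — whose prolate tensors hit a prescribed FA exactly
(for an axisymmetric tensor, eigenvalue split `d = FA / sqrt(3 - 2
FA^2)`).  Non-tract brain voxels are not empty: they carry mildly
anisotropic "parenchyma" tensors (FA 0.05–0.22, below the evaluation
threshold) with a smooth coherent orientation field shared by all
stages — real tissue is weakly anisotropic everywhere, and an isotropic
sea would hand scalar FA registration an unrealistically easy,
noise-free landscape.  The assembled field is smoothed by a 0.8-voxel
Gaussian (componentwise; convex combinations of PSD tensors stay PSD)
so the phantom is band-limited like acquired data — with
piecewise-constant fields, interpolation artifacts displace sub-voxel
registration optima.

A cohort emulates a longitudinal infant sample.  Maturation stages
differ in tract FA (defaults 0.35 / 0.50 / 0.65, myelination), in
global scale (0.80 / 1.00 / 1.15 — infant brain volume nearly doubles
over the first half year, so linear size spans about 1.4x), and in
anatomy *shape*: the brain outline elongates, the midline arc widens
and flattens, the lateral bundles migrate outward and tilt, and the
crossing bundle shifts (the `stage_shape` morph).  The shape component
matters: differences expressible as a global affine are absorbed by
every method's 12-dof stage and create no separation between one-level
and two-level registration.  Each scan is its stage phantom seen
through a random rigid transform (up to 8 degrees, 4 mm — variable
infant positioning) composed with a random smooth warp
(Gaussian-filtered white noise, 4 mm peak, 12 mm correlation length —
individual anatomy), plus Gaussian noise of SD 0.08 on the log-tensor
components inside the brain (about 8% multiplicative eigenvalue noise,
infant-protocol level; air stays empty as after skull-stripping).  Ages
are drawn from disjoint per-stage ranges ([0,3), [3,6), [6,8) months)
so age binning and similarity clustering are comparable on the same
cohort.  All randomness descends from one seed; ground truth (labels,
rigid matrices, warp fields, ages) is recorded and the generation is
bit-reproducible.

What the phantom does *not* emulate: real anatomy and cortical folding,
DWI acquisition noise (noise is added post-"fit" in log-tensor space),
susceptibility or motion artifacts, and contrast changes beyond the
FA/scale stage differences.  Passing tests therefore demonstrate the
machinery's correctness and the direction of the method effects under
controlled heterogeneity, not clinical performance.

## Problem sizes of the packaged experiments

Chosen once as desk-scale study conditions: the method-comparison cohort
has 12 scans in 3 stages on a 48^3 grid of 2 mm voxels with one
iteration per stage for every compared method; the subsampling
robustness harness (fractions 0.5–0.9, 10 stratified draws each, the
two-level vs one-level tensor methods re-run per draw) uses an otherwise
identical 20^3 cohort with the rigid and affine stages only and the
FA > 0.1 (white-matter-enriched) evaluation mask — the 0.25 mask
degenerates at that grid size — so the ~100 full pipeline reruns stay
tractable on one CPU.

## Numerical choices and degenerate inputs

* Eigenvalue floor 1e-12 mm^2/s; FA of an all-zero tensor defined as 0.
* Distance-normalization floor eps = 1e-6; all-equidistant cohorts warn
  and set normalized distances to 1.
* Louvain gain tolerance 1e-9; ties keep the current community.
* Degenerate leading eigenvalues (lambda1 - lambda2 < 1e-12 lambda1) are
  flagged; the returned eigenvector is deterministic via a
  first-nonzero-component-positive sign convention.
* Deformable Jacobian floor 0.1 via step damping; a level that cannot
  improve the cost is skipped rather than accepted.
* Empty evaluation masks, constant images in NMI, zero pooled variance
  in comparisons, and missing ages in age clustering raise errors rather
  than returning silent values.

## The FA baseline and evaluation circularity

The scalar FA baseline here is the package's own engine run on FA maps
(single iteration per stage), *not* a reimplementation of the
medium-resolution nonlinear tools historically used for scalar
registration.  This has a consequence worth stating plainly: a
deformable registration that minimizes squared FA differences is, up to
masking details, directly minimizing the across-scan FA dispersion that
sigma_FA measures and directly maximizing FA-map agreement with the
evolving mean that the NMI statistic rewards.  On the packaged cohort
the FA baseline therefore posts the best sigma_FA and NMI numbers while
generating by far the largest nonlinear deformation burden — it warps
FA values into agreement rather than recovering anatomy — and its
orientation alignment cannot be assessed at all (dyadic coherence needs
tensors).  With a weaker, strongly regularized scalar tool this
circularity is broken and FA-derived statistics degrade for the scalar
method; with an equally powered one they cannot be expected to.
Comparisons against the FA baseline should therefore lean on the
deformation burden and on orientation-based measures, and FA-derived
statistics should be read jointly with them.

## Known limitations

* The deformable model is piecewise-affine with trilinear blending, not
  a diffeomorphic flow; invertibility is enforced only through the
  Jacobian floor.
* In homogeneous image regions the deformable field is unconstrained by
  the data (aperture problem); the corner-tie penalty interpolates
  between informative regions but does not guarantee pointwise recovery
  of a ground-truth warp there.
* NMI on small masks (a few thousand voxels) with 64 bins is an
  undersmoothed estimate; it is used comparatively, never absolutely.
* The engine is designed for desk-scale volumes (tens of voxels per
  axis); clinical-resolution cohorts would need coarser pyramids and a
  compiled inner loop.
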
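# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and what its synthetic validation does and does
not demonstrate.

## Superimposition

Configurations are superimposed by generalized Procrustes analysis in
the *partial* form: each configuration is centred, scaled to unit
centroid size (CS = √Σᵢ‖xᵢ−x̄‖²), and rotated to the running consensus;
the consensus is re-estimated until its change falls below 1e-10 (100
iterations maximum). Reflections are never admitted in superimposition —
object symmetry is handled explicitly instead. Size is carried
separately as the pre-scaling centroid size in micrometres.

Object symmetry: each aligned configuration is mirrored, paired points
are relabelled, and the mirror image is rotated back onto the original.
The symmetric component is the fixed point of averaging a shape with its
re-superimposed mirror image (iterated to 1e-12, which makes the
decomposition an idempotent projection); the asymmetric component is the
remainder. All downstream shape statistics use the symmetric component
by default (switchable), since the questions concern symmetric shape;
the choice matters little for the synthetic data, whose effects are
symmetric by construction.

Before linear modelling, shapes are orthogonally projected onto the
tangent plane to the unit sphere at the consensus. At the shape
distances involved here (≤ 0.1) the projection is a sub-percent
correction; it is applied because linear models in shape space assume a
Euclidean chart.

## Thin-plate splines and sliding

The 3D TPS uses the biharmonic kernel U(r) = −r (2D: r² log r). With
this sign the bending-energy matrix B — the upper-left k × k block of
the inverted TPS system — is symmetric positive semi-definite with a
null space spanned exactly by the four affine functions per coordinate,
which the tests verify by eigendecomposition. The bending energy of a
map to target Y is Σ_c Y_cᵀ B Y_c.

Sliding follows the standard tangent-linearized protocol: per outer
iteration, B is built from the current consensus; each specimen's curve
points get one tangent direction (central differences along curve
order) and each surface point two (from the mesh normal when a mesh is
available, local neighbour PCA otherwise); the displacement restricted
to those tangents that minimizes the quadratic energy is solved in
closed form (the normal equations collapse to A[j,j′] =
(v_j·v_j′)·B[i_j,i_j′], so the solve is cheap even at 529 points);
points are then snapped back — curve points to the original curve
polyline, surface points to the specimen mesh — and the sample is
re-superimposed. Three outer iterations are the default. When the
sample declares a symmetry pairing, the displacement field is averaged
with its reflection-relabelled mirror before application, so paired
points slide jointly.

Monotonicity: total bending energy is monitored against the *initial*
consensus (a fixed quadratic form, so the sequence is well defined
across iterations). An iteration that fails to decrease it — possible
because snapping and consensus updates are outside the quadratic model —
is rejected and sliding stops with a flag. The recorded energy trace is
therefore non-increasing by construction, and honestly so: the procedure
halts rather than accepting a worse configuration. Sliding minimizes
energy toward the consensus (not the template), and surface points are
re-projected to the mesh after every iteration; both choices follow
common practice where the protocol leaves the detail open.

## Template projection

Surface semilandmarks are transferred by fitting the TPS from the
template's fixed + curve points to the specimen's homologous points,
warping the template's surface points, and snapping them to the nearest
point on the specimen's triangle soup (exact point–triangle projection,
KD-tree-culled but exact, hence mesh-resolution independent). The
template's own surface points lie on its mesh, so self-projection and
affine-specimen projection are exact to rounding — two of the test
oracles.

## Statistical battery

All permutation p-values use p = (1 + #{stat* ≥ stat}) / (1 + n_perm)
and are reproducible given a seed. When the variable count exceeds the
sample size, data are first rotated onto an orthonormal basis of their
row space — this preserves every distance and sum of squares used and
makes the permutation loops cheap.

- **Group-mean permutation test** (default 10 000 permutations): all
  individuals are re-labelled jointly; each group pair's p is the
  fraction of permuted mean-to-mean distances at least as large. Because
  one shuffle feeds every pair, the tests share a null and no
  multiplicity correction is applied.
- **RRPP Procrustes ANOVA**: sequential (type-I) sums of squares from
  multivariate least squares, F per term against the full-model
  residual; the null distribution permutes reduced-model residuals
  (the model with all preceding terms). Effect size Z is the
  standardized position of log F in its permutation distribution
  (log-transformed F is the convention for this estimator). Temperature
  is categorical throughout: three levels, no linearity assumption.
- **Trajectory analysis**: a population's trajectory is its sequence of
  cell means over the ordered temperatures. Attributes: path length
  (sum of consecutive mean-to-mean distances), direction (first
  principal component of the trajectory's means, oriented low → high
  temperature; pairwise angle reported in [0°, 180°], not folded), and
  trajectory shape (Procrustes distance between centred, unit-scaled,
  orthogonally aligned level × variable matrices). Inference is RRPP
  under the additive model population + temperature, so the permuted
  residuals carry exactly the interaction signal the attributes measure.
- **Allometry**: multivariate regression of shape on log CS; slope
  homogeneity is the RRPP significance of the log CS × population term
  after the main effects.
- **CV equality**: CV = 100·sd/mean per group; equality is tested with a
  modified signed-likelihood-ratio statistic, chi-square with
  (groups − 1) df. The likelihood is profiled under a common CV by
  alternating the stationarity equations for the group means and the
  common CV; the small-sample modification weights by n − 1 with
  unbiased variances, which simulation shows holds the 5% level to
  within [0.05, 0.07] down to n = 15 per group.
- **Mahalanobis / CVA distances**: between temperature-group means in
  the metric of the pooled within-group covariance of the first n_pcs
  principal components. Both structures use the same n_pcs; the default
  is the largest count valid for both (the 15-landmark 2D wing caps it
  at 26), overridable.
- **Plasticity comparison**: for each structure, every
  individual-to-individual distance across each temperature pair is
  computed in the Mahalanobis-sphered score space (Euclidean switchable);
  the statistic is the difference of the two structures' mean distances,
  and the null re-assigns the pooled distances to two groups of the
  original sizes (default 1000 permutations, two-sided). **Known
  limitation, by design**: pairwise distances sharing an individual are
  dependent, so these pooled distances are not exchangeable units; the
  permutation null consequently understates the sampling variance of a
  mean distance and the test is anti-conservative (empirically ~0.2–0.3
  rejection at nominal 0.05 under a true null at this design's sample
  sizes, essentially independent of dimensionality). The procedure is
  retained in its classical distance-pooling form because that is the
  method practitioners use and expect; treat small p-values as decisive only when the observed
  difference is large, and prefer the per-structure Mahalanobis
  distances themselves for effect-size reasoning. The corresponding
  calibration check in the acceptance suite documents this failure
  rather than hiding it.
- **Repeatability**: Procrustes ANOVA with individual as the factor on
  replicated configurations; reports MS_individual/MS_residual with an
  explicit infinity flag when the residual vanishes.

## Synthetic data

The generator emulates the study conditions: 3 populations × 3
developmental temperatures (16/22/28 °C) with group sizes 20/11/13,
19/20/23, 14/6/13 (n = 139); a 529-point bilaterally symmetric
half-ellipsoid "valve pair" (≈ 500 µm long) standing in for the
ovipositor, and a 15-landmark 2D wing. Each specimen is

base + population field + temperature field (+ optional interaction)
+ allometry · (log size − mean log size) + individual variation
+ landmark noise,

on the unit-CS scale, then scaled to a log-normal size and given a
uniform random rotation and translation (superimposition is genuinely
exercised). Deformation fields are smooth (sums of Gaussian bumps),
zero-mean per coordinate (pure shape), and symmetrized against the
pairing.

Default magnitudes (Frobenius norms in shape units) were fixed once, by
simulation, to behave like the study system and are not data: thermal
fields 0.05 for the ovipositor and 0.15 (3×) for the wing;
population fields 0.03; a shared allometric field of 0.2 per unit
log CS; within-group individual variation 0.07 distributed over 8
smooth fields with geometrically decaying standard deviations plus a
0.01 isotropic landmark-noise floor; sizes decreasing with temperature
(522/500/478 µm ovipositor — among-temperature spread of a few percent —
vs 2850/2500/2175 µm wing, whose size is the markedly more plastic),
with a 3.7% size CV. The low-rank structure of individual variation is
deliberate: statistics standardized by the within-group covariance
(Mahalanobis, CVA) are meaningless against an isotropic noise model,
where per-direction variance shrinks with the point count. Replicate
measurement error defaults to 1.3× the total within-group scatter per
coordinate, sized so a 2-individual × 5-replicate repeatability study
has an expected MS ratio near 4.

What passing tests show — and what they do not: the synthetic data have
exactly additive effects, Gaussian variation, exact landmark
correspondence and clean meshes. Real ovipositor data add
reconstruction artefacts, correspondence error from manual landmarking,
non-additive shape responses and line structure (an isofemale-line
random intercept is available in the generator but off by default, as
the analyses here do not model it). Calibration and recovery results
transfer to real data only insofar as those violations are mild.

## Numerical choices

- GPA convergence 1e-10 relative, 100 iterations; symmetrization fixed
  point at 1e-12.
- Rotation fits resolve reflection ambiguities to proper rotations
  (det +1) always.
- Singular TPS systems (e.g. coplanar 3D sources) are ridge-regularized
  with a logged epsilon of 1e-8 × ‖L‖∞; genuinely planar data should use
  the 2D kernel.
- Sliding solves add a 1e-10 relative ridge to the reduced normal
  matrix; an iteration that increases the monitored energy is rejected
  (stop + flag), never accepted.
- Permutation conventions: +1-corrected p-values; observed statistic
  included in the Z-scoring distribution; per-stage child seeds derived
  from one master seed via a seed sequence, all below 2³¹.
- Ties in nearest-point projection resolve to the first minimal
  triangle; degenerate (zero-area) faces are dropped at load time.

## Known limitations

- The plasticity permutation test's anti-conservatism (above).
- Sliding optimizes a tangent linearization; heavily curved specimens
  may need more outer iterations than the default three.
- The pipeline's repeatability sub-study replicates the first two
  generated specimens (same cell), mirroring the small published design;
  its MS ratio is a one-draw estimate with wide sampling spread.
- bgPCA scores are well known to overstate group separation when
  variables vastly outnumber specimens; the package uses bgPCA for
  ordination figures only, never for inference.
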
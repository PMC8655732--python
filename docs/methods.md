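# Methods

## Problem and model

`fedmorph` selects patches of surface-morphometry features associated with
a continuous response across institutions that cannot share row-level
data. Subjects are rows of a design X ∈ R^{N×p}; columns are vertex-wise
scalars (radial distance and tensor-based morphometry) on one or two
rows×cols vertex grids, partitioned into patch groups. The estimator is
the group LASSO

F(β) = ½‖y − Σ_g X_g β_g‖₂² + λ Σ_g w_g ‖β_g‖₂,

whose non-smooth penalty zeroes whole groups. No intercept is fit: both
the features (per-subject Z-scores) and typical responses are centered in
practice; users with uncentered responses should center y.

Group weights w_g = √p_g, the standard convention that equalizes the
penalty across group sizes; they are overridable wherever groups are
supplied.

### Layout conventions

Grids are stored rows×cols with rows=100, cols=150 by default; vertex
indices are 0-based row-major. Feature columns are group-major: groups
ascend by (hemisphere, feature type, patch row-major), each contributing
its member vertices' columns consecutively. The group-index file header
documents this, so fixtures are self-describing. One- and two-hemisphere
layouts are both supported; two hemispheres × 15,000 vertices × 2 feature
types = 60,000 columns is the documented default.

### Per-subject standardization

"Z-score per subject" is read as within-row standardization, computed
separately over the RD columns and the TBM columns with the sample (n−1)
divisor, putting the two feature types on a common scale for every
subject. A zero-variance row block is set to zeros with a warning rather
than producing NaNs. The operation is idempotent to 1e−12.

## Federated block coordinate descent (FBCD)

The squared loss decomposes over institutions, so the gradient of any
group block is the sum of per-site partials (Gram blocks likewise). The
solver cycles over groups in fixed ascending order (a seeded shuffle is
available) and applies the proximal update

β_g ← S_{λ w_g / L_g}(β_g − ∇_g f / L_g),  S_t(z) = z·max(0, 1 − t/‖z‖₂),

with L_g the largest eigenvalue of the aggregated Gram Σᵢ (X_gᵢ)ᵀX_gᵢ
(floored at 1e−12 for all-zero columns). Blockwise-Lipschitz proximal
steps guarantee monotone descent. Convergence is declared when the
relative objective change over an epoch falls below `tol` (default 1e−8
for standalone solves); a KKT gap is reported as a certificate. The
federation is simulated in-process by master/worker objects exchanging
per-group messages; the transport records message shapes so the privacy
contract (nothing longer than a per-group aggregate ever crosses the
wire) is auditable in tests. Aggregation sums in ascending site order, so
results are bit-reproducible for a fixed partition; across different
partitions solutions agree to optimizer precision (measured ~1e−12 in
objective at study scale).

Within an epoch, consecutive groups whose coefficients are currently zero
are evaluated with one batched gradient query; the first group whose
gradient norm exceeds λw_g (with a 1e−12 relative slack so boundary
groups, e.g. the λ_max argmax, stay exactly zero) is activated and the
scan resumes after it. This is exactly cyclic BCD — a run of zero groups
leaves the residual unchanged — but turns the dominant cost into one
BLAS call.

## λ path and safe screening

λ grids are fractions of λ_max = max_g ‖Σᵢ(X_gᵢ)ᵀyᵢ‖₂/w_g by default
(absolute grids behind a flag); the path anchor is always λ_max itself,
where β = 0 and the dual point θ = y/λ_max are exact in closed form. For
each subsequent λ the sequential EDPP construction bounds the next dual
optimum in a ball built from the previous one:

v1 = y/λ_prev − θ(λ_prev) (at λ_max: v1 = X_{g*}X_{g*}ᵀy for the argmax
group), v2 = y/λ_new − θ(λ_prev), v2⊥ = v2 − (⟨v1,v2⟩/‖v1‖₂²)v1, and
group g is discarded when

‖X_gᵀ(θ(λ_prev) + v2⊥/2)‖₂ < w_g − ½‖v2⊥‖₂·‖X_g‖₂.

Per-group spectral norms ‖X_g‖₂ come from the cached aggregated Grams.
All dual vectors stay on the sites; only inner products (scalars) and
per-group Xᵀ-products cross the wire.

Screening is *safe* only against an exact anchor. Three numerical guards
keep it honest with finite-precision anchors: (1) path solves default to
tol=1e−10, tighter than standalone solves, because an anchor's KKT error
must be far below the screening margin; (2) the dual point is rescaled
into the feasible polytope (divided by max_g ‖X_gᵀθ‖/w_g when that
exceeds 1) before the geometry is built; (3) if the anchor's relative KKT
violation exceeds 1e−4 a staleness warning is raised and screening is
skipped for that step (all groups retained) rather than risking an unsafe
discard. The binding contract, enforced in tests over hundreds of random
instances and full paths, is zero safety violations against unscreened
solves and path objectives equal to 1e−8.

Solves are warm-started from the previous λ's solution and restricted to
the retained groups; solutions are embedded back into full p-space with
zeros for discarded groups. Each solve counts its group updates, which is
the hardware-independent work measure the screened/unscreened comparison
reports (on the 60,000-feature, 100-point path screening performs well
under 20% — typically <1% — of the unscreened updates).

## Stability selection and ROI summarization

For a path of κ solutions, each vertex's raw count is the number of
(λ, feature type) pairs with |coefficient| > 1e−12 — the threshold
ignores numerical dust. RD and TBM counts on a vertex are summed by
default (a `max` merge is available), normalized to [0,100] by 2κ, and
smoothed with a 2×3 averaging filter whose window is centered on the
vertex (even extents extend forward) and clipped at grid boundaries, so
values stay in [0,100]. Vertices are ranked by smoothed value with ties
broken toward the lower row-major index; the top-k vertices contribute
their RD and TBM columns (2k features).

The ROI scalar per subject is built from the *smoothed* frequencies (the
same map that is visualized): s_RD = Σ_{v∈ROI} freq(v)·RD(v), s_TBM
analogously, and the two-column table is reduced to its first principal
component score with the sign fixed so the RD loading is non-negative.
Both columns constant is a degenerate-PCA error.

Maps export as TSV (row, col, hemisphere, value) and as ASCII PLY with
the grid triangulated regularly (two triangles per cell; a 100×150 grid
gives 15,000 vertices and 2·99·149 faces), values printed with 9
significant digits so text round-trips to 1e−6.

## Synthetic cohorts

The generator emulates smoothed morphometry fields: per-subject Gaussian
random fields convolved with a separable Gaussian kernel (σ = smoothness,
in vertices, reflecting boundaries) on each grid — a grid-level stand-in
for mesh heat-kernel smoothing — then Z-scored per subject. The response
is y = Xβ_true + ε with ε ~ N(0, noise_sd²); β_true is constant within
each planted patch at magnitude effect_scale/√p_g with a random sign per
patch, support drawn without replacement. Defaults: 200 subjects, two
100×150 hemispheres (60,000 features), 10 planted patches, effect_scale
1, noise_sd 1, smoothness 3, 5 sites — roughly the documented study
conditions with a signal-to-noise ratio around 10 on the planted
component. One root seed spawns four named streams (field, support,
noise, partition) so components vary in isolation; identical seeds give
bit-identical cohorts.

What the generator does **not** emulate: mesh geometry (fields live on
the parameter grid, not a surface mesh), site heterogeneity (all sites
are draws from one distribution — real scanners differ), non-Gaussian
tails, demographic covariates, and longitudinal structure. Passing
recovery tests therefore demonstrates the selection machinery under
idealized smooth-field conditions, not robustness to site effects or
confounding.

A note on identifiability: at the default smoothness the six columns of a
patch are nearly collinear (condition numbers in the thousands), so
*per-coefficient* recovery on the true support is ill-posed even for OLS
with the support known; *patch-level* recovery — what stability
selection ranks — is unaffected. Tests that assert classical OLS error
bounds run at low smoothness where the support design is
well-conditioned.

## Problem sizes used in the checks

Federated invariance is checked at n=300 on the full 60,000-feature
layout across 1/3/5-site partitions at λ_rel ∈ {1.0, 0.5, 0.1};
screening safety on 100 random instances (N ∈ [40,200], up to 200
groups) with 20-point paths; oracle agreement on 100 small instances
against an independent FISTA solver run to 1e−13; planted-patch recovery
on 20 cohorts of 500 subjects with a 20-point path from 1.0 to 0.1,
requiring all 10 planted patches inside the top 20 of 5,000
patch-averaged frequencies; the work-reduction ratio on the 100-point
path at study scale. These sizes were chosen as the smallest that
exercise the study-scale layout and give stable statistics.

## Known limitations

- The staleness guard trades speed for safety: a poorly converged anchor
  silently disables screening for that step (with a warning) rather than
  failing.
- Screening effectiveness degrades with large λ gaps; the 3-point grid
  {1.0, 0.5, 0.1} screens little, while the 100-point grid screens >95%
  of groups per step. Grid density is a tuning choice, not a correctness
  one.
- No intercept, no encryption/differential privacy, no asynchronous or
  fault-tolerant communication; the in-process message passing is
  transport-agnostic but single-host.
- Frequency maps require all grids in a design to share dimensions.
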
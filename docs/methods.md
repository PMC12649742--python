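# Methods

## The model

A subject hemisphere's tractography output is summarized as a
nonnegative connectivity matrix `V` (vertices × voxels): rows are
cortical-surface seed points, columns are white-matter target voxels,
entries are visitation intensities. The analysis treats connections as
rank-one structures: a connection contributes
`gain · g wᵀ` to `V`, where `g ≥ 0` is its gray-matter termination
profile over vertices and `w ≥ 0` its volumetric tract core. NMF of the
species-averaged matrix recovers such structures as components;
screening and anatomical filtering pick out the anterior
temporal-frontal (ATF) and occipitotemporal-frontal (OTF) connections;
the orbitofrontal bias index (OBI) then quantifies how deeply each
connection's prefrontal termination reaches into orbitofrontal cortex;
and a nested ANOVA partitions OBI variance across species, hemispheres
and the NMF component count K.

## Synthetic cohorts

The generator emulates the *statistical structure* of surface-seeded
tractography, not the imaging physics. Its design choices:

- **Geometry.** Vertices are an indexed set (no mesh) carrying parcel
  labels (OFC, PFC_OTHER, TEMPORAL_POLE, TEMPORAL_OTHER, OCCIPITAL,
  PARIETAL, OTHER) and hemisphere labels. Per hemisphere, parcel counts
  are `round(fraction × n_vertices/2)` with OTHER absorbing the
  rounding residual. Default parcel fractions (OFC 5%, PFC_OTHER 15%,
  TEMPORAL_POLE 5%, TEMPORAL_OTHER 15%, OCCIPITAL 15%, PARIETAL 15%,
  OTHER 30%) give |OFC|/|PFC| = 1/4. The right hemisphere repeats the
  left hemisphere's label sequence, so mirroring a right-hemisphere
  matrix onto a canonical left-indexed frame is a swap of row halves.
  Voxels are uniform random points in a unit box whose first axis is
  posterior→anterior; positions only shape tract cores.
- **Bundles.** Gray profiles are piecewise-constant over endpoint
  vertex blocks with uniform [0.8, 1.2] within-block jitter; half the
  mass sits at each endpoint, and within prefrontal cortex the OFC
  block is rescaled so its share of prefrontal mass equals the species
  parameter `ofc_fraction` *exactly* (block rescaling, not sampling).
  White cores are Gaussian tubes (radius 0.08 box units) along
  polylines between nominal parcel anchors; the ATF polyline dips
  ventrally (a hook), the OTF polyline runs nearly parallel to the
  anterior-posterior axis. Distractor bundles connect non-prefrontal
  parcel pairs; when several distractors terminate in the same parcel
  each takes a disjoint contiguous slice of it. Whole-parcel endpoints
  shared among bundles make the factorization non-identifiable (mass
  can be reshuffled among components without changing the product), and
  focal patches are also the more realistic depiction of termination
  fields.
- **Hierarchy and noise.** Each subject hemisphere perturbs
  `logit(ofc_fraction)` by N(0, hemisphere_sd) — the logit scale keeps
  fractions in [0, 1] for any SD — and draws a lognormal subject gain
  (SD 0.2) to mimic inter-subject intensity differences (OBI is
  scale-invariant, so the gain only affects signal-to-noise). Noise is
  Poisson counts with mean `scale × signal` (scale 0 = noiseless) or
  additive truncated Gaussian. Poisson is the natural model for
  streamline visitation counts; the default gain of 50 puts peak
  expected counts near 50, i.e. a relative error of ~14% at the tract
  core.
- **Default species.** The default cohort mirrors a three-species,
  three-subjects-per-species design. OFC fractions were derived once
  from published per-species OBI means via `f = OBI × |OFC|/|PFC|`
  (macaque-like 0.38/0.29 for ATF/OTF, squirrel-like 0.47/0.32,
  lemur-like 0.93/0.77) and are not tuned thereafter; `hemisphere_sd`
  defaults to 0.2, which yields a hemisphere variance share in the
  single-digit percent range.

What the generator does **not** emulate: cortical folding and mesh
topology, distance correction of streamline counts, spatially
correlated noise, registration error, or partial-volume effects.
Passing tests therefore demonstrate that the pipeline's inference is
correct when its structural assumptions hold — not that those
assumptions hold in any particular real dataset.

## NMF and dual regression

`fit_group_nmf` minimizes `‖Vᵀ − W H‖_F` under nonnegativity using
HALS (hierarchical alternating least squares): each column of `W` and
row of `H` is set to its exact nonnegative least-squares minimizer in
turn, so the recorded objective trace is nonincreasing by construction.
Initialization is NNDSVDa (nonnegative parts of the truncated SVD,
zeros filled with mean/100) plus a tiny seed-controlled perturbation;
runs are deterministic per seed. Defaults: `tol = 1e-6` (relative
objective improvement per iteration, measured against the initial
objective so the criterion stays meaningful as the loss approaches
zero), `max_iter = 500`. After fitting, `W` columns are rescaled to
unit L2 norm with the scale absorbed into `H`; OBI is scale-invariant
but screening products are not, so a fixed convention is required for
reproducibility. Component order is arbitrary: all benchmarking matches
components to references by maximal Pearson correlation.

`dual_regress` projects group factors onto a subject matrix in two
stages — solve for the subject `W_s` with the group `H` fixed, then for
`H_s` with `W_s` fixed — each stage an exact nonnegative least-squares
solve. Because the design matrix is shared across rows/columns and K is
small, the problem is reduced through the Gram matrix (Cholesky) to a
K×K NNLS per row/column; a 1e-12 ridge keeps the factorization defined
when a component is identically zero. Exactness gives the guarantee
that the subject-level residual never exceeds the group-factor
baseline. An all-zero subject matrix returns zero factors flagged
degenerate rather than raising. The W-then-H order is a convention (the
reverse is a one-line change in the call order); with exact stages the
fixed-point property — a subject equal to an exactly factorized group
average recovers the group factors — holds either way.

## Screening, anatomical filtering, merging

Selection criteria originally applied by visual inspection are encoded
as declared numeric surrogates, all exposed in configuration:

- **Screening score** = mean gray signal in ROI A × mean in ROI B
  (temporal pole × PFC for ATF; occipital × PFC for OTF), computed
  after contralateral zeroing. Selected = the smaller nonempty of
  {scores > median + 2·MAD} and the top-5 scores; zero-score components
  are never selected while a positive score exists.
- **Anatomical filter** (fractions of total gray mass, so the test is
  mask-size aware): ATF needs parietal < 0.10, occipital < 0.10, and
  ≥ 0.15 at both the temporal pole and PFC; OTF needs parietal < 0.10,
  ≥ 0.15 at occipital and PFC, and the intensity-weighted principal
  axis of its white core within 30° of the anterior-posterior axis.
  The ATF "hook" morphology has no quantitative counterpart on abstract
  geometry and is represented by the endpoint-mass tests only.
- **Merging**: components that split one connection are summed
  (gray maps after contralateral zeroing), order-independently.

In the pipeline, if no screened component passes the filter for a
class, the top-scoring screened component is used and the fallback is
recorded in the run report — the filter itself is never weakened.

## OBI

`OBI = (Σ_OFC g / Σ_PFC g) ÷ (|OFC|/|PFC|)`, identically equal to
`mean_OFC(g) / mean_PFC(g)`; the identity is asserted in tests at
1e-12. The normalizer uses the whole-PFC denominator, under which a
uniform map scores exactly 1; the OFC-versus-rest-of-PFC convention is
available as `denominator="rest"` and also scores 1 on uniform maps.
ROI "size" is vertex count (no surface-area weighting — the geometry
has no areas). Zero prefrontal mass raises rather than returning a
silent 0.

## Nested ANOVA

Balanced two-level nested design only (the study design is balanced: 3
species × 6 hemispheres × 4 K values); unbalanced input raises
explicitly rather than silently approximating. Sums of squares follow
the expected-mean-squares scheme; the among-species test is
`F = MS_among / MS_subgroup` on `(a−1, a(b−1))` degrees of freedom
(df = (2, 15) at the study design). Variance components are
method-of-moments estimates truncated at zero before conversion to
percentages. All-identical observations yield the defined degenerate
result: F = NaN, percentages (0, 0, 100), `zero_variance` flag.

Post-hoc comparisons default to Welch t-tests on all observations
pooled within species (n = b·n each) with Bonferroni adjustment
`min(1, p × #pairs)`; pooling by subgroup means and the pooled-variance
Student variant are options.

`variance_recovery_check` validates the partition by simulation:
hierarchical Gaussian data with known components, estimated per
replicate. Replicates are aggregated by averaging the *components* and
converting the means to percentages. The per-replicate percentage is a
bounded ratio whose mean is substantially biased at small group counts
(with three groups the among-species mean square has two degrees of
freedom), whereas the component estimates are unbiased, so
component-first aggregation converges to the true split.

## Pipeline scales and determinism

The default geometry is 2,000 vertices × 3,000 voxels with desk K
values {4, 8, 12, 16} — a deliberate scale-down of a full surface
(10,000 seeds per hemisphere, K up to 200) chosen so complete runs take
minutes; the replicated species-effect analyses in the test suite and
acceptance script run at 400 × 600 with K ∈ {8, 12}, sizes at which
the planted eight-bundle structure is still comfortably identifiable
(the NMF recovery check passes at both scales). Every random draw
derives from the single config seed through named seed streams, so
reruns are bit-identical; the run manifest records a config hash and
per-output SHA-256 hashes, and `--resume` reuses decompositions only
when those hashes verify.

## Known limitations

- Only balanced ANOVA designs; no REML/mixed models.
- Vertex sets carry no topology, so morphological criteria reduce to
  mass-fraction and axis tests.
- The generator's bundles are exactly rank-one; real tracts fan out and
  curve, so component splitting at high K is milder here than in real
  data (it appears under Poisson noise).
- Species averaging assumes hemispheric label symmetry and
  hemisphere-agnostic white cores; real data would need a registration
  step in place of the index mirror.
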
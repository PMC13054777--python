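# Methods

## The quantities

Joint angles are measured at three discrete stance events — touchdown (TD),
midstance (MS) and toe-off (TO) — for shoulder, elbow and wrist (forelimb)
and hip, knee and ankle (hindlimb). No continuous trajectory is modelled:
the data model is three poses per joint per limb, which is what comparative
video digitization typically yields.

From those poses the package derives, per limb:

* **JAE** (joint angular excursion): `max − min` over the present event
  angles of one joint. At least two of the three events are required;
  missing events propagate as missing, never as zero.
* **TAE** (total angular excursion): the net sweep of the functional limb
  segment — the line from the ground-contact point to the shoulder (fore)
  or hip (hind) — between TD and TO, `|seg_TO − seg_TD|`.
* **∑JAE**: the sum of the limb's computable JAEs. A joint with missing JAE
  is excluded from the sum and flagged, so per-joint sample sizes can differ.
* **AUI%** (angular utilization index): `100 · TAE / ∑JAE`, the fraction of
  summed joint excursion realized as net limb excursion.
* **relative JAE**: each joint's percentage share of ∑JAE; shares of a
  complete limb sum to 100.

### Conventions

* Angles are stored in degrees throughout; radians appear only inside
  trigonometric calls.
* The interior joint angle in [0, 180] is reported (arccosine of the
  normalized dot product of the joint-to-proximal and joint-to-distal rays).
  The flexion-positive rotation convention affects only the sign of angular
  change, which `max − min` removes.
* The functional-segment angle is signed, measured from the vertical axis
  through the contact point, positive toward the direction of travel. No
  standard reference axis exists for this angle in the comparative
  literature; the vertical-through-contact choice makes TAE independent of
  camera placement and travel direction. Because net limb sweep during
  stance is monotonic, TAE uses TD and TO only; a `use_midstance` switch
  computes `max − min` over all three segment angles should MS ever be an
  extremum.
* Landmark coordinates are treated as mathematical y-up; a `y_down` flag
  flips image-style input at read time.
* Body mass enters all scaling models as log10 kilograms. Pearson
  correlations are invariant to the logarithm base, so correlation outputs
  are base-agnostic.

### Factor categories

Species carry four categorical factors. Body mass class: small (< 1 kg),
medium (1–29 kg), large (30–100 kg), very large (> 100 kg) — checked for
consistency with the numeric mass on input. Limb posture: plantigrade,
digitigrade, subunguligrade, unguligrade, mixed. Top speed: slow
(< 35 km/h), medium (35–50 km/h), fast (> 50 km/h), optional. Locomotor
habit: cursorial, scansorial, arboreal, terrestrial.

## Comparative statistics

Group differences in TAE, ∑JAE and AUI% across factor categories use
Welch's heteroscedastic one-way ANOVA by default (species-level samples
routinely have unequal spread across categories). Post hoc pairwise
comparisons switch on variance homogeneity, judged by the Brown–Forsythe
(median-centered Levene) test at α = 0.05: Tukey HSD on the pooled variance
when homogeneous, Dunnett's T3 otherwise (Welch-type pairwise t referred to
the studentized maximum modulus distribution, evaluated by numerical
integration over the chi density). A `kruskal` option replaces the chain
with Kruskal–Wallis (tie-corrected H) plus Dunn's z tests; no automatic
normality gate is applied — the omnibus choice is the caller's. Dunn and
simulation-based pairwise p-values are Holm-adjusted; Holm is the step-down
adjustment with monotonicity enforcement.

Pearson correlations report Fisher-z confidence intervals and t-based
p-values. Stride length is normalized for body mass as
`stride / mass^(1/3)` by default — isometric length scaling — with the
exponent configurable.

Intrarater reliability uses ICC(3,1) from the two-way mixed model,
`(MSR − MSE) / (MSR + (k−1) MSE)`, with `SEM = SD · √(1 − ICC)` where SD is
the standard deviation of all ratings.

## Quadrant framework

Species with both limb AUI values are placed in quadrants by the 50%
thresholds: I (FL > 50, HL > 50), II (FL ≤ 50, HL > 50), III (both ≤ 50),
IV (FL > 50, HL ≤ 50); values exactly at 50 fall in the ≤ branches. Species
missing one limb's AUI are excluded and logged. Factor association uses the
Pearson chi-square of independence (no continuity correction; zero-margin
rows/columns dropped with a warning). Per-cell enrichment collapses the
table to category-vs-rest × quadrant-vs-rest and applies Fisher's exact
test: two-sided p by the sum-of-≤-likely-tables convention, direction from
the sample odds ratio (0.5 added to each cell only for reporting the OR
when a zero cell exists, never for p). Per-cell p-values are reported raw
by default — they are descriptive flags, not a confirmatory family — with a
Holm option.

## Phylogenetic machinery

A rooted, branch-length tree induces the Brownian-motion covariance
`C[i,j] = shared root-to-MRCA path length`. PGLS fits
`β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` with an intercept column, residual variance on
n − 2 df, and a two-sided t test on the slope. Pagel's λ is fixed at 1.0
(pure BM); the λ transform (off-diagonals scaled by λ) is implemented but
estimation is out of scope. R² is the whitened-space coefficient of
determination, `1 − RSS_w / TSS_w`, with TSS_w centered at the GLS grand
mean — there is no unique GLS R², so this definition is checked by
properties (OLS reduction at C = I, R² = 1 on noiseless data) rather than
against external values. Zero-length branches are perturbed by
1e-8 × tree depth before inversion (logged).

The phylogenetic ANOVA refers the observed one-way F to a null distribution
of F statistics recomputed (group labels fixed) on BM simulations along the
tree. The BM rate for the null is the grand-mean GLS estimator
`σ̂² = (y−μ̂)ᵀC⁻¹(y−μ̂)/(n−1)`. The simulation p uses the add-one
estimator, `p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sim)`, so p ≥ 1/(n_sim+1).
Pairwise tests use pooled-variance t statistics (MSE from the full one-way
ANOVA) with the same simulation treatment and Holm adjustment; a Welch-type
pairwise t is a possible alternative but the pooled form matches the
standard simulation-ANOVA practice.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without restricted data. On a pure-birth (Yule)
tree — lineages split at rate k·b, one final exponential interval after the
n-th lineage, depth-normalized to 1 for trait evolution:

* **log10 mass**: BM with rate 1.44 per unit depth from a root of 1.2
  (≈ 16 kg). Tip SD ≈ 1.2 covers roughly 0.1–4000 kg, the span typical of
  broad terrestrial-mammal samples.
* **TAE** per limb: `intercept + slope · log10mass + BM residual`, slopes
  −10.33 (hind) and −10.62 (fore) degrees per decade of mass, intercepts 62
  and 68 so mean TAE at the root mass sits near the empirical grand means
  (≈ 50–55°). Residual BM rates default to
  `slope² · 1.44 · (1 − R²)/R²` with R² = 0.24 (hind) and 0.15 (fore), so
  the whitened coefficient of determination of the generated data matches
  those values by construction. An `iid_residuals` switch replaces the BM
  residuals with independent normals of the same tip variance for
  misspecification checks. TAE is floored at 5°; the floor binds
  occasionally at very large masses and attenuates mean recovered slopes by
  a few percent (see Limitations).
* **AUI%**: truncated normal on (5, 100], mean 57, SD 15, independent of
  mass — bracketing the empirical group means (≈ 49–75%) and reproducing
  the null mass-scaling of AUI.
* **∑JAE** follows from the identity `∑JAE = 100 · TAE / AUI`; drawing AUI
  and deriving ∑JAE (rather than the reverse) guarantees the AUI
  distribution directly and keeps the construction identity exactly
  testable.
* **Per-joint JAE**: a Dirichlet split of ∑JAE with concentration 20 around
  the empirical relative-JAE shares (fore 0.39/0.26/0.35,
  hind 0.39/0.30/0.31) — strong enough to respect proximal dominance, loose
  enough to vary. On the rare draw whose implied per-joint excursion cannot
  fit in [0, 360), AUI and shares are redrawn (at most 100 attempts).
* **Event angles**: per joint, the event with the smallest empirical mean
  angle gets `base`, the largest gets `base + JAE`, the middle
  `base + u·JAE` with u uniform; `base` is normal around the joint's
  empirical minimum-event mean (SD 10°), clipped to keep all angles in
  [0, 360). Segment angles are ±TAE/2. Recomputing JAE/TAE/AUI from the
  emitted table therefore reproduces the latent values exactly.
* **Factors** are categorical draws with frequencies matching the empirical
  category sizes; optional additive TAE effects per category are applied
  before ∑JAE is derived, preserving the identity. Stride length is
  `0.5 · mass^(1/3)` meters with lognormal noise (SD 0.15 on the log).

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning (tree, masses, per-limb residuals, factors, one stream per
species), so any species is reproducible in isolation.

### What the generator does not emulate

Real clade composition and non-random missing-data patterns; literature
heterogeneity in digitization protocols; within-species variation and
measurement error; any dependence of AUI on mass or factors (unless
configured). Passing tests therefore demonstrate that the pipeline's
estimators recover known structure under a correctly specified model — not
that the empirical dataset satisfies that model.

## Numerical choices

* Welch's F uses the standard weighted formulation with the
  Welch–Satterthwaite df; it equals the classical F exactly only for two
  balanced equal-variance groups (the k > 2 correction term is O(1/n)).
* The studentized-maximum-modulus survival function is computed by
  adaptive quadrature of `[2Φ(qu) − 1]^k` against the scaled chi density.
* Cholesky factorization backs all C inversions; singular or non-PD
  covariance raises a dedicated error rather than silently regularizing
  (only prescribed zero-length-branch perturbation is applied).
* CSV output uses fixed float formatting (`%.10g`) and LF line endings;
  the run manifest contains input hashes, seed and version, no timestamps —
  so identical configurations produce byte-identical runs.
* Degenerate inputs: constant traits give F = 0 and maximal simulation p;
  zero-variance groups, all-tied ranks, zero ∑JAE, coincident landmarks and
  incomplete rating designs raise specific exceptions.

## Problem sizes

Replicate counts used by the test suite and the acceptance script: 200
replicate datasets for slope-recovery and null-AUI checks (54/46 species,
matching the degrees of freedom of the empirical PGLS fits); 200 × 500
simulations for the phylogenetic-ANOVA type-I check at 30 tips; 2,000
replicates for the Welch type-I check; 1,000 random tables for the
contingency oracles. These sizes give Monte-Carlo standard errors
comfortably inside the asserted bands.

## Known limitations

* The 5° TAE floor censors the left tail at very large body masses, which
  attenuates mean recovered PGLS slopes by roughly 3–7% relative to the
  generating constants; recovery criteria account for this within their
  ±1.0° band.
* AUI slope standard errors from PGLS are computed under the BM covariance,
  while generated AUI is independent across species — the reported SEs for
  AUI models are therefore conservative descriptions of a misspecified fit
  (deliberately so: the empirical AUI result is a null under the same
  machinery).
* The phylogenetic-ANOVA pairwise test uses pooled-variance t; no
  Welch-type pairwise variant is currently exposed.
* `prune_to` requires exact `Genus_species` label matches after
  underscore/space normalization performed by the caller; no fuzzy
  name-matching is attempted.
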
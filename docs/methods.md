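# Methods

`vdrdti` is a synthetic-data re-implementation of a value-directed
remembering DTI analysis: it generates cohorts whose behavior and diffusion
phantoms share latent traits, runs the imaging measurements (tensor fit, FA
extraction in atlas masks, probabilistic tractography), and applies the
brain–behavior statistical battery. This note documents the models, the
parameters that matter, and the places where the synthetic data are a
deliberate simplification of real diffusion MRI.

## Behavioral task and scoring

The task is the classic value-directed remembering design: five study–test
cycles, each a list of 24 unique words, half assigned high point values
(10, 11 or 12; four words each) and half low values (1, 2 or 3). The mean
point value of a list is therefore exactly 6.5. Per list we compute:

- **actual score** — sum of the values of the recalled words;
- **chance score** — mean list value × number recalled, the expected score
  had values been assigned at random to the recalled set (verified in the
  tests by Monte-Carlo permutation of value assignments);
- **ideal score** — the sum of the N largest list values for N recalled
  words;
- **Selectivity Index** — `SI = (actual − chance)/(ideal − chance)`,
  1 for perfectly value-prioritized recall, 0 for value-insensitive recall,
  negative for low-value-prioritized recall.

SI is undefined when `ideal == chance`, i.e., zero or full recall. Such
lists are dropped from a subject's selectivity mean but kept in the
high/low recall means; this edge case has no canonical treatment in the
task literature, so the exclusion rule is our documented choice. Ties in
the ideal score are irrelevant by construction (values are summed, not
word identities). Per-subject summaries average over the five scored lists.

Group-level t-tests (paired high-vs-low recall, one-sample SI against
zero) use the standard formulas with df = n − 1; zero-variance input is
reported as an infinite-t signal rather than an error or a silent number.

## Cohort generator

Each subject carries three independent (by default) standard-normal latent
traits: general ability, semantic integrity, and reward sensitivity. Words
are recalled independently with probability

    p = logistic(a_i + g_i · z(v)),
    a_i = alpha0 + w_ability·ability_i + w_semantic·semantic_i,
    g_i = gamma0 + w_reward·reward_i,

where `z(v)` is the word value standardized within the list. The same
traits drive the imaging side: semantic integrity sets the UF-like
bundle's anisotropy (`FA = 0.55 + 0.07·(fa_loading·semantic + ε)`,
ε ~ N(0, fa_noise_sd)), reward sensitivity sets the seed–target bundle's
orientation dispersion (`σ = 0.22 − 0.07·(ts_loading·reward + ε)` radians,
clamped to [0.02, 0.60]), and the control bundle's FA is trait-independent
noise. The exclusive (non-overlapping) portion of the IFOF-like corridor is
also trait-independent, so any apparent IFOF effect flows through the
voxels it shares with the UF-like bundle — the structure the exclusive-mask
analysis is designed to expose.

Defaults were calibrated once, by large-n simulation, to the published
behavioral regime and the intended population effect sizes:
`alpha0 = −0.06`, `w_ability = 0.35`, `w_semantic = 0.8`, `gamma0 = 1.2`,
`w_reward = 0.45`, `fa_noise_sd = 0.44`, `ts_noise_sd = 1.36`. At these
values (n = 60 000) the cohort shows mean high recall 8.6/12, mean low
recall 3.2/12, mean SI 0.60, population corr(UF FA surrogate, high recall)
= 0.70, corr(tract-strength surrogate, SI) = 0.49, and null control-tract
correlations. The calibration targets the qualitative ordering — UF↔high
recall strong, control null, seed–target↔selectivity moderate — not the
published sample correlations, which are statistics of a 19-subject sample.

Two properties of the generator deserve emphasis:

- `w_reward` scales the *spread* of the value-sensitivity slope across
  subjects, not its mean; because SI is concave in the slope near the
  calibrated operating point, raising `w_reward` lowers the population mean
  SI slightly while strengthening the reward-trait↔SI coupling. The knob
  that raises expected SI is `gamma0`.
- Semantic integrity enters the recall intercept, so it raises recall of
  low-value words too; the generator does not force the high/low
  dissociation for the UF that the original sample displayed. Passing tests
  therefore show recovery of the configured couplings, not that the
  dissociation is inevitable.

Randomness is governed by one seed; all stages draw from deterministically
spawned child streams, making every table bit-reproducible.

## Diffusion phantoms

Phantoms are 24³ grids of 2 mm isotropic voxels (a toy-scale stand-in for
a whole-brain acquisition) containing:

- an **IFOF-like corridor**: a straight bundle spanning the grid;
- a **UF-like bundle** whose anterior half runs inside that corridor and
  then hooks away — the thresholded atlas masks of the two tracts overlap,
  as the real atlas masks do;
- a **control bundle**, geometrically isolated, trait-independent;
- a **crossing bundle** intersecting the corridor, giving two-fiber voxels
  with 0.5/0.5 volume fractions;
- a short **seed→target bundle** joining two compact ROIs, with per-subject
  orientation jitter (dispersion) and a per-subject target-ROI radius,
  which makes the target-size covariate non-degenerate;
- isotropic background (d = 0.8 × 10⁻³ mm²/s) everywhere else.

Signals follow the multi-tensor forward model
`S = S0 Σ f_k exp(−b gᵀ D_k g)` on a 64-direction, b = 1000 s/mm² scheme
plus one b0 volume. Directions are spread by electrostatic repulsion of
antipodal pairs from a seeded random start (bounded, decaying steps; the
refined schemes reach ≈17° minimal axial separation at 64 directions).
Bundle tensors are prolate with mean diffusivity fixed at 0.8 × 10⁻³ mm²/s;
eigenvalues are derived from a target FA by inverting
`FA = (λ∥ − λ⊥)/sqrt(λ∥² + 2λ⊥²)` at fixed MD. Noise is Rician — the
magnitude of a complex Gaussian perturbation — with default scale S0/25
(SNR 25); magnitude data is why the tensor fit floors signals before the
log. Atlas probability maps are Gaussian-smoothed (σ = 1 voxel) bundle
indicators rescaled to peak 1, which reproduces the threshold sensitivity
the 10% probability cut addresses.

What the phantoms do **not** emulate: head geometry, eddy-current and
susceptibility artifacts, partial-volume CSF, multi-shell schemes,
registration/normalization error. Results on phantoms validate the
estimators' semantics, not their robustness to real-acquisition confounds.

## Tensor fit and FA extraction

Tensors are fit per voxel by ordinary least squares on
`ln S = ln S0 − b gᵀ D g` (the classic DTIFIT-style estimator; a one-step
weighted refinement is available behind a flag but is not the default,
matching the named tool's standard behavior). The design matrix is
column-scaled before solving so that the b-value magnitude does not inflate
the condition number; noise-free fits recover ground-truth tensors to
≈1e-15 and rotation/scale invariance of FA holds to 1e-8. Signals at or
below 1e-6·S0 are floored before the log; negative eigenvalues are clamped
to zero for the FA value only, with the raw tensor preserved so fit
pathology stays visible. Background voxels (mean b0 under the floor) get
FA 0.

Atlas masks are thresholded at probability ≥ 0.10 (inclusive, so behavior
at the boundary is deterministic); the exclusive IFOF mask is the set
difference IFOF \ UF; mean FA is the arithmetic mean over included voxels,
and an empty mask is an error (it signals over-thresholding) rather than a
NaN.

## Probabilistic tractography

Full Bayesian posterior sampling of fiber orientations is replaced by a
parametric stand-in: each voxel carries up to two mean directions with a
concentration κ and mixture fractions. From fitted tensors, the mean
direction is the principal eigenvector and κ = 30·FA/(1 − FA + 1e-6),
capped at 1e4 and zeroed below FA 0.15 (an anisotropy stopping rule);
from ground-truth fibers, κ is supplied directly. This preserves exactly
what the downstream statistic consumes — the fraction of seed samples
reaching the target — at desk scale.

Streamlines start at uniform random positions inside each seed voxel
(avoiding lattice artifacts), sample a mixture component and then a
direction from a sign-folded von Mises–Fisher distribution (axial
symmetry), step 0.5 voxels, and terminate on grid exit, 200 steps, a turn
sharper than 80°, or entry into a voxel with κ < 1e-3. Each sample is
propagated in both directions from its start, as standard trackers do, and
hits if either pass enters a target voxel. Tract strength is
`hits / (samples_per_seed_voxel × n_seed_voxels)`; 5000 samples per seed
voxel is the reference setting, and tests use a few hundred since the
binomial error of the strength, not the sampler, is the limiting factor.
The target-ROI voxel count is recorded per subject as the covariate for
the partial correlation. Step size, curvature and stopping thresholds are
documented defaults, not values inferred from any particular acquisition.

## Statistical battery

All brain–behavior correlations are tested one-tailed in the positive
direction (the a-priori hypothesis is that more coherent pathways support
better performance): `t = r√(n−2)/√(1−r²)`, upper-tail p with df = n − 2.
The tract-strength tests are partial correlations controlling for
target-ROI size, `r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with
df = n − 3, identical (to 1e-12) to correlating the two OLS residual
vectors. Benjamini–Hochberg step-up adjustment is applied across all
correlation tests of a battery run as one family (the family definition is
a config field recorded in the report). Comparisons of two dependent
correlations sharing one variable use Steiger's Z1*: Fisher transforms of
r12 and r13 with the Dunn–Clark covariance evaluated at the pooled
correlation, `Z = (z12 − z13)√((n−3)/(2 − 2s̄))`, two-tailed and reported
without FDR adjustment, matching how such comparisons are conventionally
reported; Williams' t is available as an alternative. Monte-Carlo
validation at n = 19 under a trivariate-normal null puts the Z1* type-I
error at 0.048 over 10⁵ replicates, and the battery's empirical FDR under
a global-null cohort (all imaging loadings zero) is ≤ the nominal q over
1000 replicates.

## Numerical and design choices

- Threshold comparisons are inclusive (≥), so the 0.10 mask cut is
  deterministic at the boundary.
- The tensor fit floors signals at 1e-6·S0; Rician magnitudes can be
  arbitrarily close to zero.
- vMF sampling treats κ < 1e-9 as uniform on the sphere; the first step of
  a streamline picks its sign at random, later steps fold the sign toward
  the previous direction.
- Battery report ordering is deterministic; every adjusted p ≥ its raw p.
- Problem sizes in the test suite (24³ grids, 12–64 directions, hundreds
  of samples per seed voxel, 10³–10⁵ Monte-Carlo replicates) were chosen
  as the smallest sizes at which the targeted invariants are measurably
  sharp.

## Known limitations

- The orientation model is a parametric simplification; it does not
  propagate tensor-fit uncertainty the way a posterior sampler does, so
  absolute strength values are not comparable to a full Bayesian tracker —
  only their ordering and normalization semantics are.
- Ground-truth FA in two-fiber voxels is defined as the FA of the
  fraction-weighted mean tensor, an approximation used only for reporting
  (single-fiber voxels, where oracles apply, are mono-exponential).
- Recall is independent Bernoulli per word: no list-capacity constraint,
  no serial-position or retrieval-order structure, no strategy learning
  across lists.
- The generator cannot constrain trait correlations from published data;
  they default to zero and are exposed in the config.
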
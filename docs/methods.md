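# Methods

## Outcome labelling

Follow-up information is a day-resolution interval history: psychotic
episodes and remission periods, each `(start_day, duration_days)`, within
a follow-up window (3–7 years in the reference design). Durations are
positive, intervals lie inside the window and are pairwise disjoint.

"Six months" is pinned at **183 days**; "longer than six months" is
strict (`> 183`), "at least six months" inclusive (`>= 183`). The label
is decided by fixed clause precedence, first match wins:

1. exactly one episode, lasting ≤ 183 days → **remitting** (a single
   short episode counts as remitting even when no remission interval was
   recorded);
2. a remission ≥ 183 days and no episode > 183 days → **remitting**;
3. a remission ≥ 183 days together with an episode > 183 days →
   **excluded** (neither extreme course; such subjects take part in sex
   models only);
4. otherwise → **continuous** (no qualifying remission anywhere).

The precedence resolves two corner cases the prose definitions leave
open: a remission of exactly 183 days combined with a long episode is
*excluded* (clause 3 outranks the no-long-remission reading of
continuous), and alternating short episodes/short remissions of any
length are *continuous*. A history with no recorded episodes and no
qualifying remission also falls through to continuous; subjects with no
history at all are labelled excluded. The whole rule is verified against
an independently coded truth table on all histories with ≤ 2 episodes
and ≤ 2 remissions on a 30-day grid (~111k cases).

## Synthetic gray-matter cohorts

The generator emulates what arrives *after* segmentation and spatial
normalization: per-subject gray-matter probability volumes on a common
grid. Default grid 16×16×16 at 2 mm — desk-scale, same voxel size as the
reference 91×109×91 space.

A subject volume is

```
clip01( baseline + Σ_effects d·σ_site + offset_site ) · gain_site + ε
→ blur by site PSF → clip01 ,   ε ~ N(0, σ_site²) i.i.d. per voxel
```

* **baseline** — a "pseudo-brain": 12 Gaussian blobs superposed inside an
  ellipsoid support, rescaled to [0.05, 0.95] inside and 0 outside.
  Deterministic in the grid shape. The exterior falls below the 0.03
  mask, so the feature space is the ellipsoid interior (~2600 of 4096
  voxels at 16³), nonuniform as in real maps.
* **effects** — compact spherical regions (the `n_voxels` grid points
  nearest a fractional center; 50 voxels by default) carrying an additive
  shift `d·σ_site` for the positive class (male for the sex factor,
  continuous for the course factor). Expressing effects in units of the
  site noise SD makes `d` read as a per-voxel Cohen's d; the site PSF and
  the 4-mm analysis smoothing attenuate signal and noise together.
* **site profiles** — additive intensity offset, multiplicative gain,
  noise SD, and PSF FWHM per site, standing in for scanner/protocol
  heterogeneity. No quantitative description of real inter-site
  differences is available, so the magnitudes (offsets ±0.02, gains
  0.96–1.04, σ 0.05–0.09, PSF 0–2.5 mm) are free parameters chosen for
  test sensitivity, not realism.
* **seeds** — one master seed; per-subject seeds derive from
  `SeedSequence([master, subject_counter, stream])` where the counter
  enumerates subjects in sorted (site, sex, course) order. Cohort
  generation is a pure function of the configuration.

Episode histories are constructed per requested label (and round-trip
through the classifier by construction): remitting = short episode, gap,
long remission, optionally a second short episode; continuous = a long
episode, a short remission, a second episode; excluded = a long episode
followed by a long remission. Follow-ups shorter than 400 days are
rejected because the defining intervals cannot fit.

The roster preset reproduces the five-center reference demographics
(389 subjects: per-site totals 97/67/54/107/64, male/female splits,
remitting/continuous splits and their male subsets, with the remainder
per site in the excluded-course group). What the generator does **not**
emulate: anatomy, tissue-class mixing, registration error, intensity
non-uniformity within a volume, age/diagnosis structure, or any
correlation between voxels beyond the PSF. Passing recovery/pooling
tests therefore demonstrates the statistical machinery, not performance
on real brains.

## Preprocessing

Smoothing is separable Gaussian convolution, per-axis sigma in voxels
`fwhm / (voxel_size · 2√(2 ln 2))`, reflect (mirror) boundary padding
(mass-preserving away from edges), FWHM 0 = identity, output clipped to
[0, 1]; default 4 mm FWHM. It is checked against a direct padded
convolution to < 1e-10.

The gray-matter mask is **group-level**: a voxel enters the shared
feature space iff the cohort-mean smoothed probability is ≥ 0.03
(`rule="mean"`, default). A stricter per-subject variant
(`rule="all"`: every subject ≥ threshold) is available. A single shared
mask is required so every subject maps onto the same feature vector; the
mask is built on smoothed volumes, i.e. on the probabilities the
classifier actually sees. Features are the masked voxels flattened in
row-major (C) order; rows follow cohort order. Features are not rescaled
(probabilities already share the [0, 1] scale); optional per-feature
standardization fit on training data only exists for other inputs.

## Classifier

Soft-margin linear SVM, `min ½‖w‖² + C Σ hinge`. The solver is libsvm
(scikit-learn `SVC`, linear kernel, tolerance 1e-8 in `train`), checked
on ≤ 5-point toys against an SLSQP solution of the dual QP to 1e-6.
Decision values are w·x + b; **sign(0) predicts the positive class** so
confusion counts are reproducible. Positive class: *male* (sex task),
*continuous* (outcome task).

C is selected from the grid {10⁻³…10³} by stratified inner
cross-validation (5 folds by default), maximising mean balanced
accuracy, ties broken toward the smallest C (the stronger-regularised
model). Inside the L2O engine the fold count is clamped to the smallest
training-class size, and a single-value grid skips the search entirely.

The evaluation engine solves every fold through the *precomputed* linear
kernel: the subjects' Gram matrix is computed once per run and each fold
fits on a submatrix. This is the same optimisation problem (identical
solutions up to solver tolerance) at a small fraction of the cost, which
is what makes 10⁴-fold permutation experiments feasible on one CPU.

## Evaluation protocol

* **Balanced subsampling** — the globally smaller class is the minority;
  within each site all minority members are kept plus an equally-sized
  uniform random subset of the majority. If a site has fewer majority
  than minority members, the shortfall is drawn from the unselected
  majority members of other sites, so overall counts come out equal.
* **Site-matched L2O** — within each site the two classes are matched
  into random disjoint pairs; the pairing RNG is seeded per (seed, site),
  so one site's fold composition is independent of which other sites are
  present. Each fold selects C on the remaining subjects, trains, and
  records the held-out pair's decision values. Unpairable remainders
  (site class imbalance, or single-class sites) are never tested but stay
  in every training set (`times_tested = 0` in the per-subject records).
* **Bootstrap ensemble** — `n_bootstraps` independent
  (subsample → L2O) repetitions with counter-derived seeds; metrics are
  arithmetic means over repetitions where defined. The per-site
  breakdown restricts each repetition's confusion counts to one site.
* **Permutation test** — labels are shuffled **within site** (preserving
  the site structure the matched CV assumes); the pipeline re-runs with
  the same internal seed stream as the observed run, so only the label
  assignment differs. p = #(null ≥ observed)/N, inclusive at ties; the
  plain estimator can return exactly 0, and a smoothed (k+1)/(N+1)
  variant is exposed. Zero-denominator metrics (e.g. PPA with no
  positive predictions) propagate as missing, never as 0.

## Calibration and validation studies

Problem sizes are chosen so each study runs in minutes on one CPU:

* **Null calibration** — 50 replicate two-site cohorts, 20 subjects per
  course class, all effects 0; permutation test with 200 permutations at
  α = 0.05, single-value C grid (with no signal anywhere the inner search
  adds cost but no information to the outer calibration). Expected:
  rejection count inside the exact binomial 95% band around 0.05·50, mean
  observed accuracy within 0.05 of ½.
* **Effect recovery** — course effect d ∈ {0, 1, 3} in a 50-voxel
  region, 40 subjects over two sites, 10-repetition ensembles with the
  full C grid. Expected: per-class accuracies ≥ 0.9 at d = 3 and
  monotone non-decreasing balanced accuracy in d.
* **Pooling comparison** — three sites share one sex-effect region
  (d = 0.6); the small site has 10 subjects, the two large ones 30 each.
  The pooled model and the small site's own model are each run as
  ensembles and judged on the small site's subjects, averaged over 10
  replicate cohorts × 4 repetitions. A single 10-subject site often sits
  at accuracy ceiling for both models, which would make a one-shot
  comparison degenerate; replicate averaging yields a stable one-sided
  contrast. In pilot runs the pooled − single gap was +0.04 to +0.18.
  At much weaker effects the comparison inverts — site heterogeneity
  swamps the shared signal and pooling hurts — consistent with the
  qualitative finding that a center must carry a classifiable effect to
  benefit from pooling.

## Numerical conventions and degenerate inputs

* Tie at decision value 0 → positive class.
* C-selection ties → smallest C; candidate grids must be strictly
  increasing and positive.
* Sphere regions break distance ties by flat voxel index (stable).
* Masks at threshold 0 include everything; above the global max, nothing.
* Empty cohorts, single-class training labels, non-finite features,
  mixed grid shapes, and fold counts exceeding class sizes raise typed
  errors (`CohortError`, `ImagingError`, `ClassifierError`,
  `EvaluationError`).
* Reports serialise with sorted keys; identical configurations produce
  byte-identical `report.json` files.

## Known limitations

* The synthetic PSF/noise model is stationary and Gaussian; real scanner
  effects are neither.
* The L2O pairing uses one random matching per repetition rather than
  enumerating all same-site cross-class pairs; the ensemble averages over
  matchings.
* Permutation reruns share the observed run's seed stream; this isolates
  the label association but means the null does not average over
  alternative subsample draws within one permutation.
* No multiple-comparison correction across centers/analyses, and no
  confidence intervals beyond the bootstrap spread.
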
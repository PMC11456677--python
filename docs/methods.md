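# Methods

## Model and scope

The package analyses intrahemispheric cortico–basal ganglia–thalamo–cortical
(CBTC) circuits in a stroke case–control design. Five cortical regions (MPFC,
DLPFC, M1, premotor cortex PMC, orbitofrontal cortex OFC) and four subcortical
structures (caudate CAU, putamen PUT, pallidum PAL, thalamus THA) are assumed
already delineated and co-registered; lesion segmentation, registration,
tractography and BOLD preprocessing are upstream of this package, which
consumes region time series (or labelled volumes) and per-voxel cortical
connection probabilities.

Two parallel loops are modelled per hemisphere: the *short*
cortico–striato–thalamo–cortical loop (19 connections) and the *long*
cortico–striato–pallido–thalamo–cortical loop (21 connections), for 40 FC
values per hemisphere, plus a 26-edge whole-structure atlas set (20
cortico-subcortical pairs + 6 subcortical pairs) used as the conventional
comparison.

### The default loop manifest is a reconstruction

The exact published composition of the 19/21-edge lists is not available to
this package, so the shipped manifest is **constructed by rule and labelled a
reconstruction**: for every cortical target *c*, the short loop contributes
the chain c–CAU_c, c–PUT_c, CAU_c–THA_c, PUT_c–THA_c, THA_c–c and the long
loop the chain with a pallidal relay (CAU_c/PUT_c–PAL_c, PAL_c–THA_c) instead
of direct striato-thalamic edges; an explicit exclusion list then removes the
putamen and pallidal branches of the two prefrontal/limbic targets (MPFC,
OFC) until the counts are exactly 19 and 21. The manifest is *data*, not
code (`src/cbtc/data/loop_manifest.tsv`); supply your own TSV
(`loop hemisphere region_a region_b`) to match a published edge list.
Validation is total: any manifest accepted by `load_loop_manifest` has
exactly 19/21/26 unique intrahemispheric edges per hemisphere.

### Hemisphere convention

Left-lesion patients' imaging is mirrored across the mid-sagittal plane
(`flip_lr`, the voxel axis identified as left–right by the affine, an
involution), so R = ipsilesional for all patients. Controls keep native
orientation and R is treated as the affected-homologue hemisphere in group
comparisons. Whether control hemispheres should instead be randomly mirrored
to match patient lateralisation is an open design point; we keep native
orientation as the simpler, deterministic choice.

## Synthetic cohort generator

The generator emulates the *structure* of the modelled study so every stage
runs without MRI data:

- **Series.** Region × time draws from a zero-mean multivariate normal. The
  target correlation matrix places `rho0 = 0.4` on every loop edge (region
  pairs; a pair shared by the short and long loop has one physical
  correlation) and zero elsewhere, repaired to the nearest positive
  semidefinite correlation matrix by eigenvalue clipping at 1e−8 with
  diagonal renormalisation (Higham iteration is unnecessary at this
  sparsity; the perturbation is reported and must not move a targeted entry
  by more than 0.05).
- **Group effect.** Patients have `delta = 0.15` subtracted from the three
  designated ipsilesional edges (thalamus_DLPFC–DLPFC in the long loop,
  caudate_M1–M1 and putamen_DLPFC–DLPFC in the short loop), encoding the
  decreased-connectivity phenotype as a correlation decrement, not a variance
  change. No published effect size exists for these decrements; 0.4/0.15 are
  calibration choices giving a clearly detectable but not degenerate effect
  at n = 64/64.
- **Behavior.** UE-FMA (Upper Extremity Fugl-Meyer Assessment, 33 items,
  integer 0–66) is an affine map of the subject's Fisher-z FC on four
  designated edges (three positive weights, one negative; the motor-loop
  pairs reported as predictive), `score = round(offset + scale·Σ w·z + ε)`,
  clipped to [0, 66]. Defaults (offset −7, scale 40, noise SD 4) centre
  scores near the moderate-to-severe range. Across-subject FC variability
  arises from finite scan length (z SD ≈ 1/√(T−3)), which bounds how strongly
  behavior can correlate with any edge at a given T.
- **Profiles.** Voxel connectivity profiles for each subcortical structure are
  Dirichlet draws with concentration κ on the voxel's true target and 1
  elsewhere; κ → ∞ gives perfectly peaked profiles, κ = 1 is uninformative.
  Default κ = 50 (clearly recoverable, imperfect boundaries).
- **Demographics.** Ages ~ Normal(57, 12) truncated to [30, 80]; sex ~
  Bernoulli(0.55 male); 15/64 of patients left-lesioned. Cosmetic only — no
  stage conditions on them.

What the generator does **not** emulate: hemodynamics, autocorrelated BOLD
noise, motion, lesion-distorted anatomy, registration error, or
subject-level heterogeneity of the underlying correlation structure beyond
sampling noise. Passing tests therefore demonstrate the correctness and
calibration of the analysis machinery under the stated generative
assumptions, not performance on real stroke data.

## Stage-by-stage choices

**Parcellation.** Hard winner-take-all on raw probabilities with threshold
τ = 0.01 and deterministic tie-breaking (first target in recorded order, or
`unassigned`). Rescaling a voxel's profile never changes the argmax; τ
compares raw probabilities, so it is scale-sensitive by design. No spatial
regularisation by default (an optional 6-neighbourhood strict-majority filter
exists for 3D grids). Per-loop parcellation contexts are supported by running
the segmentation per profile set; whether the original design segmented per
loop or once globally is unknown, and nothing downstream depends on the
choice.

**FC.** Pearson r on region mean series, z = arctanh(r) with |r| clipped at
1 − 1e−7 so z is always finite. Whole-structure series for the atlas scheme
fall back to the mean of the structure's subdivision series, which equals
averaging the voxels they jointly cover. Degenerate edges (empty subdivision,
constant series) raise rather than impute: downstream stages require complete
cases. No nuisance regression, filtering or scrubbing here.

**Group statistics.** χ² for 2×2 tables is Pearson's without continuity
correction — required to reproduce the printed demographic value (0.032 on
[[35,29],[36,28]]; Yates would give ≈ 0). Mann–Whitney z uses the
tie-corrected normal approximation (the convention of standard statistical
packages). FDR is Benjamini–Hochberg; the family is all tested edges of one
scheme across both hemispheres, with a per-hemisphere option since the
original family is unstated. t-tests are Welch by default (Student's pooled
available); with balanced groups the statistics coincide.

**Classification.** Fisher criterion with unbiased within-class variances; a
zero denominator with separated means ranks first (+∞). Features are z-scored
with training-fold statistics only. `ranking_scope='fold'` (default) ranks
inside each LOOCV fold and is leakage-safe; `'global'` ranks once on the full
sample, mirroring the common published variant, and is optimistically biased
— both are exposed and the difference is the user's responsibility. Linear
kernel, C = 1 default (no nested search). Ties on the accuracy curve resolve
to the smallest k. AUC is computed from held-out decision values and equals
concordant-pair counting with half-weight ties. The permutation p is the
literal exceedance proportion k/N (zero possible); a (k+1)/(N+1) variant is
available.

**CPM.** Edge selection by training-set correlation (Pearson default,
Spearman optional) at p_sel = 0.05 via the t approximation; positive and
negative networks are disjoint by construction. Network strength is the
unweighted sum of member z values (so spuriously selected edges dilute the
predictor — visible in the calibration tests). The combined model is a
two-predictor regression on positive and negative strengths; a
`sum-diff` single-predictor variant (positive − negative) is also provided
because the original parameterisation is ambiguous. A fold selecting no
edges predicts the training mean and is flagged; note that if *every* fold is
empty the predictions are exactly anti-correlated with the observed scores
(leave-one-out means), a small-sample degeneracy worth knowing about.
"Well represented" connections are those selected in ≥ `min_frac` of folds
(default 1.0, relaxable). CPM runs on patients only — behavior exists only
for them.

**Pipeline.** Stages run in fixed order (simulate/load → segment → fc →
compare → classify → predict); all randomness flows from named seeds
(simulate, classify-perm, cpm-perm) recorded in `summary.json`, floats are
rounded to 10 decimals and keys sorted, so identical configs give
byte-identical summaries. Wall time is logged but excluded from the summary.
A stage failure aborts with the stage name; partial outputs remain beside a
`FAILED` marker.

## Numerical and testing notes

- Problem sizes in the test suite are chosen for a single-CPU desk run:
  calibration suites use 100 replicates of scaled-down cohorts (e.g. 20/20
  subjects, T = 200 for the false-positive rate; 200-shuffle permutation
  nulls) while single-cohort checks run at the modelled 64/64 scale.
- The reported real-cohort headline metrics of the modelled study (≈ 83%
  accuracy, AUC 0.86, CPM r ≈ 0.35) require the original MRI data, which are
  not redistributable; the suite instead verifies the in-paper computable
  statistics (the demographic χ², the 19/21/40/26 structural counts, the
  0–66 instrument bound) and the statistical properties of every stage
  (oracle equivalence, null calibration, power, parameter recovery,
  determinism).
- Known limitations: no interhemispheric edges, no covariate adjustment, no
  partial or dynamic FC, no probabilistic (non-hard) parcellation, and the
  reconstructed default manifest stands in for the unpublished edge lists.
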
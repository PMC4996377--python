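# Methods

## Model and procedure

The package tests, window by window along the genome, whether a *test*
cohort of aCGH profiles carries copy-number changes that a *control*
cohort lacks. The core objects and steps:

1. **Sections.** Each chromosome arm is covered by windows of
   `section_size` clones (default 20) stepping by `section_size − overlap`
   (default overlap 10). When the last full step does not land on the arm
   end, one extra window anchored at the arm end is appended, so telomeric
   clones are always covered (the final pair of windows may then overlap by
   more than the nominal overlap). Arms shorter than the section size form
   a single section; arms with fewer than 4 clones are skipped and logged —
   a cloud of fewer than 3 points carries no usable β₀ contrast at D = 2.

2. **Embedding.** A section (y₀,…,y_{m−1}) maps to m points in R^D via
   cyclic sliding windows, point j = (y_j, …, y_{j+D−1 mod m}). The
   wrap-around keeps the cloud size equal to the section length and makes
   every value occupy every coordinate slot exactly once; consequently the
   cloud's center of mass has all coordinates equal to the section mean
   (asserted to 1e-12 in the tests). Coincident points are retained as
   distinct members; they merge at ε = 0. Default D = 2: section p-values
   are highly correlated across window sizes (window-size experiment
   below), so nothing is gained by embedding higher.

3. **β₀ curves.** Two points are adjacent when their Euclidean distance is
   ≤ ε (ties connect). β₀(ε) is the component count of that threshold
   graph, computed by one union-find pass over distance-sorted edges; the
   recorded merge heights coincide with single-linkage dendrogram heights,
   and β₀(ε) = m − #{merges at height ≤ ε}. Higher Rips simplices are
   never materialized — they cannot change β₀. The filtration grid is
   uniform with step 0.05 (configurable) from 0 to the smallest step
   multiple ≥ the largest pairwise distance in the comparison, so every
   curve reaches 1 on-grid. The step value only needs to resolve the merge
   heights on the log2-ratio scale; results are insensitive to moderate
   changes.

4. **Cohort comparison.** With mean curves t and c, the statistic is
   S_exp = Σ_{k=0..K}(t_k − c_k)², truncated at the first grid index K
   where both means equal exactly 1 (exact comparison is sound because a
   mean of integer curves equals 1.0 only when every patient is at 1; if
   the curves never jointly reach 1, K is the last index). Significance
   comes from shuffling cohort labels: per-patient curves are computed
   once, and each of B shuffles only re-averages them, recomputing K and S
   per shuffle. The p-value uses the add-one estimator (1 + #{S* ≥ S}) /
   (B + 1), which cannot be 0; an exhaustive mode enumerates all label
   splits and returns the exact fraction instead. All sections of a run
   form a single Benjamini–Hochberg family (the stricter and simpler
   choice; the alternative of per-arm families would only loosen it).
   Sections with a negative signed sum of (t − c) on the truncated grid
   are *control-driven*: their signal describes aberrations of the control
   cohort, and they are excluded from the significant list regardless of p.
   Ties count as test-driven (moot, as S_exp is then 0).

5. **Clone calls.** Within each significant test-driven section, each
   clone's group-mean difference gets a two-sided permutation p; clones
   with p < α (default 0.05) are called gain or loss by the sign. These
   p-values are deliberately not multiplicity-corrected within the section;
   a significant section with no called clone is reported *undetermined*
   (this happens when test and control both carry aberrations at the
   locus).

6. **Whole-arm test.** The window statistic sees only local contrast, so
   full-arm dosage shifts are tested separately: per patient, the arm-wide
   cloud's center of mass reduces to the arm's mean log ratio (the cyclic
   identity above; a `norm` summary |mean|·√D is available as config).
   Two permutation tests must both pass at α: cohort difference, and a
   sign-randomization test of the test-cohort means against 0. The second
   guard drops arms whose displacement is driven by the control cohort.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `section_size` / `overlap` | 20 / 10 clones | window length and sharing between consecutive windows |
| `D` | 2 | embedding window size (cloud dimension) |
| `step` | 0.05 | filtration grid spacing, in log2-ratio distance units |
| `B` | 10 000 (analysis), 1000 (simulation harnesses) | permutations per test |
| `q_threshold` / `alpha` | 0.05 | section FDR level; clone/arm test level |
| `lowess span` | 0.3 | fraction of a chromosome's clones in each local fit |
| `max_distance_bp` | 5×10⁶ | harmonization distance threshold |

Patients may be excluded explicitly via config (`excluded_patients`), as
may whole subtypes from the control set (`excluded_control_labels`);
no automated outlier removal is applied by default.

## Preprocessing

Harmonization against a user-supplied reference clone map removes, in
order: clones absent from the reference; clones whose reference chromosome
differs from the reported one; clones whose reference position lies more
than `max_distance_bp` from the reported position; and, after survivors
take their reference positions, clones whose position is inconsistent with
their immediate surviving neighbors (single left-to-right pass per
chromosome; a clone is dropped when it falls below the last kept position
or above the next surviving one, with ties allowed so that co-located
clones survive). The pass leaves positions non-decreasing, which makes
harmonization idempotent. Clones sharing a position are then averaged per
patient over their non-missing entries, and remaining gaps are imputed by
lowess of each patient's values against position, per chromosome
(statsmodels lowess evaluated at the missing positions with `it=0`,
because robustness reweighting is undefined at out-of-sample abscissae;
the local window is floored at 3 observed points so small strata still
define a fit). Imputation never touches observed entries. Per-patient
rather than pooled imputation is used: profiles differ by genuine copy
number, so pooling would shrink real aberrations.

## Synthetic cohorts and what they do (not) show

The generator draws each clone independently from N(μ, σ) inside a planted
aberration and N(0, σ) outside, σ constant within a profile; the default
cohort is 120 profiles × 100 clones, split 60/60, on one synthetic arm at
1 Mb spacing, aberrations centered in the profile unless placed
explicitly. This reproduces the standard benchmark model for supervised
aCGH methods. It does **not** emulate spatial autocorrelation of real
array noise, GC/print-tip waves, platform-specific dye effects, tumor-cell
admixture, or heterogeneous aberration boundaries — so passing the
calibration experiments demonstrates correctness and power of the
statistic under idealized noise, not performance on any particular
platform.

"Detection" in every experiment means: some section overlapping at least
one aberrant clone is significant after FDR (q < 0.05) and test-driven;
significant sections elsewhere count against specificity. Each harness
takes one integer seed; replicate substreams are
`default_rng([seed, cell, rep])`, making every experiment reproducible and
order-independent.

The four experiments and the problem sizes used by the acceptance script:

* **Overlapping aberrations** — both cohorts carry a centered aberration at
  the same locus; μ ∈ {0.6, 1, −1}, λ ∈ {5, 10, 15}, 30 replicates per
  cell, B = 1000. Cells are pooled by which aberration *magnitude*
  dominates: the β₀ statistic sees only the distance of aberrant points
  from the origin, so |μt| > |μc| is the detectable regime,
  |μc| > |μt| is control-driven (filtered, detection ≈ 0), and equal
  means give neither cohort an edge (detection depends on the length
  difference; the pooled figure is reported for medium-length test
  aberrations, λt = 10 of a 20-clone section).
* **Null specificity** — μ = 0 cohorts, 50 replicates: fraction with no
  significant section at all.
* **Section size** — single cloud of 20/50/80/100 points, planted μ = 1,
  λ = 2 test aberration, 100 replicates per size plus 100 matched null
  replicates. Sensitivity degrades with cloud size: the same two aberrant
  points are a progressively smaller perturbation of the mean curve of a
  larger cloud.
* **Window size** — 50-clone sections over all (λ, μ, σ) combinations with
  λ ∈ {2,3,5,10,20}, μ ∈ {−1,1,0.6}, σ ∈ {0.2,0.5}, 20 repeats, analyzed
  at D ∈ {2, 5, 10}; one cohort and one permutation family are shared
  across the window sizes of a replicate (a paired design isolating the
  statistic itself), and the report is the minimum off-diagonal Pearson
  correlation among the per-dimension p-value vectors.

## Numerical choices and degenerate inputs

* Edge condition ≤ ε; coincident points merge at ε = 0.
* Exact float equality in the K rule is intentional (see above); means are
  sums of small exact integers divided by cohort size.
* All-constant clouds yield the minimal grid {0, step} and a curve
  identically 1.
* Degenerate label vectors (an empty cohort, or fewer than 2 patients per
  group) are rejected with errors, as are sections no longer than D,
  overlapping planted aberrations, and p-values outside [0, 1].
* Chromosome names are accepted with or without the `chr` prefix and
  normalized; sort order is 1–22, X, Y, MT.

## Known limitations

* β₀ is the only topological invariant used; cycles (β₁) and higher
  structure are out of scope.
* The window statistic is insensitive to aberrations common to both
  cohorts at comparable magnitude — by design, since such changes are not
  subtype-specific — and the equal-mean overlap experiment quantifies how
  little power remains in that regime.
* Clone-level calls are uncorrected within a section and should be read as
  localization hints, not genome-wide discoveries.
* The measured sensitivity of the section-size study at 100 points
  (~70%) exceeds historically reported figures for this design (~62%);
  unreported implementation details of earlier tools (filtration
  resolution, permutation count, p-value convention) plausibly account
  for differences of this size. The acceptance script reports whatever the
  current implementation measures.
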
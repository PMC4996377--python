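# taacgh — topological analysis of aCGH copy-number profiles

`taacgh` detects DNA copy-number aberrations (CNAs) that are specific to a
patient subgroup — e.g. a breast-cancer molecular subtype — from array-CGH
log2-ratio profiles. Instead of segmenting each profile independently, it
compares the *topology* of the two cohorts: each window of consecutive
clones is turned into a point cloud, and the number of connected components
of that cloud across a distance filtration (the zeroth Betti number,
β₀(ε)) summarizes how strongly the window's values separate from the
baseline. Aberrations that are common to one cohort and not the other show
up as a persistent difference between the cohort-averaged β₀ curves.

It is aimed at researchers analyzing clone-based (BAC/PAC) or similar
log-ratio copy-number data who want a supervised, segmentation-free test
for subtype-specific gains and losses, together with a full simulation
harness to calibrate its sensitivity and specificity.

## Method

For a section of *m* consecutive log2 ratios (y₀,…,y_{m−1}) on one
chromosome arm (default *m* = 20, consecutive sections overlapping by 10
clones), the cyclic sliding-window map produces the point cloud

    { (y_j, y_{j+1 mod m}, …, y_{j+D−1 mod m}) : j = 0,…,m−1 } ⊂ R^D

with window size D = 2 by default. Points within Euclidean distance ε are
connected; β₀(ε) is the resulting number of connected components (for
component counting only the 1-skeleton of the Vietoris–Rips complex
matters, so β₀ is computed exactly by a union-find over distance-sorted
edges). Averaging over the patients of a cohort gives the mean curves
t_ε (test) and c_ε (control), compared by

    S_exp = Σ_{ε=0..K} (t_ε − c_ε)²,   K = first grid value with t_ε = c_ε = 1.

Significance of S_exp comes from a label-permutation test (add-one
estimator, default B = 10 000 for data analysis), with Benjamini–Hochberg
FDR across all tested sections. Sections whose signal is carried by the
*control* cohort (signed sum of t − c negative on the truncated grid) are
filtered out regardless of p, since they describe the control population.
Within each significant section, per-clone permutation tests classify
clones as gains or losses; whole-arm aberrations, invisible to the
window-level contrast, are caught by testing displacements of the point
clouds' centers of mass (whose coordinates all equal the arm's mean log
ratio under the cyclic embedding), guarded by a second test against the
origin.

The `simulate` module generates Gaussian cohorts (120 profiles × 100
clones, equal test/control split; clone values N(μ, σ) inside a planted
aberration of λ clones and N(0, σ) outside) and drives four calibration
experiments: window size, sensitivity/specificity, section size and
overlapping test/control aberrations.

## Worked example

Simulate a cohort of 30 + 30 patients on one synthetic arm with a gain
(μ = 1, λ = 10 clones) planted at the arm center of the test group, then
run the full analysis:

```python
import taacgh as tg
from taacgh.simulate import centered_aberration

design = tg.SimulationDesign(
    n_test=30, n_control=30, seed=5,
    test_aberrations=[centered_aberration(1.0, 10, 100)])
pm = tg.simulate_cohort(design)

cfg = tg.RunConfig(test_label="test", B=999, seed=0)
rt = tg.run_subtype_analysis(cfg, pm=pm)
print(rt.sections.round(3))
```

Output (columns abridged):

```
arm  section  first_clone  last_clone  K  s_exp     p     q      direction  significant
 1q        0            0          19 26  2.036 0.634 0.884    test-driven        False
 1q        3           30          49 37 52.744 0.001 0.003    test-driven         True
 1q        4           40          59 28 80.871 0.001 0.003    test-driven         True
 1q        5           50          69 30 96.782 0.001 0.003    test-driven         True
 1q        8           80          99 25  8.028 0.093 0.209 control-driven        False
```

Exactly the three sections overlapping the planted clones 45–54 are
significant (q < 0.05, test-driven): their mean test β₀ curve keeps an
extra connected component — the aberrant points sitting away from the
origin — over a long stretch of ε, producing large S_exp and the minimal
attainable permutation p = 1/(B+1). The per-section clone calls
(`rt.clones`) flag the aberrant clones as gains, e.g.:

```
clone_id  position_bp call  mean_test  mean_control     p
sim00047     47000001 gain      1.009        -0.062 0.001
sim00048     48000001 gain      1.106        -0.065 0.001
```

On real data the same pipeline runs from TSV inputs through the CLI:

```sh
taacgh preprocess --matrix matrix.tsv --clone-map clones.tsv \
    --labels labels.tsv --reference-map ensembl_map.tsv --out prep/
taacgh analyze --config run.yaml --test-label basal --out results/
taacgh report --results results/
```

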
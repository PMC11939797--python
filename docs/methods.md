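# Methods

This note records the statistical model behind `pddbench`, the defaults and
why they were chosen, what the synthetic benchmark does and does not show,
and the numerical conventions that make runs reproducible.

## Model and assumptions

PDD treats a records × features table of non-negative reals as a collection
of discrete events. Discretization maps each feature to one attribute value
(AV) per record; class labels are AVs of a designated label attribute, so
label–feature and feature–feature associations are measured identically.

The association statistic is the adjusted standardized residual of
contingency-table analysis: for AVs a, b with co-occurrence count o,
marginals n_a, n_b and n records,

    e = n_a n_b / n,   z = (o − e)/√e,   v = (1 − n_a/n)(1 − n_b/n),   d = z/√v.

Under independence d is approximately standard normal, so a fixed threshold
τ doubles as a significance level. The approximation assumes expected
counts that are not tiny; with the default Q = 3 bins plus a zero bin on
n ≥ 1000 records the smallest expected cells are in the tens. Degenerate
cells (e = 0, or an AV present in every record, v = 0) are defined as 0 —
non-informative rather than infinite. Pairs of AVs from the same attribute
are structurally exclusive and forced to 0. No multiple-testing correction
is applied to the matrix; τ is a per-pair threshold and the null
calibration test pins the matrix-wide false-positive rate at its nominal
≈5% for τ = 1.96.

Disentanglement eigendecomposes the symmetric SRM. Components are ranked by
|eigenvalue|; the projection of AV a on component c is
`eigvec_c[a]·√|λ_c|`. Within a component, projection sign splits AVs into
two contrasting groups, and each group is partitioned into AV subgroups:
the connected components of the significant-association graph restricted to
the group. This is the unique structure in which every member is associated
with at least one other member and with none outside the subgroup. AVs may
appear in several spaces; the knowledge base keeps every occurrence, since
pruning to a single "best" space would hide genuine multi-component
structure.

A knowledge-base row ties one subgroup to one class AV. Its Pattern Section
lists the subgroup AVs whose residual against that class AV exceeds τ.
The restriction matters: connected components routinely chain a class AV to
AVs *anti*-associated with it through hub AVs (zero bins shared by several
classes), and a pattern that "appears" when an anti-associated event occurs
would invert the meaning of coverage. Unlabeled subgroups (no class AV)
keep all their AVs. Coverage for a record is the number of the row's AVs it
matches; a pattern "appearing three times" in a record means three of its
AVs are present.

Classification scores class c for record r as the matched fraction: the sum
of coverage over c's rows divided by the total number of AVs in c's rows.
The raw summed coverage is exposed too, but the fraction drives assignment:
classes accumulate different numbers of pattern AVs across spaces, and the
raw sum would hand larger pattern sets a constant additive advantage
(observed as a ~15-point balanced-accuracy loss on the synthetic
benchmark). The fraction is invariant under splitting a row into same-class
rows, because numerator and denominator are both additive. Ties break
toward the class with the highest training prevalence, then the lowest
class index. Normalized scores serve as probabilities for ROC-AUC; PDD has
no native probability model, and this is the standard way to score a
match-count classifier on threshold metrics.

## Attribution and faithfulness

The attribution suite works against a minimal classifier contract:
`predict_proba` over records and a per-record gradient of a class
probability with respect to the inputs. A central finite-difference
fallback (relative step 1e-5) covers models without analytic gradients; the
step was chosen so the fallback agrees with analytic softmax gradients to
better than 1e-6 relative while staying far above roundoff. All attribution
is computed on the probability scale, the same scale the faithfulness
metrics subtract on.

The reference classifier is a multinomial logistic model on standardized
features, fitted with scikit-learn's L-BFGS solver (a gradient-based
optimizer; `epochs` caps its iterations) with C = 10, and exposing the
analytic input-gradient p_j(W_j − Σ_c p_c W_c)/s elementwise over the
standardization scales s. It exists so the faithfulness suite has a
deterministic, differentiable model to audit; it is not a claim about deep
baselines.

Integrated Gradients integrates the probability gradient along the
straight path from baseline to input with the midpoint rule. Midpoint has
O(1/m²) quadrature error, so the completeness identity
Σ_i IG_i = p_j(x) − p_j(baseline) holds to ~1e-4 at 50 steps; an endpoint
(Riemann) rule has O(1/m) bias, which on saturating softmax paths is ~1e-2
at the same step count — too coarse for completeness to be a usable
diagnostic. Gradient SHAP follows the expected-gradients scheme: noise the
input (σ defaults to 0.09 × the per-feature value range), draw a baseline
and a uniform interpolation point, accumulate (x − b)·∇p_j. Feature
permutation reports the mean absolute probability change under seeded
column shuffles; the absolute value is deliberate, as sign is meaningless
after shuffling.

Faithfulness follows the rationale-removal scheme with levels
B = {1, 5, 10, 20, 50} percent. The rationale size is ceil(k/100 · F) with
a floor of 1; ties in importance break toward lower feature index. Removal
sets features to a baseline value of 0 — these are fixed-length vector
positions, not tokens, and 0 is the natural absence value for TF-IDF and
topic weights. Sufficiency, comprehensiveness, and sensitivity are signed
differences averaged over B and then over the records whose *true* label is
the evaluated class (conditioning on the predicted label is available as
`target="predicted"` when computing attributions). Sensitivity noises only
rationale features with Gaussian noise whose σ defaults to the same
0.09 × range convention. Window curves use absolute differences — they
measure a distance — over consecutive windows of 5 ranked features,
ceil(F/5) windows in total. Report averages are exact unweighted means of
the per-class values, summed in sorted class order so the result does not
depend on dict construction order; rounding to 3 decimals happens only at
display.

## Synthetic benchmark

The generator emulates the statistical silhouette of L2-normalized TF-IDF
tables: a background entry is exactly 0 with probability π = 0.6, otherwise
|N(0.02, 0.01)|. Each of 4 equiprevalent classes owns 3 disjoint
informative features; for records of that class the feature's zero
probability drops to π/4 and its mean shifts up by δ = 0.05 (five
background standard deviations). Default size is 2000 records × 30
features. At δ = 0 the informative modification is disabled entirely —
including the zero-rate change — so the table is an exact null with labels
independent of features. Ground truth records each class's informative set
and shift direction; a planted pair counts as recovered when a
knowledge-base row ties the class to the feature's top bin.

What passing shows: the residual/disentanglement machinery finds planted
value-level associations (recall ≥ 0.95 over 10 seeds), pattern matching
classifies at balanced accuracy ≥ 0.90 held out, and everything collapses
to chance on the null. What it does not show: behavior under correlated
vocabularies, label noise, heavy class imbalance, or the semantic
structure of real clinical notes — the generator's features are
conditionally independent given the class, which real TF-IDF columns are
not. An `overlap` of informative sets across classes (shared symptoms) can
be emulated by passing overlapping indices, but the default keeps sets
disjoint so recovery has an unambiguous answer.

## Defaults and knobs

| Knob | Default | Why |
| --- | --- | --- |
| Q (bins/attribute) | 3 + zero bin | zero-inflated tables; low/medium/high reading of positive mass |
| τ (significance) | 1.96 | two-sided 5% normal quantile |
| θ (projection threshold) | 0 | sign alone defines the contrasting groups |
| retained spaces | \|λ\| ≥ 1% of max, cap 10 | drop numerically negligible components |
| B levels | 1, 5, 10, 20, 50 (%) | standard rationale-removal ladder |
| window w | 5 | effectiveness curves at the granularity importance rankings are read |
| σ (noise) | 0.09 × feature range | common expected-gradients convention |
| split | 70/10/20 stratified | stratified because every metric here is imbalance-sensitive |

Interval convention: bins are left-open right-closed, the lowest bin closed
at its left edge; the zero bin is the singleton {0}. Ranges render as
percentages when the table is probability-like (max ≤ 1). Out-of-range
values at apply time clamp to the outermost bin rather than erroring —
test-time robustness. Eigenvectors are sign-fixed so their
largest-magnitude entry is positive, making group numbering stable across
platforms; subgroups order by descending size, then smallest AV index.
Splits compute integer test/validation counts (round(n·fraction)) before
calling the stratified splitter, so 100 records at 70−10−20 give exactly
70/10/20.

Problem sizes in the test suite and acceptance script (600–2000 records,
12–30 features, 10 seeds for recovery) were chosen as the smallest at which
the binomial and spectral approximations are comfortably in regime; the
statistics of interest stabilize well below them.

## Known limitations

- The adjusted-residual normal approximation degrades for very rare AVs;
  with many bins on small data, τ no longer tracks the nominal level.
- Connected-component subgroups are sensitive to single spurious edges on
  dense graphs; the per-class residual filter in the knowledge base
  contains the damage for classification but the Knowledge Section still
  reflects the merged component.
- Match-fraction scoring assumes pattern AVs are roughly exchangeable in
  evidential weight; a residual-weighted variant (`residual_weighted=True`)
  is available when they are not.
- The faithfulness suite's conditioning (true vs predicted label) and the
  sensitivity σ are genuinely free choices; both are exposed as
  configuration, and conclusions can shift with them.
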
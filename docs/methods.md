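# Methods

## The calibration model

`ontothresh` treats threshold determination as an empirical classification
problem. The input is a partition of genes into groups whose members are
expected to be functionally similar (families, pathway memberships, homolog
sets). Every unordered intra-group pair contributes one value to the S
("similar") distribution and every cross-group pair one value to the N
("non-similar") distribution, for any pairwise measure with values in
[0, 1]. The modelling assumptions are:

1. group labels are a usable proxy for ground truth — intra-group pairs are
   genuinely similar, inter-group pairs genuinely not;
2. the measure is informative — S and N differ in location. This is checked,
   not assumed: Welch's unequal-variance two-sided t-test gates the
   procedure, and p ≥ α means the groups must be redefined
   (`SimilarityThresholdModel.fit` raises unless `force=True`);
3. pooled values are treated as exchangeable within S and within N, even
   though pairs sharing a gene are not independent. The t-test is used as a
   gate, not as an inferential claim about pair-level independence.

Three thresholds are then read off the two samples. With *a* the lower
Tukey whisker of S and *b* the upper Tukey whisker of N: τ_S = max(a, b)
(above it no false positives are possible within whisker range), τ_N =
min(a, b), and τ_opt the smallest grid point in [τ_N, τ_S] minimizing
FN(τ) + FP(τ), where FN(τ) is the proportion of S strictly below τ and
FP(τ) the proportion of N at or above τ. A value equal to a threshold
counts as a positive call everywhere in the package (similarity, both
particularity signs, FN/FP counting); mixing conventions would make the
pattern truth table inconsistent with the scan objective.

When the whisker ranges do not overlap (a > b) every τ in (b, a) is
error-free; the midpoint is reported as τ_opt and the full gap as the flat
interval. Otherwise the scan reports the maximal contiguous grid run
attaining the minimum (the plateau) and its left end as τ_opt, making the
result deterministic.

The particularity threshold reuses the machinery with a different
objective: (sim, par_ab, par_ba) triples over all gene pairs are classified
into the eight sign patterns at a fixed τ_sim, and τ_par minimizes the
pooled proportion of the two uninformative patterns "+ + +" and "- - -"
over a [0, 1] scan. No FN/FP reading exists here because similar genes may
legitimately be somewhat particular; the uninformative-pattern proportion
is the quantity a useful threshold should make small.

## Measures

* **Wang.** Semantic contributions decay multiplicatively along the best
  root-ward path, with per-relation factors 0.8 (`is_a`), 0.6 (`part_of`)
  and 0.7 (the `regulates` family), all user-overridable but constrained to
  (0, 1). The recurrence is evaluated in topological order restricted to
  the target's ancestor closure, so it is deterministic and O(edges).
* **Lin.** IC(t) = −ln(term_count[t] / total) with gene counts propagated
  root-ward (a gene counts once per ancestor regardless of annotation
  multiplicity) and total the number of annotated genes in the namespace.
  Terms annotating no gene have *undefined* IC and any measure touching
  one raises; smoothing would silently distort Lin values. Natural log is
  cosmetic (Lin's ratio is base-invariant). The 0/0 case (both terms the
  root) is defined as 1: identical terms are maximally similar.
* **simUI / simGIC** operate on ancestor closures of the direct annotation
  sets; all set-level inputs throughout the package are *direct*
  annotations, with closures taken inside each measure's own construction.
* **MICA** ties are broken toward the lexicographically smallest term id,
  for cross-platform determinism.
* **Gene-level combination.** Wang uses its own (m+n)-weighted best-match
  sum; Lin uses the best-match average (mean of the two directional means),
  with the pooled (m+n)-weighted variant selectable (`pooled=True`) — the
  two differ when annotation set sizes differ.

## Particularity

MPT(Sg1, Sg2) keeps the terms of Sg1 with no proper descendant in Sg1
(literally the raw set, not its closure) that are outside Sg2's ancestor
closure. PI sums, per MPT term, the informativeness beyond the most
informative ancestor shared with Sg2. Two deliberate choices:

* **MCT reading.** The normalizer MCT is by default the set of leaves of
  the shared sub-graph Sg1* ∩ Sg2* ("no descendant within the
  intersection"). The literal alternative — excluding any shared term with
  a descendant in *either* full closure — can empty MCT whenever the sets
  share only upper-level terms, driving Par to 1 discontinuously; it is
  available as `mct_mode="literal"`. The default keeps Par continuous in
  shared content, which matches the normalizing role MCT plays.
* **PI clamping.** Wang SV is not monotone along edges on multi-parent
  DAGs: an ancestor with many parents can have a larger SV than its child,
  so the raw difference I(tp) − I(MICA) can be negative. Each term's
  contribution is clamped at zero: a particular term whose best shared
  ancestor is more informative contributes no particular information. On
  monotone informativeness (IC always; SV on tree-like regions) the clamp
  is inert. Without it Par can leave [0, 1], which the pattern
  classification requires.

## Synthetic data generator

`SynthSpec` defaults describe the standard study conditions used across the
test surface: a 300-term single-rooted DAG (each later term takes one
uniform parent plus up to two extras with probability 0.15; relation kinds
drawn 80/12/8% is_a / part_of / regulates family, loosely patterned on GO's
edge composition), six groups of ten genes, 3–8 direct terms per gene, and
coherence 0.9 — each term drawn from the group's "home" sub-DAG with
probability 0.9 and uniformly otherwise. Homes are pairwise-disjoint
descendant sub-DAGs of 6–24 terms, picked smallest-first so six of them
pack reliably; group count and sizes follow the six-groups design of the
calibration workflow, and coherence 0.9 plants a clear but imperfect
separation so both the no-overlap and the overlap code paths occur across
seeds. One integer seed drives a single random stream.

What the generator does *not* emulate: GO's term-depth and fan-out
distributions, annotation-count skew across genes, evidence-code structure,
or between-group relatedness (homes are disjoint; real families share
function). Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not performance on
real GO/GOA corpora.

`planted_separation` generates S/N value samples directly (bypassing
ontologies) with a known boundary θ, a ±0.01 gap, and a fixed contamination
fraction planted on the wrong side within 0.1 of the gap: the minimal
achievable FN+FP is 2·ρ by construction, giving an exact target for
recovery tests at n = 500 values per side.

## Numerical choices

* Scan grid step 0.005, inclusive of both ends; grid points are rounded to
  12 decimals to keep plateau detection exact under float accumulation.
* Objective ties within 1e-12 are treated as equal when locating the
  plateau.
* Quartiles use linear interpolation (numpy default); `whiskers` also
  offers `minmax` for box-plot conventions without outlier fences.
* Welch gate α = 0.05, two-sided.
* Degenerate inputs raise described errors rather than returning NaN:
  empty annotation sets, zero-variance-both-sides t-tests, empty S or N,
  terms with undefined IC.
* Par 0/0 (nothing particular, nothing shared-informative) is 0; simGIC on
  closures with zero total IC is 1 for identical closures and 0 otherwise.

## Problem sizes

The default test and reproduction runs use the 300-term / 60-gene synthetic
conditions (1 770 gene pairs per calibration), 100 random DAGs of ≤ 30
terms for oracle equivalence, and 10 seeds × 1 000 values for boundary
recovery; the whole suite and the acceptance script each complete in well
under a minute on one core, and scale linearly in pairs if larger corpora
are supplied.

## Known limitations

* Cross-namespace comparisons are rejected rather than bridged; multi-
  namespace ontologies are split at load time.
* Edge kinds without a contribution factor are dropped with a warning, so
  ontologies using e.g. `occurs_in` lose those links for every measure.
* The leave-one-out spread is reported against the flat-interval width; at
  small sample sizes (tens of genes per group) plateaus are only a grid
  step or two wide and the spread routinely exceeds them — stability claims
  need corpus-scale inputs.
* Pair values within a group share genes; the Welch gate ignores this
  dependence (as a gate, not a test of record).
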
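# Methods

## Estimation model

All information quantities are maximum-likelihood plug-in estimates on
discrete variables, in bits: probabilities are raw frequency counts from a
1–3-way contingency table, `0·log 0 := 0`, and no smoothing or bias
correction is applied (the criteria compare scores *within* one dataset, so
the common plug-in bias largely cancels). Mutual information and conditional
mutual information are computed through entropy identities
(`I(X;Y) = H(X)+H(Y)−H(X,Y)`, `I(X;Y|Z) = H(X,Z)+H(Y,Z)−H(Z)−H(X,Y,Z)`);
entropy sums sorted counts so the estimators are exactly symmetric in their
arguments, and negative values above −1e−9 (floating-point cancellation) are
clamped to zero. Differential entropy and kernel/k-NN estimators are out of
scope: continuous columns are discretized first.

Degenerate cases are made total rather than erroring where a sensible value
exists: the CU factor `2/(H(f_s|C)+H(f_k|C))` is defined as 0 when its
denominator is below 1e−12 (both features deterministic given the class —
the candidate is then judged on relevance alone), while the DWFS/DWUR/DRJMIM
ratio `C_Ratio` raises a degenerate-input error when `H(f_k)+H(C) = 0`,
because no meaningful ranking exists for a constant feature under a constant
class. A constant class column is rejected outright by the selection driver.

Although `I(f_i;f_j) = 1` is sometimes treated as "fully redundant" in
informal discussions of these criteria, MI is not bounded by 1 for
multi-category variables; no normalization of MI itself is performed here.

## Criteria and search

All eight criteria share one greedy forward search: score every candidate,
move the argmax into the selected set, repeat until K features are chosen.
Ties break to the lowest feature index (column order) and non-finite scores
rank last, so runs are bit-for-bit deterministic. Empty sums/maxima/minima
over the selected set are defined as 0, which makes every criterion's first
step plain MIM — the maximum-MI feature seeds the search, matching the usual
initialize-with-argmax-MI formulation of these algorithms.

Pairwise statistics (`I(f;g)`, `I(f;g|C)`, `I(f;C|g)`, `I(g;C|f)`) are all
derived from a single 3-way tabulation per feature pair and memoized, so a
T-step search over n features performs at most `T·n` pairwise tabulations of
m samples each — O(Tmn) total work. An instrumentation counter on the
selection state asserts this bound in tests, and a no-cache execution path
guards cache correctness.

Design choices that the printed formulas leave open, resolved here:

- **DRJMIM grouping.** The criterion is read as
  `min_s [ I(f_k;s;C) · (I(f_k;C) + C_Ratio(f_k,s)·I(s;C)) ]` — the minimum
  taken over the whole product. The alternative (minimizing the interaction
  term only, then multiplying) is noted but not implemented; with one
  selected feature the two coincide.
- **DWFS/DWUR step rule.** Both are weight-update recurrences: after each
  selection, every remaining candidate's weight is multiplied by the update
  term against the newly selected feature. DWFS ranks by
  `W(f_k)·I(f_k;C)` (its multiplier is a pure adjustment factor around 1);
  DWUR's multiplier already contains the relevance term, so it ranks by
  `I(f_k;C)` before the first update and by `W(f_k)` afterwards. The DWFS
  "+1" is placed outside the normalized difference, keeping multipliers
  positive near independence.
- **DWUR redundancy factor.** The `(1 − β·I(f_k;f_s))` discount that
  distinguishes DWUR from DWFS is included; β defaults to 0.5 and is exposed
  as a configuration knob, since no canonical value exists.
- **NDCRFS conditioning direction.** The penalty charges `I(f_k;f_s|C)`
  (feature–feature coupling given the class), not `I(f_k;C|f_s)`; the two
  appear interchangeably in informal statements of the algorithm, but the
  worked fixtures here pin the former.

### A known limitation: NDCRFS and pure synergy

The NDCRFS penalty term `CU·(I(f_k;f_s|C) − I(f_s;C))` does not distinguish
redundancy from synergy: for an XOR pair, `I(f_k;f_s|C)` is *maximal* (given
the class, each member determines the other), so once one member of an
interacting pair is selected the other is penalized by roughly `CU` bits and
ranks below independent noise. CMIM/CIFE/JMI, whose penalty
`I(f_k;f_s) − I(f_k;f_s|C)` turns *negative* under synergy, reward the
partner instead. The acceptance suite asserts synergy recovery for all of
NDCRFS/CMIM/CIFE on seeded XOR designs; the NDCRFS case fails, and is left
failing deliberately — it documents a real property of the criterion as
printed, not an implementation defect. The duplicate-rejection behaviour
(the criterion's actual strength) holds only when conditional coupling
exceeds the selected feature's relevance: near-duplicates of *weakly*
relevant features are crushed, while copies of strongly relevant features
(e.g. the ρ=0.1 planted design below, where `I(rel;C) ≈ 0.71` bits exceeds
`I(copy;orig|C) ≈ 0.17` bits) still receive a net bonus and are admitted,
exactly as the formula dictates.

## Discretization

CAIM is the default class-aware scheme: candidate boundaries are midpoints
between consecutive distinct values; boundaries are added greedily, each step
keeping the candidate maximizing the quanta-matrix criterion
`(1/r) Σ_intervals max_class_count² / interval_total`, and the search stops
once the score no longer improves and at least as many intervals exist as
classes. Fitting is order-invariant and every trained interval is non-empty;
constant columns yield a single-bin scheme. Coding counts cut-points strictly
below the value, so out-of-range test values clamp to edge bins and coding is
monotone. Equal-width and equal-frequency binning (default 5 bins) are
provided as explicitly labelled unsupervised fallbacks. Integer columns with
≤ 10 distinct values (configurable) are treated as already discrete.

In cross-validated evaluation, schemes are fitted on training folds only and
applied to test folds (asserted by a spy in tests); a `discretize_once`
switch reproduces the laxer fit-on-all-rows protocol for comparability with
published setups that do not specify per-fold fitting. Rows with missing
values are deleted at load time.

## Evaluation harness

Accuracy curves are stratified 5-fold cross-validation (seeded, recorded in
the report), reported in percent for each subset size K = 1..K_max using the
first K ranked features; the reference classifier adapters are scikit-learn's
KNN (k = 3), CART decision tree (standing in for C4.5) and RBF-kernel SVC,
with hyperparameters exposed because the benchmark protocol fixes none.
Reports carry the full curve *and* the best value with its smallest argmax K,
so either reading of "accuracy at K" versus "best accuracy over K" is
available. Subset differences use the Jaccard index `|S1∩S2|/|S1∪S2|`
(equal-size subsets of size K can only produce values `i/(2K−i)`,
i = 0..K — a useful integrity check on any printed table of them), and
accuracy lists are compared as wins/ties/losses at 3-decimal precision.
Published cross-dataset accuracy tables are *not* reproduction targets: they
require external UCI/ASU downloads and unstated hyperparameters.

## Synthetic designs

The generator plants four roles around a uniformly drawn class: relevant
features (class copies, each value re-sampled uniformly with probability ρ),
redundant features (corrupted copies of relevant ones), interacting pairs
(trigger X plus partner `(C − X) mod k`, i.e. XOR for binary, each member
marginally (near-)independent of the class but jointly determining it), and
uniform irrelevant noise. Uniform re-sampling rather than bit-flip noise is
used for relevance so the scheme generalizes beyond binary alphabets; roles
live in a JSON sidecar, never in the table itself. For binary designs the
closed-form `I(f;C)` of every role is available (`expected_mi`) and the
empirical estimates are tested to converge to it.

The standard benchmark condition is n = 500 samples, binary class,
5 relevant features at ρ = 0.1, 5 redundant copies at 5% corruption, one
XOR pair, 20 irrelevant features. The synergy fixtures use one XOR pair with
a biased trigger (P(X=1) = 0.75) over 20 noise features: the bias gives the
parity partner a weak marginal leak (≈ 0.19 bits), which is what makes a
hidden pair discoverable by *any* pairwise forward criterion — with an
exactly zero-marginal pair, the first member can only ever enter the
selected set by chance. What these designs do **not** emulate: real
microarray marginal distributions, correlated noise across irrelevant
features, multi-way (beyond pairwise) interactions, or continuous
measurement noise; passing tests therefore demonstrate the criteria's
ordering behaviour under clean planted structure, not expected accuracy on
real tissue data.

Problem sizes throughout the test and acceptance suites (20 seeds per
property, n = 500–2000 samples, ≤ 35 features) are chosen so each empirical
property is decided by a comfortable signal-to-noise margin at desk scale.
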
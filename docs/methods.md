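# Methods

## The model

A corpus is a multiset of transactions, each the set of medical-problem
identifiers on one patient record. An association rule `X → Y` (disjoint
non-empty item sets) is summarized by support `supp(X∪Y)`, confidence
`supp(X∪Y)/supp(X)` and lift `confidence/supp(Y)`; lift > 1 indicates
positive dependence between the sides. The task is binary: is a mined rule
a real dependency (true) or a spurious/trivial one (false)?

Three classifiers of rules are built and compared:

* **Unsupervised** — rank rules by the one-sided Fisher exact p-value of
  their 2×2 presence table and threshold it. The table is counted on a
  holdout half of the corpus disjoint from the exploratory half the rules
  were mined on; this keeps discovery and assessment independent and
  controls false discoveries.
* **Supervised** — a random forest over the five-feature vector
  `(support, confidence, lift, |X|, |Y|)`, trained on labeled rules.
* **Semi-supervised** — the incremental loop: train the forest on the
  current seed; pick the p-value threshold that maximizes correct seed
  classifications; move every development rule on which forest and filter
  agree into the seed with the agreed label; repeat until no rule moves.
  The loop is self-training with a twist: the "second opinion" is not a
  second trained model but a fixed unsupervised statistic, so the two
  votes are genuinely independent sources of evidence.

## Key procedures and conventions

**Fisher test.** One-sided over-representation by default: with all
margins fixed, `p = P(N₁₁ ≥ n₁₁)` under the hypergeometric law (only
positive dependence is of interest; the two-sided variant is available).
Computed via `scipy.stats.hypergeom.sf`, clamped into `(0, 1]`.
Degenerate tables — zero transactions, or an antecedent/consequent that
never appears in the holdout — return p = 1, so holdout-invisible rules
rank last rather than erroring. Exactness is enforced in tests by
comparing against rational-arithmetic tail enumeration for every 2×2
table with N ≤ 30 (46 376 tables, agreement to 1e-12).

**Mining.** Apriori over vertical tid-lists; any exact algorithm would
do, and the test suite requires output identical to power-set/bipartition
enumeration on small corpora. Lift is computed as
`count(X∪Y)·N / (count(X)·count(Y))` — integer products before one
division — so exactly representable ratios (e.g. 0.72/0.60 = 1.2) come
out exact. Canonical orders: itemsets by (length, lexicographic); rules
by (descending support, lexicographic antecedent, consequent). The
`min_lift` bound is inclusive so independence-boundary rules stay visible
to the classifier. Default parameters (supp 0.01, conf 0.7, lift 1,
|X| ≤ 4, |Y| = 1) are the reported mining configuration; all are
exposed.

**Threshold selection.** The seed is sorted ascending by p; rules sharing
one p-value form an atomic block (never split, so any threshold
classifies them identically under the `p ≤ t` rule). All block-boundary
cuts are scanned; hits = true rules before the cut + false rules after
it. Ties in hits resolve to the smallest cut — fewest rules called true —
because false positives are the costly error here. The returned threshold
is the geometric mean of the flanking p-values (p-values span hundreds of
orders of magnitude, so the log-space midpoint is the natural separator),
with boundary cuts mapping to 0 and 1 and a one-ulp guard so re-applying
the threshold always reproduces the optimal hit count.

**Supervised module.** `RandomForestClassifier` with 100 trees, √5
features per split, unlimited depth — conventional defaults recorded in a
training manifest; the original study reported the algorithm choice but
not its hyperparameters. Score ≥ 0.5 maps to "true". A single-class
training set yields a constant predictor instead of an error because tiny
seeds are often class-skewed; with an all-false seed the threshold is 0,
both modules predict false everywhere, and the loop absorbs the entire
development set as false in one iteration — degenerate but well-defined.
Any estimator with `fit`/`predict`/`predict_proba` can replace the forest.

**The loop.** P-values are intrinsic rule attributes computed once, up
front, from the exploratory/holdout procedure; only the threshold is
re-selected each iteration, from the current seed (gold + agreed labels).
Promoted rules carry the *agreed* label, never their hidden gold label —
using gold labels would silently make the method supervised. Development
gold labels are retained only for post-hoc audit and evaluation; the loop
never reads them (structurally: they are not passed in). Every non-final
iteration strictly shrinks the development pool, so termination within
|development| + 1 iterations is guaranteed; a `max_iter` cap (default
100) guards misconfiguration. Splits: test = 20% by seeded shuffle,
stratified by default so small corpora keep both classes in the test set;
the seed is an absolute-size uniform draw from the training rules
(default 10, the size that performed best in the original study).

## The synthetic world

Real annotated corpora of this kind are restricted clinical data, so the
benchmark runs on a generative model chosen for *exact* ground truth
rather than maximal realism:

* every non-consequent item is an independent Bernoulli(π) "problem";
* each planted dependency `A_r → c_r` draws its consequent
  Bernoulli(q_r) when all of A_r is present, Bernoulli(b_r) otherwise,
  with q_r > b_r;
* planted components are item-disjoint, so the joint law factorizes and
  the population lift of any rule is closed-form (`model_lift`); a rule's
  gold label is `lift > 1` strictly. This is a formal surrogate for
  clinical annotation: like the human annotators it replaces, it calls
  certain-but-trivial dependencies true and cannot encode clinical
  interestingness.

Default world (`default_benchmark_spec`): 40 items, 2000 patients, 10
planted rules with 1–2-item antecedents, q ∈ [0.7, 0.95],
b ∈ [0.02, 0.1], antecedent prevalences in [0.1, 0.18], plain background
in [0.05, 0.12], and two "common comorbidity" items with π ∈ [0.7, 0.8].
The common items are essential: under a 0.7 confidence floor, a rule
predicting an independent consequent is only minable when that consequent
is itself ~70% prevalent, so they supply the gold-false class
(high-confidence, lift-exactly-1 rules); the low background prevalences
keep antecedent-superset variants of planted rules from exploding
combinatorially. At these defaults a replicate mines ≈ 1100–2100 rules,
~40% gold-true — the scale of the original ~1300-rule annotated corpus.

**Truncation caveat.** Empty transactions are redrawn (a patient record
lists at least one problem), which conditions the sampled distribution on
non-emptiness and inflates every frequency by ≈ `1/(1 − P(empty))`.
Labels and `model_lift` deliberately stay on the *untruncated* factorized
model, where independent rules have lift exactly 1; the bias is exposed
as `model_empty_probability` (≈ 0.5% in the default world, < 1% in every
test world) and folded into the fidelity-test tolerances. Worlds with few
rare items make it large; design custom worlds accordingly.

**What a green benchmark does and does not establish.** The generator's
labels are a noiseless function of population lift while empirical lift
is a feature, so the synthetic task is close to separable — all three
approaches reach far higher absolute scores than any clinical corpus
would allow, and the unsupervised filter (with an oracle best-F threshold
sweep on the test rules, mirroring how the original unsupervised module
was assessed) can even lead. Green directional checks therefore establish
the *structure* of the result — the incremental loop recovers most of the
supervised signal from 10 labels, its first iteration moves the largest
coincident batch, seed growth is monotone and convergent — not the
magnitudes of any published comparison. Absent from the world by design:
item-name semantics, coding/temporal structure, overlapping or chained
dependencies (ground truth would require graphical-model inference), and
annotator subjectivity.

## Numerical choices

* p-values clamped to `[5e-324, 1]`; thresholds combined in log space.
* Rule-filter comparisons (`conf ≥ min_conf`, `lift ≥ min_lift`) are
  plain float comparisons on exactly-recounted ratios — deterministic and
  oracle-reproducible.
* `label_rule` uses `lift > 1 + 1e-9`: the tolerance absorbs only float
  round-off (cross-component lifts are exactly 1.0 by construction;
  planted effects push lift far from 1).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / estimator `random_state`); benchmark
  replicates derive child seeds via `SeedSequence.spawn`. Fixed seeds
  reproduce traces byte-identically.

## Limitations

* The loop can converge to a wrong fixpoint from a single-class seed
  (probability ≈ 0.6% per benchmark replicate at seed size 10); this is
  inherent to the method, not guarded against, and visible in benchmark
  dispersion.
* Clinical-text normalization is reduced to casefold + whitespace
  collapse; items are opaque strings.
* Multi-item consequents beyond the configurable cap, rule-redundancy
  pruning, χ² testing and multiple-testing corrections are out of scope.
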
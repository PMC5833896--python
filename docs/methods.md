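# Methods

## The problem

Structure-based virtual screening docks every molecule of a library against
a receptor and ranks them by docking score. Docking is expensive, and the
overwhelming majority of any screening library scores poorly; almost all of
the compute is spent confirming non-binders. `cpvs` implements an iterative
triage: dock a small sample, learn which structural features predict a poor
score, discard ('prune') molecules that are *confidently* predicted
low-scoring, and keep iterating until the model is decisive enough — then
dock only the remaining predicted high-scorers. The confidence machinery is
conformal prediction, which turns "confidently predicted low-scoring" into
a statement with a distribution-free guarantee.

Throughout the package, higher score = better binder. Engines where lower
is better are negated on ingest (`score_higher_is_better: false`).

## Features: the signature descriptor

Each atom contributes, per height h, a canonical string describing its
bonded environment out to h bonds: a breadth-first expansion tree where an
edge never turns straight back toward its immediate parent (ring atoms may
recur on other branches), nodes rendered `[El]` with a bond-order prefix on
the incoming edge (none for single, `=` double, `#` triple), children
sorted lexicographically by fully rendered subtree, child lists wrapped in
`(...)`. A molecule's feature vector is the count of every signature string
over heights 1–3. Design choices worth noting:

* **Tree expansion, not the canonical-DAG construction** from the original
  descriptor literature: at heights 1–3 the variants rarely differ, the
  tree is simpler, and it is deterministic by construction. Canonicality is
  enforced by the lexicographic child sort and checked in tests against a
  brute-force enumerator that exhaustively permutes child orderings.
* **Raw counts, not binary presence**, as feature values.
* Heavy atoms only; hydrogens are implicit. Aromatic input is kekulized;
  when kekulization fails the bonds are read as single with a warning.
  Charges, isotopes and stereochemistry are dropped (nothing downstream
  uses them).

## Labels: 10-bin histogram + bin scheme

Docking scores (all docked so far, cumulatively) go into a 10-bin
equal-width histogram spanning [min, max] of the raw scores. A score on an
interior edge belongs to the higher bin; the last bin is right-closed. The
bin scheme `a_b` labels bins ≤ a as class 0 ('low-scoring'), bins ≥ b as
class 1 ('high-scoring'), and excludes the bins between from training
entirely. Default scheme `1_5`. The histogram is *recomputed every
iteration* from all accumulated scores, so bin edges drift as data accrues
and previously excluded molecules can re-enter the labeled set. If a class
ends up with fewer than two labeled examples (it could not be split into
proper-training + calibration), the offending boundary is widened by one
bin, once; if that still fails the run aborts with a diagnostic.

## Model: mondrian inductive conformal prediction

The underlying scorer is a linear SVM on the sparse signature counts:
squared-hinge loss with an L2 penalty (`reg`, default 1e-2) and an
unpenalized intercept, minimized by L-BFGS capped at 50 iterations (a
non-converged model is used as-is, with a warning — the cap is part of the
operating point). Weights start at zero, so the fit is deterministic.

The labeled set is split 90/10 (stratified per class) into proper-training
and calibration; the calibration split is re-drawn with a fresh
seed (derived from run seed + iteration index) at every retraining to
avoid calibration staleness as the training set grows. Nonconformity is
the negated signed decision toward the hypothesized class
(α(x,1) = −d(x), α(x,0) = +d(x)), the standard choice for SVM-based ICP —
it needs no probability calibration. P-values are unsmoothed,

    p_l = (#{α_i ≥ α_new} + 1) / (n_l + 1),

with ties counted on the ≥ side; both choices are deterministic and make
the validity guarantee conservative. Calibration is class-conditional
(mondrian), which keeps the per-class guarantee under the heavy class
imbalance this labeling produces. The prediction set at significance ε
(default 0.2, i.e. 80% confidence) is {l : p_l > ε}; possible sets are
{0}, {1}, {0,1} and {}.

Two metrics drive and evaluate the loop:

* **efficiency** — fraction of singleton sets ({0} or {1}) over all
  predictions; the loop's stopping statistic (threshold 0.8).
* **error rate** — fraction of examples whose true label is excluded from
  the set, overall and per class; validity means this stays ≤ ε on
  average. Note a structural ceiling: because in-class p-values are
  ~uniform, an ε fraction of each class draws p ≤ ε for its own class, so
  even perfectly separated classes yield ~ε empty sets and efficiency
  tops out near 1 − ε.

## The screening loop

Per run: featurize the whole library once (the universe); dock a uniform
random sample of `ds_init` from the candidate pool; then iterate — label
cumulatively, train, calibrate, predict sets for the *entire universe*,
remove every pool molecule predicted exactly {0} (those are never docked),
compute efficiency over the universe predictions, and while efficiency is
below threshold (and iterations and pool remain) dock another `ds_incr`
sample. At termination, dock every pool molecule whose current set is
exactly {1}. Molecules predicted {0,1} or {} stay in the pool undocked
(`dock_uncertain_at_end: true` docks them too). Oracle scores are cached
by molecule id, so no molecule is ever docked twice; once pruned, an id
can never re-enter the pool.

Desk-scale defaults are a 100× shrink of the full-scale operating point:
`ds_init` 2 000 (from 200 000), `ds_incr` 1 000 (from 100 000), ε 0.2,
efficiency threshold 0.8, scheme 1_5, calibration fraction 0.1, heights
1–3, plus a `max_iterations` safeguard of 25. Evaluation against an
exhaustive screen of the same library reports the fraction docked and the
top-30 recovery (share of the exhaustive top 30 — ties at the cutoff
broken by id — that the iterative run also docked).

## What the synthetic data emulates — and what it does not

`generate_library` grows random valence-respecting heavy-atom graphs
(uniform 4–20 atoms; element weights C 0.70 / N 0.12 / O 0.12 / S 0.03 /
F 0.015 / Cl 0.015; branch probability 0.3; one optional small-ring
closure per molecule, probability 0.3; occasional double bonds, 0.15).
Generation uses neutral-chemistry valences so every molecule round-trips
through standard toolkits. Ids are `syn%06d`; everything is deterministic
per seed.

The surrogate oracle makes scores a noisy function of structure: pick 50
signatures from the part of the height-1–3 vocabulary present in ≥ 1% of
the library, draw N(0,1) weights, standardize the linear combination into
a latent z, and score

    score = max(0, scale · Φ(z)^k + noise),    k = 10, scale = 10,

with Gaussian noise of sd 0.5 × sd(noise-free score), keyed by
(seed, molecule id) so scores are independent of query order. Two choices
here deserve their rationale:

* **Minimum-support filter for signal signatures.** ~94% of a
  random-graph library's vocabulary occurs in fewer than five molecules; a
  latent built on uniformly drawn signatures is a point mass at zero with
  a few extreme outliers — no usable signal and a degenerate histogram.
* **Bounded power-of-CDF transform rather than an unbounded exponential.**
  Equal-width bins span [min, max], so the top bins' occupancy is set by
  how much mass sits near the sample maximum. For any unbounded transform
  of a normal-tailed latent the maximum runs away with the sample size and
  the top six bins hold ~0.1% of molecules; the class-1 calibration list
  then has fewer than ~4 members, its minimum attainable p-value exceeds
  ε = 0.2, class 1 can never be excluded from a set, and nothing is ever
  pruned (efficiency flatlines near 0.2). Φ(z)^k is bounded, strongly
  right-skewed (sample skewness ≈ 2.8 at defaults; mode in bin 1; bins
  ≥ 5 hold ~7%), monotone in the same signature-linear latent, and keeps
  histogram occupancy stable across sample sizes.

On the bundled 20 000-molecule benchmark with these defaults the screen
typically terminates in 1–2 iterations with ~19–23% of the library docked
and top-30 recovery 0.97–1.0 (5 seeds).

What the generator does **not** emulate: real chemistry (drug-likeness,
synthesizability, tautomers, 3D geometry), receptor-specific structure in
the score landscape, correlated noise between similar molecules, or the
extreme vocabulary overlap of a real 2.2 M-molecule library. Passing tests
therefore demonstrate the machinery — validity of the conformal layer,
correctness of the bookkeeping, and that the loop exploits learnable
signal — not performance on any particular real receptor.

## Numerical choices and degenerate inputs

* Histograms require ≥ 2 distinct scores; all-identical scores raise a
  degenerate-data error. Out-of-range scores (possible when the histogram
  came from a subset) are clamped into the boundary bins with a warning.
* Stratified split sizes are round(n_class × fraction), clamped so both
  sides keep ≥ 1 example per class.
* p-values live in [1/(n+1), 1]; empty calibration lists are an error.
* Sampling, calibration splits and surrogate noise each consume
  independent streams derived from the run seed, so results are
  reproducible bit-for-bit (identical config + seed ⇒ byte-identical
  output CSVs) and insensitive to evaluation order.
* The conformal validity simulation uses two unit-variance Gaussian
  classes in 10 dimensions with means 1σ apart (n_train 2000, n_cal 500,
  n_test 2000, 20 seeds) — deliberately overlapping classes, so validity
  is tested where the classifier is genuinely uncertain.

## Known limitations

* The signature tree expansion can in principle merge environments the
  canonical-DAG construction distinguishes (and vice versa) on dense
  polycyclic systems; irrelevant at heights ≤ 3 for typical organic
  graphs, untested beyond.
* The external-command oracle adapter assumes the docking command is
  deterministic; a stochastic engine breaks the "docked at most once"
  accounting silently.
* Efficiency is computed over the whole universe's predictions (including
  already-docked and pruned molecules), which is the more stable choice
  but means the stopping statistic is not a pool-only quantity.
* The widening fallback for a missing label class acts once per
  iteration; pathological score distributions can still abort the run.
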
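# Methods

## The encoding: W-GDipC

A protein sequence of length *n* over the 20 standard residues is encoded
by ordered residue-pair frequencies. The adjacent dipeptide composition is

    DipC(i) = f(i) / (n − 1),   i = 1..400,

where f(i) counts the i-th ordered pair among the n − 1 adjacent pairs.
The generalized composition at gap *k* counts pairs (q_j, q_{j+1+k})
separated by k intervening residues:

    GDipC(k)(i) = f′(i) / (n − k − 1),

so GDipC(0) ≡ DipC. The weighted fusion

    W-GDipC = Σ_k α_k · GDipC(k),  Σ α_k = 1, α_k > α_{k+1} ≥ 0

is a convex combination on the 400-simplex; the constraint that weights
strictly decrease encodes the assumption that a pair's relevance decays
with its gap. The two-term form α·DipC + (1 − α)·GDipC(1) is the default
pipeline encoding with **α = 0.8**, the value at which fused accuracy peaks
in the fusion-coefficient sweep; `sweep-alpha` re-runs that sweep on any
dataset. Sequences shorter than the minimum for a gap (n < k + 2) raise an
error rather than returning a zero vector, because a zero vector would
silently break the row-sums-to-one invariant that downstream code and
tests rely on.

Column order is fixed: residues alphabetical (ACDEFGHIKLMNPQRSTVWY), pair
(a, b) at column 20·idx(a) + idx(b). Gapped pairs share this 400-name
space. The ordering is a package convention chosen for reproducible
feature indices; nothing in the method depends on it.

## The four single filters

All filters standardize features (zero mean, unit variance) before
penalized fits; binary labels become a 0/1 regression target, ≥3 classes
become one-vs-rest indicators scored by max |coefficient| across classes
(integer-coding a multiclass response would impose an arbitrary class
ordering), and a continuous response is used directly. Ties are broken by
ascending feature index everywhere.

**Lasso (dichotomy on the budget c).** The selection-count target is met by
bisecting a budget constant c ∈ [0, 10⁶] that maps monotonically to the L1
penalty (penalty weight 1/c): larger c ⇒ weaker penalty ⇒ more nonzero
coefficients. Bisection stops when the nonzero count lies in [n, 1.05·n];
after 100 failed iterations the interval is magnified ×10 and the search
restarts, up to 10 times, after which non-convergence is an explicit error
(an opt-in fallback takes the top-n coefficients at the last evaluated
budget). Because the count at convergence can exceed n, the n variables
with largest |coefficient| are kept. The bisection trace is recorded in
the diagnostics so the monotone count-vs-budget assumption can be audited.

**Ridge (grid search + magnitude ranking).** b(λ) = (X′X + λI)⁻¹X′Y has no
intrinsic sparsity, so λ* is chosen by 5-fold cross-validated mean squared
error over 50 log-spaced values in [10⁻⁴, 10⁴] and the n features with
largest |b(λ*)| are selected. Standardization makes the magnitudes
comparable across features.

**MIC.** The maximal information coefficient of each feature against the
response: max over grid shapes (x columns × y rows, x·y ≤ B(m),
B(m) = ⌊m^0.6⌋) of MI/log min{x, y} with equal-frequency partitions on
both axes. Axes with fewer distinct values than requested bins collapse to
value-based bins, so a discrete response is partitioned by its classes.
Sample sizes with B(m) < 4 admit no 2×2 grid and are rejected. The default
estimator enumerates all equal-frequency grids exhaustively (deterministic,
and fast at B ≤ 36); an optional `mine` estimator additionally refines the
x-axis partition by dynamic programming over a fine equal-frequency
super-partition, which can only raise the score. Tests check the default
estimator against an independent pure-python brute-force enumeration.

**Relief.** Instance-based weights W(A) driven by nearest hits and misses:
for each visited sample R, W(A) ← W(A) − diff(A,R,H)/m + diff(A,R,M)/m with
diff(A, ·, ·) = |difference| / (max(A) − min(A)) averaged over the k
nearest neighbours (k = 5 by default). Nearest neighbours use Euclidean
distance on standardized features; the range-normalized diff makes a 0/1
feature reproduce the discrete 0/1 branch of the difference function
exactly, and a constant feature contributes 0. By default every sample is
visited once in order (m = all, deterministic); a subsampled pass is
available and seeded. For >2 classes, miss contributions are weighted by
class prior P(C)/(1 − P(class(R))) in the usual multi-class extension.
With convex neighbour averaging and normalized diff, |W(A)| ≤ 1.

Each filter returns exactly n sorted indices, per-feature scores and a
diagnostics record; Relief alternatively supports a weight threshold θ
(returning however many features reach it), but the top-n cut is the
default so the four filters interoperate in the ensemble.

**How many features (n)?** There is no principled default; the pipeline
exposes it everywhere and uses n = 100 unless told otherwise. Results
should be read as conditional on this choice.

## The ensemble: LRMR-Ri

Stage 1 runs the four filters, each selecting n features. If the four sets
share any common feature (four-way intersection of any size ≥ 1), the
intersection is the optimal subset and stage 2 is skipped — the
intersection is returned unchanged even when smaller than n, since features
agreed on by all four filters need no re-ranking. Otherwise the four sets
are pooled into their union and Ridge re-selects min(n, |union|) features
from the pooled columns only. The four stage-1 filters share one seed,
stream-split per filter, so the whole ensemble is reproducible from a
single integer.

## Evaluation

Five metrics from TP/TN/FP/FN: accuracy, recall, precision, F-measure and
Matthews correlation. Zero-denominator conventions (PE = 0 when
TP + FP = 0; RE = 0 when TP + FN = 0; F = 0 when PE + RE = 0; MCC = 0 when
any denominator factor is 0) keep every metric defined; a class that is
never predicted reports PE = RE = F = 0, which is exactly what happens to
very small classes in practice. Multiclass runs report per-class
one-vs-rest metrics, pooled accuracy and the generalized multiclass MCC
computed from the full confusion matrix (it reduces exactly to the binary
formula for two classes); a macro-average of per-class MCCs is available
behind a flag.

Cross-validation is stratified 5-fold with a seeded shuffle and
mean-of-folds aggregation. When a feature selector is part of the
pipeline, it is refitted on each fold's training split only, so no label
information from the test fold can influence selection; `paper_mode=True`
instead selects once on the full matrix before splitting, a common but
leakage-prone shortcut kept for comparability. Classifier hyperparameters
are deliberately plain (SVM: RBF kernel, library defaults; decision tree:
Gini, unlimited depth; SGD: hinge loss, L2), all behind a StandardScaler;
they shape demonstration numbers only, not the method.

## The synthetic generator

Sequences are drawn i.i.d. from a background residue distribution (uniform
by default), lengths uniform in a range; class signal is planted by
inserting whole ordered pairs: a plant (pair, k, ρ) inserts
Binomial(L − k − 1, (ρ − 1)/400) occurrences at random positions, raising
the pair's expected composition from 1/400 to ≈ ρ/400. Insertion was
chosen over Markov transition biasing because the expected enrichment is
then analytically computable, which the calibration tests use (at ρ = 1
the mean composition of any pair is 1/400 within sampling error; at ρ = 10
with 200 samples per class the planted column separates class means by
many standard errors).

Default study conditions: binary sets mirror a 480/374 class imbalance
with lengths 50–100 (the typical antifreeze-protein length range); the
eight-class configuration mirrors class sizes
(1054, 390, 30, 56, 4581, 189, 228, 1054) at configurable scale, keeping
the tiny classes tiny so the zero-metric behaviour of rarely predicted
categories is reproducible. Each class plants **two** enriched dipeptides
at ρ = 10 (gap 0): with a single planted pair per class roughly a fifth of
sequences would receive no insertion at all, capping attainable accuracy
near 0.8; two pairs per class drop the per-sequence no-signal probability
to ~4%, making the classes genuinely separable, and spreading
discriminative signal over several pairs is also closer to real
composition signal. Recovery and end-to-end experiments in the tests and
the acceptance script use 200 samples per class (selector recovery) and
120/94 samples (cross-validated pipeline), sizes chosen to keep the full
suite quick to re-run while leaving comfortable statistical margins.

What the generator does **not** emulate: homology and phylogenetic
correlation between sequences, realistic motif structure or
physicochemical composition bias, length–class correlation, and
redundancy. Passing tests therefore demonstrate that the implementation
recovers planted composition signal under known conditions — not that the
method attains any particular accuracy on real protein data.

## Numerical choices and limitations

* Compositions are exact rationals stored as doubles; no rounding at
  encode time. Sum-to-one is tested at 1e−9, fusion linearity at 1e−12.
* The Lasso nonzero count along its regularization path moves in steps of
  ~1, so the [n, 1.05n] band is reachable by bisection; extremely
  correlated designs could in principle step over a narrow band, which
  surfaces as the explicit non-convergence error rather than a silent
  wrong answer.
* MIC equal-frequency binning resolves ties by keeping equal values in one
  bin (stable sort order), so duplicated columns score identically and
  results are deterministic.
* Relief distances and Lasso/Ridge fits standardize with population
  standard deviation; constant columns are mapped to zero and can never be
  selected on merit.
* The ensemble's intersection branch can return fewer than n features by
  design; downstream code must not assume |final| == n.
* Encoding loses positional information beyond pair adjacency; two
  sequences with equal pair compositions are indistinguishable.
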
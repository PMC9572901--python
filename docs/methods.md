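# Methods

## The optimizer

Harris Hawks Optimization (HHO) maintains `N` candidate positions in the
box `[LB, UB]^d` and one incumbent best (the rabbit). Each iteration, each
hawk draws an initial energy `E0 ~ U(−1, 1)` and moves according to the
escaping energy `E = 2 E0 (1 − t/T)`:

| regime | move |
|---|---|
| `\|E\| ≥ 1` | exploration: perch on a random hawk or offset from rabbit/mean |
| `\|E\| ≥ 0.5`, `p ≥ 0.5` | soft siege: `Δx − E \|J·x_rabbit − x\|` |
| `\|E\| < 0.5`, `p ≥ 0.5` | hard siege: `x − E \|Δx\|` |
| `\|E\| ≥ 0.5`, `p < 0.5` | soft-siege rapid dives with greedy acceptance |
| `\|E\| < 0.5`, `p < 0.5` | hard-siege rapid dives (anchored on the mean) |

Choices the published update rules leave open, fixed here:

* **Lévy flight.** The dive perturbation is `W ⊙ L(d)` with `W ~ U(0,1)^d`
  and `L` from Mantegna's algorithm, stability exponent `β = 1.5`, scale
  0.01 — the construction used by the algorithm's original reference
  implementation.
* **Boundary handling.** Coordinate-wise clipping to `[LB, UB]` after every
  update; the simplest rule that preserves the box invariant.
* **Iteration clock.** `t` runs 1..T inside the energy formula, so `E = 0`
  exactly in the final iteration and the last sweep is pure exploitation.
* **Rabbit updates.** Fitness is evaluated immediately after each hawk
  moves and the rabbit is refreshed at once (within-iteration elitism);
  exact ties keep the incumbent, for determinism.
* **Random draws.** `E0, p, q, r1..r4` are redrawn per hawk per iteration
  from one seeded `numpy` Generator; a fixed seed makes the whole run —
  positions, history, evaluation counts — bit-reproducible.
* **Dive evaluation order.** `f(k)` first; `f(z)` only when `k` is
  rejected. Greedy acceptance guarantees a dive never worsens a hawk.

## Decoding and fitness

The wrapper searches `[0,1]^{n_genes}`; a position decodes to the indices
of its `n_selected` largest coordinates (ties to the lower index). The
decoding is rank-equivariant: any strictly monotone transform of a
position yields the same subset. Subset size is therefore exact, and the
fitness is the LOOCV error rate alone, with no size penalty.

LOOCV is the standard orientation — train on `n − 1`, predict the held-out
sample. (Descriptions of this protocol sometimes invert the wording of
the train/test roles; the `n`-fold average-accuracy definition only makes
sense in the standard orientation, which is what is implemented.)

* **k-NN**: Euclidean distance, `k = 7` by default (odd, so binary votes
  cannot tie); distance ties resolve to the lower training index, vote
  ties to the earlier class in `class_names`. Implemented directly in
  numpy so these tie-breaks are contractual.
* **SVM**: scikit-learn `SVC`, linear kernel, `C = 1`, one-vs-one for
  multiclass. A training fold that contains a single class predicts that
  class.
* **Scaling**: per-gene min-max to `[0,1]`, fit on each training fold only
  (no leakage); constant genes map to 0. Configurable off.
* **Memoization**: fitness is cached by decoded subset; many positions
  decode to one subset, and caching never changes results.

Defaults follow the standard benchmark protocol for this method family:
10 hawks, 100 iterations, box `[0,1]`, `k = 7`, 30 repeated runs per
subset size, subset sizes 1–30.

## Pre-filter (phase 1)

An optional, off-by-default reduction of the gene pool before the wrapper
search: per-gene one-way ANOVA F relevance, then a greedy mRMR-style
ranking maximizing `relevance − mean |Pearson r|` against the already-kept
genes. The measures and cut-off are this package's own documented
reconstruction of a generically described relevance/redundancy phase; no
claim is made that they match any particular prior implementation. With
the filter disabled the pipeline is identical to running the selector
directly, and reported gene identifiers always refer to the original
input columns.

## Synthetic data

The generator emulates benchmark-shaped expression matrices: `n_samples`
(default 62) × `n_genes` (default 2000), 2–4 classes, a small planted set
of informative genes among i.i.d. `Normal(0, noise_sd)` noise genes.
Informative genes shift their class means by `effect_size · noise_sd`
between adjacent classes (default effect size 3 — strongly but not
trivially separable); a log-normal option exponentiates the matrix to
mimic intensity skew. Everything is a pure function of the seed.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heavy-tailed per-gene variances, or gene–gene correlation beyond
the planted redundancy (all informative genes share one signal
direction). Passing tests on this generator therefore demonstrate the
machinery — search, fitness, protocol — not performance on real
microarray data.

## Identifiability of planted subsets — a known limitation

With an error-rate-only fitness, the optimizer is rewarded for reaching
the minimum LOOCV error, not for naming the planted genes. At benchmark
sample sizes the LOOCV error has resolution `1/n`, and at effect size 3 a
single planted gene already classifies well; two of them (or one plus a
favourable noise gene) typically reach error 0. The zero-error plateau
then contains many subsets with only partial overlap with the truth, and
no optimizer minimizing this fitness — including exhaustive search — can
be driven to full recovery. Measured consequence: mean planted-gene
recovery for 5 redundant planted genes among 200 sits near 30% for both
classifiers even at full search budget, far above the 2.5% chance level
but nowhere near complete. The test suite asserts the above-chance
property at module level and retains a strict full-recovery check that
documents this gap; treat selected subsets as *predictive*, not as the
unique causal genes.

## Problem sizes

Verification runs are sized so the whole suite completes in minutes on
one CPU: exhaustive-oracle comparisons use 10-gene instances (45 subsets
of size 2, full 10 × 100 search budget), recovery checks use 200 genes ×
62 samples over 20 seeds (full budget for k-NN; 30 iterations for the
SVM arm, whose per-fold refits dominate runtime), and the protocol-shape
check runs the full 62 × 2000 grid with 5 hawks × 6 iterations × 5 runs.
The statistics these checks assert (oracle-match rate, above-chance
recovery, ordering and byte-level reproducibility of summaries) are
stable at these sizes.

## Degenerate inputs and numerical notes

Loaders reject missing values (optional per-gene mean imputation),
non-numeric cells, duplicate gene ids and single-class labels. Constant
genes score 0 relevance; perfectly separating genes score `+inf`, which
orders correctly in the greedy filter. Zero-variance correlation pairs
count as correlation 0. The protocol clamps the mean accuracy into
`[worst, best]` to keep the ordering invariant exact under float
summation. Per-run protocol seeds derive from `SeedSequence` spawn keys
`(classifier, subset size, run index)`, so summaries are independent of
grid traversal order and never share streams.
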
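# hhoselect

Wrapper gene selection for labelled expression matrices with **Harris Hawks
Optimization (HHO)** and leave-one-out cross-validated classifiers
(**HHO-KNN** and **HHO-SVM**).

Microarray and bulk/single-cell expression studies routinely face tens of
samples against thousands of genes. Wrapper feature selection attacks this
directly: score a candidate gene subset by the cross-validated performance
of an actual classifier, and search over subsets. `hhoselect` implements
that search with HHO, a swarm metaheuristic in which candidate solutions
("hawks") pursue the best solution found so far (the "rabbit") through
exploration and four siege-style exploitation moves, including Lévy-flight
rapid dives with greedy acceptance.

## Method

The optimizer works on the continuous box `[LB, UB]^d` with `d = n_genes`.
Writing `x(t)` for a hawk, `x_rabbit(t)` for the best-so-far and
`x_mean(t)` for the population mean:

* **Escaping energy** `E = 2 E0 (1 − t / T)`, `E0 ~ U(−1, 1)`, decays over
  the `T` iterations and switches the search from exploration (`|E| ≥ 1`)
  to exploitation.
* **Exploration**: with equal odds, perch on a random hawk
  (`x_random − r1 |x_random − 2 r2 x|`) or relative to the rabbit and the
  mean (`(x_rabbit − x_mean) − r3 (LB + r4 (UB − LB))`).
* **Soft siege** (`0.5 ≤ |E| < 1`): `Δx − E |J x_rabbit − x|` with jump
  strength `J = 2(1 − r)`; **hard siege** (`|E| < 0.5`): `x − E |Δx|`.
* **Progressive rapid dives** (escape probability `p < 0.5`): candidate
  `k = x_rabbit − E |J x_rabbit − x|` (soft; the mean replaces `x` in the
  hard variant), Lévy-perturbed candidate `z = k + W ⊙ L(d)`, and greedy
  acceptance — move only if `f(k)` or `f(z)` beats `f(x)`.

A position is decoded to a gene subset by taking its `n_selected` largest
coordinates, so the subset size is exact and externally controlled. The
fitness minimized is the **LOOCV error rate** of the chosen classifier —
k-NN (Euclidean, `k = 7` by default) or a linear soft-margin SVM — on the
decoded subset, with per-gene min-max scaling fit inside each training
fold. Defaults follow the standard benchmark protocol: 10 hawks, 100
iterations, `[0, 1]` box, 30 repeated runs summarized as best/average/worst
accuracy per subset size.

An optional phase-1 pre-filter (ANOVA-F relevance with greedy Pearson
redundancy removal, mRMR-style) can shrink the gene pool before the
wrapper search. A synthetic generator produces benchmark-shaped matrices
(e.g. 62 samples × 2000 genes, 2 classes) with planted informative genes
for end-to-end testing without external downloads.

## Worked example

```python
from hhoselect import make_expression, select_genes, FitnessSpec, HHOParams

ds, truth = make_expression(n_samples=40, n_genes=500, n_classes=2,
                            n_informative=3, effect_size=3.0, seed=7)
sol = select_genes(ds, 3, FitnessSpec("knn", 7),
                   HHOParams(dim=500, n_hawks=10, max_iter=100, seed=1))
print("selected genes:", [ds.gene_ids[i] for i in sol.gene_indices])
print("planted genes: ", [ds.gene_ids[i] for i in truth])
print(f"LOOCV accuracy: {sol.accuracy:.4f} ({sol.n_evaluations} fitness evaluations)")
```

prints

```
selected genes: ['g298', 'g375', 'g390']
planted genes:  ['g77', 'g298', 'g375']
LOOCV accuracy: 1.0000 (1391 fitness evaluations)
```

Two of the three planted genes are recovered and the selected triple
classifies all 40 samples correctly under LOOCV. The third selected gene
(`g390`) is a noise gene that happens to complete a zero-error subset —
with an error-rate-only fitness, any subset on the zero-error plateau is a
legitimate optimum (see `docs/methods.md` on identifiability).

The same is available as a scikit-learn selector:

```python
from hhoselect import HHOGeneSelector
sel = HHOGeneSelector(n_genes_to_select=3, classifier="knn", random_state=1)
X_reduced = sel.fit_transform(ds.matrix, ds.labels.astype(str))  # (40, 3)
```

and from the shell:

```sh
hhoselect synth --out demo.csv --samples 40 --genes 200 --informative 3 --seed 7
hhoselect select --data demo.csv --n-genes 3 --iters 100 --seed 1
hhoselect protocol --data demo.csv --n-genes 2:5 --runs 5 --seed 0 --out summary.tsv
```

`protocol` writes a TSV with one row per (classifier, subset size) cell
holding best/average/worst LOOCV accuracy over the repeated runs.

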
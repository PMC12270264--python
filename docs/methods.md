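# Methods

This note records the model assumptions, numerical choices and open design
decisions behind `gbnea`, in the spirit of a statistical software appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Network model and estimation

Each phenotype-specific network is the support of per-target elastic-net
regressions: for target gene ℓ with expression vector yℓ (n samples) and
all other genes as candidate regulators,

    minimize  ½‖yℓ − Xβ‖² + λ[δ‖β‖₁ + (1−δ)/2 ‖β‖²],   0 ≤ δ ≤ 1,

with δ = 1 (lasso) the default.  The model assumes approximately linear
regulator–target relationships on whatever scale the expression matrix is
provided (log-scale data are the intended input) and estimates *directed*
edges in the Granger-like sense of "regressor selected for this target" —
no causal identification is claimed beyond that.

**Standardization.** Regulator columns are scaled to unit variance and the
response is centered before fitting; coefficients are reported on the
original data scale.  Penalization is scale-sensitive, so this makes one λ
meaningful across genes.  `RegressionConfig(standardize=False)` fits raw
columns (used by the orthonormal-design exactness tests).

**Penalty grid.** With `lambda_grid=None` the per-target grid is the
relative ladder (1, 0.5, 0.1, 0.01, 0.001) times the smallest penalty that
zeroes every coefficient for that target (max|Xᵀy|/δ on the standardized
design).  The ladder therefore spans the path from near-least-squares to
the empty model on any data scale.  λ = 0 (plain least squares) joins the
grid only when the gene count is below the sample count.  An explicit
absolute grid can be supplied instead.

**BIC.**  λ is selected per target by minimizing

    BIC(λ) = ‖yℓ − ŷℓ(λ)‖² / (n σ²)  +  log(n) · df(λ) / n ,

with df(λ) the number of nonzero coefficients (the standard lasso df
estimator).  σ² is not specified by the criterion itself; the default
plug-in is the residual variance RSS/(n − df) of the least-penalized model
on the grid, falling back to the sample variance of y when that is
degenerate (df ≥ n, or RSS numerically zero, as happens in the
near-interpolating p ≈ n regime).  `sigma2_estimator="response_variance"`
uses var(y) directly.  BIC ties resolve to the larger λ (sparser model).

**Solver.**  The fits use a warm-started cyclic coordinate-descent path
solver operating on the Gram matrix of the standardized expression matrix
(`gbnea.solver`).  Because the permutation null re-estimates every network,
one analysis performs on the order of `n_perm × n_genes` path fits; solving
on the shared Gram matrix removes all per-target matrix products (the
per-target `XᵀX` and `Xᵀy` are sub-blocks of one precomputed `ZᵀZ`).  The
solver is verified against scikit-learn's ElasticNet to ~1e−10 in the test
suite.  Numerical controls: convergence when the largest coordinate update
falls below `cd_tol` (default 1e−6) relative to ‖β‖∞, and a per-grid-point
sweep cap `cd_max_sweeps` (default 100).  The cap only binds on the densest
grid points when p ≈ n, where coordinate descent approaches an
interpolating solution slowly and the BIC essentially never selects the
fit; it is a documented solver tolerance, and the monotone-sparsity
property of the lasso path is asserted in tests at converged settings.
Genes with zero variance are excluded as targets and regulators and can
never carry an edge.  A fit producing non-finite values is retried at
relaxed tolerance and finally replaced by the all-zero solution with a
warning; one failed target does not abort a network.

## 2. Behavior statistics

For gene j with mean expression x̄ⱼ per phenotype:

* rⱼ = Σℓ |β̂ℓⱼ x̄ⱼ| — outgoing influence only; a pure target has r = 0.
* dJIⱼ — Jaccard distance between neighbor sets.  "Directly connected" is
  read as *direction-agnostic* adjacency (in-edges ∪ out-edges): restricting
  to out-edges would make the distance degenerate for pure targets.  A gene
  isolated in both networks gets dJI = 0 (no phenotype-specific interplay),
  not an undefined value.
* d⁽¹⁾ⱼ = rⱼC − rⱼN (signed), d⁽²⁾ⱼ = Σℓ (β̂Cℓⱼ x̄Cⱼ − β̂Nℓⱼ x̄Nⱼ)²
  (nonnegative, sign-sensitive through the products), Wd⁽ᵗ⁾ = dJI · d⁽ᵗ⁾.

Any stored (nonzero) coefficient constitutes an edge; no extra magnitude
threshold is applied, since the lasso already performs selection.  Mean
expression is the arithmetic mean over that phenotype's samples on the
scale used for fitting.

## 3. Enrichment score

Genes are ranked by the signed statistic, descending, ties broken by
lexicographic gene identifier (deterministic across platforms).  Walking
the list, hits add |Wd(j)|ᵏ/VR (VR = Σ over in-set genes of |Wd(j)|ᵏ) and
misses add 1/(|V| − |V_T|); ES is the running difference of maximal
absolute value, keeping its sign, with the positive extreme preferred on an
exact tie.  k = 0 (default, used throughout the benchmarks) reduces to the
classical unweighted two-sample KS statistic — asserted against a
brute-force oracle in the acceptance suite.  No automatic selection of k is
implemented; it is a user parameter.  Pathway genes absent from the network
universe are dropped before scoring (the miss denominator uses the
in-universe set size, the only coherent choice); a pathway with no overlap
is excluded from testing and reported as skipped.

## 4. Permutation significance

The null re-runs the *entire* pipeline — label permutation preserving group
sizes, both network estimations, behavior statistics, ranking, scoring —
Π times (default 200; the desk-scale benchmarks use 50).  No shortcut nulls
(e.g. gene-label shuffling) are offered.  Observed and permuted scores are
normalized per pathway by the mean of the same-sign permuted scores;
a pathway with no same-sign permuted score gets an undefined nES and the
resolution-floor p-value 1/(Π+1) with a warning.

**Two p-values.**  For observed nES ≥ 0 the tail count is
c = #{π : nES(π) ≥ nES}; for negative scores the mirrored lower tail is
used (bottom-of-list enrichments are meaningful and must be testable).
The plain estimate `p = c/Π` is reported as `p_value`; it can be exactly 0
and is what a fraction-of-permutations reading of the tail produces.  It
is, however, biased low, and combined with sign-matched counting over a
denominator that includes *both* signs it yields an anti-conservative
test: under exchangeability the rejection rate at nominal α = 0.05 is
approximately 2α (the sign-conditioning halves the effective denominator).
The package therefore also computes the add-one estimate
`p_conservative = (c+1)/(Π+1)` — the standard finite-permutation correction
— and bases the `significant` flag and the BH/FDR adjustment on it.  The
type-I error of the resulting test on fully null synthetic data is measured
by the acceptance suite (100 replicates at Π = 50) and must fall within the
exact binomial 95% band around 0.05.  Note the discreteness at small Π: a
sign-matched permutation test with Π = 50 has achievable sizes in steps of
2/(Π+1), and at nominal α = 0.05 its exact size is 4/51 ≈ 0.078, so
measured null rejection rates near 0.08 are the expected behavior, not an
inflation artifact; the size approaches the nominal level as Π grows
(e.g. within 1/201 of 0.05 at the default Π = 200).  BH correction is applied across the
pathways tested within one phenotype comparison; p-value resolution is 1/Π
for the plain estimate and 1/(Π+1) for the add-one estimate.

**Determinism.**  Every permutation owns a sub-seed spawned from the
top-level seed before any work starts, so results are bit-identical for any
`n_workers`; failed permutations are re-drawn from deterministically
spawned fresh sub-seeds, and more than 10% failures abort the run.

## 5. Synthetic benchmark

The generator emulates a cancer-vs-normal design with planted ground truth:

* Gene index order is the topological order; edges run only from lower to
  higher index, so structures are acyclic by construction.
* Background: non-module gene pairs receive shared (identical in C and N)
  edges with probability `background_density`, weights uniform on
  ±[0.2, 0.8].
* Planted module: a chain over the module genes with weights
  ±`effect_size` present in C; in N each chain edge is absent, or with
  probability `rewire_fraction` (default 0) rewired to a fresh random
  module pair.  The default concentrates the module on one side of the
  signed ranking, which is the condition the benchmark is meant to pose
  (an enriched pathway at one end of the list).  A nonzero
  `rewire_fraction` creates genes whose activity *increases* in N; those
  land at the opposite end of the signed ranking and the one-tailed
  running sum cannot aggregate the two tails — a deliberate stress
  variant, not the default benchmark.
* Expression: linear structural-equation sampling in topological order;
  root genes standard normal, children the weighted sum of parents plus
  N(0, noise_sd²).  At the scenario level each gene receives a baseline
  drawn uniform on [2, 8] and parents enter centered on their baselines,
  so every gene keeps a nonzero mean — emulating the location of log-scale
  expression, on which the regulatory-effect statistic depends.  Chain
  weights of magnitude ~1 keep variances bounded along the chain.
* Negative arm: only `pathway_fraction_in_negative` (default 5%) of the
  pathway genes remain in the universe, as plain background genes, and the
  planted module moves to a decoy set of non-pathway genes.  The two
  phenotype networks therefore still differ genuinely — the arm tests
  specificity against global network differences, not merely against pure
  noise.

What the generator does **not** emulate: count noise and mean–variance
coupling of sequencing data, hub-dominated degree distributions,
feedback loops (structures are DAGs), and confounded or batch-structured
samples.  Passing benchmarks therefore demonstrate correctness of the
machinery and calibration under the linear-Gaussian model, not performance
on any particular real dataset.

**Benchmark scales.**  The scenario defaults mirror the motivating study's
shape (500 genes, 87-gene pathway, 85 vs 103 samples, Π = 200, 50
iterations per arm).  The acceptance-grade runs in this repository use
desk-scale versions chosen as the package's own benchmark sizes: null
calibration at 60 genes / 15-gene set / 30 samples per group / Π = 50 /
100 replicates, and planted recovery at 100 genes / 20-gene pathway /
100 samples per group / effect 1.0 vs noise 0.2 (5× ratio) / Π = 50 / 20
iterations per arm.  Confusion metrics follow the usual definitions;
precision is undefined (printed "-") when nothing is called positive.

## 6. Known limitations

* The regulatory effect counts outgoing edges only; a gene regulated
  differently but regulating nothing is visible to dJI and d⁽²⁾ through
  its zero rows, not to d⁽¹⁾.
* Permutation re-estimation is the dominant cost (Π + 1 full network
  pairs per analysis); wall time scales roughly with Π · p² per target
  sweep.
* The sweep cap makes the densest grid points approximate in the p ≈ n
  regime; BIC selection is insensitive to this in all tested conditions,
  but pathological designs could interact with it.
* With very small Π the same-sign normalization can be undefined for some
  pathway; the resolution-floor fallback keeps the pipeline total but such
  p-values carry little information.
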
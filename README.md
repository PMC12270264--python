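# gbnea — gene behaviors-based network enrichment analysis

`gbnea` asks a question that single-gene enrichment tools cannot: given two
*phenotype-specific directed gene networks* — say, one estimated from cancer
cell lines and one from non-cancerous lines — which functional pathways are
over-represented among the genes whose **network behavior** differs most
between the phenotypes?  It is aimed at systems-biology analyses where the
interesting signal is a rewired regulatory program rather than a shift in
mean expression.

## Method

**Network estimation.** For each phenotype, a directed weighted network is
estimated by sparse linear regression: each target gene *yℓ* is regressed on
all other genes, `yℓ = βℓᵀx + ε`, with an elastic-net penalty
`λ[δ‖β‖₁ + (1−δ)/2 ‖β‖²]` (δ = 1, the lasso, by default).  Nonzero β̂ℓⱼ are
directed edges j → ℓ.  The per-target penalty λ is selected from a grid by
minimizing `BIC = ‖yℓ − ŷℓ‖²/(nσ²) + log(n)·df/n`, with df the number of
nonzero coefficients.  Pre-estimated networks can be supplied as edge lists
instead.

**Gene behavior statistics.** For each gene *j*, with phenotype networks C
and N and per-phenotype mean expression x̄ⱼ:

- regulatory effect  `rⱼ = Σℓ |β̂ℓⱼ · x̄ⱼ|` — total outgoing influence;
- Jaccard distance  `dJIⱼ = 1 − |NⱼC ∩ NⱼN| / |NⱼC ∪ NⱼN|` between the
  gene's neighbor sets in the two networks (0 = identical wiring,
  1 = fully phenotype-specific wiring);
- difference statistics  `d⁽¹⁾ⱼ = rⱼC − rⱼN` and
  `d⁽²⁾ⱼ = Σℓ (β̂Cℓⱼ x̄Cⱼ − β̂Nℓⱼ x̄Nⱼ)²`, and their Jaccard-weighted
  versions `Wd⁽ᵗ⁾ⱼ = dJIⱼ · d⁽ᵗ⁾ⱼ` (method variants GbNEA1R / GbNEA2R /
  GbNEA1RJ / GbNEA2RJ rank by d⁽¹⁾ / d⁽²⁾ / Wd⁽¹⁾ / Wd⁽²⁾).

**Enrichment and significance.** Genes are ranked by the chosen statistic
and each pathway V_T is scored with a weighted Kolmogorov–Smirnov running
sum: hits add `|Wd(j)|ᵏ / VR`, misses add `1/(|V| − |V_T|)`; the enrichment
score ES is the maximal signed deviation (k = 0 gives exactly the classical
unweighted KS statistic).  Significance comes from a phenotype-label
permutation null: labels are reshuffled, **both networks are re-estimated
from scratch**, and the pipeline is re-run Π times.  Scores are normalized
by same-sign permutation means (nES), tail-counted into permutation
p-values, and BH-corrected across pathways.  Two p-values are reported: the
plain tail count `c/Π` (can be exactly 0) and the add-one estimate
`(c+1)/(Π+1)`; significance calls use the latter, which is a valid level-α
permutation test (see `docs/methods.md`).

## Worked example

The package ships a synthetic-data generator that plants a
phenotype-specific regulatory chain on a designated pathway inside a shared
background network, then samples expression from the corresponding linear
structural-equation model:

```python
import numpy as np
from gbnea import (GeneSetCollection, PermutationConfig, SimulationScenario,
                   build_scenario_dataset, run_enrichment)

scenario = SimulationScenario(n_genes=60, pathway_size=12, n_samples_C=60,
                              n_samples_N=60, effect_size=1.0, noise_sd=0.2,
                              background_density=0.02, seed=42)
sim = build_scenario_dataset(scenario, np.random.default_rng(42), "positive")
gene_sets = GeneSetCollection({
    "planted_module": sim.pathway,
    "random_dozen": set(list(sim.data.gene_ids)[:12]),
})
analysis = run_enrichment(sim.data, gene_sets, labels=("C", "N"),
                          stat_name="Wd1", k=0.0,
                          perm_config=PermutationConfig(n_perm=100, seed=7))
print(analysis.to_frame().round(4).to_string(index=False))
```

which prints:

```
       pathway  n_hits    ES     nES  p_value  p_conservative  fdr_q  significant  n_perm_same_sign
planted_module      12  1.00  2.4316     0.00          0.0099 0.0198         True                50
  random_dozen      12 -0.25 -1.0112     0.16          0.1683 0.1683        False                45
```

The planted module's 12 genes occupy the very top of the Wd⁽¹⁾ ranking, so
its running sum peaks at ES = 1.0 — 2.43 times the mean of the positive
permutation scores (nES) and beyond all 100 permutations (plain p = 0, add
-one p = 0.0099): the pathway is correctly called enriched.  The arbitrary
control set drifts with the background (|ES| = 0.25, p ≈ 0.17) and is
correctly rejected.

The same analysis runs from the shell on TSV/GMT files:

```sh
gbnea enrich --expr expr.tsv --phenotypes pheno.tsv --labels C,N \
      --gmt pathways.gmt --stat Wd1 --k 0 --n-perm 200 --seed 1 \
      --alpha 0.05 --out results_dir
```

plus `gbnea estimate-network`, `gbnea score` and `gbnea simulate` for the
individual stages and the benchmark harness.

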
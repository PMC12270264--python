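"""Synthetic two-phenotype expression data with planted network differences.

The benchmark design mirrors a cancer-vs-normal study: a designated
"pathway" module of genes carries phenotype-specific directed regulatory
structure (a chain of edges present in phenotype C and dropped or rewired in
phenotype N), embedded in a shared background network, and expression is
sampled from the corresponding linear structural-equation model per
phenotype.  Two scenario arms are produced:

* the *positive* arm keeps the whole pathway in the gene universe, so the
  pathway should be called enriched (a miss is a false negative);
* the *negative* arm keeps only a small fraction of the pathway genes in the
  universe and moves the planted phenotype-specific module onto a decoy set
  of non-pathway genes, so the network difference is real but the pathway
  should NOT be called enriched (a call is a false positive).

Aggregating calls over iterations of both arms yields the usual
confusion-matrix metrics (accuracy, precision, recall, F1, true-negative
rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .behavior import STAT_NAMES
from .enrichment import GeneSetCollection
from .exceptions import DataValidationError
from .network import DirectedNetwork, ExpressionDataset, RegressionConfig
from .permutation import (PermutationConfig, _null_distribution_multi,
                          _observed_es, _results_from_null)

#: Method name -> ranking statistic. The 1R/2R variants rank by the plain
#: regulatory-effect differences d1/d2; the RJ variants use the
#: Jaccard-weighted Wd1/Wd2.
METHOD_STATISTIC: Mapping[str, str] = {
    "GbNEA1R": "d1",
    "GbNEA2R": "d2",
    "GbNEA1RJ": "Wd1",
    "GbNEA2RJ": "Wd2",
}


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic benchmark condition.

    Defaults mirror the benchmark shape of the colorectal-cancer condition
    (universe of 500 genes, 87-gene pathway, 85 vs 103 samples, 5% of the
    pathway present in the negative-arm universe); effect size, noise level
    and background density govern the planted linear structural-equation
    model and are freely reducible for desk-scale runs.
    """

    n_genes: int = 500
    pathway_size: int = 87
    pathway_fraction_in_negative: float = 0.05
    n_samples_C: int = 85
    n_samples_N: int = 103
    effect_size: float = 1.0
    background_density: float = 0.02
    noise_sd: float = 0.5
    rewire_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pathway_size > self.n_genes:
            raise DataValidationError(
                "pathway cannot be larger than the gene universe")
        if not 0.0 < self.pathway_fraction_in_negative <= 1.0:
            raise DataValidationError(
                "pathway_fraction_in_negative must lie in (0, 1]")
        for name in ("n_genes", "pathway_size", "n_samples_C", "n_samples_N"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise DataValidationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise DataValidationError("effect_size must be >= 0")
        if not 0.0 <= self.background_density <= 1.0:
            raise DataValidationError(
                "background_density must lie in [0, 1]")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise DataValidationError("rewire_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedScenarioData:
    """One simulated dataset pair plus its ground truth."""

    data: ExpressionDataset
    pathway: frozenset[str]
    tested_set: frozenset[str]
    structure_C: DirectedNetwork
    structure_N: DirectedNetwork
    baseline: np.ndarray


def _structure_pair(scenario: SimulationScenario, module: np.ndarray,
                    background: np.ndarray, n_genes: int,
                    rng: np.random.Generator):
    """Shared-background coefficient matrices for phenotypes C and N.

    Gene index order is the topological order: edges only run from lower to
    higher index, so both structures are acyclic by construction.  The
    module genes (sorted by topological position) carry a chain of
    phenotype-specific edges of weight ``+-effect_size`` in C; in N each
    chain edge is absent, or — with probability ``rewire_fraction`` —
    rewired to a fresh random module pair, so the module is concentrated on
    one side of the signed ranking by default.  Background edges are
    sampled once and shared by both phenotypes.
    """
    W_C = np.zeros((n_genes, n_genes))
    W_N = np.zeros((n_genes, n_genes))

    # shared background edges among non-module genes (i -> j, i < j)
    bg = np.sort(background)
    n_bg = bg.size
    if n_bg >= 2 and scenario.background_density > 0:
        upper = np.triu_indices(n_bg, k=1)
        draw = rng.random(upper[0].size) < scenario.background_density
        weights = rng.uniform(0.2, 0.8, upper[0].size) * \
            rng.choice([-1.0, 1.0], upper[0].size)
        for a, b, keep, w in zip(upper[0], upper[1], draw, weights):
            if keep:
                W_C[bg[a], bg[b]] = w
                W_N[bg[a], bg[b]] = w

    # phenotype-specific chain on the module genes
    mod = np.sort(module)
    eff = scenario.effect_size
    chain_signs = rng.choice([-1.0, 1.0], max(mod.size - 1, 0))
    for t in range(mod.size - 1):
        W_C[mod[t], mod[t + 1]] = chain_signs[t] * eff
    for t in range(mod.size - 1):
        action = rng.random()
        sign = rng.choice([-1.0, 1.0])
        if action >= scenario.rewire_fraction or mod.size < 2:
            continue  # edge absent in N
        a, b = np.sort(rng.choice(mod.size, size=2, replace=False))
        W_N[mod[a], mod[b]] = sign * eff
    return W_C, W_N


def generate_planted_network(scenario: SimulationScenario, phenotype: str,
                             rng: np.random.Generator,
                             ) -> DirectedNetwork:
    """Planted coefficient structure of one phenotype (positive-arm layout).

    Both phenotype structures are derived from the same generator state, so
    calling this twice with identically seeded generators yields the
    consistent (C, N) pair.
    """
    if phenotype not in ("C", "N"):
        raise DataValidationError("phenotype must be 'C' or 'N'")
    gene_ids, pathway_idx, background_idx = _positive_universe(scenario, rng)
    W_C, W_N = _structure_pair(scenario, pathway_idx, background_idx,
                               scenario.n_genes, rng)
    W = W_C if phenotype == "C" else W_N
    return DirectedNetwork.from_matrix(gene_ids, W, phenotype)


def _gene_ids(n: int, prefix: str = "G") -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def _positive_universe(scenario: SimulationScenario,
                       rng: np.random.Generator):
    gene_ids = _gene_ids(scenario.n_genes)
    pathway_idx = rng.choice(scenario.n_genes, scenario.pathway_size,
                             replace=False)
    background_idx = np.setdiff1d(np.arange(scenario.n_genes), pathway_idx)
    return gene_ids, pathway_idx, background_idx


def simulate_expression(structure: DirectedNetwork, n_samples: int,
                        noise_sd: float, rng: np.random.Generator,
                        baseline: np.ndarray | None = None) -> np.ndarray:
    """Sample a genes x samples matrix from the linear structural model.

    Root genes (no parents) are drawn standard normal; every downstream gene
    is the structure-weighted sum of its parents plus Gaussian noise of sd
    ``noise_sd``, evaluated in topological order.  With ``baseline`` given,
    parents enter centered on their baselines and each gene keeps its
    baseline as mean, emulating the nonzero location of (log-scale)
    expression levels; the default reduces to the plain zero-mean model.
    """
    if noise_sd <= 0:
        raise DataValidationError("noise_sd must be positive")
    p = len(structure.gene_ids)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(p))
    index = {g: i for i, g in enumerate(structure.gene_ids)}
    for (reg, tgt) in structure.coefficients:
        graph.add_edge(index[reg], index[tgt])
    try:
        order = list(nx.topological_sort(graph))
    except nx.NetworkXUnfeasible:
        raise DataValidationError(
            "coefficient structure contains a cycle") from None

    mu = np.zeros(p) if baseline is None else np.asarray(baseline, float)
    if mu.shape != (p,):
        raise DataValidationError("baseline must have one value per gene")
    B = structure.to_matrix()  # B[j, l]: weight of edge j -> l
    values = np.empty((p, n_samples))
    for g in order:
        parents = np.nonzero(B[:, g])[0]
        if parents.size == 0:
            values[g] = mu[g] + rng.standard_normal(n_samples)
        else:
            centered = values[parents] - mu[parents, None]
            values[g] = (mu[g] + B[parents, g] @ centered
                         + noise_sd * rng.standard_normal(n_samples))
    return values


def build_scenario_dataset(scenario: SimulationScenario,
                           rng: np.random.Generator,
                           arm: str = "positive") -> SimulatedScenarioData:
    """Simulate one dataset of the requested arm, with ground truth.

    In the positive arm the planted module IS the pathway; in the negative
    arm only ``pathway_fraction_in_negative`` of the pathway genes remain in
    the universe (as plain background genes) and the planted module sits on
    a decoy gene set, so both phenotype networks still differ but not
    through the tested pathway.
    """
    if arm not in ("positive", "negative"):
        raise DataValidationError("arm must be 'positive' or 'negative'")
    p, m = scenario.n_genes, scenario.pathway_size

    if arm == "positive":
        gene_ids, module_idx, background_idx = _positive_universe(
            scenario, rng)
        pathway_ids = frozenset(gene_ids[i] for i in module_idx)
        tested = pathway_ids
    else:
        n_kept = max(1, math.ceil(scenario.pathway_fraction_in_negative * m))
        # the full pathway has m members; only n_kept of them exist in this
        # universe, named so that membership is recognizable across arms
        gene_ids = _gene_ids(p - n_kept) + _gene_ids(n_kept, prefix="PW")
        pathway_ids = frozenset(
            _gene_ids(n_kept, prefix="PW")
            + _gene_ids(m - n_kept, prefix="PWX"))  # PWX*: not in universe
        # random topological placement of the identifiers
        gene_ids = tuple(rng.permutation(np.array(gene_ids, dtype=object)))
        module_idx = rng.choice(
            np.array([i for i, g in enumerate(gene_ids)
                      if not g.startswith("PW")]), m, replace=False)
        background_idx = np.setdiff1d(np.arange(p), module_idx)
        tested = pathway_ids

    W_C, W_N = _structure_pair(scenario, np.asarray(module_idx),
                               np.asarray(background_idx), p, rng)
    structure_C = DirectedNetwork.from_matrix(gene_ids, W_C, "C")
    structure_N = DirectedNetwork.from_matrix(gene_ids, W_N, "N")

    baseline = rng.uniform(2.0, 8.0, p)
    values_C = simulate_expression(structure_C, scenario.n_samples_C,
                                   scenario.noise_sd, rng, baseline)
    values_N = simulate_expression(structure_N, scenario.n_samples_N,
                                   scenario.noise_sd, rng, baseline)
    values = np.concatenate([values_C, values_N], axis=1)
    n_c, n_n = scenario.n_samples_C, scenario.n_samples_N
    sample_ids = tuple(f"C{i:04d}" for i in range(n_c)) + \
        tuple(f"N{i:04d}" for i in range(n_n))
    phenotype = ("C",) * n_c + ("N",) * n_n
    data = ExpressionDataset(values, gene_ids, sample_ids, phenotype)
    return SimulatedScenarioData(data=data, pathway=pathway_ids,
                                 tested_set=tested, structure_C=structure_C,
                                 structure_N=structure_N, baseline=baseline)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and TNR from confusion counts.

    Precision is undefined (NaN, printed as "-") when nothing was called
    positive; recall/F1/TNR degrade to 0 with empty denominators.
    """
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    tnr = tn / (tn + fp) if (tn + fp) else 0.0
    if math.isnan(precision) or precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"Accuracy": accuracy, "Precision": precision, "Recall": recall,
            "F1": f1, "TNR": tnr}


def _resolve_methods(methods: Sequence[str]) -> dict[str, str]:
    resolved = {}
    for m in methods:
        if m in METHOD_STATISTIC:
            resolved[m] = METHOD_STATISTIC[m]
        elif m in STAT_NAMES:
            resolved[m] = m
        else:
            raise DataValidationError(
                f"unknown method {m!r}; choose from "
                f"{sorted(METHOD_STATISTIC)} or {STAT_NAMES}")
    return resolved


def _arm_decisions(scenario: SimulationScenario, arm: str, iteration: int,
                   stats: tuple[str, ...], k: float,
                   reg_config: RegressionConfig,
                   perm_config: PermutationConfig) -> dict[str, bool]:
    """Significance call of the tested pathway per statistic, one dataset."""
    root = np.random.SeedSequence(
        (scenario.seed, iteration, 0 if arm == "positive" else 1))
    data_seed, perm_seed = root.spawn(2)
    rng = np.random.default_rng(data_seed)
    sim = build_scenario_dataset(scenario, rng, arm)
    gene_sets = GeneSetCollection({"planted_pathway": sim.tested_set},
                                  provenance="synthetic")
    pconf = replace(perm_config,
                    seed=int(perm_seed.generate_state(1)[0] & 0x7FFFFFFF))
    es_obs, (_, _, _, details) = _observed_es(
        sim.data, ("C", "N"), reg_config, gene_sets, stats, k)
    null = _null_distribution_multi(sim.data, ("C", "N"), reg_config, pconf,
                                    gene_sets, stats, k)
    decisions = {}
    for stat in stats:
        score_results = details[stat][1]
        results = _results_from_null(es_obs[stat], null[stat], score_results,
                                     pconf.n_perm, pconf.alpha)
        decisions[stat] = any(r.significant for r in results)
    return decisions


def run_simulation_study(scenario_grid: Sequence[SimulationScenario],
                         methods: Sequence[str] = ("GbNEA1RJ",),
                         n_iterations: int = 50,
                         k: float = 0.0,
                         reg_config: RegressionConfig | None = None,
                         perm_config: PermutationConfig | None = None):
    """Benchmark the method variants over positive/negative scenario arms.

    For each scenario and iteration, a positive-arm and a negative-arm
    dataset are simulated and the full pipeline decides whether the planted
    pathway is enriched; calls are aggregated into confusion-matrix metrics
    per method.  Returns a pandas DataFrame with one row per (scenario,
    method).
    """
    import pandas as pd

    if n_iterations <= 0:
        raise DataValidationError("n_iterations must be positive")
    if isinstance(scenario_grid, SimulationScenario):
        scenario_grid = [scenario_grid]
    if not scenario_grid:
        raise DataValidationError("at least one scenario required")
    reg_config = reg_config or RegressionConfig()
    perm_config = perm_config or PermutationConfig()
    resolved = _resolve_methods(methods)
    stats = tuple(dict.fromkeys(resolved.values()))

    rows = []
    for s_idx, scenario in enumerate(scenario_grid):
        counts = {m: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for m in resolved}
        for it in range(n_iterations):
            pos = _arm_decisions(scenario, "positive", it, stats, k,
                                 reg_config, perm_config)
            neg = _arm_decisions(scenario, "negative", it, stats, k,
                                 reg_config, perm_config)
            for m, stat in resolved.items():
                counts[m]["tp" if pos[stat] else "fn"] += 1
                counts[m]["fp" if neg[stat] else "tn"] += 1
        for m in resolved:
            c = counts[m]
            rows.append({"scenario": s_idx, "method": m,
                         "n_genes": scenario.n_genes,
                         "pathway_size": scenario.pathway_size,
                         **c, **confusion_metrics(**c)})
    return pd.DataFrame(rows)
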
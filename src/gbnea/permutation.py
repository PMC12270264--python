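"""Permutation null, score normalization, p-values and FDR control.

Significance of an enrichment score is assessed against a phenotype-label
permutation null: the labels of the two groups are reshuffled (group sizes
preserved), both networks are re-estimated from scratch, and the whole
behavior -> ranking -> enrichment-score pipeline is re-run, ``n_perm`` times.
Observed and permuted scores are normalized per pathway by separately
rescaling positive and negative scores with the mean of the same-sign
permuted scores (nES), and the p-value is the sign-matched tail count of
permuted nES values at least as extreme as the observed one.

Two p-values are produced for each pathway:

* ``p_value`` — the plain tail count divided by the number of permutations,
  which can be exactly 0 for a score beyond every permuted score;
* ``p_conservative`` — the add-one estimate ``(count + 1) / (n_perm + 1)``.

The plain count is a biased-down estimate of the true tail probability and,
combined with sign-matched counting, yields an anti-conservative test; the
add-one form is a valid permutation p-value, so the ``significant`` flag and
the BH/FDR adjustment are based on ``p_conservative`` (see the methods note
for the calibration analysis).  Benjamini-Hochberg correction is applied
across the pathways tested within one phenotype comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior import BehaviorScores, behavior_scores
from .enrichment import (EnrichmentScoreResult, GeneSetCollection, RankedList,
                         enrichment_scores_for_collection, rank_genes)
from .exceptions import DataValidationError, GbneaError
from .network import (DirectedNetwork, ExpressionDataset, RegressionConfig,
                      estimate_network)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation-based significance assessment.

    ``n_workers`` is a parallelism hint only: results are bit-identical for
    any worker count because every permutation owns a pre-derived sub-seed.
    """

    n_perm: int = 200
    seed: int = 0
    alpha: float = 0.05
    n_workers: int = 1

    def __post_init__(self):
        if self.n_perm < 1:
            raise DataValidationError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise DataValidationError("alpha must lie in (0, 1)")
        if self.n_workers < 1:
            raise DataValidationError("n_workers must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway outcome of the full significance assessment."""

    pathway: str
    n_hits: int
    ES: float
    nES: float
    p_value: float
    p_conservative: float
    fdr_q: float
    significant: bool
    n_perm_same_sign: int


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def permute_labels(phenotypes: Sequence[str],
                   rng: np.random.Generator) -> tuple[str, ...]:
    """Uniformly random reassignment of the labels, group sizes preserved."""
    labels = tuple(map(str, phenotypes))
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise DataValidationError(
            f"exactly two phenotype levels required, got {levels}")
    counts = {lev: labels.count(lev) for lev in levels}
    if min(counts.values()) == 0:
        raise DataValidationError("both phenotype groups must be non-empty")
    return tuple(rng.permutation(np.array(labels, dtype=object)))


def normalize_scores(es_obs: Mapping[str, float],
                     es_null: Mapping[str, np.ndarray],
                     ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Rescale observed and permuted scores by same-sign permutation means.

    Positive scores are divided by the mean of the strictly positive
    permuted scores of that pathway, negative scores by the absolute mean of
    the strictly negative ones.  A pathway with no same-sign permuted score
    gets an undefined (NaN) normalized value; downstream the p-value falls
    back to the permutation resolution floor.
    """
    nes_obs: dict[str, float] = {}
    nes_null: dict[str, np.ndarray] = {}
    for name, obs in es_obs.items():
        null = np.asarray(es_null[name], dtype=float)
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg.mean()) if neg.size else np.nan
        scaled = np.empty_like(null)
        scaled[null > 0] = null[null > 0] / pos_mean
        scaled[null < 0] = null[null < 0] / neg_mean
        scaled[null == 0] = 0.0
        nes_null[name] = scaled
        if obs > 0:
            nes_obs[name] = obs / pos_mean if pos.size else np.nan
        elif obs < 0:
            nes_obs[name] = obs / neg_mean if neg.size else np.nan
        else:
            nes_obs[name] = 0.0
    return nes_obs, nes_null


def permutation_pvalue(nes_obs: float, nes_null: np.ndarray,
                       conservative: bool = False) -> float:
    """Sign-matched tail probability of the observed normalized score.

    For a nonnegative observed score, the fraction of permuted scores at
    least as large; for a negative one, the mirrored lower tail.  With
    ``conservative=True`` the add-one estimate ``(count+1)/(n+1)`` is
    returned instead of the plain ``count/n``.
    """
    null = np.asarray(nes_null, dtype=float)
    if null.size == 0:
        raise DataValidationError("empty permutation null")
    if np.isnan(nes_obs):
        raise DataValidationError(
            "undefined normalized score; use the resolution floor instead")
    if nes_obs >= 0:
        count = int(np.sum(null >= nes_obs))
    else:
        count = int(np.sum(null <= nes_obs))
    if conservative:
        return (count + 1) / (null.size + 1)
    return count / null.size


def bh_correction(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# permutation pipeline
# ---------------------------------------------------------------------------

def _single_permutation_es(data: ExpressionDataset, labels: tuple[str, str],
                           reg_config: RegressionConfig,
                           gene_sets: GeneSetCollection,
                           stat_names: tuple[str, ...], k: float,
                           seed: np.random.SeedSequence,
                           ) -> dict[str, dict[str, float]]:
    """Permute labels, re-run the full pipeline, return per-stat ES maps."""
    rng = np.random.default_rng(seed)
    permuted = permute_labels(data.phenotype, rng)
    pdata = data.with_phenotype(permuted)
    return _observed_es(pdata, labels, reg_config, gene_sets,
                        stat_names, k)[0]


def _observed_es(data: ExpressionDataset, labels: tuple[str, str],
                 reg_config: RegressionConfig,
                 gene_sets: GeneSetCollection,
                 stat_names: tuple[str, ...], k: float):
    """Estimate both networks and score every pathway for each statistic."""
    label_c, label_n = labels
    net_c = estimate_network(data, label_c, reg_config)
    net_n = estimate_network(data, label_n, reg_config)
    scores = behavior_scores(net_c, net_n,
                             data.mean_expression(label_c),
                             data.mean_expression(label_n))
    es: dict[str, dict[str, float]] = {}
    details: dict[str, tuple[RankedList, dict[str, EnrichmentScoreResult],
                             list[str]]] = {}
    for stat in stat_names:
        ranking = rank_genes(scores, stat)
        results, skipped = enrichment_scores_for_collection(ranking,
                                                            gene_sets, k)
        es[stat] = {name: r.ES for name, r in results.items()}
        details[stat] = (ranking, results, skipped)
    return es, (net_c, net_n, scores, details)


def _null_distribution_multi(data: ExpressionDataset,
                             labels: tuple[str, str],
                             reg_config: RegressionConfig,
                             perm_config: PermutationConfig,
                             gene_sets: GeneSetCollection,
                             stat_names: tuple[str, ...], k: float,
                             ) -> dict[str, dict[str, np.ndarray]]:
    """Per-stat, per-pathway vectors of permuted enrichment scores.

    Each permutation owns a sub-seed derived from the top-level seed, so the
    result is identical for any ``n_workers``.  A permutation whose pipeline
    fails is re-drawn with a fresh sub-seed; more than 10% failures abort.
    """
    n_perm = perm_config.n_perm
    parent = np.random.SeedSequence(perm_config.seed)
    seeds = parent.spawn(n_perm)

    def run_one(seed):
        try:
            return _single_permutation_es(data, labels, reg_config,
                                          gene_sets, stat_names, k, seed)
        except (GbneaError, np.linalg.LinAlgError) as exc:
            logger.warning("permutation failed (%s); re-drawing", exc)
            return None

    if perm_config.n_workers > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=perm_config.n_workers)(
            delayed(run_one)(s) for s in seeds)
    else:
        outcomes = [run_one(s) for s in seeds]

    n_failures = sum(o is None for o in outcomes)
    max_failures = max(int(0.1 * n_perm), 1)
    while any(o is None for o in outcomes):
        if n_failures > max_failures:
            raise GbneaError(
                f"{n_failures} of {n_perm} permutations failed; aborting")
        idx = next(i for i, o in enumerate(outcomes) if o is None)
        outcomes[idx] = run_one(parent.spawn(1)[0])
        if outcomes[idx] is None:
            n_failures += 1

    null: dict[str, dict[str, np.ndarray]] = {}
    for stat in stat_names:
        pathways = sorted({name for o in outcomes for name in o[stat]})
        null[stat] = {
            name: np.array([o[stat].get(name, np.nan) for o in outcomes])
            for name in pathways}
    return null


def null_distribution(data: ExpressionDataset, config: RegressionConfig,
                      perm_config: PermutationConfig,
                      gene_sets: GeneSetCollection, stat_name: str = "Wd1",
                      k: float = 0.0,
                      labels: tuple[str, str] | None = None,
                      ) -> dict[str, np.ndarray]:
    """Per-pathway vectors of ``n_perm`` permuted enrichment scores."""
    labels = labels or _infer_labels(data)
    return _null_distribution_multi(data, labels, config, perm_config,
                                    gene_sets, (stat_name,), k)[stat_name]


def _infer_labels(data: ExpressionDataset) -> tuple[str, str]:
    levels = data.phenotype_levels()
    if len(levels) != 2:
        raise DataValidationError(
            f"expected exactly two phenotype levels, found {levels}; "
            "pass labels=(C, N) explicitly")
    return levels[0], levels[1]


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentAnalysis:
    """Complete outcome of one phenotype-pair enrichment analysis."""

    stat_name: str
    k: float
    results: tuple[EnrichmentResult, ...]
    network_C: DirectedNetwork
    network_N: DirectedNetwork
    scores: BehaviorScores
    ranking: RankedList
    score_results: Mapping[str, EnrichmentScoreResult]
    null_es: Mapping[str, np.ndarray]
    skipped_pathways: tuple[str, ...] = field(default=())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "pathway": r.pathway, "n_hits": r.n_hits, "ES": r.ES,
            "nES": r.nES, "p_value": r.p_value,
            "p_conservative": r.p_conservative, "fdr_q": r.fdr_q,
            "significant": r.significant,
            "n_perm_same_sign": r.n_perm_same_sign,
        } for r in self.results])


def _results_from_null(es_obs: dict[str, float],
                       null: dict[str, np.ndarray],
                       score_results: Mapping[str, EnrichmentScoreResult],
                       n_perm: int, alpha: float,
                       ) -> tuple[EnrichmentResult, ...]:
    nes_obs, nes_null = normalize_scores(es_obs, null)
    floor = 1.0 / (n_perm + 1)
    rows = []
    for name in es_obs:
        obs = nes_obs[name]
        same_sign = int(np.sum(nes_null[name] > 0) if es_obs[name] >= 0
                        else np.sum(nes_null[name] < 0))
        if np.isnan(obs):
            warnings.warn(
                f"pathway {name!r} has no same-sign permuted scores; "
                "p-value set to the permutation resolution floor")
            p_lit = p_cons = floor
        else:
            p_lit = permutation_pvalue(obs, nes_null[name])
            p_cons = permutation_pvalue(obs, nes_null[name],
                                        conservative=True)
        rows.append([name, score_results[name].n_hits, es_obs[name], obs,
                     p_lit, p_cons, same_sign])
    qs = bh_correction([r[5] for r in rows])
    return tuple(
        EnrichmentResult(pathway=r[0], n_hits=r[1], ES=r[2], nES=r[3],
                         p_value=r[4], p_conservative=r[5],
                         fdr_q=float(q), significant=bool(r[5] < alpha),
                         n_perm_same_sign=r[6])
        for r, q in zip(rows, qs))


def run_enrichment(data: ExpressionDataset, gene_sets: GeneSetCollection,
                   labels: tuple[str, str] | None = None,
                   stat_name: str = "Wd1", k: float = 0.0,
                   reg_config: RegressionConfig | None = None,
                   perm_config: PermutationConfig | None = None,
                   ) -> EnrichmentAnalysis:
    """Full gene-network enrichment analysis for one phenotype pair.

    Estimates the two phenotype-specific networks, computes the behavior
    statistics, ranks the genes by ``stat_name``, scores every pathway,
    builds the label-permutation null, and reports normalized scores,
    permutation p-values and BH-adjusted q-values.
    """
    reg_config = reg_config or RegressionConfig()
    perm_config = perm_config or PermutationConfig()
    labels = labels or _infer_labels(data)
    if labels[0] == labels[1]:
        raise DataValidationError("the two phenotype labels must differ")
    keep = [i for i, lab in enumerate(data.phenotype) if lab in labels]
    if len(keep) < len(data.phenotype):
        data = ExpressionDataset(
            data.values[:, keep], data.gene_ids,
            tuple(data.sample_ids[i] for i in keep),
            tuple(data.phenotype[i] for i in keep))

    es_multi, (net_c, net_n, scores, details) = _observed_es(
        data, labels, reg_config, gene_sets, (stat_name,), k)
    ranking, score_results, skipped = details[stat_name]
    for name in skipped:
        logger.info("pathway %r shares no genes with the universe; skipped",
                    name)
    null = _null_distribution_multi(data, labels, reg_config, perm_config,
                                    gene_sets, (stat_name,), k)[stat_name]
    results = _results_from_null(es_multi[stat_name], null, score_results,
                                 perm_config.n_perm, perm_config.alpha)
    return EnrichmentAnalysis(
        stat_name=stat_name, k=k, results=results, network_C=net_c,
        network_N=net_n, scores=scores, ranking=ranking,
        score_results=score_results, null_es=null,
        skipped_pathways=tuple(skipped))
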
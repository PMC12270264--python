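"""Weighted Kolmogorov-Smirnov-like enrichment score over a gene ranking.

Genes are ranked by a signed behavior statistic (descending).  Walking the
ranked list, a running sum accumulates ``|stat|^k / VR`` at every gene of the
tested pathway ("hit", with ``VR`` the sum of ``|stat|^k`` over all in-set
genes) and ``1 / (|V| - |V_T|)`` at every other gene ("miss").  The
enrichment score ES is the deviation Hit - Miss of maximal absolute value,
retaining its sign: large positive ES means the pathway concentrates at the
top of the ranking, large negative ES at the bottom.  With ``k = 0`` the ES
is exactly the classical unweighted two-sample Kolmogorov-Smirnov statistic
of in-set versus out-of-set rank positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .behavior import STAT_NAMES, BehaviorScores
from .exceptions import DataValidationError, NoOverlapError


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway -> member genes mapping (e.g. read from a GMT file)."""

    sets: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self):
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(map(str, members))
            if not members:
                raise DataValidationError(f"gene set {name!r} is empty")
            clean[str(name)] = members
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by a signed statistic, largest first."""

    order: tuple[str, ...]
    stat_values: np.ndarray
    stat_name: str

    def __post_init__(self):
        object.__setattr__(self, "order", tuple(map(str, self.order)))
        vals = np.asarray(self.stat_values, dtype=float)
        object.__setattr__(self, "stat_values", vals)
        if vals.shape != (len(self.order),):
            raise DataValidationError("one statistic value per gene required")
        if np.any(np.diff(vals) > 0):
            raise DataValidationError("stat_values must be non-increasing")


@dataclass(frozen=True)
class EnrichmentScoreResult:
    """Running-sum enrichment score of one pathway against one ranking."""

    pathway: str
    ES: float
    running_sum: np.ndarray
    peak_position: int
    k: float
    n_hits: int
    hit_positions: tuple[int, ...] = field(default=(), repr=False)


def rank_genes(scores: BehaviorScores, stat_name: str) -> RankedList:
    """Rank genes by one behavior statistic, descending.

    Ties are broken by lexicographic gene identifier so the ranking is
    deterministic across runs and platforms; the input gene order is
    irrelevant.
    """
    stat = scores.statistic(stat_name)
    order = sorted(range(len(scores.gene_ids)),
                   key=lambda i: (-stat[i], scores.gene_ids[i]))
    return RankedList(tuple(scores.gene_ids[i] for i in order),
                      stat[order], stat_name)


def enrichment_score(ranking: RankedList, gene_set: Iterable[str],
                     k: float = 0.0, pathway: str = "",
                     ) -> EnrichmentScoreResult:
    """Running-sum enrichment score of one gene set against the ranking.

    Pathway genes absent from the ranked universe are dropped (the score is
    computed on the in-universe subset); a pathway with no overlap at all
    raises :class:`NoOverlapError`, and a pathway covering the whole universe
    is rejected since the miss side would be empty.
    """
    if k < 0:
        raise DataValidationError("k must be >= 0")
    members = set(map(str, gene_set))
    p = len(ranking.order)
    hits = np.fromiter((g in members for g in ranking.order), bool, count=p)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise NoOverlapError(
            f"gene set {pathway!r} shares no genes with the ranked universe")
    if n_hits == p:
        raise DataValidationError(
            f"gene set {pathway!r} covers the entire universe; "
            "the miss side is empty")

    if k == 0:
        weights = hits.astype(float)
    else:
        weights = np.where(hits, np.abs(ranking.stat_values) ** k, 0.0)
    vr = weights.sum()
    if vr == 0:
        raise DataValidationError(
            "all in-set statistics are zero so the hit weights vanish; "
            "use k = 0 (unweighted) for this ranking")
    running = np.cumsum(weights) / vr - np.cumsum(~hits) / (p - n_hits)

    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # on an exact tie of the absolute extremes, keep the positive one
    if running[i_max] >= -running[i_min]:
        peak = i_max
    else:
        peak = i_min
    return EnrichmentScoreResult(
        pathway=pathway, ES=float(running[peak]), running_sum=running,
        peak_position=peak, k=float(k), n_hits=n_hits,
        hit_positions=tuple(int(i) for i in np.nonzero(hits)[0]))


def enrichment_scores_for_collection(
        ranking: RankedList, gene_sets: GeneSetCollection, k: float = 0.0,
        ) -> tuple[dict[str, EnrichmentScoreResult], list[str]]:
    """Score every pathway of a collection; returns (results, no-overlap)."""
    results: dict[str, EnrichmentScoreResult] = {}
    skipped: list[str] = []
    for name, members in gene_sets:
        try:
            results[name] = enrichment_score(ranking, members, k, name)
        except NoOverlapError:
            skipped.append(name)
    return results, skipped


__all__ = [
    "STAT_NAMES", "GeneSetCollection", "RankedList", "EnrichmentScoreResult",
    "rank_genes", "enrichment_score", "enrichment_scores_for_collection",
]
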
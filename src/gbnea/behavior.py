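"""Per-gene phenotype-distinction statistics from a pair of networks.

Given the directed networks of two phenotypes ``C`` and ``N`` over one gene
universe, each gene j is characterized by

* its regulatory effect ``r_j = sum_l |beta_lj * xbar_j|`` — the summed
  absolute influence of its outgoing edges weighted by its mean expression
  in that phenotype;
* the Jaccard distance ``dJI_j`` between its (direction-agnostic) neighbor
  sets in the two networks — 0 when the wiring is identical, 1 when it is
  fully phenotype-specific;
* the difference statistics ``d1_j = r_j^C - r_j^N`` (signed) and
  ``d2_j = sum_l (beta^C_lj xbar^C_j - beta^N_lj xbar^N_j)^2``
  (sign-sensitive, nonnegative), and their Jaccard-weighted versions
  ``Wd1 = dJI * d1`` and ``Wd2 = dJI * d2``.

Genes with large ``|Wd|`` behave most differently between the two networks;
the enrichment stage ranks genes by these statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DataValidationError
from .network import DirectedNetwork

STAT_NAMES = ("d1", "d2", "Wd1", "Wd2")


@dataclass(frozen=True)
class BehaviorScores:
    """Per-gene behavior statistics for one phenotype pair (C vs N)."""

    gene_ids: tuple[str, ...]
    r_C: np.ndarray
    r_N: np.ndarray
    d_JI: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    Wd1: np.ndarray
    Wd2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        p = len(self.gene_ids)
        for name in ("r_C", "r_N", "d_JI", "d1", "d2", "Wd1", "Wd2"):
            vec = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, vec)
            if vec.shape != (p,):
                raise DataValidationError(
                    f"{name} must have one value per gene")
        if (self.r_C < 0).any() or (self.r_N < 0).any():
            raise DataValidationError("regulatory effects must be >= 0")
        if (self.d2 < 0).any():
            raise DataValidationError("d2 must be >= 0")
        if (self.d_JI < 0).any() or (self.d_JI > 1).any():
            raise DataValidationError("d_JI must lie in [0, 1]")

    def statistic(self, stat_name: str) -> np.ndarray:
        if stat_name not in STAT_NAMES:
            raise DataValidationError(
                f"unknown statistic {stat_name!r}; choose from {STAT_NAMES}")
        return getattr(self, stat_name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene": self.gene_ids, "r_C": self.r_C, "r_N": self.r_N,
             "d_JI": self.d_JI, "d1": self.d1, "d2": self.d2,
             "Wd1": self.Wd1, "Wd2": self.Wd2})


def _as_gene_vector(gene_ids: tuple[str, ...],
                    mean_expr: Mapping[str, float] | Sequence[float],
                    ) -> np.ndarray:
    """Mean-expression input as a vector aligned with ``gene_ids``."""
    if isinstance(mean_expr, Mapping):
        missing = [g for g in gene_ids if g not in mean_expr]
        if missing:
            raise DataValidationError(
                f"mean expression missing for gene(s) {missing[:5]}")
        vec = np.array([float(mean_expr[g]) for g in gene_ids])
    else:
        vec = np.asarray(mean_expr, dtype=float)
        if vec.shape != (len(gene_ids),):
            raise DataValidationError(
                "mean expression vector length must match the gene universe")
    if not np.all(np.isfinite(vec)):
        raise DataValidationError("mean expression contains non-finite values")
    return vec


def regulatory_effect(network: DirectedNetwork,
                      mean_expr: Mapping[str, float] | Sequence[float],
                      ) -> np.ndarray:
    """Summed absolute outgoing influence ``sum_l |beta_lj xbar_j|`` per gene.

    Genes regulating nothing get 0.  The per-term absolute value makes the
    result invariant to the signs of the outgoing weights.
    """
    xbar = _as_gene_vector(network.gene_ids, mean_expr)
    B = network.to_matrix()
    return np.abs(B * xbar[:, None]).sum(axis=1)


def _adjacency(network: DirectedNetwork) -> np.ndarray:
    """Direction-agnostic boolean adjacency (in-edges union out-edges)."""
    B = network.to_matrix()
    return (B != 0) | (B.T != 0)


def neighborhood(network: DirectedNetwork, gene: str) -> set[str]:
    """Genes directly connected to ``gene``, regardless of edge direction."""
    if gene not in network.gene_ids:
        raise DataValidationError(f"gene {gene!r} not in the network universe")
    idx = network.gene_ids.index(gene)
    adj = _adjacency(network)
    return {network.gene_ids[i] for i in np.nonzero(adj[idx])[0]}


def _check_same_universe(netC: DirectedNetwork, netN: DirectedNetwork):
    if netC.gene_ids != netN.gene_ids:
        raise DataValidationError(
            "the two networks must share an identical gene universe")


def jaccard_distance(netC: DirectedNetwork, netN: DirectedNetwork,
                     gene: str) -> float:
    """Jaccard distance between the gene's neighbor sets in the two networks.

    A gene isolated in both networks exhibits no phenotype-specific
    interplay and gets distance 0.
    """
    _check_same_universe(netC, netN)
    nC = neighborhood(netC, gene)
    nN = neighborhood(netN, gene)
    union = nC | nN
    if not union:
        return 0.0
    return 1.0 - len(nC & nN) / len(union)


def behavior_scores(netC: DirectedNetwork, netN: DirectedNetwork,
                    meanC: Mapping[str, float] | Sequence[float],
                    meanN: Mapping[str, float] | Sequence[float],
                    ) -> BehaviorScores:
    """All per-gene phenotype-distinction statistics for the pair (C, N).

    Swapping the two phenotypes negates ``d1``/``Wd1`` and leaves ``d2``,
    ``Wd2`` and ``d_JI`` unchanged.
    """
    _check_same_universe(netC, netN)
    gene_ids = netC.gene_ids
    xbarC = _as_gene_vector(gene_ids, meanC)
    xbarN = _as_gene_vector(gene_ids, meanN)
    BC = netC.to_matrix()
    BN = netN.to_matrix()

    r_C = np.abs(BC * xbarC[:, None]).sum(axis=1)
    r_N = np.abs(BN * xbarN[:, None]).sum(axis=1)
    d1 = r_C - r_N
    d2 = ((BC * xbarC[:, None] - BN * xbarN[:, None]) ** 2).sum(axis=1)

    adjC = (BC != 0) | (BC.T != 0)
    adjN = (BN != 0) | (BN.T != 0)
    inter = (adjC & adjN).sum(axis=1)
    union = (adjC | adjN).sum(axis=1)
    with np.errstate(invalid="ignore"):
        d_JI = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)

    return BehaviorScores(gene_ids, r_C, r_N, d_JI, d1, d2,
                          d_JI * d1, d_JI * d2)
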
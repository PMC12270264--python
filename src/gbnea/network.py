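"""Phenotype-specific directed gene network estimation.

A directed, weighted gene network is estimated from the expression matrix of
one phenotype group by regressing every target gene on all other genes with
an elastic-net penalty (lasso when the mixing parameter ``delta`` is 1).  The
nonzero regression coefficients are the directed edges: ``beta[l, j] != 0``
means regulator ``j`` carries a directed arrow to target ``l`` with that
weight.  The per-target penalty is chosen from a grid by minimizing

    BIC = ||y - y_hat||^2 / (n * sigma^2) + log(n) * df / n

with ``df`` the number of nonzero coefficients and ``sigma^2`` a plug-in
noise variance (see :class:`RegressionConfig`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DataValidationError
from .solver import CD_TOL, _cd_enet_path, estimate_network_dense

#: Relative penalty grid used when no explicit grid is configured, expressed
#: as fractions of the smallest penalty that zeroes every coefficient for the
#: target at hand (so the grid spans the path from near-OLS to the empty
#: model on any data scale).  A zero entry (plain least squares) is appended
#: automatically when the problem has fewer genes than samples.
AUTO_RELATIVE_GRID = (1.0, 0.5, 0.1, 0.01, 0.001)

_SIGMA2_ESTIMATORS = ("least_penalized", "response_variance")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix with a phenotype label per sample.

    Parameters
    ----------
    values : (n_genes, n_samples) real matrix of expression levels.
    gene_ids : ordered unique gene identifiers (one per row).
    sample_ids : ordered unique sample identifiers (one per column).
    phenotype : phenotype label per sample (categorical).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    phenotype: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "sample_ids",
                           tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "phenotype", tuple(map(str, self.phenotype)))
        if values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        if values.shape[0] != len(self.gene_ids):
            raise DataValidationError(
                f"{values.shape[0]} rows but {len(self.gene_ids)} gene ids")
        if values.shape[1] != len(self.sample_ids):
            raise DataValidationError(
                f"{values.shape[1]} columns but "
                f"{len(self.sample_ids)} sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("sample identifiers must be unique")
        if len(self.phenotype) != len(self.sample_ids):
            raise DataValidationError("one phenotype label per sample required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_levels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.phenotype:
            seen.setdefault(lab, None)
        return tuple(seen)

    def sample_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.phenotype], dtype=bool)

    def subset_values(self, label: str) -> np.ndarray:
        """Genes x samples sub-matrix for one phenotype label."""
        mask = self.sample_mask(label)
        if not mask.any():
            raise DataValidationError(f"phenotype label {label!r} not present")
        return self.values[:, mask]

    def mean_expression(self, label: str) -> np.ndarray:
        """Arithmetic mean expression per gene over one phenotype's samples."""
        return self.subset_values(label).mean(axis=1)

    def with_phenotype(self, phenotype: Sequence[str]) -> "ExpressionDataset":
        """Same data under re-assigned phenotype labels (for permutations)."""
        return ExpressionDataset(self.values, self.gene_ids,
                                 self.sample_ids, tuple(phenotype))


@dataclass(frozen=True)
class RegressionConfig:
    """Settings of the per-target penalized regressions.

    Parameters
    ----------
    delta : elastic-net mixing parameter in [0, 1]; 1 = lasso (default),
        0 = ridge.
    lambda_grid : explicit descending-or-any-order penalty grid, or None to
        derive a per-target grid from :data:`AUTO_RELATIVE_GRID`.  A value of
        exactly 0 (plain least squares) is permitted only when the gene count
        is below the sample count.
    sigma2_estimator : rule for the noise variance in the BIC:
        ``"least_penalized"`` (residual variance of the least-penalized grid
        model, sample variance of the response as degenerate fallback) or
        ``"response_variance"`` (sample variance of the response).
    standardize : center the response and scale regulators to unit variance
        before fitting; coefficients are reported on the original scale.
    cd_tol, cd_max_sweeps : coordinate-descent stopping tolerance and sweep
        cap per grid point.
    """

    delta: float = 1.0
    lambda_grid: tuple[float, ...] | None = None
    sigma2_estimator: str = "least_penalized"
    standardize: bool = True
    cd_tol: float = CD_TOL
    cd_max_sweeps: int = 100

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise DataValidationError("delta must lie in [0, 1]")
        if self.lambda_grid is not None:
            grid = tuple(float(v) for v in self.lambda_grid)
            if len(grid) == 0:
                raise DataValidationError("lambda_grid must be non-empty")
            if any(v < 0 for v in grid):
                raise DataValidationError("lambda values must be >= 0")
            object.__setattr__(self, "lambda_grid", grid)
        if self.sigma2_estimator not in _SIGMA2_ESTIMATORS:
            raise DataValidationError(
                f"sigma2_estimator must be one of {_SIGMA2_ESTIMATORS}")


@dataclass(frozen=True)
class DirectedNetwork:
    """Directed weighted gene network over a fixed gene universe.

    ``coefficients`` maps ``(regulator, target)`` pairs to the nonzero
    regression weight of the arrow regulator -> target.  Self-edges are
    forbidden and every endpoint must belong to ``gene_ids``.
    """

    gene_ids: tuple[str, ...]
    coefficients: Mapping[tuple[str, str], float]
    phenotype_label: str | None = None
    lambda_selected: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "lambda_selected",
                           dict(self.lambda_selected))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("gene identifiers must be unique")
        universe = set(self.gene_ids)
        for (reg, tgt), w in self.coefficients.items():
            if reg == tgt:
                raise DataValidationError(f"self-edge on gene {reg!r}")
            if reg not in universe or tgt not in universe:
                raise DataValidationError(
                    f"edge ({reg!r}, {tgt!r}) leaves the gene universe")
            if w == 0 or not np.isfinite(w):
                raise DataValidationError(
                    f"edge ({reg!r}, {tgt!r}) must carry a finite nonzero "
                    f"weight, got {w!r}")

    @property
    def n_edges(self) -> int:
        return len(self.coefficients)

    def to_matrix(self) -> np.ndarray:
        """Dense coefficient matrix ``B[j, l]`` = weight of edge j -> l."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        B = np.zeros((len(self.gene_ids), len(self.gene_ids)))
        for (reg, tgt), w in self.coefficients.items():
            B[index[reg], index[tgt]] = w
        return B

    @classmethod
    def from_matrix(cls, gene_ids: Sequence[str], B: np.ndarray,
                    phenotype_label: str | None = None,
                    lambda_selected: Mapping[str, float] | None = None,
                    ) -> "DirectedNetwork":
        gene_ids = tuple(map(str, gene_ids))
        regs, tgts = np.nonzero(B)
        coefficients = {(gene_ids[j], gene_ids[l]): float(B[j, l])
                        for j, l in zip(regs, tgts)}
        return cls(gene_ids, coefficients, phenotype_label,
                   lambda_selected or {})

    def targets_of(self, gene: str) -> dict[str, float]:
        """Outgoing edges of ``gene`` as a target -> weight map."""
        return {tgt: w for (reg, tgt), w in self.coefficients.items()
                if reg == gene}

    def regulators_of(self, gene: str) -> dict[str, float]:
        """Incoming edges of ``gene`` as a regulator -> weight map."""
        return {reg: w for (reg, tgt), w in self.coefficients.items()
                if tgt == gene}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataValidationError(f"{name} contains non-finite values")
    return arr


def fit_target_regression(y: np.ndarray, X: np.ndarray,
                          config: RegressionConfig,
                          lam: float) -> np.ndarray:
    """Elastic-net coefficients of one target regressed on its regulators.

    Minimizes ``(1/2)||y - X b||^2 + lam (delta ||b||_1 +
    (1-delta)/2 ||b||^2)``; with ``delta = 1`` this is the lasso and
    coefficients shrunk out by the penalty are exactly zero.  Zero-variance
    regulator columns are excluded from the fit and keep a zero coefficient.
    Returns the coefficient vector on the original regulator scale.
    """
    y = _check_finite("y", y).ravel()
    X = _check_finite("X", X)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataValidationError("X must be (n_samples, n_regulators) with "
                                  "rows matching len(y)")
    n, p = X.shape
    if lam < 0:
        raise DataValidationError("lam must be >= 0")
    if lam == 0 and p >= n:
        raise DataValidationError(
            "lam = 0 (plain least squares) requires fewer regulators "
            "than samples")

    sd = X.std(axis=0)
    active = sd > 0
    if config.standardize:
        Z = np.zeros_like(X)
        Z[:, active] = (X[:, active] - X[:, active].mean(0)) / sd[active]
        y_fit = y - y.mean()
        scale_back = np.where(active, sd, 1.0)
    else:
        Z = np.where(active, X, 0.0)
        y_fit = y
        scale_back = np.ones(p)

    if lam == 0:
        beta = np.zeros(p)
        if active.any():
            sol, *_ = np.linalg.lstsq(Z[:, active], y_fit, rcond=None)
            beta[active] = sol
    else:
        G = Z.T @ Z
        Xy = Z.T @ y_fit
        coefs, _, _ = _cd_enet_path(
            G, Xy, float(y_fit @ y_fit), np.array([float(lam)]),
            float(config.delta), -1, active, config.cd_tol,
            config.cd_max_sweeps)
        beta = coefs[0]
    return beta / scale_back


def compute_bic(y: np.ndarray, y_hat: np.ndarray, df: float, sigma2: float,
                n: int) -> float:
    """Bayesian information criterion of one fitted target model.

    ``BIC = ||y - y_hat||^2 / (n sigma^2) + log(n) df / n``.
    """
    if n <= 0:
        raise DataValidationError("n must be positive")
    if df < 0:
        raise DataValidationError("df must be non-negative")
    if sigma2 <= 0:
        raise DataValidationError(
            "sigma2 must be positive; apply the RegressionConfig."
            "sigma2_estimator fallback (sample variance of y) instead")
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise DataValidationError("y and y_hat must have equal length")
    rss = float(np.sum((y - y_hat) ** 2))
    return rss / (n * sigma2) + np.log(n) * df / n


def _resolve_grid(config: RegressionConfig, p: int, n: int):
    """Split the configured grid into (descending positive part, has_zero)."""
    if config.lambda_grid is None:
        return None, p < n
    grid = sorted(set(config.lambda_grid), reverse=True)
    has_zero = grid and grid[-1] == 0.0
    if has_zero:
        if p >= n:
            raise DataValidationError(
                "lambda = 0 in the grid requires fewer genes than samples")
        grid = grid[:-1]
    if not grid and not has_zero:
        raise DataValidationError("lambda_grid must contain a value")
    return np.array(grid, dtype=float), has_zero


def estimate_network(data: ExpressionDataset, phenotype: str,
                     config: RegressionConfig | None = None,
                     ) -> DirectedNetwork:
    """Estimate the directed network of one phenotype group.

    For every target gene, all other genes act as candidate regulators; the
    penalty is selected per target by minimizing the BIC over the grid (ties
    resolve to the larger penalty, i.e. the sparser model) and the nonzero
    coefficients become directed edges.  The estimate is deterministic given
    the data and configuration.
    """
    config = config or RegressionConfig()
    if phenotype not in data.phenotype_levels():
        raise DataValidationError(
            f"phenotype {phenotype!r} absent from the dataset "
            f"(levels: {data.phenotype_levels()})")
    values = data.subset_values(phenotype)
    _check_finite("expression values", values)
    p, n = values.shape
    if n < 2:
        raise DataValidationError(
            f"phenotype {phenotype!r} has {n} sample(s); at least 2 required")
    if p < 2:
        raise DataValidationError("at least 2 genes required")

    X = np.ascontiguousarray(values.T)  # samples x genes
    sd = X.std(axis=0)
    active = sd > 0
    if config.standardize:
        Z = np.zeros_like(X)
        Z[:, active] = (X[:, active] - X[:, active].mean(0)) / sd[active]
        col_scale = np.where(active, sd, 1.0)
        col_norm2 = np.where(active, n * sd ** 2, 0.0)
    else:
        Z = np.where(active, X, 0.0)
        col_scale = np.ones(p)
        col_norm2 = (Z ** 2).sum(axis=0)

    G = Z.T @ Z
    abs_grid, has_zero = _resolve_grid(config, p, n)
    sigma2_mode = 0 if config.sigma2_estimator == "least_penalized" else 1

    if has_zero:
        B, lam_sel = _estimate_with_zero_grid(
            G, Z, X, col_scale, col_norm2, active, n, abs_grid, config)
    else:
        use_rel = abs_grid is None
        rel = np.array(AUTO_RELATIVE_GRID) if use_rel else np.empty(0)
        agrid = abs_grid if abs_grid is not None else np.empty(0)
        B, lam_sel, sweeps = estimate_network_dense(
            G, col_scale, col_norm2, active, n, rel, agrid, use_rel,
            float(config.delta), sigma2_mode, config.cd_tol,
            config.cd_max_sweeps)
        if not np.all(np.isfinite(B)):
            warnings.warn("coordinate descent produced non-finite "
                          "coefficients; retrying with relaxed tolerance")
            B2, lam_sel, _ = estimate_network_dense(
                G, col_scale, col_norm2, active, n, rel, agrid, use_rel,
                float(config.delta), sigma2_mode, config.cd_tol * 100,
                max(config.cd_max_sweeps // 2, 10))
            bad = ~np.all(np.isfinite(B2), axis=0)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} target fit(s) failed to converge; "
                    "falling back to the all-zero solution for them")
                B2[:, bad] = 0.0
            B = B2

    lambda_selected = {data.gene_ids[l]: float(lam_sel[l])
                       for l in range(p) if np.isfinite(lam_sel[l])}
    return DirectedNetwork.from_matrix(data.gene_ids, B, phenotype,
                                       lambda_selected)


def _estimate_with_zero_grid(G, Z, X, col_scale, col_norm2, active, n,
                             abs_grid, config):
    """Per-target selection when the grid contains lambda = 0 (p < n)."""
    p = G.shape[0]
    B = np.zeros((p, p))
    lam_sel = np.full(p, np.nan)
    log_n = np.log(n)
    for l in range(p):
        if not active[l]:
            continue
        Xy = G[:, l] * col_scale[l]
        Xy[l] = 0.0
        yty = col_norm2[l]
        keep = active.copy()
        keep[l] = False
        if abs_grid is not None and len(abs_grid):
            pos_grid = abs_grid
        else:
            # per-target auto grid: fractions of the all-zeroing penalty
            lam_max = float(np.max(np.abs(Xy[keep]))) if keep.any() else 0.0
            pos_grid = None if lam_max <= 0 else \
                np.array(AUTO_RELATIVE_GRID) * \
                (lam_max / max(config.delta, 1e-3))
        candidates: list[tuple[float, np.ndarray, float, int]] = []
        if pos_grid is not None:
            coefs, rss, _ = _cd_enet_path(
                G, Xy, yty, pos_grid, float(config.delta), l, active,
                config.cd_tol, config.cd_max_sweeps)
            for k, lamk in enumerate(pos_grid):
                candidates.append((float(lamk), coefs[k],
                                   float(rss[k]),
                                   int(np.count_nonzero(coefs[k]))))
        # lambda = 0: ordinary least squares on the active regulators
        beta0 = np.zeros(p)
        sol, *_ = np.linalg.lstsq(Z[:, keep], Z[:, l] * col_scale[l],
                                  rcond=None)
        beta0[keep] = sol
        resid = Z[:, l] * col_scale[l] - Z[:, keep] @ sol
        candidates.append((0.0, beta0, float(resid @ resid),
                           int(np.count_nonzero(beta0))))

        var_y = yty / max(n - 1, 1)
        if config.sigma2_estimator == "least_penalized":
            lam0, _, rss0, df0 = candidates[-1]
            sigma2 = rss0 / (n - df0) if n - df0 >= 1 else 0.0
            if sigma2 <= 1e-12 * max(var_y, 1e-300):
                sigma2 = var_y
        else:
            sigma2 = var_y
        if sigma2 <= 0:
            continue
        best = min(candidates,
                   key=lambda c: (c[2] / (n * sigma2) + log_n * c[3] / n,
                                  -c[0]))
        lam_sel[l] = best[0]
        B[:, l] = best[1] / col_scale
        B[l, l] = 0.0
    return B, lam_sel
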
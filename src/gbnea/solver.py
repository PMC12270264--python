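"""Warm-started coordinate-descent elastic-net path solver on the Gram matrix.

The enrichment pipeline re-estimates a full directed network for every
permutation of the phenotype labels, so a single analysis performs on the
order of ``n_perm * n_genes`` regularization-path fits.  Each fit is small
(tens to hundreds of regulators) but there are very many of them, which makes
per-call overhead and redundant matrix products the dominant cost.  This
module therefore solves the per-target problems directly on the shared Gram
matrix ``G = Z^T Z`` of the (standardized) expression matrix: for target
``l`` the regulator design is ``Z`` without column ``l``, whose Gram matrix
and ``X^T y`` vector are sub-blocks of ``G``, so no per-target matrix product
is needed at all.

The objective matches the penalized least-squares criterion

    (1/2) ||y - X b||^2 + lam * [ delta * ||b||_1 + (1 - delta)/2 * ||b||^2 ]

with mixing parameter ``delta`` in [0, 1] (``delta = 1`` is the lasso).
Coordinate updates are the standard soft-threshold steps; the path is walked
from the largest penalty down with warm starts.  Correctness is checked
against scikit-learn's ElasticNet in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Convergence is declared when the largest coordinate update in a sweep is
# below ``tol`` times max(1, ||b||_inf).  MAX_SWEEPS caps the work spent on
# the near-interpolating dense end of the path (smallest penalties with
# p ~ n), where coordinate descent converges slowly but the BIC essentially
# never selects the fit; the cap is an explicit, documented solver tolerance.
CD_TOL = 1e-6
MAX_SWEEPS = 150


@njit(cache=True)
def _cd_enet_path(G, Xy, yty, lambdas, delta, skip, active, tol, max_sweeps):
    """Coordinate descent over a descending penalty grid, Gram formulation.

    Parameters
    ----------
    G : (p, p) Gram matrix of the regressor columns.
    Xy : (p,) regressor-response inner products.
    yty : float, ``||y||^2``.
    lambdas : descending penalty grid (objective scale, see module docstring).
    delta : L1/L2 mixing parameter in [0, 1].
    skip : index of a column to exclude from the fit (-1 for none); used to
        drop the target gene itself from its own regulator set.
    active : (p,) boolean mask of usable regressor columns (zero-variance
        columns are excluded and keep a zero coefficient).
    tol, max_sweeps : convergence tolerance and sweep cap per grid point.

    Returns
    -------
    coefs : (len(lambdas), p) coefficients (excluded columns stay 0).
    rss : (len(lambdas),) residual sums of squares.
    n_sweeps : (len(lambdas),) sweeps used per grid point.
    """
    p = G.shape[0]
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    rss = np.empty(n_lam)
    n_sweeps = np.zeros(n_lam, dtype=np.int64)

    beta = np.zeros(p)
    q = Xy.copy()  # q = Xy - G @ beta, maintained incrementally

    for k in range(n_lam):
        lam = lambdas[k]
        l1 = lam * delta
        l2 = lam * (1.0 - delta)
        converged = False
        sweeps = 0
        while sweeps < max_sweeps and not converged:
            sweeps += 1
            max_step = 0.0
            max_coef = 0.0
            for j in range(p):
                if j == skip or not active[j] or G[j, j] <= 0.0:
                    continue
                b_old = beta[j]
                rho = q[j] + G[j, j] * b_old
                if rho > l1:
                    b_new = (rho - l1) / (G[j, j] + l2)
                elif rho < -l1:
                    b_new = (rho + l1) / (G[j, j] + l2)
                else:
                    b_new = 0.0
                step = b_new - b_old
                if step != 0.0:
                    beta[j] = b_new
                    for i in range(p):
                        q[i] -= G[i, j] * step
                    if abs(step) > max_step:
                        max_step = abs(step)
                if abs(b_new) > max_coef:
                    max_coef = abs(b_new)
            if max_step <= tol * max(max_coef, 1.0):
                converged = True
        n_sweeps[k] = sweeps
        coefs[k, :] = beta
        # rss = ||y||^2 - 2 b'Xy + b'Gb = ||y||^2 - b'(Xy + q)
        acc = yty
        for j in range(p):
            acc -= beta[j] * (Xy[j] + q[j])
        rss[k] = max(acc, 0.0)
    return coefs, rss, n_sweeps


@njit(cache=True)
def estimate_network_dense(G, col_scale, col_norm2, active, n, rel_grid,
                           abs_grid, use_rel, delta, sigma2_mode, tol,
                           max_sweeps):
    """Per-target elastic-net path + BIC selection for one whole network.

    Parameters
    ----------
    G : (p, p) Gram matrix of the (standardized) expression columns.
    col_scale : (p,) scale of each column before standardization (the sd of
        the gene when columns were scaled to unit variance, 1.0 otherwise).
        Used both to form ``X^T y`` on the response scale and to map fitted
        coefficients back to the original regulator scale.
    col_norm2 : (p,) squared norm of each (centered) response column.
    active : (p,) mask of genes with nonzero variance; inactive genes are
        never fitted as targets and never receive or emit an edge.
    n : number of samples.
    rel_grid : descending relative grid, scaled per target by the smallest
        all-zeroing penalty when ``use_rel`` is true.
    abs_grid : descending absolute penalty grid, used otherwise.
    sigma2_mode : 0 -> residual variance of the least-penalized grid model
        (sample variance of y as degenerate fallback); 1 -> sample variance
        of y directly.
    delta, tol, max_sweeps : solver parameters.

    Returns
    -------
    B : (p, p) coefficient matrix, ``B[j, l]`` = effect of regulator j on
        target l, on the original data scale.
    lam_sel : (p,) selected penalty per target (NaN for skipped targets).
    sweeps_max : (p,) largest sweep count used on any grid point per target.
    """
    p = G.shape[0]
    B = np.zeros((p, p))
    lam_sel = np.full(p, np.nan)
    sweeps_max = np.zeros(p, dtype=np.int64)
    log_n = np.log(n)

    for l in range(p):
        if not active[l]:
            continue  # constant target: nothing to explain
        # X^T y for target l: column l of G times the response scale
        Xy = G[:, l] * col_scale[l]
        Xy[l] = 0.0
        yty = col_norm2[l]
        if use_rel:
            lam_max = 0.0
            for j in range(p):
                if j != l and active[j] and abs(Xy[j]) > lam_max:
                    lam_max = abs(Xy[j])
            if lam_max <= 0.0:
                continue
            grid = rel_grid * (lam_max / max(delta, 1e-3))
        else:
            grid = abs_grid
        coefs, rss, n_sweeps = _cd_enet_path(G, Xy, yty, grid, delta, l,
                                             active, tol, max_sweeps)
        n_lam = grid.shape[0]
        for k in range(n_lam):
            if n_sweeps[k] > sweeps_max[l]:
                sweeps_max[l] = n_sweeps[k]
        dfs = np.zeros(n_lam, dtype=np.int64)
        for k in range(n_lam):
            for j in range(p):
                if coefs[k, j] != 0.0:
                    dfs[k] += 1
        # sigma^2: residual variance of the least-penalized (last) grid
        # model, falling back to the sample variance of y when degenerate.
        var_y = col_norm2[l] / max(n - 1, 1)
        if sigma2_mode == 0:
            resid_df = n - dfs[n_lam - 1]
            sigma2 = rss[n_lam - 1] / resid_df if resid_df >= 1 else 0.0
            if sigma2 <= 1e-12 * max(var_y, 1e-300):
                sigma2 = var_y
        else:
            sigma2 = var_y
        if sigma2 <= 0.0:
            continue
        # BIC per Eq-style criterion rss/(n sigma^2) + log(n) df / n;
        # ties resolve to the smaller index, i.e. the larger penalty.
        best = 0
        best_bic = rss[0] / (n * sigma2) + log_n * dfs[0] / n
        for k in range(1, n_lam):
            bic = rss[k] / (n * sigma2) + log_n * dfs[k] / n
            if bic < best_bic:
                best = k
                best_bic = bic
        lam_sel[l] = grid[best]
        for j in range(p):
            if coefs[best, j] != 0.0:
                # undo the unit-variance scaling of the regulator column
                B[j, l] = coefs[best, j] / col_scale[j]
    return B, lam_sel, sweeps_max
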
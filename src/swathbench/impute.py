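"""Third chain stage: missing-value imputation.

Six concrete methods plus "none".  Every method leaves observed cells
bit-identical and (except NON) returns a table with no missing cells.
ZER/BAK/CEN are deterministic closed forms; KNN is deterministic given
its tie rule; SVD/BPC are deterministic given the seed in the params.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg
from sklearn.metrics.pairwise import nan_euclidean_distances

from .errors import (
    InsufficientDataError,
    NonConvergenceError,
    ValidationError,
)
from .table import IntensityTable

__all__ = ["ImputeParams", "apply_imputation", "knn_impute", "lowrank_impute"]

STAGE = "imputation"


@dataclass
class ImputeParams:
    code: str = "NON"
    knn_k: int = 10
    n_components: int = 5
    max_iter: int = 100
    tol: float = 1e-4
    background_quantile: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if not 0.0 < self.background_quantile <= 0.5:
            raise ValidationError("background_quantile must lie in (0, 0.5]")


def _check_columns_observed(table: IntensityTable) -> None:
    n_obs = table.observed_mask.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmin(n_obs))
        raise InsufficientDataError(
            f"sample {table.sample_ids[j]!r} has no observed values", stage=STAGE
        )


# ---------------------------------------------------------------------------
# closed-form methods


def _background(values: np.ndarray, q: float) -> np.ndarray:
    out = values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        miss = np.isnan(col)
        if miss.any():
            out[miss, j] = np.quantile(col[~miss], q)
    return out


def _censored(values: np.ndarray) -> np.ndarray:
    """Left-censoring surrogate: half of each protein's minimum observed
    value; proteins with no observation get half the matrix minimum."""
    out = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_min = np.nanmin(values, axis=1)
    global_min = np.nanmin(values)
    fill = np.where(np.isnan(row_min), global_min, row_min) / 2.0
    miss = np.isnan(values)
    out[miss] = np.broadcast_to(fill[:, None], values.shape)[miss]
    return out


# ---------------------------------------------------------------------------
# KNN


def knn_impute(table: IntensityTable, params: ImputeParams | None = None) -> IntensityTable:
    """Impute from the k nearest protein rows (Euclidean over co-observed
    samples, count-normalized), weighting neighbor values by 1/distance.

    Neighbors are selected once per target protein; a neighbor missing in
    the target cell's sample is skipped, and when every selected neighbor
    is missing there, the protein's own observed mean is used.  Zero
    distances get equal weights.  Candidate neighbors must share >= 2
    observed samples with the target; a target with no candidates falls
    back to its row mean.
    """
    params = params or ImputeParams(code="KNN")
    p, s = table.values.shape
    if p < params.knn_k + 1:
        raise InsufficientDataError(
            f"KNN needs >= k+1 = {params.knn_k + 1} proteins", stage=STAGE
        )
    values = table.values
    obs = table.observed_mask
    out = values.copy()
    rows_missing = np.flatnonzero(~obs.all(axis=1))
    if rows_missing.size == 0:
        return table.with_values(out)

    # pairwise distances; nan_euclidean is sqrt(s / n_shared * sum sq diff),
    # monotone in the count-normalized RMS difference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = nan_euclidean_distances(values[rows_missing], values)
    overlap = (obs[rows_missing].astype(np.int32)) @ (obs.astype(np.int32).T)
    dist[overlap < 2] = np.inf
    dist[~np.isfinite(dist)] = np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(values, axis=1)
    grand_mean = np.nanmean(values)

    for t, i in enumerate(rows_missing):
        d = dist[t].copy()
        d[i] = np.inf  # not its own neighbor
        candidates = np.flatnonzero(np.isfinite(d))
        fallback = row_means[i] if np.isfinite(row_means[i]) else grand_mean
        if candidates.size == 0:
            out[i, ~obs[i]] = fallback
            continue
        k = min(params.knn_k, candidates.size)
        order = candidates[np.lexsort((candidates, d[candidates]))][:k]
        for j in np.flatnonzero(~obs[i]):
            donors = order[obs[order, j]]
            if donors.size == 0:
                out[i, j] = fallback
                continue
            dd = d[donors]
            if np.any(dd == 0.0):
                w = (dd == 0.0).astype(float)  # equal weights on exact ties
            else:
                w = 1.0 / dd
            out[i, j] = np.average(values[donors, j], weights=w)
    return table.with_values(out)


# ---------------------------------------------------------------------------
# low-rank completion (SVD / BPCA)


def _svds_v0(X: np.ndarray) -> np.ndarray:
    # fixed ARPACK start vector: svds defaults to a random one, which
    # would break bit-reproducibility of sweeps
    return np.linspace(1.0, 2.0, min(X.shape))


def _truncated_svd(X: np.ndarray, r: int) -> np.ndarray:
    if r >= min(X.shape) - 1 or min(X.shape) < 10:
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        return (U[:, :r] * sv[:r]) @ Vt[:r]
    U, sv, Vt = scipy.sparse.linalg.svds(X, k=r, v0=_svds_v0(X))
    return (U * sv) @ Vt


def _init_filled(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(values, axis=1)
    row_means = np.where(np.isnan(row_means), np.nanmean(values), row_means)
    filled = values.copy()
    miss = np.isnan(values)
    filled[miss] = np.broadcast_to(row_means[:, None], values.shape)[miss]
    return filled


def _iterate_lowrank(values: np.ndarray, reconstruct, tol: float, max_iter: int) -> np.ndarray:
    """Shared EM-style loop: reconstruct, overwrite missing cells only."""
    miss = np.isnan(values)
    filled = _init_filled(values)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return filled
    last_change = np.inf
    grow_streak = 0
    for _ in range(max_iter):
        recon = reconstruct(filled)
        new_missing = recon[miss]
        change = float(np.sqrt(np.mean((new_missing - filled[miss]) ** 2)))
        filled[miss] = new_missing
        if change < tol:
            break
        if change > 10.0 * last_change:
            grow_streak += 1
            if grow_streak >= 5:
                raise NonConvergenceError("low-rank completion diverged", stage=STAGE)
        else:
            grow_streak = 0
        last_change = change
    return filled


def lowrank_impute(
    table: IntensityTable, method: str, params: ImputeParams | None = None
) -> IntensityTable:
    """Iterative low-rank matrix completion.

    SVD: alternate rank-``n_components`` SVD reconstruction with
    overwriting of the missing cells until the RMS change on missing
    cells is below ``tol``.  BPC: the same loop, but components come from
    Bayesian PCA — EM with automatic-relevance-determination priors on
    the component scales so superfluous components shrink toward zero;
    the effective rank is the number of components whose scale exceeds
    1e-3 of the largest.
    """
    params = params or ImputeParams(code=method)
    _check_columns_observed(table)
    values = table.values
    p, s = values.shape
    r = min(params.n_components, min(p, s) - 1)
    if r < 1:
        raise InsufficientDataError("matrix too small for low-rank completion", stage=STAGE)

    if method == "SVD":
        def reconstruct(filled: np.ndarray) -> np.ndarray:
            mu = filled.mean(axis=0)
            return _truncated_svd(filled - mu, r) + mu

        filled = _iterate_lowrank(values, reconstruct, params.tol, params.max_iter)
        return table.with_values(filled)

    if method == "BPC":
        filled, W = _bpca_em(values, r, params.tol, params.max_iter)
        out = table.with_values(filled)
        scales = np.sqrt(np.sum(W**2, axis=0))
        out.bpca_effective_rank = int(np.sum(scales > 1e-3 * scales.max()))  # type: ignore[attr-defined]
        return out

    raise ValidationError(f"unknown low-rank method {method!r}")


def _bpca_em(values: np.ndarray, r: int, tol: float, max_iter: int):
    """EM for probabilistic PCA with ARD priors on component scales.

    Weights initialized from the SVD of the row-mean-filled matrix (the
    flat EM likelihood makes random starts mix components for hundreds of
    iterations; the SVD start is deterministic and lets ARD shrink
    superfluous components within tens of iterations).  Missing cells are
    refilled from the reconstruction each iteration.
    """
    miss = np.isnan(values)
    filled = _init_filled(values)
    n, d = filled.shape
    mu = filled.mean(axis=0)
    Xc = filled - mu
    if r < min(n, d) - 1 and min(n, d) >= 10:
        U0, s0, Vt0 = scipy.sparse.linalg.svds(Xc, k=r, v0=_svds_v0(Xc))
        order = np.argsort(s0)[::-1]
        s0, Vt0 = s0[order], Vt0[order]
    else:
        _, s0, Vt0 = np.linalg.svd(Xc, full_matrices=False)
    W = Vt0[:r].T * (s0[:r] / np.sqrt(n))
    sigma2 = 1.0
    alpha = np.ones(r)
    last_scales = np.sqrt(np.sum(W**2, axis=0))
    last_change = np.inf
    grow_streak = 0
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        Xc = filled - mu
        M = W.T @ W + sigma2 * np.eye(r)
        Minv = np.linalg.inv(M)
        Ez = Xc @ W @ Minv
        Szz = n * sigma2 * Minv + Ez.T @ Ez
        W = (Xc.T @ Ez) @ np.linalg.inv(Szz + sigma2 * np.diag(alpha))
        resid = Xc - Ez @ W.T
        sigma2 = max(
            float(
                (np.sum(resid**2) + n * sigma2 * np.trace(W @ Minv @ W.T)) / (n * d)
            ),
            1e-12,
        )
        alpha = np.minimum(d / (np.sum(W**2, axis=0) + 1e-12), 1e12)
        recon = Ez @ W.T + mu
        if miss.any():
            change = float(
                np.sqrt(np.mean((recon[miss] - filled[miss]) ** 2))
            )
            filled[miss] = recon[miss]
            if change > 10.0 * last_change:
                grow_streak += 1
                if grow_streak >= 5:
                    raise NonConvergenceError("BPCA EM diverged", stage=STAGE)
            else:
                grow_streak = 0
            last_change = change
        else:
            change = 0.0
        scales = np.sqrt(np.sum(W**2, axis=0))
        scale_shift = float(np.max(np.abs(scales - last_scales)))
        last_scales = scales
        # missing cells settle before ARD does; require both to stabilize
        if change < tol and scale_shift < 1e-3:
            break
    return filled, W


# ---------------------------------------------------------------------------
# dispatcher


def apply_imputation(table: IntensityTable, params: ImputeParams) -> IntensityTable:
    """Dispatch to the imputation method named by ``params.code``."""
    code = params.code
    if code == "NON":
        return table.copy()
    if code == "ZER":
        out = table.values.copy()
        out[np.isnan(out)] = 0.0
        return table.with_values(out)
    if code == "CEN":
        return table.with_values(_censored(table.values))
    # remaining methods need observed values in every sample
    _check_columns_observed(table)
    if code == "BAK":
        return table.with_values(_background(table.values, params.background_quantile))
    if code == "KNN":
        return knn_impute(table, params)
    if code in ("SVD", "BPC"):
        return lowrank_impute(table, code, params)
    raise ValidationError(f"unknown imputation code {code!r}")
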
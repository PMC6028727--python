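"""Second chain stage: between-sample / per-feature normalization.

Fifteen concrete methods plus "none".  Location/scale methods act on the
observed cells of each sample column (MEA, MED, TIC, ZSC, MAD) or each
protein row (AUT, PAR); QUA and PQN equalize whole distributions; TMM,
CYC, LOW, RLR, VSN and EIG have dedicated estimators below.  Statistics
always exclude missing cells, and missing cells pass through untouched.

Methods are applied to whatever scale the preceding transformation
produced: chains are blind sequential compositions, so no hidden
re-logging or scale coercion happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import (
    DegenerateScaleError,
    InsufficientDataError,
    InsufficientOverlapError,
    ValidationError,
)
from .table import IntensityTable

__all__ = [
    "NormalizeParams",
    "apply_normalization",
    "tmm_factors",
    "regression_normalize",
    "vsn_normalize",
    "eigenms_normalize",
]

STAGE = "normalization"


@dataclass
class NormalizeParams:
    code: str = "NON"
    loess_span: float = 0.7
    cyclic_iterations: int = 3
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    vsn_max_iter: int = 50
    vsn_tol: float = 1e-6
    eigenms_n_perm: int = 500
    eigenms_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.loess_span <= 1.0:
            raise ValidationError("loess_span must lie in (0, 1]")
        for name in ("tmm_trim_m", "tmm_trim_a"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5)")
        if not 0.0 < self.eigenms_alpha < 1.0:
            raise ValidationError("eigenms_alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# simple per-sample / per-protein methods


def _column_stat_scale(values: np.ndarray, stat: str) -> np.ndarray:
    """MEA/MED/TIC: rescale columns so the chosen statistic is constant."""
    if stat == "mean":
        col = np.nanmean(values, axis=0)
        grand = np.nanmean(values)
    elif stat == "median":
        col = np.nanmedian(values, axis=0)
        grand = np.nanmedian(values)
    else:  # total ion current: column sums, target = mean column sum
        col = np.nansum(values, axis=0)
        grand = np.mean(col)
    if np.any(col == 0.0):
        raise DegenerateScaleError(f"zero column {stat}; cannot rescale", stage=STAGE)
    return values * (grand / col)[None, :]


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    mean = np.nanmean(values, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(values, axis=0, ddof=1)
    if np.any(~np.isfinite(sd)) or np.any(sd == 0.0):
        raise DegenerateScaleError("zero column sd for Z-score", stage=STAGE)
    return (values - mean[None, :]) / sd[None, :]


def _mad_columns(values: np.ndarray) -> np.ndarray:
    med = np.nanmedian(values, axis=0)
    mad = np.nanmedian(np.abs(values - med[None, :]), axis=0)
    if np.any(mad == 0.0) or np.any(np.isnan(mad)):
        raise DegenerateScaleError("zero column MAD", stage=STAGE)
    return (values - med[None, :]) / mad[None, :]


def _row_scaling(values: np.ndarray, pareto: bool) -> np.ndarray:
    """AUT / PAR: center rows, divide by row sd (or its square root).

    Rows with fewer than two observed values, or zero spread, carry no
    scale information and are emitted as missing.
    """
    out = np.full_like(values, np.nan)
    obs = ~np.isnan(values)
    n_obs = obs.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    ok = (n_obs >= 2) & np.isfinite(sd) & (sd > 0.0)
    denom = np.sqrt(sd[ok]) if pareto else sd[ok]
    out[ok] = (values[ok] - mean[ok, None]) / denom[:, None]
    return out


def _pqn(values: np.ndarray) -> np.ndarray:
    """Probabilistic quotient: TIC pre-scale, divide columns by the median
    quotient against the per-protein median reference."""
    pre = _column_stat_scale(values, "tic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(pre, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        quot = pre / ref[:, None]
        factors = np.nanmedian(quot, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors == 0.0):
        raise DegenerateScaleError("degenerate PQN quotient factors", stage=STAGE)
    return pre / factors[None, :]


def _quantile(values: np.ndarray) -> np.ndarray:
    """Quantile normalization with missing values.

    Complete, equal-length columns reduce to the classic rank-mean scheme
    (tied values receive the mean of the means over their tied ranks).
    With missing cells, each column's quantile function is interpolated to
    a common grid of the maximum column length and averaged.
    """
    p, s = values.shape
    obs = ~np.isnan(values)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise InsufficientDataError("column with no observed values", stage=STAGE)
    L = int(n_obs.max())
    grid = np.linspace(0.0, 1.0, L)
    mean_q = np.zeros(L)
    for j in range(s):
        col = np.sort(values[obs[:, j], j])
        if col.size == L:
            mean_q += col
        else:
            mean_q += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    mean_q /= s

    out = np.full_like(values, np.nan)
    for j in range(s):
        idx = np.flatnonzero(obs[:, j])
        col = values[idx, j]
        order = np.argsort(col, kind="stable")
        n = col.size
        pos = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        mapped = np.interp(pos, grid, mean_q)
        new = np.empty(n)
        new[order] = mapped
        # ties: average the mapped values over tied ranks
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=new, minlength=uniq.size)
            counts = np.bincount(inv, minlength=uniq.size)
            new = (sums / counts)[inv]
        out[idx, j] = new
    return out


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(table: IntensityTable, params: NormalizeParams | None = None) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors (applied as division).

    The reference sample is the column whose upper quartile of observed
    values is closest to the mean upper quartile.  For every sample,
    M = log2(x_j / x_ref) and A = 0.5 * log2(x_j * x_ref) over proteins
    observed in both; the top/bottom ``tmm_trim_m`` of M and
    ``tmm_trim_a`` of A are dropped and the factor is 2 to the
    precision-weighted mean of the remaining M.  Factors are rescaled to
    multiply to 1.
    """
    params = params or NormalizeParams(code="TMM")
    values = table.values
    # M/A ratios are defined for strictly positive cells only; nonpositive
    # cells are excluded like unobserved ones (zeros are common in exports)
    obs = table.observed_mask & (table.values > 0)

    uq = np.array([
        np.quantile(values[obs[:, j], j], 0.75) if obs[:, j].any() else np.nan
        for j in range(table.n_samples)
    ])
    if np.all(np.isnan(uq)):
        raise InsufficientOverlapError("no positive observed values", stage=STAGE)
    ref = int(np.nanargmin(np.abs(uq - np.nanmean(uq))))

    log_factors = np.zeros(table.n_samples)
    for j in range(table.n_samples):
        if j == ref:
            continue
        both = obs[:, j] & obs[:, ref]
        if both.sum() < 10:
            raise InsufficientOverlapError(
                f"only {int(both.sum())} positive proteins co-observed with reference",
                stage=STAGE,
            )
        xj, xr = values[both, j], values[both, ref]
        m = np.log2(xj / xr)
        a = 0.5 * np.log2(xj * xr)
        lo_m, hi_m = np.quantile(m, [params.tmm_trim_m, 1.0 - params.tmm_trim_m])
        lo_a, hi_a = np.quantile(a, [params.tmm_trim_a, 1.0 - params.tmm_trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        # delta-method precision of M for intensity data
        w = 1.0 / (1.0 / xj[keep] + 1.0 / xr[keep])
        log_factors[j] = np.average(m[keep], weights=w)

    log_factors -= log_factors.mean()  # product of factors = 1
    return np.power(2.0, log_factors)


# ---------------------------------------------------------------------------
# loess / robust-line trend removal (LOW, RLR, CYC)


_LOESS_MAX_POINTS = 400


def _loess_fit(a: np.ndarray, d: np.ndarray, span: float) -> np.ndarray:
    """Fitted loess trend of d on a, evaluated at every input point.

    For large inputs the trend is fitted on ~400 points spread evenly
    over the rank of a and linearly interpolated to all points; combined
    with the lowess delta shortcut this keeps pairwise (cyclic) loess
    over hundreds of sample pairs tractable without changing the fitted
    trend materially.
    """
    if np.ptp(a) == 0:
        return np.full_like(d, d.mean())
    delta = 0.01 * np.ptp(a)
    if a.size <= _LOESS_MAX_POINTS:
        fitted = sm_lowess(d, a, frac=span, it=1, delta=delta, return_sorted=False)
        return np.asarray(fitted, dtype=float)
    order = np.argsort(a, kind="stable")
    pick = order[np.linspace(0, a.size - 1, _LOESS_MAX_POINTS).astype(int)]
    grid = sm_lowess(d[pick], a[pick], frac=span, it=0, delta=delta,
                     return_sorted=True)
    return np.interp(a, grid[:, 0], grid[:, 1])


def _huber_line_fit(a: np.ndarray, d: np.ndarray, tuning: float = 1.345,
                    max_iter: int = 30) -> tuple[float, float]:
    """Straight line d ~ a by IRLS with Huber weights; returns (intercept, slope)."""
    w = np.ones_like(d)
    beta0, beta1 = 0.0, 0.0
    for _ in range(max_iter):
        sw = np.sqrt(w)
        X = np.column_stack([sw, sw * a])
        coef, *_ = np.linalg.lstsq(X, sw * d, rcond=None)
        new0, new1 = float(coef[0]), float(coef[1])
        resid = d - (new0 + new1 * a)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale < 1e-12:
            beta0, beta1 = new0, new1
            break
        u = np.abs(resid) / scale
        w = np.where(u <= tuning, 1.0, tuning / u)
        if abs(new0 - beta0) < 1e-10 and abs(new1 - beta1) < 1e-10:
            beta0, beta1 = new0, new1
            break
        beta0, beta1 = new0, new1
    return beta0, beta1


def regression_normalize(
    table: IntensityTable, method: str, params: NormalizeParams | None = None
) -> IntensityTable:
    """Trend-removal normalization: LOW (loess vs reference), RLR (robust
    line vs reference), CYC (pairwise cyclic loess on M-A coordinates).

    LOW/RLR: per sample, the difference to the per-protein median
    reference is modelled as a function of the mean level and the fitted
    trend subtracted.  CYC: for every unordered sample pair, half the
    fitted M-on-A loess trend is subtracted from one sample and added to
    the other, repeated ``cyclic_iterations`` times.
    """
    params = params or NormalizeParams(code=method)
    values = table.values.copy()
    obs = table.observed_mask
    s = table.n_samples

    if method in ("LOW", "RLR"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmedian(values, axis=1)
        fitted_pairs = 0
        for j in range(s):
            both = obs[:, j] & ~np.isnan(ref)
            if both.sum() < 10:
                warnings.warn(f"sample {table.sample_ids[j]}: <10 points vs reference; skipped")
                continue
            d = values[both, j] - ref[both]
            a = 0.5 * (values[both, j] + ref[both])
            if method == "LOW":
                trend = _loess_fit(a, d, params.loess_span)
            else:
                b0, b1 = _huber_line_fit(a, d)
                trend = b0 + b1 * a
            values[both, j] -= trend
            fitted_pairs += 1
        if fitted_pairs == 0:
            raise InsufficientOverlapError("no sample could be fitted", stage=STAGE)
        return table.with_values(values)

    if method == "CYC":
        any_pair = False
        for _ in range(params.cyclic_iterations):
            for j in range(s):
                for k in range(j + 1, s):
                    both = obs[:, j] & obs[:, k]
                    if both.sum() < 10:
                        continue
                    any_pair = True
                    m = values[both, j] - values[both, k]
                    a = 0.5 * (values[both, j] + values[both, k])
                    trend = _loess_fit(a, m, params.loess_span)
                    values[both, j] -= trend / 2.0
                    values[both, k] += trend / 2.0
        if not any_pair:
            raise InsufficientOverlapError("all sample pairs skipped", stage=STAGE)
        return table.with_values(values)

    raise ValidationError(f"unknown regression normalization {method!r}")


# ---------------------------------------------------------------------------
# VSN


def vsn_normalize(
    table: IntensityTable, params: NormalizeParams | None = None
) -> IntensityTable:
    """Variance-stabilizing normalization: per-sample affine calibration
    followed by a generalized log (arsinh).

    Each sample j gets h_j(x) = arsinh(a_j + b_j * x) with b_j > 0.  The
    affine coefficients minimize the pooled across-sample variance of
    per-protein deviations from the per-protein median reference, by
    coordinate descent over (trim set, coefficients): each column is fit
    to the reference by least squares over the middle 90% of proteins
    (10% largest residuals under the current coefficients dropped),
    iterated until the largest coefficient change is below ``vsn_tol``.
    The fixed reference anchors the overall affine scale, which the
    deviation criterion alone leaves unidentified.  Non-convergence is
    flagged with a warning, never a chain failure.
    """
    params = params or NormalizeParams(code="VSN")
    values = table.values
    obs = table.observed_mask
    s = table.n_samples
    a = np.zeros(s)
    b = np.ones(s)
    # intercept changes are measured relative to the data scale
    data_scale = float(np.median(np.abs(values[obs]))) or 1.0
    # fixed per-protein reference anchors the (otherwise unidentified)
    # overall affine scale; the deviation criterion is minimized against it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(values, axis=1)

    def _trimmed_line(x: np.ndarray, y: np.ndarray,
                      a0: float, b0: float) -> tuple[float, float]:
        # trimmed LS: drop the 10% largest |residual| under the current
        # coefficients, refit on the middle 90% of proteins
        X = np.column_stack([np.ones_like(x), x])
        if x.size >= 20:
            resid = np.abs(y - (a0 + b0 * x))
            keep = resid <= np.quantile(resid, 0.9)
        else:
            keep = np.ones_like(x, dtype=bool)
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        return float(coef[0]), float(coef[1])

    converged = False
    for _ in range(params.vsn_max_iter):
        new_a, new_b = a.copy(), b.copy()
        for j in range(s):
            both = obs[:, j] & ~np.isnan(ref)
            if both.sum() < 3:
                continue
            inter, slope = _trimmed_line(values[both, j], ref[both], a[j], b[j])
            new_a[j], new_b[j] = inter, max(slope, 1e-12)  # b_j > 0 enforced
        max_change = max(
            float(np.max(np.abs(new_a - a))) / data_scale,
            float(np.max(np.abs(new_b - b))),
        )
        a, b = new_a, new_b
        if max_change < params.vsn_tol:
            converged = True
            break
    if not converged:
        warnings.warn("VSN coordinate descent did not converge; using last iterate")

    out = np.arcsinh(a[None, :] + b[None, :] * values)
    return table.with_values(np.where(obs, out, np.nan))


# ---------------------------------------------------------------------------
# EigenMS


def eigenms_normalize(
    table: IntensityTable, params: NormalizeParams | None = None
) -> IntensityTable:
    """Remove systematic bias trends found by SVD on group-centered residuals.

    Steps: (1) subtract per-protein group means (fixed treatment effects);
    (2) SVD of the complete-case residual matrix; (3) the number of
    significant bias trends is the count of leading singular values
    exceeding the (1 - alpha) quantile of the first singular value under
    ``eigenms_n_perm`` random within-row permutations of the residuals;
    (4) subtract the significant-trend component (projection onto the
    significant right singular vectors); (5) re-add the group means.
    Group-mean differences are preserved exactly by construction.
    """
    params = params or NormalizeParams(code="EIG")
    values = table.values
    obs = table.observed_mask
    groups = [table.group_columns(g) for g in table.group_names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(">=2 groups with >=2 samples required", stage=STAGE)

    # per-protein group means on observed cells
    group_means = np.full_like(values, np.nan)
    for cols in groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gm = np.nanmean(values[:, cols], axis=1)
        group_means[:, cols] = gm[:, None]
    resid = values - group_means

    complete = obs.all(axis=1)
    n_cc, s = int(complete.sum()), table.n_samples
    if n_cc < s:
        raise InsufficientDataError(
            f"{n_cc} complete-case proteins < {s} samples", stage=STAGE
        )
    R = resid[complete]

    U, sv, Vt = np.linalg.svd(R, full_matrices=False)
    rng = np.random.default_rng(params.seed)

    def _first_sv(mat: np.ndarray) -> float:
        if min(mat.shape) <= 2 or mat.shape[0] < 20:
            return float(np.linalg.svd(mat, compute_uv=False)[0])
        try:
            v0 = np.linspace(1.0, 2.0, min(mat.shape))
            return float(
                scipy.sparse.linalg.svds(
                    mat, k=1, v0=v0, return_singular_vectors=False
                )[0]
            )
        except Exception:
            return float(np.linalg.svd(mat, compute_uv=False)[0])

    # null: permute each row's residuals within each group's columns —
    # this preserves the per-row zero-sum constraint group centering
    # imposes, which a global permutation would break (deflating the
    # null first singular value and inflating detection)
    null_sv = np.empty(params.eigenms_n_perm)
    shuffled = np.empty_like(R)
    for t in range(params.eigenms_n_perm):
        for cols in groups:
            block = R[:, cols]
            idx = np.argsort(rng.random(block.shape), axis=1)
            shuffled[:, cols] = np.take_along_axis(block, idx, axis=1)
        null_sv[t] = _first_sv(shuffled)
    threshold = np.quantile(null_sv, 1.0 - params.eigenms_alpha)
    n_trends = int(np.sum(sv > threshold))
    # trailing singular values cannot be significant if a leading one is not
    for k in range(len(sv)):
        if sv[k] <= threshold:
            n_trends = k
            break

    if n_trends == 0:
        out_table = table.copy()
        out_table.eigenms_n_trends = 0  # type: ignore[attr-defined]
        return out_table

    V_t = Vt[:n_trends]  # (t, s) bias trends in sample space
    # project every protein's observed residuals onto the trends
    out = values.copy()
    for i in range(table.n_proteins):
        oi = obs[i]
        if oi.sum() <= n_trends:
            continue
        Vi = V_t[:, oi]
        coef, *_ = np.linalg.lstsq(Vi.T, resid[i, oi], rcond=None)
        out[i, oi] = group_means[i, oi] + resid[i, oi] - coef @ Vi
    out_table = table.with_values(out)
    out_table.eigenms_n_trends = n_trends  # type: ignore[attr-defined]
    return out_table


# ---------------------------------------------------------------------------
# dispatcher


def apply_normalization(
    table: IntensityTable, params: NormalizeParams
) -> IntensityTable:
    """Dispatch to the normalization method named by ``params.code``."""
    if table.n_samples < 2:
        raise InsufficientDataError("normalization needs >= 2 samples", stage=STAGE)
    code = params.code
    if code == "NON":
        return table.copy()
    if code == "MEA":
        return table.with_values(_column_stat_scale(table.values, "mean"))
    if code == "MED":
        return table.with_values(_column_stat_scale(table.values, "median"))
    if code == "TIC":
        return table.with_values(_column_stat_scale(table.values, "tic"))
    if code == "ZSC":
        return table.with_values(_zscore_columns(table.values))
    if code == "MAD":
        return table.with_values(_mad_columns(table.values))
    if code == "AUT":
        return table.with_values(_row_scaling(table.values, pareto=False))
    if code == "PAR":
        return table.with_values(_row_scaling(table.values, pareto=True))
    if code == "PQN":
        return table.with_values(_pqn(table.values))
    if code == "QUA":
        return table.with_values(_quantile(table.values))
    if code == "TMM":
        factors = tmm_factors(table, params)
        return table.with_values(table.values / factors[None, :])
    if code in ("CYC", "LOW", "RLR"):
        return regression_normalize(table, code, params)
    if code == "VSN":
        return vsn_normalize(table, params)
    if code == "EIG":
        return eigenms_normalize(table, params)
    raise ValidationError(f"unknown normalization code {code!r}")
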
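"""First chain stage: element-wise intensity transformations.

All transformations act on observed cells only and leave the missing mask
untouched.  They are strictly monotone increasing on their domain, so the
rank order of observed values within a column is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import DomainError, NonConvergenceError, ValidationError
from .table import IntensityTable

__all__ = ["TransformParams", "apply_transformation", "estimate_boxcox_lambda"]

STAGE = "transformation"


@dataclass
class TransformParams:
    code: str = "NON"
    log_base: float = 2.0
    power_exponent: float = 0.5
    boxcox_lambda: float | str = "estimate"

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValidationError("log_base must be > 1")
        if not 0.0 < self.power_exponent < 1.0:
            raise ValidationError("power_exponent must lie in (0, 1)")


def estimate_boxcox_lambda(observed: np.ndarray) -> float:
    """Maximum-likelihood Box-Cox lambda over pooled observed values."""
    observed = np.asarray(observed, dtype=float)
    if observed.size < 2 or np.ptp(observed) == 0:
        raise NonConvergenceError(
            "Box-Cox lambda undefined for constant data", stage=STAGE
        )
    try:
        return float(scipy.stats.boxcox_normmax(observed, method="mle"))
    except Exception as exc:  # optimizer breakdowns on pathological data
        raise NonConvergenceError(f"Box-Cox estimation failed: {exc}", stage=STAGE)


def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def apply_transformation(table: IntensityTable, params: TransformParams) -> IntensityTable:
    """Apply LOG / CUB / POW / BOX / NON to the observed cells of a table.

    LOG and BOX require strictly positive observed values; POW (default
    exponent 0.5) requires nonnegative values when the exponent is not an
    integer.  Violations raise a :class:`DomainError` tagged with
    stage="transformation" so the chain engine can record the failure.
    """
    code = params.code
    if code == "NON":
        return table.copy()

    values = table.values
    obs = table.observed_mask
    observed = values[obs]

    if code == "LOG":
        if np.any(observed <= 0):
            raise DomainError("log transform requires positive values", stage=STAGE)
        out = np.where(obs, np.log(np.where(obs, values, 1.0)) / np.log(params.log_base), np.nan)
    elif code == "CUB":
        out = np.where(obs, np.cbrt(values), np.nan)
    elif code == "POW":
        # exponent constrained to (0, 1): fractional, so negatives are out of domain
        if np.any(observed < 0):
            raise DomainError(
                "power transform with fractional exponent requires nonnegative values",
                stage=STAGE,
            )
        out = np.where(obs, np.power(np.where(obs, values, 0.0), params.power_exponent), np.nan)
    elif code == "BOX":
        if np.any(observed <= 0):
            raise DomainError("Box-Cox requires positive values", stage=STAGE)
        lam = (
            estimate_boxcox_lambda(observed)
            if params.boxcox_lambda == "estimate"
            else float(params.boxcox_lambda)
        )
        out = np.where(obs, _boxcox(np.where(obs, values, 1.0), lam), np.nan)
    else:
        raise ValidationError(f"unknown transformation code {code!r}")

    return table.with_values(out)
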
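"""Small shared numerics: reporting-precision rounding and weighted quantiles."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_up", "weighted_quantile"]

# standard normal 75th percentile, used when fitting distributions to IQRs
Z75 = 0.6744897501960817


def round_half_up(x, ndigits: int = 2):
    """Round half away from zero (48.005 -> 48.01), scalar or array.

    Reported table cells use this instead of banker's rounding so printed
    values match conventional hand rounding.
    """
    q = Decimal(1).scaleb(-ndigits)

    def _one(v: float) -> float:
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    if np.ndim(x) == 0:
        return _one(float(x))
    return np.array([_one(v) for v in np.asarray(x, dtype=float).ravel()]).reshape(
        np.shape(x)
    )


def weighted_quantile(values, q, weights=None) -> float:
    """Quantile of ``values`` under sampling weights.

    With ``weights=None`` this is ``numpy.quantile``.  Otherwise it inverts
    the weighted empirical CDF with the midpoint convention (each observation
    carries its mass at its CDF midpoint, linearly interpolated), which
    agrees with the unweighted quantile up to O(1/n) for uniform weights.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if weights is None:
        return float(np.quantile(values, q))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative weights")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    cdf = (np.cumsum(w) - 0.5 * w) / total
    return float(np.interp(q, cdf, v))
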
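"""Weighted summary statistics used by the descriptive tables."""

from __future__ import annotations

import numpy as np

from hhnet.errors import HHNetError


def _check_weights(values, weights):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise HHNetError("empty input")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise HHNetError("weights must be non-negative with positive total")
    return values, weights


def weighted_mean(values, weights=None) -> float:
    values, weights = _check_weights(values, weights)
    return float(np.sum(weights * values) / weights.sum())


def weighted_mean_se(values, weights=None) -> tuple[float, float]:
    """Weighted mean and its linearised standard error.

    SE uses the standard ratio-estimator approximation
    ``sqrt(sum w_i^2 (x_i - xbar)^2) / sum w_i`` (no finite-population
    or stratification adjustment).
    """
    values, weights = _check_weights(values, weights)
    m = np.sum(weights * values) / weights.sum()
    se = np.sqrt(np.sum((weights * (values - m)) ** 2)) / weights.sum()
    return float(m), float(se)


def weighted_quantile(values, q: float, weights=None) -> float:
    """Weighted sample quantile.

    The quantile is the smallest value whose cumulative weight reaches
    ``q * W``; when the cumulative weight hits ``q * W`` exactly, the
    midpoint with the next distinct value is returned (so the equal-
    weight median of {2, 3} is 2.5 and of {1, 2, 3} is 2).
    """
    values, weights = _check_weights(values, weights)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    target = q * cw[-1]
    idx = int(np.searchsorted(cw, target, side="left"))
    idx = min(idx, len(v) - 1)
    if np.isclose(cw[idx], target) and idx + 1 < len(v):
        return float(0.5 * (v[idx] + v[idx + 1]))
    return float(v[idx])


def weighted_share(flags, weights=None) -> float:
    """Weighted proportion (0-1) of a boolean/0-1 vector."""
    flags, weights = _check_weights(np.asarray(flags, dtype=float), weights)
    return float(np.sum(weights * flags) / weights.sum())
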
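"""Structural ego-network measures: degree, effective size, constraint.

All three are Burt's structural-hole measures evaluated on the binary
household network in which the ego (the woman respondent) is tied to
every alter and alters are tied to each other when related.

For a binary, symmetric ego network the effective size reduces to the
well-known simplification ``n - 2t/n`` (Borgatti), with ``n`` the number
of alters and ``t`` the number of alter-alter ties; the general
redundancy formula is also implemented (:func:`effective_size_general`)
and the two agree to machine precision — the test suite enumerates every
alter graph up to n=6 to verify this.

Constraint is standard (un-normalised) Burt constraint

    C = sum_j ( p_ej + sum_{q != e,j} p_eq * p_qj )^2

with proportional tie investments ``p_ij = z_ij / sum_k z_ik`` on the
binary adjacency including ego-alter ties. Its attainable range for a
degree-n ego is (0, 1.125]: the isolated-alters network gives 1/n and
the n-alter clique gives (2n-1)^2 / n^3 (1.125 at n=2). Survey reports
sometimes describe constraint as a 0-1 score; no truncation, capping or
normalisation is applied here.
"""

from __future__ import annotations

import numpy as np

from hhnet.errors import DegenerateNetworkError, HHNetError
from hhnet.kinship import EgoNetwork


def degree(net: EgoNetwork) -> int:
    """Number of alters: household size minus the ego herself."""
    return net.n_alters


def _require_alters(net: EgoNetwork) -> None:
    if net.n_alters < 1:
        raise DegenerateNetworkError("structural measures need at least one alter")


def effective_size_from_counts(n_alters: int, t_ties: int) -> float:
    """Simplified binary-network effective size ``n - 2t/n``."""
    if n_alters < 1:
        raise DegenerateNetworkError("effective size undefined for degree 0")
    return n_alters - 2.0 * t_ties / n_alters


def effective_size(net: EgoNetwork) -> float:
    """Burt effective size: the ego's number of nonredundant contacts.

    Ranges from 1 (one alter, or all alters mutually tied) to the
    degree (no alter-alter ties).
    """
    _require_alters(net)
    return effective_size_from_counts(net.n_alters, net.t_ties)


def burt_proportions(z: np.ndarray) -> np.ndarray:
    """Row-stochastic proportional tie investments from an adjacency.

    ``p[i, j] = (z[i, j] + z[j, i]) / sum_k (z[i, k] + z[k, i])``;
    rows of isolated nodes are left at zero.
    """
    z = np.asarray(z, dtype=float)
    s = z + z.T
    totals = s.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, s / totals, 0.0)
    return p


def constraint_from_adjacency(z: np.ndarray, ego: int = 0) -> float:
    """Burt constraint of node ``ego`` on a full adjacency matrix."""
    p = burt_proportions(z)
    n = z.shape[0]
    # inner_j = p_ej + sum_q p_eq p_qj ; the q=e and q=j terms vanish
    # because p_ee = p_jj = 0
    inner = p[ego] + p[ego] @ p
    alters = np.flatnonzero(z[ego] + z[:, ego])
    return float(np.sum(inner[alters] ** 2))


def burt_constraint(net: EgoNetwork) -> float:
    """Burt constraint of the ego: concentration of her network in
    mutually related alters. No truncation or capping applied."""
    _require_alters(net)
    return constraint_from_adjacency(net.adjacency(), ego=0)


def effective_size_general(z: np.ndarray, ego: int = 0) -> float:
    """Burt's general redundancy formula for effective size.

    ES = sum_j [ 1 - sum_q p_eq * m_jq ],  q != e, j

    with ``m_jq = (z_jq + z_qj) / max_k (z_jk + z_kj)`` the marginal
    strength of j's tie to q. Kept alongside the simplified formula as
    the second route of the dual-route check.
    """
    z = np.asarray(z, dtype=float)
    p = burt_proportions(z)
    s = z + z.T
    alters = np.flatnonzero(s[ego])
    if alters.size == 0:
        raise DegenerateNetworkError("effective size undefined for degree 0")
    total = 0.0
    for j in alters:
        mj = s[j] / s[j].max()
        q = alters[alters != j]
        total += 1.0 - float(np.dot(p[ego, q], mj[q]))
    return total


def dichotomise_effective_size(
    values,
    rule: str = "fixed",
    threshold: float = 3.0,
    weights=None,
) -> tuple[np.ndarray, float]:
    """Band effective sizes as ``low`` (<= threshold) or ``high`` (>).

    ``rule="fixed"`` uses the conventional survey cut of 3 nonredundant
    contacts; ``rule="weighted_median"`` derives the threshold as the
    weighted median of the pooled values. Values exactly at the
    threshold go to ``low``. Returns (bands, threshold used).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise HHNetError("cannot dichotomise an empty collection")
    if rule == "fixed":
        thr = float(threshold)
    elif rule == "weighted_median":
        from hhnet.stats import weighted_quantile

        w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
        thr = float(weighted_quantile(values, 0.5, w))
    else:
        raise HHNetError(f"unknown dichotomisation rule: {rule!r}")
    bands = np.where(values <= thr, "low", "high")
    return bands, thr
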
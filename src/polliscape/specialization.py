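"""Node-level specialization (d') and node strength for weighted bipartite networks.

d' measures how strongly a node's interaction frequencies deviate from the
availability of its potential partners.  For a site (row) ``i`` with weights
``A[i, j]``, row total ``K_i`` and partner availabilities ``q_j = L_j / F``:

    d_raw = sum_j p_ij * ln(p_ij / q_j),   p_ij = A[i, j] / K_i

i.e. the Kullback-Leibler divergence of the node's realized interaction
distribution from the marginal partner distribution (nats).  Because the
achievable range of d depends on the node's integer total and on partner
availability, d_raw is standardized to

    d' = (d_raw - d_min) / (d_max - d_min)  in [0, 1]

where d_min and d_max are the extremes over integer re-allocations of K_i
across partners.  d' near 0: a generalist node interacting in proportion to
availability; d' = 1: a node as specialized as its marginal totals allow
(e.g. a site whose visitor species occur nowhere else).

d_max is computed exactly by dynamic programming over availability-capped
integer allocations (each partner can absorb at most its observed total);
an ``unconstrained`` variant places the whole total on the rarest partner.
d_min uses largest-remainder allocation proportional to availability, which
converges to the continuous minimum d = 0 as counts grow.

Node strength sums, over a node's partners, the share of the partner's
interactions involving the focal node; for species, strengths add up to the
number of sites, so a single strong species can dominate the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IncidenceMatrix, ValidationError

__all__ = [
    "SpecializationResult",
    "StrengthResult",
    "dprime",
    "dprime_all",
    "node_strength",
]


@dataclass(frozen=True)
class SpecializationResult:
    node_id: str
    level: str  # "lower" (site) or "higher" (species)
    d_raw: float
    d_min: float
    d_max: float
    d_prime: float


@dataclass(frozen=True)
class StrengthResult:
    node_id: str
    level: str
    strength: float


def _kl(alloc: np.ndarray, total: float, q: np.ndarray) -> float:
    """KL divergence of alloc/total from q, with 0*ln(0) := 0."""
    p = np.asarray(alloc, dtype=float) / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _dmin_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Largest-remainder integer allocation of ``total`` proportional to q."""
    target = total * q
    base = np.floor(target).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = target - base
        # deterministic tie-break: larger remainder first, then larger q, then index
        order = np.lexsort((np.arange(len(q)), -q, -frac))
        base[order[:short]] += 1
    return base


def _dmax_capped(total: int, caps: np.ndarray, q: np.ndarray) -> float:
    """Exact maximum of the KL objective over capped integer allocations.

    Maximizes sum_j f_j(a_j) with f_j(a) = (a/total) * ln(a / (total * q_j))
    subject to sum_j a_j = total and 0 <= a_j <= caps_j, by dynamic
    programming over partners (the objective is separable, so the DP is
    exact).  Cost is O(total * sum(caps)) which is modest at field scale.
    """
    caps = np.minimum(caps.astype(int), total)
    if int(caps.sum()) < total:
        raise ValidationError("availability caps cannot absorb the node total")
    neg = -np.inf
    dp = np.full(total + 1, neg)
    dp[0] = 0.0
    for cap, qj in zip(caps, q):
        if cap == 0:
            continue
        a = np.arange(1, cap + 1, dtype=float)
        f = (a / total) * np.log(a / (total * qj))
        new = dp.copy()  # a_j = 0 contributes nothing
        for aj in range(1, cap + 1):
            cand = dp[: total + 1 - aj] + f[aj - 1]
            np.maximum(new[aj:], cand, out=new[aj:])
        dp = new
    return float(dp[total])


def _row_dprime(
    row: np.ndarray,
    L: np.ndarray,
    F: float,
    node_id: str,
    level: str,
    dmax_unconstrained: bool,
) -> SpecializationResult:
    total = float(row.sum())
    if total <= 0:
        raise ValidationError(f"node {node_id!r} has zero marginal total")
    q = L / F
    d_raw = _kl(row, total, q)

    k_int = int(round(total))
    if k_int != total:
        # non-integer weights: fall back to continuous extremes
        k_int = max(1, int(round(total)))
    d_min = _kl(_dmin_allocation(k_int, q), k_int, q)
    d_min = min(d_min, d_raw)  # largest-remainder is a near-minimizer; keep the invariant
    if dmax_unconstrained:
        d_max = float(np.log(1.0 / q.min()))
    else:
        d_max = _dmax_capped(k_int, L.copy(), q)
    d_max = max(d_max, d_raw)

    if d_max > d_min:
        d_prime = (d_raw - d_min) / (d_max - d_min)
    else:
        d_prime = 0.0
    return SpecializationResult(
        node_id=node_id,
        level=level,
        d_raw=d_raw,
        d_min=d_min,
        d_max=d_max,
        d_prime=float(np.clip(d_prime, 0.0, 1.0)),
    )


def dprime(
    matrix: IncidenceMatrix,
    node_id: str,
    level: str = "lower",
    dmax_unconstrained: bool = False,
) -> SpecializationResult:
    """Standardized specialization d' of one node.

    ``level="lower"`` treats ``node_id`` as a site (row); ``"higher"`` as a
    species (column, handled by transposing the matrix).
    """
    if level == "lower":
        i = matrix.row_index(node_id)
        return _row_dprime(matrix.A[i], matrix.L, matrix.F, node_id, level, dmax_unconstrained)
    if level == "higher":
        j = matrix.col_index(node_id)
        return _row_dprime(matrix.A[:, j], matrix.K, matrix.F, node_id, level, dmax_unconstrained)
    raise ValueError(f"unknown level {level!r}")


def dprime_all(
    matrix: IncidenceMatrix,
    level: str = "lower",
    dmax_unconstrained: bool = False,
) -> list[SpecializationResult]:
    labels = matrix.row_labels if level == "lower" else matrix.col_labels
    return [dprime(matrix, lab, level, dmax_unconstrained) for lab in labels]


def node_strength(matrix: IncidenceMatrix, level: str = "higher") -> list[StrengthResult]:
    """Node strength: sum of partner dependencies on the focal node.

    For species ``j``: strength_j = sum_i A[i, j] / K_i (each site's rows of
    dependencies sum to one, so species strengths sum to the number of
    sites); symmetric definition for sites.
    """
    A, K, L = matrix.A, matrix.K, matrix.L
    if level == "higher":
        dep = A / K[:, None]  # dependency of site i on species j
        return [
            StrengthResult(lab, "higher", float(s))
            for lab, s in zip(matrix.col_labels, dep.sum(axis=0))
        ]
    if level == "lower":
        dep = A / L[None, :]  # dependency of species j on site i
        return [
            StrengthResult(lab, "lower", float(s))
            for lab, s in zip(matrix.row_labels, dep.sum(axis=1))
        ]
    raise ValueError(f"unknown level {level!r}")
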
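"""Node roles: participation coefficient, within-module degree, classification.

Given a module partition, each node's position is summarized by two numbers:

* participation coefficient ``c = 1 - sum_t (k_it / k_i)^2`` where ``k_it``
  is the node's interaction weight into module ``t`` -- 0 when all its
  partners sit in one module, approaching ``1 - 1/M`` for an even spread
  over M modules;
* within-module degree ``z``: the node's weight into its own module,
  standardized by the mean and sample standard deviation of that weight over
  the same-level nodes of the module (0 when the module is degenerate).

Comparing (c, z) against null-derived critical thresholds classifies nodes
as network hubs (both high), between-module connectors (high c only),
within-module hubs (high z only) or peripheral nodes.  Both metrics use
interaction weights by default, consistent with the weighted modularity; a
``binary`` flag reduces them to the classic presence/absence versions for
sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import IncidenceMatrix, ValidationError
from .modularity import ModulePartition
from .nullmodels import ThresholdSet

logger = logging.getLogger("polliscape")

__all__ = [
    "NodeRole",
    "ROLES",
    "OLESEN_THRESHOLDS",
    "participation_coefficient",
    "participation_coefficients",
    "within_module_degree",
    "within_module_degrees",
    "classify_roles",
    "node_roles",
]

ROLES = ("network_hub", "connector", "module_hub", "peripheral")

#: classic fixed thresholds sometimes used for binary pollination networks;
#: provided only as a preset -- the pipeline derives thresholds from nulls
OLESEN_THRESHOLDS = {
    "lower": ThresholdSet(level="lower", c_crit=0.62, z_crit=2.5, quantile=float("nan")),
    "higher": ThresholdSet(level="higher", c_crit=0.62, z_crit=2.5, quantile=float("nan")),
}


@dataclass(frozen=True)
class NodeRole:
    node_id: str
    level: str
    c: float
    z_wmd: float
    role: str


def _level_arrays(matrix: IncidenceMatrix, partition: ModulePartition, level: str):
    """(weights to partners, own module labels, partner module labels)."""
    if level == "lower":
        return matrix.A, partition.row_modules, partition.col_modules
    if level == "higher":
        return matrix.A.T, partition.col_modules, partition.row_modules
    raise ValueError(f"unknown level {level!r}")


def participation_coefficients(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    level: str = "lower",
    binary: bool = False,
) -> np.ndarray:
    """Participation coefficient of every node at one level (label order)."""
    W, _, partner_mod = _level_arrays(matrix, partition, level)
    W = (W > 0).astype(float) if binary else W
    labels = np.unique(np.concatenate([partition.row_modules, partition.col_modules]))
    ind = (partner_mod[None, :] == labels[:, None]).astype(float)  # (M, n_partner)
    k_it = W @ ind.T  # (n_nodes, M)
    k_i = k_it.sum(axis=1)
    if (k_i <= 0).any():
        isolated = np.flatnonzero(k_i <= 0)
        raise ValidationError(f"isolated node(s) at level {level}: indices {isolated.tolist()}")
    shares = k_it / k_i[:, None]
    return 1.0 - (shares**2).sum(axis=1)


def participation_coefficient(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    node_id: str,
    level: str = "lower",
    binary: bool = False,
) -> float:
    idx = matrix.row_index(node_id) if level == "lower" else matrix.col_index(node_id)
    return float(participation_coefficients(matrix, partition, level, binary)[idx])


def within_module_degrees(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    level: str = "lower",
    binary: bool = False,
) -> np.ndarray:
    """Standardized within-module degree of every node at one level.

    Standardization is over same-level nodes sharing the module (sample
    standard deviation); modules with a single same-level node or zero
    spread yield 0, so classification is total.
    """
    W, own_mod, partner_mod = _level_arrays(matrix, partition, level)
    W = (W > 0).astype(float) if binary else W
    n = W.shape[0]
    k_is = np.array([W[i, partner_mod == own_mod[i]].sum() for i in range(n)])
    z = np.zeros(n)
    for m in np.unique(own_mod):
        members = np.flatnonzero(own_mod == m)
        vals = k_is[members]
        if members.size < 2:
            logger.debug("module %d has a single %s-level node; z set to 0", m, level)
            continue
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            logger.debug("module %d has zero within-module spread at level %s; z set to 0", m, level)
            continue
        z[members] = (vals - vals.mean()) / sd
    return z


def within_module_degree(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    node_id: str,
    level: str = "lower",
    binary: bool = False,
) -> float:
    idx = matrix.row_index(node_id) if level == "lower" else matrix.col_index(node_id)
    return float(within_module_degrees(matrix, partition, level, binary)[idx])


def classify_roles(c: np.ndarray, z_wmd: np.ndarray, thresholds: ThresholdSet) -> list[str]:
    """Role label for each (c, z) pair; strict inequalities at the thresholds."""
    out = []
    for ci, zi in zip(np.asarray(c, dtype=float), np.asarray(z_wmd, dtype=float)):
        high_c = ci > thresholds.c_crit
        high_z = zi > thresholds.z_crit
        if high_c and high_z:
            out.append("network_hub")
        elif high_c:
            out.append("connector")
        elif high_z:
            out.append("module_hub")
        else:
            out.append("peripheral")
    return out


def node_roles(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    thresholds: dict[str, ThresholdSet],
    binary: bool = False,
) -> list[NodeRole]:
    """Compute (c, z) and classify every node of both levels."""
    results: list[NodeRole] = []
    for level, labels in (("lower", matrix.row_labels), ("higher", matrix.col_labels)):
        c = participation_coefficients(matrix, partition, level, binary)
        z = within_module_degrees(matrix, partition, level, binary)
        roles = classify_roles(c, z, thresholds[level])
        results.extend(
            NodeRole(lab, level, float(ci), float(zi), r)
            for lab, ci, zi, r in zip(labels, c, z, roles)
        )
    return results
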
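"""Marginal- and connectance-preserving null models and derived thresholds.

Each randomized network keeps the observed row totals (site activity),
column totals (species abundance), grand total and number of realized links,
while shuffling which site-species pairs interact and how strongly.  Cells
are selected with probability proportional to (K_i/F)(L_j/F): first so that
every row and column receives a link, then up to the observed link count;
one interaction unit goes on each selected cell and the remaining units are
placed one at a time with the same probabilities, rejecting placements that
would overshoot a marginal total.  When placement stalls (remaining units
but every candidate row or column saturated) bounded swap moves rebalance
units between rows within a column; if the draw still cannot satisfy the
contract it is regenerated from scratch.  Every returned matrix satisfies
the marginal and link-count invariants exactly.

The null ensemble supplies (i) the Q distribution that converts observed
modularity into a z-score and (ii) pooled per-level distributions of
participation coefficient and within-module degree from which critical
thresholds for node-role classification are taken as an upper empirical
quantile (default 0.975, the upper limit of a central 95% interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import FAST_NULL_FACTOR, IncidenceMatrix, RunConfig, ValidationError
from .modularity import ModulePartition, optimize_modules

logger = logging.getLogger("polliscape")

__all__ = [
    "NullModelError",
    "NullEnsemble",
    "NullDistributions",
    "ThresholdSet",
    "vaznull_one",
    "null_ensemble",
    "null_distributions",
    "derive_thresholds",
]


class NullModelError(RuntimeError):
    """The randomization could not satisfy its constraints."""


@dataclass
class NullEnsemble:
    matrices: list[IncidenceMatrix]
    method: str = "vaznull"
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.matrices)


@dataclass(frozen=True)
class ThresholdSet:
    """Critical thresholds for one network level, from pooled null values."""

    level: str  # "lower" or "higher"
    c_crit: float
    z_crit: float
    quantile: float


@dataclass
class NullDistributions:
    """Pooled null distributions: Q per replicate, node c/z per level."""

    q_null: np.ndarray
    c_null: dict[str, np.ndarray]  # level -> pooled participation coefficients
    z_null: dict[str, np.ndarray]  # level -> pooled within-module degrees
    partitions: list[ModulePartition] = field(default_factory=list)
    c_by_replicate: list[dict[str, np.ndarray]] = field(default_factory=list)
    z_by_replicate: list[dict[str, np.ndarray]] = field(default_factory=list)


def _weighted_pick(rng: np.random.Generator, w: np.ndarray) -> int:
    """Index into flat weight array w (must have positive sum)."""
    c = np.cumsum(w)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def _vaznull_attempt(
    A: np.ndarray,
    K: np.ndarray,
    L: np.ndarray,
    links: int,
    rng: np.random.Generator,
    max_repair: int,
) -> np.ndarray | None:
    n, p = A.shape
    P = np.outer(K, L).astype(float)

    chosen = np.zeros((n, p), dtype=bool)
    row_cnt = np.zeros(n, dtype=int)
    col_cnt = np.zeros(p, dtype=int)

    # phase 1: cover every row and column (each accepted cell covers at least
    # one still-empty row or column, so this takes at most n + p draws)
    while (row_cnt == 0).any() or (col_cnt == 0).any():
        elig = (
            ~chosen
            & (row_cnt[:, None] < K[:, None])
            & (col_cnt[None, :] < L[None, :])
            & ((row_cnt[:, None] == 0) | (col_cnt[None, :] == 0))
        )
        w = (P * elig).ravel()
        if w.sum() <= 0:
            return None
        idx = _weighted_pick(rng, w)
        i, j = divmod(idx, p)
        chosen[i, j] = True
        row_cnt[i] += 1
        col_cnt[j] += 1
        if chosen.sum() > links:
            return None  # cannot cover within the observed link budget

    # phase 2: fill to the observed number of links
    while chosen.sum() < links:
        elig = ~chosen & (row_cnt[:, None] < K[:, None]) & (col_cnt[None, :] < L[None, :])
        w = (P * elig).ravel()
        if w.sum() <= 0:
            return None
        idx = _weighted_pick(rng, w)
        i, j = divmod(idx, p)
        chosen[i, j] = True
        row_cnt[i] += 1
        col_cnt[j] += 1

    # phase 3: one unit per link, then distribute the remainder
    X = chosen.astype(int)
    k_res = K - row_cnt  # remaining row capacity
    l_res = L - col_cnt
    remaining = int(K.sum()) - links
    repairs = 0
    while remaining > 0:
        elig = chosen & (k_res[:, None] > 0) & (l_res[None, :] > 0)
        if elig.any():
            w = (P * elig).ravel()
            idx = _weighted_pick(rng, w)
            i, j = divmod(idx, p)
            # place as many units as this cell can take in one go; the cell
            # was chosen proportionally, so this only shortcuts re-draws of
            # the same still-eligible cell
            take = 1
            X[i, j] += take
            k_res[i] -= take
            l_res[j] -= take
            remaining -= take
        else:
            # stall: every deficit row sees only saturated columns; move one
            # unit between rows within a column to open capacity
            if repairs >= max_repair:
                return None
            moved = False
            deficit_rows = np.flatnonzero(k_res > 0)
            for r in rng.permutation(deficit_rows):
                cols = np.flatnonzero(chosen[r])
                for j in rng.permutation(cols):
                    donors = np.flatnonzero(chosen[:, j] & (X[:, j] >= 2))
                    donors = donors[donors != r]
                    if donors.size:
                        i = int(donors[int(rng.integers(donors.size))])
                        X[i, j] -= 1
                        X[r, j] += 1
                        k_res[i] += 1
                        k_res[r] -= 1
                        repairs += 1
                        moved = True
                        break
                if moved:
                    break
            if not moved:
                return None

    ok = (
        np.array_equal(X.sum(axis=1), K)
        and np.array_equal(X.sum(axis=0), L)
        and int(np.count_nonzero(X)) == links
    )
    return X if ok else None


def vaznull_one(
    matrix: IncidenceMatrix,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> IncidenceMatrix:
    """One marginal- and connectance-preserving randomization of the matrix.

    Raises :class:`NullModelError` if no conforming draw is found within
    ``max_attempts`` regenerations (a Patefield-style r2dtable fallback,
    which relaxes the link-count constraint, would then be the usual way
    out, but is not part of this pipeline).
    """
    K = matrix.K
    L = matrix.L
    if not (np.allclose(K, np.round(K)) and np.allclose(L, np.round(L))):
        raise ValidationError("null model requires integer visit counts")
    Ki = np.round(K).astype(int)
    Li = np.round(L).astype(int)
    links = matrix.n_links
    max_repair = 10 * int(Ki.sum())
    for _ in range(max_attempts):
        X = _vaznull_attempt(matrix.A, Ki, Li, links, rng, max_repair)
        if X is not None:
            return matrix.with_weights(X.astype(float))
    raise NullModelError(
        f"no conforming randomization in {max_attempts} attempts; "
        "consider a Patefield (r2dtable) fallback"
    )


def null_ensemble(
    matrix: IncidenceMatrix, n: int, seed: int | None = 0
) -> NullEnsemble:
    rng = np.random.default_rng(seed)
    mats = [vaznull_one(matrix, rng) for _ in range(n)]
    return NullEnsemble(matrices=mats, method="vaznull", seed=seed)


def null_distributions(
    matrix: IncidenceMatrix, config: RunConfig
) -> NullDistributions:
    """Null distributions of Q and of node c/z values per network level.

    Runs the module search on each of ``config.n_null`` randomized matrices
    (with the reduced ``fast_null`` budget when configured, logged) and pools
    the node-level participation coefficients and within-module degrees
    across replicates and nodes, per level.
    """
    from . import roles as _roles  # deferred: roles imports ThresholdSet from here

    ss = np.random.SeedSequence(entropy=config.random_seed, spawn_key=(0x6E75,))
    children = ss.spawn(config.n_null)
    sa = config.null_sa_params()
    if config.fast_null:
        logger.info(
            "null module searches use the fast budget (x%.2f of the observed search)",
            FAST_NULL_FACTOR,
        )
    q_vals = []
    c_pool: dict[str, list[np.ndarray]] = {"lower": [], "higher": []}
    z_pool: dict[str, list[np.ndarray]] = {"lower": [], "higher": []}
    partitions = []
    for child in children:
        rng = np.random.default_rng(child)
        nmat = vaznull_one(matrix, rng)
        opt_seed = int(child.generate_state(1)[0] % (2**31))
        part = optimize_modules(nmat, sa_params=sa, seed=opt_seed)
        q_vals.append(part.q)
        partitions.append(part)
        for level in ("lower", "higher"):
            c_pool[level].append(
                _roles.participation_coefficients(nmat, part, level=level, binary=config.binary_roles)
            )
            z_pool[level].append(
                _roles.within_module_degrees(nmat, part, level=level, binary=config.binary_roles)
            )
    n_rep = len(q_vals)
    return NullDistributions(
        q_null=np.array(q_vals),
        c_null={lv: np.concatenate(c_pool[lv]) for lv in c_pool},
        z_null={lv: np.concatenate(z_pool[lv]) for lv in z_pool},
        partitions=partitions,
        c_by_replicate=[{lv: c_pool[lv][k] for lv in c_pool} for k in range(n_rep)],
        z_by_replicate=[{lv: z_pool[lv][k] for lv in z_pool} for k in range(n_rep)],
    )


def derive_thresholds(
    c_null: np.ndarray, z_null: np.ndarray, quantile: float, level: str
) -> ThresholdSet:
    """Empirical-quantile critical thresholds from pooled null node values.

    Type-7 (linear) interpolation, the convention of the reference
    statistical environment.
    """
    c_null = np.asarray(c_null, dtype=float)
    z_null = np.asarray(z_null, dtype=float)
    if c_null.size == 0 or z_null.size == 0:
        raise ValidationError("cannot derive thresholds from an empty null distribution")
    return ThresholdSet(
        level=level,
        c_crit=float(np.quantile(c_null, quantile, method="linear")),
        z_crit=float(np.quantile(z_null, quantile, method="linear")),
        quantile=quantile,
    )
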
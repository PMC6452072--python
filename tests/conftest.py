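"""Shared fixtures: toy matrices and small synthetic landscapes."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from polliscape.io import IncidenceMatrix, VisitationRecord, VisitationTable
from polliscape.synthetic import SyntheticConfig, generate_landscape


@pytest.fixture
def toy_matrix() -> IncidenceMatrix:
    """2x2 worked example: [[3, 1], [0, 2]], F = 6."""
    return IncidenceMatrix(np.array([[3.0, 1.0], [0.0, 2.0]]), ["s1", "s2"], ["p1", "p2"])


@pytest.fixture
def block_matrix() -> IncidenceMatrix:
    """Two perfectly separated site-species blocks (Q = 0.5 at the right split)."""
    return IncidenceMatrix(np.array([[4.0, 0.0], [0.0, 4.0]]), ["s1", "s2"], ["p1", "p2"])


def random_incidence(rng: np.random.Generator, n: int, p: int, hi: int = 4) -> IncidenceMatrix:
    """Random small integer matrix without zero margins."""
    while True:
        A = rng.integers(0, hi, size=(n, p)).astype(float)
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return IncidenceMatrix(
                A, [f"s{i}" for i in range(n)], [f"p{j}" for j in range(p)]
            )


@pytest.fixture(scope="session")
def small_landscape():
    """Two-land-use landscape with clean planted modules and its ground truth."""
    cfg = SyntheticConfig(
        n_sites_per_landuse={"forest": 5, "dairy": 5},
        pool_size_per_landuse={"forest": 8, "dairy": 8},
        shared_pool_size=0,
        overlap=0.0,
        specialist_fraction=0.0,
        visit_rate=60.0,
        seed=101,
    )
    return cfg, generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """Default 20-site, four-land-use landscape (the study-shaped conditions)."""
    cfg = SyntheticConfig(seed=2024)
    return cfg, generate_landscape(cfg)


def set_partitions(items: list):
    """All set partitions of ``items`` (exhaustive oracle helper)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def integer_compositions(total: int, caps: tuple[int, ...]):
    """All integer allocations of ``total`` over bins with per-bin caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for a in range(min(total, caps[0]) + 1):
        for rest in integer_compositions(total - a, caps[1:]):
            yield (a,) + rest
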
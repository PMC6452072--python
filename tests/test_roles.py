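"""Participation coefficient / within-module degree closed forms and roles."""

import numpy as np
import pytest

from polliscape.io import IncidenceMatrix
from polliscape.modularity import ModulePartition
from polliscape.nullmodels import ThresholdSet
from polliscape.roles import (
    classify_roles,
    node_roles,
    participation_coefficient,
    participation_coefficients,
    within_module_degree,
    within_module_degrees,
)

from conftest import random_incidence


def _partition(matrix, rm, cm):
    return ModulePartition(
        row_labels=list(matrix.row_labels),
        col_labels=list(matrix.col_labels),
        row_modules=np.asarray(rm),
        col_modules=np.asarray(cm),
        q=0.0,
    )


class TestParticipationCoefficient:
    def test_all_links_in_one_module_gives_zero(self, toy_matrix):
        part = _partition(toy_matrix, [0, 0], [0, 0])
        c = participation_coefficients(toy_matrix, part, "lower")
        assert np.allclose(c, 0.0)

    @pytest.mark.parametrize("n_mod", [2, 3, 4, 5, 6])
    def test_even_split_closed_form(self, n_mod):
        """A node spread evenly over M modules has c = 1 - 1/M."""
        A = np.vstack([np.ones(n_mod), np.ones(n_mod)])
        m = IncidenceMatrix(A, ["focal", "other"], [f"p{j}" for j in range(n_mod)])
        part = _partition(m, [0, 0], list(range(n_mod)))
        c = participation_coefficient(m, part, "focal", "lower")
        assert c == pytest.approx(1.0 - 1.0 / n_mod)

    def test_uneven_split(self):
        m = IncidenceMatrix(np.array([[3.0, 1.0]]), ["s"], ["p1", "p2"])
        part = _partition(m, [0], [0, 1])
        assert participation_coefficient(m, part, "s") == pytest.approx(1 - (0.75**2 + 0.25**2))

    def test_bounded_by_module_count(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = random_incidence(rng, 4, 5)
            rm = rng.integers(0, 3, 4)
            cm = rng.integers(0, 3, 5)
            part = _partition(m, rm, cm)
            n_mod = part.n_modules
            for lv in ("lower", "higher"):
                c = participation_coefficients(m, part, lv)
                assert np.all(c >= -1e-12)
                assert np.all(c <= 1 - 1.0 / n_mod + 1e-12)


class TestWithinModuleDegree:
    def test_equal_within_module_weights_give_zero(self):
        A = np.full((3, 2), 2.0)
        m = IncidenceMatrix(A, ["a", "b", "c"], ["x", "y"])
        part = _partition(m, [0, 0, 0], [0, 0])
        assert np.allclose(within_module_degrees(m, part, "lower"), 0.0)

    def test_weights_2_4_6_standardize_to_unit_steps(self):
        """Module weights {2, 4, 6} give z = {-1, 0, 1} (sample sd = 2)."""
        A = np.array([[2.0], [4.0], [6.0]])
        m = IncidenceMatrix(A, ["a", "b", "c"], ["x"])
        part = _partition(m, [0, 0, 0], [0])
        z = within_module_degrees(m, part, "lower")
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_singleton_module_node_gets_zero(self):
        A = np.array([[2.0, 0.0], [0.0, 3.0], [0.0, 1.0]])
        m = IncidenceMatrix(A, ["lone", "b", "c"], ["x", "y"])
        part = _partition(m, [0, 1, 1], [0, 1])
        z = within_module_degrees(m, part, "lower")
        assert z[0] == 0.0  # module 0 has a single site

    def test_scalar_accessor_matches_vector(self, toy_matrix):
        part = _partition(toy_matrix, [0, 1], [0, 1])
        z_all = within_module_degrees(toy_matrix, part, "lower")
        assert within_module_degree(toy_matrix, part, "s2", "lower") == z_all[1]


class TestBinaryReduction:
    def test_weighted_equals_classic_binary_on_01_matrices(self):
        """On a 0/1 matrix the weighted c and z reduce to the classic
        degree-based definitions (checked against a direct implementation)."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            A = (rng.random((5, 6)) < 0.6).astype(float)
            A[A.sum(1) == 0, 0] = 1
            A = A[:, A.sum(0) > 0]
            if A.shape[1] < 2:
                continue
            m = IncidenceMatrix(A, [f"s{i}" for i in range(A.shape[0])],
                                [f"p{j}" for j in range(A.shape[1])])
            rm = rng.integers(0, 2, m.n_rows)
            cm = rng.integers(0, 2, m.n_cols)
            part = _partition(m, rm, cm)

            # direct binary Guimera-Amaral style computation
            for i in range(m.n_rows):
                k_it = [A[i, cm == t].sum() for t in np.unique(np.r_[rm, cm])]
                k_i = A[i].sum()
                c_direct = 1 - sum((k / k_i) ** 2 for k in k_it)
                c_pkg = participation_coefficients(m, part, "lower")[i]
                assert c_pkg == pytest.approx(c_direct)
            k_is = np.array([A[i, cm == rm[i]].sum() for i in range(m.n_rows)])
            z_pkg = within_module_degrees(m, part, "lower")
            for t in np.unique(rm):
                sel = rm == t
                if sel.sum() < 2 or np.std(k_is[sel], ddof=1) == 0:
                    assert np.allclose(z_pkg[sel], 0.0)
                else:
                    mu, sd = k_is[sel].mean(), np.std(k_is[sel], ddof=1)
                    assert np.allclose(z_pkg[sel], (k_is[sel] - mu) / sd)


SITE_THRESH = ThresholdSet(level="lower", c_crit=0.60, z_crit=1.88, quantile=0.975)


class TestClassification:
    @pytest.mark.parametrize(
        "c,z,expected",
        [
            (0.7, 2.0, "network_hub"),
            (0.0, 0.0, "peripheral"),
            (0.62, 1.0, "connector"),
            (0.3, 2.5, "module_hub"),
            (0.60, 1.88, "peripheral"),  # strict inequalities at thresholds
            (0.60001, 1.88, "connector"),
        ],
    )
    def test_role_quadrants(self, c, z, expected):
        assert classify_roles([c], [z], SITE_THRESH) == [expected]

    def test_every_node_gets_exactly_one_role(self):
        rng = np.random.default_rng(1)
        m = random_incidence(rng, 4, 6)
        part = _partition(m, rng.integers(0, 2, 4), rng.integers(0, 2, 6))
        thresholds = {"lower": SITE_THRESH,
                      "higher": ThresholdSet("higher", 0.57, 3.12, 0.975)}
        roles = node_roles(m, part, thresholds)
        assert len(roles) == m.n_rows + m.n_cols
        assert {r.node_id for r in roles} == set(m.row_labels) | set(m.col_labels)
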
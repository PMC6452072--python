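"""d' specialization against a brute-force allocation oracle; node strength."""

import numpy as np
import pytest

from polliscape.io import IncidenceMatrix
from polliscape.specialization import dprime, dprime_all, node_strength

from conftest import integer_compositions, random_incidence


def oracle_dprime(A: np.ndarray, i: int) -> tuple[float, float, float]:
    """Independent d' for row i: enumerated d_max, proportional-baseline d_min.

    d_max enumerates every availability-capped integer allocation of the row
    total; d_min re-implements the largest-remainder proportional baseline
    from scratch.
    """
    L = A.sum(axis=0)
    F = A.sum()
    q = L / F
    K = int(A[i].sum())

    def kl(alloc):
        p = np.asarray(alloc, dtype=float) / K
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))

    d_raw = kl(A[i])
    caps = tuple(int(min(l, K)) for l in L)
    d_max = max(kl(c) for c in integer_compositions(K, caps))
    # largest-remainder baseline
    target = K * q
    base = np.floor(target).astype(int)
    frac = target - base
    order = np.lexsort((np.arange(len(q)), -q, -frac))
    base[order[: K - base.sum()]] += 1
    d_min = min(kl(base), d_raw)
    d_prime = (d_raw - d_min) / (d_max - d_min) if d_max > d_min else 0.0
    return d_raw, d_max, d_prime


class TestDprime:
    def test_exclusive_partner_site_is_maximally_specialized(self):
        """A site whose visitors occur nowhere else has d' = 1 exactly."""
        # focal site: 3 exclusive species, 2 visits each; five other sites
        # share 4 common, abundant species
        rng = np.random.default_rng(7)
        common = rng.integers(15, 30, size=(5, 4)).astype(float)
        A = np.zeros((6, 7))
        A[0, :3] = 2.0
        A[1:, 3:] = common
        m = IncidenceMatrix(A, [f"s{i}" for i in range(6)], [f"p{j}" for j in range(7)])
        res = dprime(m, "s0", "lower")
        assert res.d_prime == 1.0
        assert res.d_max == pytest.approx(res.d_raw)

    def test_single_column_means_no_discrimination(self):
        m = IncidenceMatrix(np.array([[3.0], [5.0]]), ["s1", "s2"], ["p1"])
        for r in dprime_all(m, "lower"):
            assert r.d_raw == 0.0
            assert r.d_prime == 0.0

    def test_worked_2x2_against_oracle(self, toy_matrix):
        d_raw, d_max, d_prime = oracle_dprime(toy_matrix.A, 0)
        res = dprime(toy_matrix, "s1", "lower")
        assert res.d_raw == pytest.approx(d_raw)
        assert res.d_max == pytest.approx(d_max)
        assert res.d_prime == pytest.approx(d_prime)

    def test_matches_oracle_on_small_matrices(self):
        """d' equals the exhaustive-allocation oracle when row totals <= 8."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            m = random_incidence(rng, int(rng.integers(2, 4)), int(rng.integers(2, 5)), hi=4)
            for i, lab in enumerate(m.row_labels):
                if m.K[i] > 8:
                    continue
                d_raw, d_max, d_prime = oracle_dprime(m.A, i)
                res = dprime(m, lab, "lower")
                assert res.d_raw == pytest.approx(d_raw, abs=1e-12)
                assert res.d_max == pytest.approx(d_max, abs=1e-12)
                assert res.d_prime == pytest.approx(d_prime, abs=1e-10)
                assert 0.0 <= res.d_prime <= 1.0
                checked += 1

    def test_higher_level_is_transpose(self, toy_matrix):
        res = dprime(toy_matrix, "p1", "higher")
        d_raw, d_max, d_prime = oracle_dprime(toy_matrix.A.T, 0)
        assert res.d_raw == pytest.approx(d_raw)
        assert res.d_prime == pytest.approx(d_prime)

    def test_d_raw_invariant_to_integer_scaling(self):
        rng = np.random.default_rng(3)
        m = random_incidence(rng, 3, 4)
        m3 = IncidenceMatrix(m.A * 3.0, m.row_labels, m.col_labels)
        for lab in m.row_labels:
            assert dprime(m, lab).d_raw == pytest.approx(dprime(m3, lab).d_raw)

    def test_concentration_raises_specialization(self):
        """Shifting a node's visits onto its rarest partner raises d'.

        Two large background rows pin the availabilities q_j nearly constant
        while the focal row moves weight from its commonest to its rarest
        partner one visit at a time.
        """
        base = np.array([[200.0, 100.0, 20.0], [100.0, 200.0, 30.0]])
        prev = -1.0
        for k in range(9):
            row = np.array([8.0 - k, 4.0, 2.0 + k])  # shift toward rarest column
            A = np.vstack([row, base])
            m = IncidenceMatrix(A, ["focal", "b1", "b2"], ["c1", "c2", "c3"])
            cur = dprime(m, "focal").d_prime
            assert cur >= prev - 1e-9
            prev = cur

    def test_unconstrained_dmax_upper_bounds_capped(self):
        rng = np.random.default_rng(5)
        m = random_incidence(rng, 3, 4)
        for lab in m.row_labels:
            capped = dprime(m, lab, dmax_unconstrained=False)
            free = dprime(m, lab, dmax_unconstrained=True)
            assert free.d_max >= capped.d_max - 1e-12
            assert free.d_prime <= 1.0


class TestNodeStrength:
    def test_sole_species_carries_all_sites(self):
        A = np.ones((20, 1)) * 3.0
        m = IncidenceMatrix(A, [f"s{i}" for i in range(20)], ["p1"])
        (res,) = node_strength(m, "higher")
        assert res.strength == pytest.approx(20.0)

    def test_worked_example(self, toy_matrix):
        by_id = {r.node_id: r.strength for r in node_strength(toy_matrix, "higher")}
        assert by_id == {"p1": pytest.approx(0.75), "p2": pytest.approx(1.25)}

    def test_strength_conservation_both_levels(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_incidence(rng, int(rng.integers(2, 6)), int(rng.integers(2, 7)))
            sp = sum(r.strength for r in node_strength(m, "higher"))
            si = sum(r.strength for r in node_strength(m, "lower"))
            assert sp == pytest.approx(m.n_rows)
            assert si == pytest.approx(m.n_cols)
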
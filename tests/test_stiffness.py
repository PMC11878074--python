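"""Stiffness parameters: closed-form identities and brute-force oracles."""

import numpy as np
import pytest

from stiffnet import (
    CooccurrenceNetwork,
    NodeAttribute,
    StiffnessConfig,
    compute_displacement,
    compute_force,
    compute_impact,
    compute_perturbation_matrix,
    compute_profile,
    compute_stability,
    compute_stiffness_scale,
)

from conftest import random_signed_network


def make_net(W, A=None):
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if A is None:
        A = (W != 0).astype(int)
        np.fill_diagonal(A, 0)
    sign = A.copy()
    return CooccurrenceNetwork(taxa=[f"t{i}" for i in range(n)],
                               W=W, sign=sign, A=A)


def attr(x_a, x_b):
    n = len(x_a)
    return NodeAttribute(taxa=[f"t{i}" for i in range(n)],
                         x_a=np.asarray(x_a, float),
                         x_b=np.asarray(x_b, float))


class TestForce:
    def test_row_sums(self):
        net = make_net([[1, 0.5], [0.5, 1]])
        f = compute_force(net, np.array([1.0, 1.0]))
        assert np.allclose(f, [1.5, 1.5])

    def test_zero_displacement_zero_force(self, rng):
        net = random_signed_network(rng, 6)
        assert np.allclose(compute_force(net, np.zeros(6)), 0.0)

    def test_linearity_in_displacement(self, rng):
        net = random_signed_network(rng, 7)
        d = rng.normal(size=7)
        assert np.allclose(compute_force(net, 3.5 * d),
                           3.5 * compute_force(net, d))

    def test_unit_displacement_on_unweighted_net_gives_degrees(self):
        """Applying unit displacements to a hollow 0/1 network yields the
        degree vector as force (and conversely the degree vector as force
        causes unit displacements)."""
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        net = CooccurrenceNetwork.from_adjacency(["a", "b", "c"], A)
        f = compute_force(net, np.ones(3))
        assert np.allclose(f, [1, 2, 1])


class TestDisplacement:
    def test_identity_matrix(self):
        net = make_net(np.eye(2))
        d, reg = compute_displacement(net, np.array([3.0, 7.0]))
        assert np.allclose(d, [3, 7]) and not reg

    def test_diagonal_solve(self):
        W = np.diag([2.0, 4.0])
        net = CooccurrenceNetwork(taxa=["a", "b"], W=np.eye(2),
                                  sign=np.zeros((2, 2), int),
                                  A=np.zeros((2, 2), int))
        net.W = W  # diagonal-only stiffness
        d, _ = compute_displacement(net, np.array([2.0, 4.0]))
        assert np.allclose(d, [1, 1])

    def test_force_displacement_round_trip(self, rng):
        """W d0 -> f -> solve recovers d0 on well-conditioned instances."""
        for _ in range(20):
            net = random_signed_network(rng, 8)
            if np.linalg.cond(net.effective_weights) > 1e6:
                continue
            d0 = rng.normal(size=8)
            f = compute_force(net, d0)
            d, reg = compute_displacement(net, f)
            assert not reg
            assert np.allclose(d, d0, atol=1e-8)

    def test_singular_matrix_flagged_regularized(self):
        W = np.ones((3, 3))
        A = np.ones((3, 3), int) - np.eye(3, dtype=int)
        net = make_net(W, A)
        d, reg = compute_displacement(net, np.array([1.0, 1.0, 1.0]))
        assert reg
        assert np.all(np.isfinite(d))


class TestStiffnessScale:
    def test_hand_arithmetic(self):
        net = make_net([[1, 1], [1, 2]])
        s, defined = compute_stiffness_scale(net, np.array([2.0, 3.0]),
                                             np.array([1.0, 1.0]))
        assert np.allclose(s, [1, 1]) and defined.all()
        assert np.allclose(np.diag(s) @ net.effective_weights
                           @ np.array([1.0, 1.0]), [2, 3])

    def test_zero_x_gives_zero_scale(self, rng):
        net = random_signed_network(rng, 5)
        y = rng.uniform(0.5, 1, 5)
        s, defined = compute_stiffness_scale(net, np.zeros(5), y)
        assert np.allclose(s[defined], 0.0)

    def test_defining_identity_holds(self, rng):
        """diag(s) W y = x to 1e-10 wherever s is defined."""
        for _ in range(10):
            net = random_signed_network(rng, 6)
            x = rng.uniform(0.1, 2, 6)
            y = rng.uniform(0.1, 2, 6)
            s, defined = compute_stiffness_scale(net, x, y)
            lhs = np.diag(np.nan_to_num(s)) @ net.effective_weights @ y
            assert np.allclose(lhs[defined], x[defined], atol=1e-10)

    def test_zero_denominator_masked(self):
        net = make_net([[1, -1], [-1, 1]])
        # row sums of W*y vanish for y = [1, 1]
        s, defined = compute_stiffness_scale(net, np.array([1.0, 1.0]),
                                             np.array([1.0, 1.0]))
        assert not defined.any()
        assert np.isnan(s).all()


class TestPerturbationMatrix:
    def test_proportional_change_gives_unit_ratios(self):
        P = compute_perturbation_matrix(attr([1, 2], [2, 4]))
        assert np.allclose(P.G[P.defined_mask], 1.0)

    def test_zero_change_column_masked(self):
        P = compute_perturbation_matrix(attr([1, 2], [2, 2]))
        assert not P.defined_mask[:, 1].any()
        assert P.defined_mask[:, 0].all()

    def test_elementwise_oracle(self, rng):
        x_a = rng.uniform(0.1, 1, 5)
        x_b = rng.uniform(0.1, 1, 5)
        P = compute_perturbation_matrix(attr(x_a, x_b))
        r = (x_b - x_a) / x_a
        for i in range(5):
            for j in range(5):
                if abs(r[j]) > 1e-12:
                    assert P.defined_mask[i, j]
                    assert P.G[i, j] == pytest.approx(abs(r[i] / r[j]))

    def test_reciprocal_symmetry(self, rng):
        x_a = rng.uniform(0.1, 1, 6)
        x_b = rng.uniform(0.1, 1, 6)
        P = compute_perturbation_matrix(attr(x_a, x_b))
        both = P.defined_mask & P.defined_mask.T & (P.G > 0)
        prod = P.G[both] * P.G.T[both]
        assert np.allclose(prod, 1.0)


class TestImpactStability:
    def _ones_G(self, n):
        from stiffnet import PerturbationMatrix
        return PerturbationMatrix(taxa=[f"t{i}" for i in range(n)],
                                  G=np.ones((n, n)),
                                  defined_mask=np.ones((n, n), bool))

    def test_two_nodes_all_ones(self):
        net = make_net([[1, 0.5], [0.5, 1]])
        I, defined = compute_impact(net, self._ones_G(2))
        assert np.allclose(I, [1, 1]) and defined.all()

    def test_isolated_node_undefined(self):
        W = np.eye(3)
        W[0, 1] = W[1, 0] = 0.5
        net = make_net(W)
        I, defined = compute_impact(net, self._ones_G(3))
        assert not defined[2] and np.isnan(I[2])

    def test_impact_with_unit_G_is_degree(self, rng):
        net = random_signed_network(rng, 8)
        I, defined = compute_impact(net, self._ones_G(8))
        deg = net.degree()
        assert np.allclose(I[defined], deg[defined])
        assert np.array_equal(defined, deg > 0)

    def test_star_center_stability_quarter(self):
        A = np.zeros((5, 5), int)
        A[0, 1:] = A[1:, 0] = 1
        net = CooccurrenceNetwork.from_adjacency(
            [f"t{i}" for i in range(5)], A, unit_diagonal=True)
        S, defined = compute_stability(net, self._ones_G(5))
        assert S[0] == pytest.approx(0.25)

    def test_single_neighbor_g2_gives_half(self):
        from stiffnet import PerturbationMatrix
        net = make_net([[1, 0.5], [0.5, 1]])
        G = np.full((2, 2), 2.0)
        P = PerturbationMatrix(taxa=net.taxa, G=G,
                               defined_mask=np.ones((2, 2), bool))
        S, _ = compute_stability(net, P)
        assert S[0] == pytest.approx(0.5)

    def test_impact_stability_brute_force_oracle(self, rng):
        """Random masked instances match independent double loops."""
        from stiffnet import PerturbationMatrix
        for _ in range(20):
            n = int(rng.integers(3, 9))
            net = random_signed_network(rng, n)
            G = rng.uniform(0.1, 3.0, (n, n))
            mask = rng.random((n, n)) < 0.8
            P = PerturbationMatrix(taxa=net.taxa, G=np.where(mask, G, np.nan),
                                   defined_mask=mask)
            I, I_def = compute_impact(net, P)
            S, S_def = compute_stability(net, P)
            for i in range(n):
                ti = [G[j, i] for j in range(n)
                      if net.A[i, j] == 1 and mask[j, i]]
                if ti:
                    assert I_def[i] and I[i] == pytest.approx(sum(ti))
                else:
                    assert not I_def[i]
                si = [G[i, j] for j in range(n)
                      if net.A[i, j] == 1 and mask[i, j]]
                if si and sum(si) > 1e-12:
                    assert S_def[i] and S[i] == pytest.approx(1 / sum(si))
                else:
                    assert not S_def[i]


class TestProfile:
    def test_no_displacement_everything_undefined(self):
        net = make_net(np.eye(3))
        x = np.array([0.2, 0.3, 0.5])
        p = compute_profile(net, attr(x, x))
        assert np.allclose(p.force, 0)
        assert np.allclose(p.displacement, 0)
        assert not p.impact_defined.any()
        assert not p.stability_defined.any()

    def test_columns_match_standalone_operations(self, rng):
        net = random_signed_network(rng, 10)
        x_a = rng.uniform(0.05, 0.2, 10)
        x_b = rng.uniform(0.05, 0.2, 10)
        a = attr(x_a, x_b)
        p = compute_profile(net, a)
        f = compute_force(net, x_b - x_a)
        assert np.allclose(p.force, f)
        d, _ = compute_displacement(net, f)
        assert np.allclose(p.displacement, d)
        s, s_def = compute_stiffness_scale(net, x_b, x_a)
        assert np.allclose(p.stiffness_scale[s_def], s[s_def])
        P = compute_perturbation_matrix(a)
        I, _ = compute_impact(net, P)
        S, _ = compute_stability(net, P)
        assert np.allclose(p.impact[p.impact_defined], I[p.impact_defined])
        assert np.allclose(p.stability[p.stability_defined],
                           S[p.stability_defined])

    def test_unweighted_chain_degree_force(self):
        """Unit attribute change on a hollow 3-chain gives the degree
        vector as force."""
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        net = CooccurrenceNetwork.from_adjacency(["t0", "t1", "t2"], A)
        p = compute_profile(net, attr([0, 0, 0], [1, 1, 1]))
        assert np.allclose(p.force, [1, 2, 1])

    def test_relabeling_invariance(self, rng):
        """All five parameters commute with a simultaneous permutation
        of the taxa."""
        n = 8
        net = random_signed_network(rng, n)
        x_a = rng.uniform(0.05, 0.3, n)
        x_b = rng.uniform(0.05, 0.3, n)
        p = compute_profile(net, attr(x_a, x_b))
        perm = rng.permutation(n)
        net_p = CooccurrenceNetwork(
            taxa=[net.taxa[i] for i in perm],
            W=net.W[np.ix_(perm, perm)],
            sign=net.sign[np.ix_(perm, perm)],
            A=net.A[np.ix_(perm, perm)])
        a_p = NodeAttribute(taxa=net_p.taxa, x_a=x_a[perm], x_b=x_b[perm])
        p_p = compute_profile(net_p, a_p)
        for name in ("force", "stiffness_scale", "impact", "stability"):
            v, vp = getattr(p, name), getattr(p_p, name)
            assert np.allclose(v[perm], vp, equal_nan=True)
        if not p.regularized and not p_p.regularized:
            assert np.allclose(p.displacement[perm], p_p.displacement,
                               atol=1e-8)
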
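import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genespin import (CLASSICAL, GENE, ModelParams, Network, SpinConfiguration,
                      delta_energy, generate_ba_network, hamiltonian, map_spins,
                      map_to_classical, order_parameter)
from genespin.errors import ConventionError, DimensionError, InvalidParameterError
from genespin.spin_model import load_spins, save_spins


def cfg(states, convention=GENE):
    return SpinConfiguration(np.asarray(states, dtype=np.int8), convention)


class TestHamiltonian:
    def test_triangle_all_active(self, triangle):
        p = ModelParams(J=1, h=0, T=1)
        assert hamiltonian(cfg([1, 1, 1]), triangle, p) == -3.0

    def test_all_inactive_is_zero_energy(self, ba_small):
        p = ModelParams(J=2.7, h=-1.3, T=1)
        assert hamiltonian(cfg([0] * 10), ba_small, p) == 0.0

    def test_single_edge_field_term(self, single_edge):
        p = ModelParams(J=2, h=1, T=1)
        assert hamiltonian(cfg([1, 0]), single_edge, p) == -1.0

    def test_classical_convention(self, single_edge):
        p = ModelParams(J=1, h=0, T=1)
        assert hamiltonian(cfg([1, 1], CLASSICAL), single_edge, p) == -1.0
        assert hamiltonian(cfg([1, -1], CLASSICAL), single_edge, p) == 1.0

    def test_length_mismatch_raises(self, triangle):
        with pytest.raises(DimensionError):
            hamiltonian(cfg([1, 0]), triangle, ModelParams(J=1, h=0, T=1))

    def test_additive_over_disconnected_components(self, rng):
        """At h = 0 the energy of a disjoint union is the sum of the parts."""
        a = Network(3, [(0, 1), (1, 2), (0, 2)])
        b = Network(4, [(0, 1), (2, 3)])
        union = Network(7, [(0, 1), (1, 2), (0, 2), (3, 4), (5, 6)])
        p = ModelParams(J=-1.7, h=0, T=1)
        for _ in range(20):
            sa = rng.integers(0, 2, 3).astype(np.int8)
            sb = rng.integers(0, 2, 4).astype(np.int8)
            total = hamiltonian(cfg(np.concatenate([sa, sb])), union, p)
            assert total == pytest.approx(
                hamiltonian(cfg(sa), a, p) + hamiltonian(cfg(sb), b, p))


class TestOrderParameter:
    @pytest.mark.parametrize("states, expected", [
        ([1, 1, 1, 1, 1], 1.0),
        ([0, 0, 0, 0], 0.0),
        ([1, 0, 1, 0], 0.5),
    ])
    def test_gene_examples(self, states, expected):
        assert order_parameter(cfg(states)) == expected

    def test_bounds(self, rng):
        g = SpinConfiguration.random(50, rng, GENE)
        c = SpinConfiguration.random(50, rng, CLASSICAL)
        assert 0.0 <= order_parameter(g) <= 1.0
        assert -1.0 <= order_parameter(c) <= 1.0

    def test_empty_raises(self):
        with pytest.raises(InvalidParameterError):
            order_parameter(cfg([]))


def _random_graph(rng, n):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keep = rng.random(len(pairs)) < 0.4
    return Network(n, [e for e, k in zip(pairs, keep) if k])


class TestDeltaEnergy:
    def test_isolated_node_gains_field_energy(self):
        net = Network(2, [])
        p = ModelParams(J=1, h=2, T=1)
        assert delta_energy(cfg([0, 0]), net, p, 0) == -2.0

    def test_triangle_activation(self, triangle):
        p = ModelParams(J=1, h=0, T=1)
        assert delta_energy(cfg([1, 1, 0]), triangle, p, 2) == -2.0

    def test_flip_twice_sums_to_zero(self, ba_small, rng):
        p = ModelParams(J=1.3, h=-0.4, T=1)
        s = SpinConfiguration.random(10, rng)
        d1 = delta_energy(s, ba_small, p, 4)
        flipped = s.copy()
        flipped.states[4] = 1 - flipped.states[4]
        d2 = delta_energy(flipped, ba_small, p, 4)
        assert d1 + d2 == pytest.approx(0.0)

    def test_invalid_node_raises(self, triangle):
        with pytest.raises(IndexError):
            delta_energy(cfg([1, 1, 0]), triangle, ModelParams(J=1, h=0, T=1), 7)

    @given(seed=st.integers(0, 10**6))
    def test_matches_hamiltonian_difference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        net = _random_graph(rng, n)
        p = ModelParams(J=float(rng.normal()), h=float(rng.normal()), T=1.0)
        for convention in (GENE, CLASSICAL):
            s = SpinConfiguration.random(n, rng, convention)
            i = int(rng.integers(0, n))
            flipped = s.copy()
            if convention == GENE:
                flipped.states[i] = 1 - flipped.states[i]
            else:
                flipped.states[i] = -flipped.states[i]
            exact = hamiltonian(flipped, net, p) - hamiltonian(s, net, p)
            fast = delta_energy(s, net, p, i)
            assert fast == pytest.approx(exact, rel=1e-10, abs=1e-10)

    def test_thousand_random_triples(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 10))
            net = _random_graph(rng, n)
            p = ModelParams(J=float(rng.normal()), h=float(rng.normal()), T=1.0)
            s = SpinConfiguration.random(n, rng)
            i = int(rng.integers(0, n))
            flipped = s.copy()
            flipped.states[i] = 1 - flipped.states[i]
            exact = hamiltonian(flipped, net, p) - hamiltonian(s, net, p)
            assert delta_energy(s, net, p, i) == pytest.approx(
                exact, rel=1e-10, abs=1e-10)


class TestMapping:
    @pytest.mark.parametrize("gene, classical", [
        ([0], [-1]),
        ([1], [1]),
        ([0, 1, 0], [-1, 1, -1]),
    ])
    def test_map_spins_elementwise(self, gene, classical):
        assert list(map_spins(cfg(gene)).states) == classical

    def test_map_spins_requires_gene_convention(self):
        with pytest.raises(ConventionError):
            map_spins(cfg([1, -1], CLASSICAL))

    def test_quartered_coupling(self, ba_small):
        mapped = map_to_classical(ba_small, ModelParams(J=1, h=0, T=1))
        assert mapped.J_prime == 0.25

    def test_local_field_from_degree(self, path5):
        # middle node of the path has degree 2: h' = h/2 + (J/4) k
        mapped = map_to_classical(path5, ModelParams(J=1, h=0, T=1))
        assert mapped.h_prime[2] == pytest.approx(0.5)
        mapped2 = map_to_classical(path5, ModelParams(J=2, h=1, T=1))
        assert mapped2.h_prime[2] == pytest.approx(0.5 + 1.0)

    def test_energy_identity_on_random_configs(self, rng):
        """H_gene(s) = H_classical(s') + E0 for every configuration."""
        net = generate_ba_network(8, 2, seed=11)
        p = ModelParams(J=1.0, h=0.7, T=1.0)
        mapped = map_to_classical(net, p)
        for _ in range(50):
            s = SpinConfiguration.random(8, rng)
            lhs = hamiltonian(s, net, p)
            rhs = mapped.energy(map_spins(s)) + mapped.E0
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_zero_coupling_zero_field_constant_vanishes(self, triangle):
        mapped = map_to_classical(triangle, ModelParams(J=0, h=0, T=1))
        assert mapped.E0 == 0.0
        assert np.all(mapped.h_prime == 0.0)


class TestSerialization:
    def test_spin_round_trip(self, tmp_path, rng):
        s = SpinConfiguration.random(20, rng)
        path = tmp_path / "spins.txt"
        save_spins(s, path)
        back = load_spins(path)
        assert back.convention == GENE
        assert np.array_equal(back.states, s.states)

    def test_invalid_states_rejected(self):
        with pytest.raises(ConventionError):
            cfg([0, 2])
        with pytest.raises(ConventionError):
            cfg([0, 1], CLASSICAL)
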
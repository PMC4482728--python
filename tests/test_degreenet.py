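"""Degree distributions, network construction, rewiring and correlation
statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare

import assortlif as al
from assortlif.degreenet import (
    DegenerateCorrelationError,
    bin_kernel,
    pearson_literal_shifted,
)
from assortlif.workbench import build_toy_network


class TestTruncatedPowerlaw:
    def test_uniform_case(self):
        d = al.truncated_powerlaw(0.0, 10, 12)
        assert np.allclose(d.pmf, 1 / 3)
        assert list(d.degrees) == [10, 11, 12]

    def test_power_ratio(self):
        d = al.truncated_powerlaw(-2.0, 10, 500)
        i10 = np.searchsorted(d.degrees, 10)
        i20 = np.searchsorted(d.degrees, 20)
        assert d.pmf[i10] / d.pmf[i20] == pytest.approx(4.0)

    def test_point_mass(self):
        d = al.truncated_powerlaw(-2.0, 10, 10)
        assert d.pmf.tolist() == [1.0]
        assert al.degree_moments(d) == (10.0, 0.0)

    @pytest.mark.parametrize("kmin,kmax", [(0, 5), (10, 9), (-3, 4)])
    def test_invalid_support(self, kmin, kmax):
        with pytest.raises(ValueError):
            al.truncated_powerlaw(-2.0, kmin, kmax)

    @given(
        alpha=st.floats(-3.0, 0.5),
        kmin=st.integers(1, 50),
        span=st.integers(0, 200),
    )
    def test_pmf_normalized_and_powerlaw(self, alpha, kmin, span):
        d = al.truncated_powerlaw(alpha, kmin, kmin + span)
        assert abs(d.pmf.sum() - 1.0) < 1e-12
        assert np.allclose(d.pmf, d.Z * d.degrees.astype(float) ** alpha)


class TestSampling:
    def test_determinism_and_bounds(self, dist_a2):
        a = al.sample_degree_sequence(dist_a2, 500, 5)
        b = al.sample_degree_sequence(dist_a2, 500, 5)
        assert np.array_equal(a, b)
        assert a.min() >= 10 and a.max() <= 500

    def test_single_draw(self, dist_a2):
        k = al.sample_degree_sequence(dist_a2, 1, 0)
        assert k.shape == (1,) and 10 <= k[0] <= 500

    def test_goodness_of_fit(self):
        dist = al.truncated_powerlaw(-1.5, 5, 25)
        N = 200_000
        seq = al.sample_degree_sequence(dist, N, 11)
        obs = np.bincount(seq, minlength=26)[5:26]
        stat, pval = chisquare(obs, dist.pmf * N)
        assert pval > 1e-3


class TestConfigurationModel:
    def test_invariants_and_degree_shortfall(self, small_net):
        small_net.validate()
        # realized degrees never exceed targets and total in = total out
        assert small_net.in_degree.sum() == small_net.out_degree.sum()
        assert small_net.n_edges == small_net.in_degree.sum()

    def test_stub_accounting_without_collisions(self):
        # a 2-regular ring-capable sequence on many nodes: collisions are
        # rare, and every surviving node keeps in == out by construction
        seq = np.full(50, 2)
        net = al.configuration_model(seq, 3)
        assert net.in_degree.sum() == net.n_edges
        assert np.all(net.in_degree <= 2) and np.all(net.out_degree <= 2)

    def test_two_node_forced_collisions(self):
        net = al.configuration_model(np.array([1, 1]), 0)
        net.validate()  # self-loops/duplicates removed whatever the pairing
        assert net.n_edges in (0, 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            al.configuration_model(np.array([], dtype=int), 0)

    def test_independent_out_degrees_option(self):
        rng = np.random.default_rng(4)
        deg = rng.integers(1, 6, size=200)
        out = rng.permutation(deg)
        net = al.configuration_model(deg, 5, out_degree_sequence=out)
        net.validate()

    def test_delays_within_range(self, small_net):
        assert small_net.delay_ms.min() >= 0.0
        assert small_net.delay_ms.max() <= 6.0


class TestPearson:
    def test_perfectly_assortative_toy(self):
        net = build_toy_network("two-class-assortative")
        assert al.pearson_in_degree_correlation(net).p == pytest.approx(1.0)

    def test_perfectly_disassortative_toy(self):
        net = build_toy_network("two-class-disassortative")
        assert al.pearson_in_degree_correlation(net).p == pytest.approx(-1.0)

    def test_regular_network_degenerate(self):
        net = build_toy_network("ring")
        with pytest.raises(DegenerateCorrelationError):
            al.pearson_in_degree_correlation(net)

    def test_enumeration_oracle_hand_graph(self):
        # 6-node graph; brute-force evaluation of the correlation by
        # explicit summation over the edge list
        src = np.array([0, 1, 2, 3, 4, 5, 0, 2, 4, 1])
        tgt = np.array([1, 2, 3, 4, 5, 0, 3, 5, 1, 4])
        net = al.DirectedNetwork(6, src, tgt, np.ones(src.size))
        kin = np.bincount(tgt, minlength=6)
        xs = [kin[s] for s in src]
        ys = [kin[t] for t in tgt]
        E = len(xs)
        mx = sum(xs) / E
        my = sum(ys) / E
        cov = sum(x * y for x, y in zip(xs, ys)) / E - mx * my
        vx = sum(x * x for x in xs) / E - mx * mx
        vy = sum(y * y for y in ys) / E - my * my
        expected = cov / (vx * vy) ** 0.5
        assert al.pearson_in_degree_correlation(net).p == pytest.approx(
            expected, abs=1e-9
        )

    def test_matches_networkx(self, small_net):
        nx = pytest.importorskip("networkx")
        g = nx.DiGraph()
        g.add_nodes_from(range(small_net.N))
        g.add_edges_from(zip(small_net.src.tolist(), small_net.tgt.tolist()))
        expected = nx.degree_assortativity_coefficient(g, x="in", y="in")
        assert al.pearson_in_degree_correlation(small_net).p == pytest.approx(
            expected, abs=1e-9
        )

    def test_stats_distributions_normalized(self, small_net):
        st_ = al.pearson_in_degree_correlation(small_net)
        assert st_.e.sum() == pytest.approx(1.0)
        assert st_.Q_in.sum() == pytest.approx(1.0)
        assert st_.sigma_in_sq >= 0.0
        assert -1 - 1e-9 <= st_.p <= 1 + 1e-9

    def test_literal_shifted_diagnostic_overshoots_on_assortative(self):
        # the shifted-marginal variant is inconsistent: on a perfectly
        # assortative graph it exceeds 1, which is why the consistent
        # edge-sample estimator is the primary one
        net = build_toy_network("two-class-assortative")
        assert pearson_literal_shifted(net) > 1.0


class TestMetropolis:
    def test_degree_conservation_and_simplicity(self, small_net):
        before_in = small_net.in_degree.copy()
        before_out = small_net.out_degree.copy()
        net, _ = al.metropolis_rewire(
            small_net, "assortative", g=1.0, n_attempts=20 * small_net.n_edges,
            seed=9,
        )
        net.validate()
        assert np.array_equal(net.in_degree, before_in)
        assert np.array_equal(net.out_degree, before_out)
        assert net.n_edges == small_net.n_edges

    def test_p_trace_nondecreasing_at_g1(self, small_net):
        _, trace = al.metropolis_rewire(
            small_net, "assortative", g=1.0, n_attempts=20 * small_net.n_edges,
            seed=10,
        )
        assert np.all(np.diff(trace) >= -1e-12)

    def test_disassortative_decreases_p(self, small_net):
        _, trace = al.metropolis_rewire(
            small_net, "disassortative", g=1.0,
            n_attempts=20 * small_net.n_edges, seed=11,
        )
        assert trace[-1] < trace[0]

    def test_plateau_stops_early(self, small_net):
        net, trace = al.metropolis_rewire(
            small_net, "assortative", g=1.0,
            n_attempts=500 * small_net.n_edges, seed=12,
            plateau_tol=1e-3, plateau_window=10,
        )
        # saturation detected well before the attempt budget
        assert len(trace) < 500

    def test_g0_preserves_uncorrelated_state(self, small_net):
        p0 = al.pearson_in_degree_correlation(small_net).p
        net, trace = al.metropolis_rewire(
            small_net, "assortative", g=0.0,
            n_attempts=10 * small_net.n_edges, seed=13,
        )
        net.validate()
        assert abs(trace[-1] - p0) < 0.2  # random swaps keep p near 0

    def test_mode_validation(self, small_net):
        with pytest.raises(ValueError):
            al.metropolis_rewire(small_net, "sideways")
        with pytest.raises(ValueError):
            al.metropolis_rewire(small_net, "assortative", g=1.5)

    def test_too_few_edges(self):
        net = al.DirectedNetwork(3, np.array([0]), np.array([1]), np.ones(1))
        with pytest.raises(ValueError):
            al.metropolis_rewire(net, "assortative")


class TestJointDegree:
    def test_row_sums_equal_degree(self, small_net):
        kern = al.sample_joint_degree(small_net)
        assert np.allclose(kern.counts.sum(axis=1), kern.degrees, atol=1e-9)
        assert np.allclose(kern.f.sum(axis=1), 1.0, atol=1e-9)

    def test_hand5_manual_tally(self):
        net = build_toy_network("hand5")
        # in-degrees: node0=1, node1=3, node2=2, node3=1, node4=2
        # classes: k=1 {0,3}, k=2 {2,4}, k=3 {1}
        # tally of links into each class by origin in-degree k':
        #   k=1: (4,0) origin deg 2; (0,3) origin deg 1   -> E = [1, 1, 0]
        #   k=2: (1,2) d3, (3,2) d1, (1,4) d3, (2,4) d2   -> E = [1, 1, 2]
        #   k=3: (0,1) d1, (2,1) d2, (3,1) d1             -> E = [2, 1, 0]
        # N_kk' = E_kk' / n_k with n = [2, 2, 1]
        kern = al.sample_joint_degree(net)
        assert kern.degrees.tolist() == [1.0, 2.0, 3.0]
        manual = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 1.0], [2.0, 1.0, 0.0]])
        assert np.allclose(kern.counts, manual)
        assert np.allclose(kern.counts.sum(axis=1), [1, 2, 3])

    def test_assortative_toy_is_diagonal(self):
        net = build_toy_network("two-class-assortative")
        kern = al.sample_joint_degree(net)
        assert np.allclose(kern.f, np.eye(2))

    def test_weights_are_node_fractions(self, small_net):
        kern = al.sample_joint_degree(small_net)
        assert kern.weights.sum() == pytest.approx(1.0)


class TestAnalyticKernels:
    def test_uncorrelated_equal_inout_rows(self, dist_a2):
        kern = al.analytic_kernel(dist_a2, "uncorrelated_equal_inout")
        deg = dist_a2.degrees.astype(float)
        row = deg * dist_a2.pmf / np.sum(deg * dist_a2.pmf)
        assert np.allclose(kern.f, row[None, :])
        assert np.allclose(kern.f.sum(axis=1), 1.0)

    def test_independent_inout_rows(self, dist_a2):
        kern = al.analytic_kernel(dist_a2, "independent_inout")
        assert np.allclose(kern.f, dist_a2.pmf[None, :])

    def test_assortative_delta_counts(self, dist_a2):
        kern = al.analytic_kernel(dist_a2, "assortative_delta")
        assert np.allclose(np.diag(kern.counts), dist_a2.degrees)
        assert np.count_nonzero(kern.counts) == dist_a2.degrees.size

    def test_disassortative_partner_mapping(self, dist_a2):
        kern = al.analytic_kernel(dist_a2, "disassortative_delta")
        deg = kern.degrees
        # partner of the largest degree is the smallest and vice versa
        j = np.argmax(kern.f[np.searchsorted(deg, 500)])
        assert deg[j] == 10
        j = np.argmax(kern.f[np.searchsorted(deg, 10)])
        assert deg[j] == 500

    def test_unknown_kind(self, dist_a2):
        with pytest.raises(ValueError):
            al.analytic_kernel(dist_a2, "nope")


class TestKernelOps:
    def test_bin_kernel_preserves_row_identity(self, net_a2_10k):
        kern = al.sample_joint_degree(net_a2_10k)
        coarse = bin_kernel(kern, 40)
        assert coarse.degrees.size <= 40
        assert np.allclose(coarse.counts.sum(axis=1), coarse.degrees, atol=1e-9)
        assert coarse.weights.sum() == pytest.approx(1.0)
        # mean degree is conserved by the coarse-graining
        assert np.sum(coarse.weights * coarse.degrees) == pytest.approx(
            np.sum(kern.weights * kern.degrees)
        )

    def test_kernel_csv_roundtrip(self, tmp_path, dist_a2):
        kern = al.analytic_kernel(dist_a2, "uncorrelated_equal_inout")
        path = tmp_path / "kern.csv"
        kern.to_csv(path)
        back = al.ConnectionKernel.from_csv(path)
        assert np.allclose(back.degrees, kern.degrees)
        assert np.allclose(back.f, kern.f, atol=1e-12)

    def test_edgelist_roundtrip(self, tmp_path, small_net):
        path = tmp_path / "net.tsv"
        small_net.to_edgelist(path)
        back = al.DirectedNetwork.from_edgelist(path)
        assert back.N == small_net.N
        assert np.array_equal(back.src, small_net.src)
        assert np.array_equal(back.tgt, small_net.tgt)
        assert np.allclose(back.delay_ms, small_net.delay_ms, atol=1e-5)
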
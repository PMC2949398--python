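import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccanet import association as assoc
from ccanet.io_formats import ExpressionMatrix, GeneMetadata
from ccanet.network import CCANetwork
from ccanet.synthetic_data import simulate_expression

from .oracles import spearman_oracle


class TestRandomizationP:
    def test_minimum_p_formula(self):
        res = assoc.randomization_p(100.0, [0.0] * 5000, tail="ge")
        assert res.exceedances == 0
        assert res.p == pytest.approx(1 / 5001)
        assert round(res.p, 5) == round(2.0e-4, 5)

    def test_t_equals_r(self):
        res = assoc.randomization_p(0.0, [1.0] * 200, tail="ge")
        assert res.p == 1.0

    def test_t_49_r_5000(self):
        null = [1.0] * 49 + [-1.0] * 4951
        res = assoc.randomization_p(0.5, null, tail="ge")
        assert res.exceedances == 49
        assert res.p == pytest.approx(50 / 5001)

    def test_le_tail(self):
        res = assoc.randomization_p(0.0, [1, 2, 3, 0], tail="le")
        assert res.exceedances == 1
        assert res.p == pytest.approx(2 / 5)

    def test_empty_null_error(self):
        with pytest.raises(ValueError, match="empty"):
            assoc.randomization_p(1.0, [], tail="ge")

    @settings(max_examples=50, deadline=None)
    @given(
        observed=st.floats(-5, 5),
        null=st.lists(st.floats(-5, 5), min_size=1, max_size=100),
        tail=st.sampled_from(["ge", "le"]),
    )
    def test_p_bounds_always_hold(self, observed, null, tail):
        res = assoc.randomization_p(observed, null, tail=tail)
        assert 1 / (len(null) + 1) <= res.p <= 1.0

    def test_null_simulation_super_uniform(self):
        # observed drawn from the same distribution as the null: p must be
        # (super-)uniform at 10-bin resolution
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(2000):
            values = rng.standard_normal(100)
            ps.append(assoc.randomization_p(values[0], values[1:].tolist()).p)
        for q in np.arange(0.1, 1.0, 0.1):
            frac = np.mean([p <= q for p in ps])
            assert frac <= q + 3 * np.sqrt(q * (1 - q) / len(ps))


class TestADStatistic:
    def test_reference_frequencies(self):
        assert assoc.ad_statistic(0.9, 0.075) == pytest.approx(0.825)

    def test_identity(self):
        assert assoc.ad_statistic(0.3, 0.3) == 0.0

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_symmetry(self, a, b):
        assert assoc.ad_statistic(a, b) == assoc.ad_statistic(b, a)


def _planted_ad_network(seed):
    """Co edges join equal-frequency genes, anti edges divergent ones."""
    rng = np.random.default_rng(seed)
    net = CCANetwork()
    freqs = {}
    base = rng.uniform(0.2, 0.6, size=10)
    for i, f in enumerate(base):  # co pairs with nearly equal frequencies
        a, b = f"co{i}a", f"co{i}b"
        freqs[a] = float(f)
        freqs[b] = float(np.clip(f + rng.normal(0, 0.01), 0, 1))
        net.add_edge(a, b, relation="co")
    for i in range(5):  # anti pairs with divergent frequencies
        a, b = f"an{i}a", f"an{i}b"
        freqs[a] = float(rng.uniform(0.0, 0.1))
        freqs[b] = float(rng.uniform(0.75, 0.95))
        net.add_edge(a, b, relation="anti")
    return net, freqs


class TestADComparison:
    def test_planted_direction(self):
        net, freqs = _planted_ad_network(seed=0)
        out = assoc.ad_comparison(net, freqs, R=500, seed=1)
        co = out["co_vs_random"]
        anti = out["anti_vs_random"]
        assert co.observed < float(np.median(co.null_sample))
        assert anti.observed > float(np.median(anti.null_sample))
        assert out["co_vs_anti_p"] < 0.01

    def test_recovery_rate_over_seeds(self):
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            net, freqs = _planted_ad_network(seed)
            out = assoc.ad_comparison(net, freqs, R=60, seed=seed + 10_000)
            ok_co = out["co_vs_random"].observed < float(
                np.median(out["co_vs_random"].null_sample)
            )
            ok_anti = out["anti_vs_random"].observed > float(
                np.median(out["anti_vs_random"].null_sample)
            )
            wins += ok_co and ok_anti
        assert wins >= 0.95 * n_seeds

    def test_all_equal_frequencies_degenerate(self):
        net = CCANetwork()
        net.add_edge("a", "b", relation="co")
        net.add_edge("c", "d", relation="anti")
        freqs = {g: 0.5 for g in "abcd"}
        out = assoc.ad_comparison(net, freqs, R=50, seed=0)
        assert out["co_vs_anti_p"] == 1.0

    def test_no_anti_edges_branch_skipped(self):
        net = CCANetwork()
        net.add_edge("a", "b", relation="co")
        net.add_edge("b", "c", relation="co")
        freqs = {"a": 0.1, "b": 0.2, "c": 0.3}
        out = assoc.ad_comparison(net, freqs, R=50, seed=0)
        assert out["anti_vs_random"] is None
        assert any("anti" in n for n in out["notices"])


class TestExpressionSimilarity:
    @staticmethod
    def _expr(rows):
        genes = [f"g{i}" for i in range(len(rows))]
        tissues = [f"t{j}" for j in range(len(rows[0]))]
        return ExpressionMatrix(genes, tissues, np.array(rows, dtype=float))

    def test_identical_profiles(self):
        expr = self._expr([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert assoc.expression_similarity(expr, "g0", "g1") == pytest.approx(1.0)

    def test_opposite_profiles_absolute(self):
        expr = self._expr([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert assoc.expression_similarity(expr, "g0", "g1") == pytest.approx(1.0)

    def test_orthogonal_profiles_zero(self):
        expr = self._expr([[1, 2, 1, 2], [1, 1, 2, 2]])
        assert assoc.expression_similarity(expr, "g0", "g1") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_constant_profile_undefined(self):
        expr = self._expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        assert math.isnan(assoc.expression_similarity(expr, "g0", "g1"))


class TestDistanceSimilarity:
    @staticmethod
    def _path(n):
        net = CCANetwork()
        for i in range(n - 1):
            net.add_edge(f"g{i}", f"g{i + 1}", relation="co")
        return net

    def test_monotone_decreasing_gives_grouped_rho_minus_one(self):
        net = self._path(5)
        # hand-build profiles whose similarity strictly decreases in distance
        expr = simulate_expression(net, 0.5, 40, noise_sd=0.0, seed=0)
        # noiseless decay: |r|=1 everywhere; perturb with distance-dependent noise
        rng = np.random.default_rng(1)
        values = expr.values.copy()
        for i in range(len(expr.genes)):
            values[i] += rng.standard_normal(40) * (0.3 * i)
        expr = ExpressionMatrix(expr.genes, expr.tissues, values)
        out = assoc.distance_similarity_analysis(net, expr)
        if out["grouped_rho"] is not None:
            assert out["grouped_rho"] < 0

    def test_independent_similarity_rho_near_zero(self):
        net = self._path(30)
        rng = np.random.default_rng(5)
        expr = ExpressionMatrix(
            sorted(net.nodes()), [f"t{j}" for j in range(20)],
            rng.standard_normal((30, 20)),
        )
        out = assoc.distance_similarity_analysis(net, expr)
        assert abs(out["pairwise_rho"]) < 3 / np.sqrt(out["n_pairs"])

    def test_decay_generator_negative_pairwise_rho(self):
        net = self._path(8)
        expr = simulate_expression(net, 0.6, 79, noise_sd=0.8, seed=4)
        out = assoc.distance_similarity_analysis(net, expr)
        assert out["pairwise_rho"] < 0

    def test_infinite_distances_excluded(self):
        net = self._path(3)
        net.add_edge("x", "y", relation="co")  # disjoint component
        expr = simulate_expression(net, 0.5, 10, noise_sd=0.1, seed=0)
        out = assoc.distance_similarity_analysis(net, expr)
        # pairs across components are unreachable: 3 within path + 1 within edge
        assert out["n_pairs"] == 4


class TestSpearmanAndCorrelations:
    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=4, max_size=30,
        )
    )
    def test_spearman_matches_rank_pearson_oracle(self, data):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        rho, _ = assoc.spearman(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_attribute_correlations_extremes(self, triangle_network):
        net = triangle_network
        net.add_edge("c", "d", relation="co")
        meta = {}
        for node in net.nodes():
            k = net.degree(node)
            meta[node] = GeneMetadata(node, 1000 * k, k + 1, "nucleus")
        freqs = {node: net.degree(node) / 10 for node in net.nodes()}
        out = assoc.attribute_correlations(net, meta, freqs)
        assert out[("degree", "exon_count")][0] == pytest.approx(1.0)
        assert out[("degree", "raw_freq")][0] == pytest.approx(1.0)

    def test_constant_attribute_undefined(self, triangle_network):
        meta = {
            n: GeneMetadata(n, 1000, 5, "nucleus") for n in triangle_network.nodes()
        }
        freqs = {n: 0.1 * (i + 1) for i, n in enumerate(triangle_network.nodes())}
        out = assoc.attribute_correlations(triangle_network, meta, freqs)
        assert math.isnan(out[("degree", "exon_count")][0])  # degree constant too


class TestLocationGradient:
    def test_single_class(self, triangle_network):
        for n in triangle_network.nodes():
            triangle_network.nodes[n]["location"] = "nucleus"
        out = assoc.location_gradient(triangle_network)
        assert out["nucleus"]["n"] == 3
        assert out["extracellular"]["n"] == 0

    def test_unknown_excluded(self, triangle_network):
        for n in triangle_network.nodes():
            triangle_network.nodes[n]["location"] = "unknown"
        out = assoc.location_gradient(triangle_network)
        assert all(out[l]["n"] == 0 for l in
                   ("extracellular", "membrane", "cytoplasm", "nucleus"))

    def test_planted_gradient_monotone(self):
        rng = np.random.default_rng(2)
        net = CCANetwork()
        order = ["extracellular", "membrane", "cytoplasm", "nucleus"]
        nodes_by_loc = {}
        for rank, loc in enumerate(order):
            group = [f"{loc[:3]}{i}" for i in range(6)]
            nodes_by_loc[loc] = group
            # higher-rank locations get denser internal wiring -> higher degree
            for i, u in enumerate(group):
                for v in group[i + 1:]:
                    if rng.random() < 0.2 + 0.25 * rank:
                        net.add_edge(u, v, relation="co")
        for loc, group in nodes_by_loc.items():
            for node in group:
                if node not in net:
                    net.add_node(node)
                net.nodes[node]["location"] = loc
        out = assoc.location_gradient(net)
        medians = [out[l]["median_degree"] for l in order]
        assert all(a <= b for a, b in zip(medians, medians[1:]))
        assert out["monotone_degree"]


class TestRankSum:
    def test_exact_enumeration_small(self):
        assert assoc.rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples(self):
        assert assoc.rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_tied(self):
        assert assoc.rank_sum_test([5, 5], [5, 5, 5]) == 1.0

    def test_exact_vs_approximation_at_n12(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(0, 1, 6).tolist()
            b = rng.normal(0.5, 1, 6).tolist()
            exact = assoc._exact_rank_sum(a, b)
            from scipy.stats import mannwhitneyu

            approx = float(
                mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
            assert abs(exact - approx) < 0.02

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            assoc.rank_sum_test([], [1.0])

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40).tolist()
        b = rng.normal(1.5, 1, 40).tolist()
        p = assoc.rank_sum_test(a, b)
        assert p < 1e-6
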
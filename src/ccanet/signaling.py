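"""Placement of co-occurring mutation pairs in pathways and the cellular
signaling network, and the signal types they use.

Null models: uniform edge rewiring on the same node set with the same link
count (degree NOT preserved; a degree-preserving double-edge-swap variant is
available behind a flag), and uniform resampling of typed signaling links
for the signal-usage test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .association import RandomizationResult, randomization_p
from .io_formats import PathwayCollection, SignalingNetwork
from .network import CCANetwork
from .pairstats import fisher_exact_two_sided

__all__ = [
    "SignalUsage",
    "same_pathway_pair_count",
    "rewire_random",
    "rewire_degree_preserving",
    "pathway_comembership_test",
    "direct_interaction_enrichment",
    "signal_type_usage",
    "signal_usage_tests",
]

_TYPED = ("activation", "repression", "physical")


@dataclass
class SignalUsage:
    """Typed-link usage among directly linked co-occurring pairs, with the
    whole-network typed-link fractions as the expectation."""

    n_activation: int
    n_repression: int
    n_physical: int
    expected_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_activation + self.n_repression + self.n_physical

    @property
    def counts(self) -> dict[str, int]:
        return {
            "activation": self.n_activation,
            "repression": self.n_repression,
            "physical": self.n_physical,
        }

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {t: c / self.total for t, c in self.counts.items()}


def same_pathway_pair_count(
    network: CCANetwork, pathways: PathwayCollection
) -> int:
    """Co-occurring edges whose endpoints share at least one pathway; each
    edge counted once regardless of how many pathways are shared."""
    return sum(
        1 for a, b in network.co_edges if pathways.share_a_set(a, b)
    )


def rewire_random(network: CCANetwork, rng: np.random.Generator) -> CCANetwork:
    """Random network on the same node set with the same link count: edges
    drawn uniformly without replacement from all unordered node pairs.  No
    self-loops or parallel edges; degree is NOT preserved."""
    nodes = sorted(network.nodes())
    n = len(nodes)
    m = network.number_of_edges()
    capacity = n * (n - 1) // 2
    if m > capacity:
        raise ValueError("link count exceeds simple-graph capacity")
    out = CCANetwork()
    out.add_nodes_from(nodes)
    pids = rng.choice(capacity, size=m, replace=False)
    i = (n - 2 - np.floor(np.sqrt(-8 * pids + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (pids + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2).astype(int)
    for a, b in zip(i, j):
        out.add_edge(nodes[a], nodes[b], relation="co")
    return out


def rewire_degree_preserving(
    network: CCANetwork, rng: np.random.Generator, n_swaps: int | None = None
) -> CCANetwork:
    """Degree-preserving double-edge-swap rewiring (sensitivity-analysis
    alternative to the uniform null)."""
    import networkx as nx

    out = CCANetwork()
    out.add_nodes_from(network.nodes())
    out.add_edges_from((a, b, {"relation": "co"}) for a, b in network.edges())
    m = out.number_of_edges()
    if m < 2:
        return out
    try:
        nx.double_edge_swap(
            out, nswap=n_swaps or 10 * m, max_tries=1000 * m,
            seed=int(rng.integers(2**31 - 1)),
        )
    except nx.NetworkXAlgorithmError:
        pass  # small dense graphs: accept however many swaps succeeded
    return out


def pathway_comembership_test(
    network: CCANetwork,
    pathways: PathwayCollection,
    R: int = 5000,
    seed: int = 0,
    degree_preserving: bool = False,
) -> RandomizationResult:
    """Randomization test for pathway co-membership of co-occurring pairs.

    Observed = number of co edges inside a shared pathway; null = the same
    count on R rewired networks with the same nodes and the same number of
    (co) links; p = (T+1)/(R+1) with T = #{null >= observed}.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    observed = same_pathway_pair_count(network, pathways)
    co_net = CCANetwork()
    co_net.add_nodes_from(network.nodes())
    co_net.add_edges_from((a, b, {"relation": "co"}) for a, b in network.co_edges)
    rng = np.random.default_rng(seed)
    rewire = rewire_degree_preserving if degree_preserving else rewire_random
    null = []
    for _ in range(R):
        random_net = rewire(co_net, rng)
        assert set(random_net.nodes()) == set(co_net.nodes())
        assert random_net.number_of_edges() == co_net.number_of_edges()
        null.append(same_pathway_pair_count(random_net, pathways))
    return randomization_p(observed, null, tail="ge")


def direct_interaction_enrichment(
    network: CCANetwork, signaling: SignalingNetwork
) -> dict:
    """2x2 Fisher test: co-occurring edge (yes/no) x direct signaling link
    (yes/no, any type, direction ignored) over all unordered pairs of network
    genes mappable to the signaling network."""
    mapped = sorted(set(network.nodes()) & signaling.nodes)
    if len(mapped) < 2:
        raise ValueError("need >=2 network genes mappable to the signaling network")
    co_pairs = {frozenset(e) for e in network.co_edges}
    edge_linked = edge_unlinked = other_linked = other_unlinked = 0
    for a, b in itertools.combinations(mapped, 2):
        linked = signaling.has_direct_link(a, b)
        if frozenset((a, b)) in co_pairs:
            edge_linked += linked
            edge_unlinked += not linked
        else:
            other_linked += linked
            other_unlinked += not linked
    table = [[edge_linked, edge_unlinked], [other_linked, other_unlinked]]
    p, odds = fisher_exact_two_sided(table)
    n_edge = edge_linked + edge_unlinked
    n_other = other_linked + other_unlinked
    return {
        "table": table,
        "p_value": p,
        "odds_ratio": odds,
        "n_mapped_genes": len(mapped),
        "frac_edge_linked": edge_linked / n_edge if n_edge else math.nan,
        "frac_other_linked": other_linked / n_other if n_other else math.nan,
    }


def signal_type_usage(
    network: CCANetwork, signaling: SignalingNetwork
) -> SignalUsage:
    """Count typed links among directly linked co-occurring pairs.

    A pair connected by several typed links contributes each typed link once;
    unknown-type links never enter counts or denominators.
    """
    counts = {t: 0 for t in _TYPED}
    for a, b in network.co_edges:
        for link_type in signaling.link_types_between(a, b):
            if link_type in counts:
                counts[link_type] += 1
    expected = (
        signaling.typed_fractions() if signaling.typed_links() else {}
    )
    return SignalUsage(
        n_activation=counts["activation"],
        n_repression=counts["repression"],
        n_physical=counts["physical"],
        expected_fractions=expected,
    )


def signal_usage_tests(
    usage: SignalUsage,
    signaling: SignalingNetwork,
    R: int = 5000,
    seed: int = 0,
) -> dict:
    """Chi-square goodness of fit of the 3-category usage counts against the
    whole-network typed-link proportions (df = 2), plus a joint randomization
    test: R draws of the same number of links sampled uniformly (without
    replacement) from the network's typed links; T_act counts null activation
    counts >= observed, T_rep counts null repression counts <= observed.

    Also returns the joint (n_activation, n_repression) null grid.
    """
    if usage.total < 1:
        raise ValueError("no typed links among co-occurring pairs")
    expected_fracs = usage.expected_fractions or signaling.typed_fractions()
    observed = [usage.n_activation, usage.n_repression, usage.n_physical]
    expected = [expected_fracs[t] * usage.total for t in _TYPED]
    for obs, exp in zip(observed, expected):
        if exp == 0 and obs > 0:
            raise ValueError("observed count in a category with expected proportion 0")
    keep = [i for i, e in enumerate(expected) if e > 0]
    chi_res = stats.chisquare(
        [observed[i] for i in keep], f_exp=[expected[i] for i in keep]
    )
    chi2_stat, chi2_p = float(chi_res.statistic), float(chi_res.pvalue)

    typed = signaling.typed_links()
    if len(typed) < usage.total:
        raise ValueError("fewer typed links in the network than observed usage")
    types = np.array([l.type for l in typed])
    rng = np.random.default_rng(seed)
    null_act = np.empty(R, dtype=int)
    null_rep = np.empty(R, dtype=int)
    for r in range(R):
        drawn = types[rng.choice(len(types), size=usage.total, replace=False)]
        null_act[r] = int(np.sum(drawn == "activation"))
        null_rep[r] = int(np.sum(drawn == "repression"))
    act_res = randomization_p(usage.n_activation, null_act.tolist(), tail="ge")
    rep_res = randomization_p(usage.n_repression, null_rep.tolist(), tail="le")

    grid: dict[tuple[int, int], int] = {}
    for a, b in zip(null_act.tolist(), null_rep.tolist()):
        grid[(a, b)] = grid.get((a, b), 0) + 1
    return {
        "chi2_stat": chi2_stat,
        "chi2_df": len(keep) - 1,
        "chi2_p": chi2_p,
        "activation_preference": act_res,
        "repression_avoidance": rep_res,
        "joint_null_grid": grid,
    }
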
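"""Randomization engine, frequency-difference (AD) analysis, expression
similarity vs network distance, attribute correlations and rank-sum tests."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, GeneMetadata
from .network import (
    CCANetwork,
    clustering_coefficient,
    shortest_path_distances,
)
from .pairstats import GeneFrequency

__all__ = [
    "RandomizationResult",
    "ADRecord",
    "randomization_p",
    "ad_statistic",
    "ad_records",
    "ad_comparison",
    "expression_similarity",
    "distance_similarity_analysis",
    "attribute_correlations",
    "location_gradient",
    "rank_sum_test",
    "spearman",
]


@dataclass
class RandomizationResult:
    """Empirical significance from a constructed null.

    ``p = (T + 1) / (R + 1)`` where T counts null replicates at least as
    extreme as the observed statistic in the requested tail.
    """

    observed: float
    replicates: int
    exceedances: int
    p: float
    tail: str
    null_sample: list[float]


@dataclass(frozen=True)
class ADRecord:
    gene_a: str
    gene_b: str
    ad: float
    relation: str


def randomization_p(
    observed: float, null_values: Sequence[float], tail: str = "ge"
) -> RandomizationResult:
    """p = (T+1)/(R+1); T = #{null >= observed} (tail='ge') or <= (tail='le')."""
    null = list(null_values)
    if not null:
        raise ValueError("empty null sample")
    if tail not in ("ge", "le"):
        raise ValueError("tail must be 'ge' or 'le'")
    if tail == "ge":
        t = sum(1 for v in null if v >= observed)
    else:
        t = sum(1 for v in null if v <= observed)
    r = len(null)
    return RandomizationResult(
        observed=float(observed),
        replicates=r,
        exceedances=t,
        p=(t + 1) / (r + 1),
        tail=tail,
        null_sample=[float(v) for v in null],
    )


def ad_statistic(freq_a: float, freq_b: float) -> float:
    """Absolute difference of mutation frequency of a gene pair."""
    if freq_a < 0 or freq_b < 0:
        raise ValueError("frequencies must be non-negative")
    return abs(freq_a - freq_b)


def _freq_of(frequencies: Mapping, gene: str) -> float:
    value = frequencies[gene]
    if isinstance(value, GeneFrequency):
        return value.raw_freq
    return float(value)


def ad_records(network: CCANetwork, frequencies: Mapping) -> list[ADRecord]:
    """AD for every network edge with frequencies available for both genes."""
    out: list[ADRecord] = []
    for a, b, rel in network.edges(data="relation", default="co"):
        if a in frequencies and b in frequencies:
            out.append(
                ADRecord(a, b, ad_statistic(_freq_of(frequencies, a),
                                            _freq_of(frequencies, b)), rel)
            )
    return out


def ad_comparison(
    network: CCANetwork,
    frequencies: Mapping,
    R: int = 5000,
    seed: int = 0,
) -> dict:
    """Compare AD of co edges, anti edges and random node pairs.

    Returns co-vs-anti rank-sum p, plus randomization results comparing the
    median AD of the co group (tail='le': are co medians small?) and the
    anti group (tail='ge') against R random groups of node pairs drawn
    uniformly from the network's nodes.
    """
    records = ad_records(network, frequencies)
    co = [r.ad for r in records if r.relation == "co"]
    anti = [r.ad for r in records if r.relation == "anti"]
    out: dict = {"n_co": len(co), "n_anti": len(anti), "notices": []}

    if co and anti:
        out["co_vs_anti_p"] = rank_sum_test(co, anti)
    else:
        out["co_vs_anti_p"] = None
        out["notices"].append("co-vs-anti rank-sum skipped: a group is empty")

    rng = np.random.default_rng(seed)
    nodes = sorted(n for n in network.nodes() if n in frequencies)
    freqs = np.array([_freq_of(frequencies, n) for n in nodes])
    n = len(nodes)
    if n < 2:
        raise ValueError("need >=2 nodes with frequencies for the random null")

    def null_medians(group_size: int) -> list[float]:
        capacity = n * (n - 1) // 2
        take = min(group_size, capacity)
        medians = []
        for _ in range(R):
            pids = rng.choice(capacity, size=take, replace=False)
            i = (n - 2 - np.floor(
                np.sqrt(-8 * pids + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
            j = (pids + i + 1 - n * (n - 1) // 2
                 + (n - i) * ((n - i) - 1) // 2).astype(int)
            medians.append(float(np.median(np.abs(freqs[i] - freqs[j]))))
        return medians

    if co:
        out["co_vs_random"] = randomization_p(
            float(np.median(co)), null_medians(len(co)), tail="le"
        )
    else:
        out["co_vs_random"] = None
        out["notices"].append("co-vs-random skipped: no co edges")
    if anti:
        out["anti_vs_random"] = randomization_p(
            float(np.median(anti)), null_medians(len(anti)), tail="ge"
        )
    else:
        out["anti_vs_random"] = None
        out["notices"].append("anti-vs-random skipped: no anti edges")
    return out


def expression_similarity(
    expr: ExpressionMatrix, gene_a: str, gene_b: str
) -> float:
    """Absolute Pearson correlation of two expression profiles across tissues.

    Returns nan (undefined) when either profile is constant; such pairs are
    excluded downstream.
    """
    x = expr.profile(gene_a)
    y = expr.profile(gene_b)
    if len(x) < 3:
        raise ValueError("need >=3 tissues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(abs(r))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation (rho, two-sided p)."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def distance_similarity_analysis(network: CCANetwork, expr: ExpressionMatrix) -> dict:
    """Correlate network distance with absolute expression similarity.

    Pairwise: Spearman over all finite-distance gene pairs with defined
    similarity.  Grouped: mean similarity per integer distance, Spearman over
    the group means (skipped with <2 groups).
    """
    distances = shortest_path_distances(network)
    genes = sorted(
        g for g in network.nodes() if g in expr and g not in expr.constant_genes
    )
    dist_vals: list[float] = []
    sim_vals: list[float] = []
    for a, b in itertools.combinations(genes, 2):
        d = distances[a][b]
        if math.isinf(d):
            continue
        s = expression_similarity(expr, a, b)
        if math.isnan(s):
            continue
        dist_vals.append(d)
        sim_vals.append(s)
    if len(dist_vals) < 2:
        raise ValueError("need >=2 finite-distance pairs with defined similarity")
    rho, p = spearman(dist_vals, sim_vals)
    out = {
        "n_pairs": len(dist_vals),
        "pairwise_rho": rho,
        "pairwise_p": p,
        "groups": {},
        "grouped_rho": None,
        "grouped_p": None,
    }
    groups: dict[float, list[float]] = {}
    for d, s in zip(dist_vals, sim_vals):
        groups.setdefault(d, []).append(s)
    means = {d: float(np.mean(v)) for d, v in sorted(groups.items())}
    out["groups"] = means
    if len(means) >= 2:
        g_rho, g_p = spearman(list(means.keys()), list(means.values()))
        out["grouped_rho"] = g_rho
        out["grouped_p"] = g_p
    return out


_ATTRIBUTE_PAIRS = (
    ("degree", "exon_count"),
    ("degree", "length_bp"),
    ("degree", "raw_freq"),
    ("cc", "raw_freq"),
    ("cc", "degree"),
    ("raw_freq", "length_bp"),
)


def attribute_correlations(
    network: CCANetwork,
    metadata: Mapping[str, GeneMetadata],
    frequencies: Mapping,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Spearman (rho, p) for degree/CC/frequency/length/exon-count pairs over
    pairwise-complete nodes; constant attributes give (nan, nan)."""
    rows: dict[str, dict[str, float]] = {}
    for node in network.nodes():
        row: dict[str, float] = {
            "degree": float(network.degree(node)),
            "cc": clustering_coefficient(network, node),
        }
        if node in frequencies:
            row["raw_freq"] = _freq_of(frequencies, node)
        if node in metadata:
            row["length_bp"] = float(metadata[node].length_bp)
            row["exon_count"] = float(metadata[node].exon_count)
        rows[node] = row
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for attr_x, attr_y in _ATTRIBUTE_PAIRS:
        xs, ys = [], []
        for row in rows.values():
            if attr_x in row and attr_y in row:
                xs.append(row[attr_x])
                ys.append(row[attr_y])
        if len(xs) < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
            out[(attr_x, attr_y)] = (math.nan, math.nan)
            continue
        out[(attr_x, attr_y)] = spearman(xs, ys)
    return out


_LOCATION_ORDER = ("extracellular", "membrane", "cytoplasm", "nucleus")


def location_gradient(network: CCANetwork) -> dict[str, dict]:
    """Median degree and median CC per cellular-location class, ordered from
    extracellular space to nucleus; unknown-location nodes excluded."""
    by_location: dict[str, list[tuple[int, float]]] = {l: [] for l in _LOCATION_ORDER}
    for node in network.nodes():
        location = network.nodes[node].get("location", "unknown")
        if location in by_location:
            by_location[location].append(
                (network.degree(node), clustering_coefficient(network, node))
            )
    out: dict[str, dict] = {}
    medians_k: list[float] = []
    medians_c: list[float] = []
    for location in _LOCATION_ORDER:
        entries = by_location[location]
        if not entries:
            out[location] = {"n": 0, "median_degree": None, "median_cc": None}
            continue
        ks = [k for k, _ in entries]
        cs = [c for _, c in entries]
        mk, mc = float(np.median(ks)), float(np.median(cs))
        out[location] = {"n": len(entries), "median_degree": mk, "median_cc": mc}
        medians_k.append(mk)
        medians_c.append(mc)
    out["monotone_degree"] = all(
        a <= b for a, b in zip(medians_k, medians_k[1:])
    ) and len(medians_k) > 1
    out["monotone_cc"] = all(
        a <= b for a, b in zip(medians_c, medians_c[1:])
    ) and len(medians_c) > 1
    return out


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum (Mann-Whitney) p-value.

    Exact permutation enumeration for combined n <= 12 (ties handled
    naturally); tie-corrected normal approximation otherwise.  Fully
    degenerate pooled samples give p = 1.
    """
    a = [float(v) for v in sample_a]
    b = [float(v) for v in sample_b]
    if not a or not b:
        raise ValueError("both samples must be nonempty")
    pooled = a + b
    if len(set(pooled)) == 1:
        return 1.0  # all values tied: no evidence either way
    n1, n2 = len(a), len(b)
    if n1 + n2 <= 12:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Enumerate all group assignments of the pooled values; two-sided p is
    the fraction with |U - n1*n2/2| at least as large as observed."""
    pooled = list(a) + list(b)
    n1 = len(a)
    center = n1 * (len(pooled) - n1) / 2.0

    def u_statistic(group: Sequence[float], other: Sequence[float]) -> float:
        u = 0.0
        for x in group:
            for y in other:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed_dev = abs(u_statistic(a, b) - center)
    count = 0
    total = 0
    indices = range(len(pooled))
    for subset in itertools.combinations(indices, n1):
        chosen = set(subset)
        group = [pooled[i] for i in subset]
        other = [pooled[i] for i in indices if i not in chosen]
        dev = abs(u_statistic(group, other) - center)
        if dev >= observed_dev - 1e-12:
            count += 1
        total += 1
    return count / total
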
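"""Synthetic input generators with planted, recoverable structure.

Everything the pipeline consumes can be generated here: mutation matrices
with planted co-occurring / mutually exclusive gene pairs, typed signaling
networks, expression profiles whose similarity decays with network distance,
and annotation bundles (pathway sets, methylated genes, module labels, gene
metadata).  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io_formats import (
    LINK_TYPES,
    LOCATIONS,
    MUTATED,
    NOT_SEQUENCED,
    WILDTYPE,
    ExpressionMatrix,
    GeneMetadata,
    MutationMatrix,
    PathwayCollection,
    SignalingLink,
    SignalingNetwork,
)

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_mutation_matrix",
    "simulate_signaling_network",
    "simulate_expression",
    "simulate_annotations",
]


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    effect: float  # shared-driver prob q (co) or exclusive-driver prob e (anti)
    direction: str  # "co" | "anti"

    def __post_init__(self) -> None:
        if not 0 < self.effect <= 1:
            raise ValueError("effect probability must be in (0, 1]")
        if self.direction not in ("co", "anti"):
            raise ValueError("direction must be co or anti")


@dataclass
class SimulationConfig:
    """Parameters of the planted-pair mutation matrix simulator."""

    n_samples: int
    n_genes: int
    baseline_freqs: Sequence[float] | float | None = None  # default: log-uniform
    co_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    anti_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    coverage: float = 1.0
    seed: int = 0
    baseline_range: tuple[float, float] = (0.01, 0.3)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        used: set[str] = set()
        for a, b, effect in [*self.co_pairs, *self.anti_pairs]:
            if not 0 < effect <= 1:
                raise ValueError(f"pair ({a}, {b}): effect must be in (0, 1]")
            for gene in (a, b):
                if gene in used:
                    raise ValueError(f"gene {gene!r} appears in two planted pairs")
                used.add(gene)

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Planted structure plus per-gene realized marginals, for recovery tests."""

    planted_pairs: list[PlantedPair]
    baseline_freqs: dict[str, float]
    realized_freqs: dict[str, float]


def _resolve_baselines(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.baseline_freqs is None:
        lo, hi = config.baseline_range
        # log-uniform to mimic heterogeneous per-gene frequencies
        freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    elif np.isscalar(config.baseline_freqs):
        freqs = np.full(config.n_genes, float(config.baseline_freqs))
    else:
        freqs = np.asarray(config.baseline_freqs, dtype=float)
        if freqs.shape != (config.n_genes,):
            raise ValueError("baseline_freqs length must equal n_genes")
    if np.any((freqs < 0) | (freqs >= 1)):
        raise ValueError("baseline frequencies must be in [0, 1)")
    return freqs


def simulate_mutation_matrix(
    config: SimulationConfig,
) -> tuple[MutationMatrix, SyntheticTruth]:
    """Simulate a samples x genes status matrix with planted pair structure.

    Per sample: every gene mutates independently with its baseline frequency;
    for each planted co pair a shared latent event (prob q) sets BOTH genes
    mutated; for each planted anti pair an exclusive latent event (prob e)
    sets exactly one of the two (fair coin) and suppresses the pair's
    independent baselines in that sample, guaranteeing exclusivity.  An
    i.i.d. per-cell sequencing mask (prob ``coverage``) is applied last.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gidx = {g: j for j, g in enumerate(genes)}
    for a, b, _ in [*config.co_pairs, *config.anti_pairs]:
        for gene in (a, b):
            if gene not in gidx:
                raise ValueError(f"planted pair gene {gene!r} not among gene names")

    baselines = _resolve_baselines(config, rng)
    n, m = config.n_samples, config.n_genes

    mutated = rng.random((n, m)) < baselines[None, :]

    planted: list[PlantedPair] = []
    for a, b, q in config.co_pairs:
        ja, jb = gidx[a], gidx[b]
        event = rng.random(n) < q
        mutated[event, ja] = True
        mutated[event, jb] = True
        planted.append(PlantedPair(a, b, q, "co"))
    for a, b, e in config.anti_pairs:
        ja, jb = gidx[a], gidx[b]
        event = rng.random(n) < e
        pick_a = rng.random(n) < 0.5
        # exclusive event overrides the independent baselines of the pair
        mutated[event, ja] = pick_a[event]
        mutated[event, jb] = ~pick_a[event]
        planted.append(PlantedPair(a, b, e, "anti"))

    data = np.where(mutated, MUTATED, WILDTYPE).astype(np.int8)
    if config.coverage < 1:
        covered = rng.random((n, m)) < config.coverage
        data[~covered] = NOT_SEQUENCED

    samples = [f"S{i:04d}" for i in range(n)]
    matrix = MutationMatrix(samples, genes, data)

    sequenced = data != NOT_SEQUENCED
    with np.errstate(invalid="ignore"):
        realized = np.where(
            sequenced.sum(axis=0) > 0,
            (data == MUTATED).sum(axis=0) / np.maximum(sequenced.sum(axis=0), 1),
            np.nan,
        )
    truth = SyntheticTruth(
        planted_pairs=planted,
        baseline_freqs={g: float(f) for g, f in zip(genes, baselines)},
        realized_freqs={g: float(f) for g, f in zip(genes, realized)},
    )
    return matrix, truth


def simulate_signaling_network(
    n_nodes: int,
    n_links: int,
    type_proportions: Sequence[float],
    seed: int = 0,
) -> SignalingNetwork:
    """Random simple-graph link list with multinomially drawn types.

    ``type_proportions`` are (activation, repression, physical, unknown) and
    must sum to 1.
    """
    proportions = np.asarray(type_proportions, dtype=float)
    if proportions.shape != (4,):
        raise ValueError("type_proportions must have 4 entries (a, r, p, unknown)")
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("type_proportions must sum to 1")
    capacity = n_nodes * (n_nodes - 1) // 2
    if n_links > capacity:
        raise ValueError(f"n_links={n_links} exceeds simple-graph capacity {capacity}")
    rng = np.random.default_rng(seed)
    pair_ids = rng.choice(capacity, size=n_links, replace=False)
    types = rng.choice(np.array(LINK_TYPES), size=n_links, p=proportions)
    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    links = []
    for pid, link_type in zip(pair_ids, types):
        i, j = _pair_from_index(int(pid), n_nodes)
        links.append(SignalingLink(nodes[i], nodes[j], str(link_type)))
    return SignalingNetwork(links=links)


def _pair_from_index(pid: int, n: int) -> tuple[int, int]:
    """Inverse of the row-major upper-triangle pair enumeration."""
    i = int(n - 2 - np.floor(np.sqrt(-8 * pid + 4 * n * (n - 1) - 7) / 2 - 0.5))
    j = pid + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2
    return i, int(j)


def simulate_expression(
    network: nx.Graph,
    decay_alpha: float,
    n_tissues: int,
    noise_sd: float,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression profiles whose similarity decays with network distance.

    Each connected component gets a latent root profile; a gene at distance d
    from the root receives ``decay_alpha**d * latent + N(0, noise_sd)``, so
    the expected absolute Pearson similarity decreases with distance.
    """
    if not 0 < decay_alpha < 1:
        raise ValueError("decay_alpha must be in (0, 1)")
    if n_tissues < 3:
        raise ValueError("need at least 3 tissues")
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes())
    values = np.zeros((len(genes), n_tissues))
    gidx = {g: i for i, g in enumerate(genes)}
    for component in nx.connected_components(network):
        root = min(component)  # deterministic seeding node
        latent = rng.standard_normal(n_tissues)
        dist = nx.single_source_shortest_path_length(network, root)
        for gene in sorted(component):
            profile = decay_alpha ** dist[gene] * latent
            if noise_sd > 0:
                profile = profile + rng.normal(0.0, noise_sd, size=n_tissues)
            values[gidx[gene]] = profile
    tissues = [f"T{i:02d}" for i in range(n_tissues)]
    return ExpressionMatrix(genes=genes, tissues=tissues, values=values)


def simulate_annotations(
    genes: Sequence[str],
    n_pathways: int,
    set_size_range: tuple[int, int],
    methylation_rate_by_module: Mapping[str, float],
    module_split: Mapping[str, Sequence[str]],
    seed: int = 0,
    network: nx.Graph | None = None,
    adjacency_bias: float = 0.0,
    length_range: tuple[int, int] = (1_000, 100_000),
    exon_range: tuple[int, int] = (1, 60),
) -> tuple[PathwayCollection, list[str], dict[str, str], dict[str, GeneMetadata]]:
    """Generate pathway sets, a methylated-gene list, module labels and gene
    metadata for a gene universe.

    ``module_split`` must partition ``genes``; methylation labels are drawn
    per module at the stated rates; lengths and exon counts are log-uniform.
    With ``adjacency_bias`` > 0 and a network given, pathway sets are seeded
    from a gene's network neighborhood with that probability, planting
    pathway co-membership of linked genes.
    """
    genes = list(genes)
    covered: set[str] = set()
    for module, members in module_split.items():
        members = list(members)
        if not members:
            raise ValueError(f"module {module!r} is empty")
        overlap = covered.intersection(members)
        if overlap:
            raise ValueError(f"genes in two modules: {sorted(overlap)[:5]}")
        covered.update(members)
    if covered != set(genes):
        raise ValueError("module_split must partition the gene list")

    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError("invalid set_size_range")

    sets: dict[str, frozenset[str]] = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if network is not None and adjacency_bias > 0 and rng.random() < adjacency_bias:
            seed_gene = genes[int(rng.integers(len(genes)))]
            pool = [seed_gene]
            if seed_gene in network:
                pool += sorted(network.neighbors(seed_gene))
            members = set(pool[:size])
            remaining = [g for g in genes if g not in members]
            extra = size - len(members)
            if extra > 0:
                members.update(
                    rng.choice(remaining, size=extra, replace=False).tolist()
                )
        else:
            members = set(rng.choice(genes, size=size, replace=False).tolist())
        sets[f"PW{k:04d}"] = frozenset(members)
    pathways = PathwayCollection(sets=sets, descriptions={k: "" for k in sets})

    methylated: list[str] = []
    module_labels: dict[str, str] = {}
    for module, members in module_split.items():
        rate = methylation_rate_by_module.get(module, 0.0)
        for gene in members:
            module_labels[gene] = module
            if rate > 0 and rng.random() < rate:
                methylated.append(gene)

    metadata: dict[str, GeneMetadata] = {}
    for gene in genes:
        length = int(
            np.exp(rng.uniform(np.log(length_range[0]), np.log(length_range[1])))
        )
        exons = int(
            round(np.exp(rng.uniform(np.log(exon_range[0]), np.log(exon_range[1]))))
        )
        metadata[gene] = GeneMetadata(
            gene_id=gene,
            length_bp=max(length, 1),
            exon_count=max(exons, 1),
            location=str(rng.choice(np.array(LOCATIONS[:4]))),
        )
    return pathways, methylated, module_labels, metadata
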
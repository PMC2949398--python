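"""Two-module functional and mutational contrasts: gene-set enrichment,
methylation enrichment, per-sample module mutation distribution and module
frequency comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .association import RandomizationResult, randomization_p, rank_sum_test
from .io_formats import PathwayCollection
from .pairstats import fisher_exact_two_sided

__all__ = [
    "EnrichmentRow",
    "geneset_enrichment",
    "methylation_enrichment",
    "sample_module_distribution",
    "module_frequency_comparison",
]


@dataclass
class EnrichmentRow:
    set_name: str
    n_set_in_background: int
    n_set_in_module: int
    p_value: float
    significant: bool


def geneset_enrichment(
    module_genes: Iterable[str],
    background: Iterable[str],
    gene_sets: PathwayCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation of each gene set in the
    module, relative to the background population.

    This is the generic stand-in for interactive enrichment tools: for a set
    with K members in the background of size N and a module of size n with k
    members in the set, p = P[X >= k], X ~ Hypergeom(N, K, n).
    """
    background = set(background)
    module = set(module_genes)
    if not background:
        raise ValueError("empty background population")
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    n_bg = len(background)
    n_mod = len(module)
    rows: list[EnrichmentRow] = []
    for name, members in gene_sets.sets.items():
        in_bg = len(members & background)
        if in_bg == 0:
            continue
        in_mod = len(members & module)
        p = float(hypergeom.sf(in_mod - 1, n_bg, in_bg, n_mod))
        rows.append(
            EnrichmentRow(
                set_name=name,
                n_set_in_background=in_bg,
                n_set_in_module=in_mod,
                p_value=min(p, 1.0),
                significant=p <= alpha,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def methylation_enrichment(
    module_labels: Mapping[str, str], methylated_genes: Iterable[str]
) -> dict:
    """2x2 Fisher test of methylated vs non-methylated gene counts across the
    two modules (rows = modules, columns = methylated / not)."""
    modules = sorted(set(module_labels.values()))
    if len(modules) != 2:
        raise ValueError(f"need exactly 2 modules, got {modules}")
    methylated = set(methylated_genes)
    counts = {m: [0, 0] for m in modules}
    for gene, module in module_labels.items():
        counts[module][0 if gene in methylated else 1] += 1
    table = [counts[modules[0]], counts[modules[1]]]
    p, odds = fisher_exact_two_sided(table)
    return {
        "modules": modules,
        "table": table,
        "p_value": p,
        "odds_ratio": odds,
        "fractions": {
            m: counts[m][0] / (counts[m][0] + counts[m][1]) for m in modules
        },
    }


def sample_module_distribution(
    sample_mutations: Mapping[str, Iterable[str]],
    module_labels: Mapping[str, str],
    R: int = 5000,
    seed: int = 0,
) -> dict:
    """Classify samples by which modules their mutated genes hit, with a
    mutation-count-preserving randomization null.

    Per sample the mutated genes are intersected with the module-labeled
    genes and classified {both, only module one, only module two, neither}.
    The null keeps each sample's number of mutated module genes fixed and
    reassigns those mutations uniformly at random over all module genes.
    Returns the joint null grid over (M = samples hitting Module Two,
    N = samples hitting only Module Two) and the randomization p for the
    number of samples hitting Module One (tail='ge').
    """
    modules = sorted(set(module_labels.values()))
    if len(modules) != 2:
        raise ValueError(f"need exactly 2 modules, got {modules}")
    mod_one, mod_two = modules
    module_genes = sorted(module_labels)
    gene_module = np.array([module_labels[g] == mod_one for g in module_genes])
    gene_index = {g: i for i, g in enumerate(module_genes)}

    per_sample_counts: list[int] = []
    n_both = n_only1 = n_only2 = n_neither = 0
    observed_hit_one = 0
    for sample, mutated in sample_mutations.items():
        hits = [gene_index[g] for g in set(mutated) if g in gene_index]
        per_sample_counts.append(len(hits))
        in_one = any(gene_module[h] for h in hits)
        in_two = any(not gene_module[h] for h in hits)
        if in_one and in_two:
            n_both += 1
        elif in_one:
            n_only1 += 1
        elif in_two:
            n_only2 += 1
        else:
            n_neither += 1  # zero module-gene mutations: counted neither
        observed_hit_one += in_one

    rng = np.random.default_rng(seed)
    n_module_genes = len(module_genes)
    null_hit_one: list[int] = []
    grid: dict[tuple[int, int], int] = {}
    for _ in range(R):
        hit_one_count = 0
        m_count = 0  # samples with >=1 mutation in Module Two
        n_count = 0  # samples with mutations only in Module Two
        for k in per_sample_counts:
            if k == 0:
                continue
            draw = rng.choice(n_module_genes, size=min(k, n_module_genes), replace=False)
            one = bool(gene_module[draw].any())
            two = bool((~gene_module[draw]).any())
            hit_one_count += one
            m_count += two
            n_count += two and not one
        null_hit_one.append(hit_one_count)
        grid[(m_count, n_count)] = grid.get((m_count, n_count), 0) + 1

    return {
        "n_both": n_both,
        "n_only_module_one": n_only1,
        "n_only_module_two": n_only2,
        "n_neither": n_neither,
        "module_one_coverage": randomization_p(
            observed_hit_one, null_hit_one, tail="ge"
        ),
        "joint_null_grid": grid,
        "modules": (mod_one, mod_two),
    }


def module_frequency_comparison(
    module_labels: Mapping[str, str], frequencies: Mapping[str, float]
) -> dict:
    """Two-sided rank-sum test of per-gene mutation frequencies between the
    two modules."""
    modules = sorted(set(module_labels.values()))
    if len(modules) != 2:
        raise ValueError(f"need exactly 2 modules, got {modules}")
    groups: dict[str, list[float]] = {m: [] for m in modules}
    for gene, module in module_labels.items():
        if gene in frequencies:
            value = frequencies[gene]
            groups[module].append(
                value.raw_freq if hasattr(value, "raw_freq") else float(value)
            )
    for module, values in groups.items():
        if not values:
            raise ValueError(f"module {module!r} has no genes with frequencies")
    p = rank_sum_test(groups[modules[0]], groups[modules[1]])
    return {
        "modules": modules,
        "n": {m: len(v) for m, v in groups.items()},
        "median": {m: float(np.median(v)) for m, v in groups.items()},
        "p_value": p,
    }
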
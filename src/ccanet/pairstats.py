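"""Per-gene mutation frequency and per-pair co-occurrence inference.

Each unordered gene pair is reduced, over the samples sequenced for BOTH
genes, to a 2x2 contingency table (mutated-in-both / only A / only B /
neither) which is tested with a two-sided Fisher exact test.  Pairs at
p <= cutoff become network edges, with the odds ratio giving the direction
(co-occurring vs anti-co-occurring / mutually exclusive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .io_formats import MUTATED, GeneMetadata, MutationMatrix

__all__ = [
    "PairContingency",
    "PairTestResult",
    "GeneFrequency",
    "EmptyOverlapError",
    "pair_contingency",
    "fisher_exact_two_sided",
    "classify_relation",
    "benjamini_hochberg",
    "all_pair_tests",
    "mutation_frequency",
    "write_pair_results",
]


class EmptyOverlapError(ValueError):
    """No sample was sequenced for both genes of a pair."""


@dataclass(frozen=True)
class PairContingency:
    """Counts over the co-sequenced samples of a gene pair."""

    gene_a: str
    gene_b: str
    n_ab: int        # mutated in both
    n_a_only: int    # mutated in A, wildtype in B
    n_b_only: int    # wildtype in A, mutated in B
    n_neither: int   # wildtype in both

    def __post_init__(self) -> None:
        if min(self.n_ab, self.n_a_only, self.n_b_only, self.n_neither) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cosequenced(self) -> int:
        return self.n_ab + self.n_a_only + self.n_b_only + self.n_neither

    def as_table(self) -> list[list[int]]:
        return [[self.n_ab, self.n_a_only], [self.n_b_only, self.n_neither]]


@dataclass
class PairTestResult:
    contingency: PairContingency
    p_value: float
    odds_ratio: float  # may be inf; nan when undefined (all-zero table)
    relation: str      # co | anti | none
    fdr_q: float | None = None

    @property
    def gene_a(self) -> str:
        return self.contingency.gene_a

    @property
    def gene_b(self) -> str:
        return self.contingency.gene_b


@dataclass(frozen=True)
class GeneFrequency:
    gene_id: str
    n_sequenced: int
    n_mutated: int
    raw_freq: float
    corrected_freq: float | None = None  # raw_freq / gene length (per bp)

    def __post_init__(self) -> None:
        if not 0 <= self.n_mutated <= self.n_sequenced:
            raise ValueError("need 0 <= n_mutated <= n_sequenced")


def pair_contingency(matrix: MutationMatrix, gene_a: str, gene_b: str) -> PairContingency:
    """Contingency counts restricted to samples sequenced for both genes."""
    col_a = matrix.gene_column(gene_a)
    col_b = matrix.gene_column(gene_b)
    both = (col_a >= 0) & (col_b >= 0)
    if not both.any():
        raise EmptyOverlapError(
            f"no sample sequenced for both {gene_a!r} and {gene_b!r}"
        )
    a = col_a[both] == MUTATED
    b = col_b[both] == MUTATED
    return PairContingency(
        gene_a=gene_a,
        gene_b=gene_b,
        n_ab=int(np.sum(a & b)),
        n_a_only=int(np.sum(a & ~b)),
        n_b_only=int(np.sum(~a & b)),
        n_neither=int(np.sum(~a & ~b)),
    )


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with a 0.5 continuity add-on when any cell is 0."""
    if a == b == c == d == 0:
        return math.nan
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_exact_two_sided(contingency: PairContingency | Sequence[Sequence[int]]):
    """Two-sided Fisher exact test (point-probability summation method).

    Returns ``(p_value, odds_ratio)``.  The odds ratio is the sample
    cross-product ratio, with a 0.5 continuity correction applied to every
    cell when any cell is zero; an all-zero table gives p = 1 and OR = nan.
    """
    if isinstance(contingency, PairContingency):
        (a, b), (c, d) = contingency.as_table()
    else:
        (a, b), (c, d) = contingency
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    odds_ratio = _sample_odds_ratio(a, b, c, d)
    if a == b == c == d == 0:
        return 1.0, odds_ratio
    p = float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue)
    return min(p, 1.0), odds_ratio


def classify_relation(p_value: float, odds_ratio: float, cutoff: float = 0.02) -> str:
    """co if significant with OR > 1, anti if significant with OR < 1."""
    if math.isnan(odds_ratio) or p_value > cutoff:
        return "none"
    if odds_ratio > 1:
        return "co"
    if odds_ratio < 1:
        return "anti"
    return "none"


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up adjustment)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def all_pair_tests(
    matrix: MutationMatrix,
    cutoff: float = 0.02,
    min_cosequenced: int = 1,
) -> list[PairTestResult]:
    """Fisher-test every unordered gene pair with enough co-sequenced samples.

    Results are in lexicographic (gene_a, gene_b) order with Benjamini-
    Hochberg q-values attached over all performed tests.  Pairs below
    ``min_cosequenced`` co-sequenced samples are skipped.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes")
    genes = sorted(matrix.genes)
    seq = matrix.sequenced_mask().astype(np.int32)
    mut = matrix.mutated_mask().astype(np.int32)
    gidx = {g: j for j, g in enumerate(matrix.genes)}

    # vectorized pairwise counts over co-sequenced samples
    mut_seq = mut  # mutated implies sequenced
    n_ab = mut_seq.T @ mut_seq
    n_coseq = seq.T @ seq
    n_a_mut_b_seq = mut_seq.T @ seq  # A mutated among samples sequenced for both

    results: list[PairTestResult] = []
    cache: dict[tuple[int, int, int, int], tuple[float, float]] = {}
    for name_a, name_b in itertools.combinations(genes, 2):
        i, j = gidx[name_a], gidx[name_b]
        total = int(n_coseq[i, j])
        if total < min_cosequenced:
            continue
        ab = int(n_ab[i, j])
        a_only = int(n_a_mut_b_seq[i, j]) - ab
        b_only = int(n_a_mut_b_seq[j, i]) - ab
        neither = total - ab - a_only - b_only
        table = (ab, a_only, b_only, neither)
        if table not in cache:
            cache[table] = fisher_exact_two_sided(
                [[ab, a_only], [b_only, neither]]
            )
        p, odds = cache[table]
        results.append(
            PairTestResult(
                contingency=PairContingency(name_a, name_b, *table),
                p_value=p,
                odds_ratio=odds,
                relation=classify_relation(p, odds, cutoff),
            )
        )
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
    return results


def mutation_frequency(
    matrix: MutationMatrix,
    gene: str,
    metadata: Mapping[str, GeneMetadata] | None = None,
) -> GeneFrequency:
    """Raw mutation frequency = mutated / sequenced; corrected = raw / length_bp
    when gene length metadata is available."""
    col = matrix.gene_column(gene)
    n_sequenced = int(np.sum(col >= 0))
    if n_sequenced == 0:
        raise ValueError(f"gene {gene!r} was never sequenced")
    n_mutated = int(np.sum(col == MUTATED))
    raw = n_mutated / n_sequenced
    corrected = None
    if metadata is not None and gene in metadata:
        corrected = raw / metadata[gene].length_bp
    return GeneFrequency(
        gene_id=gene,
        n_sequenced=n_sequenced,
        n_mutated=n_mutated,
        raw_freq=raw,
        corrected_freq=corrected,
    )


def write_pair_results(results: Sequence[PairTestResult], path: str | Path) -> None:
    """One TSV row per tested pair with counts, p, OR, q and relation."""
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tn_ab\tn_a_only\tn_b_only\tn_neither\t"
            "p_value\todds_ratio\tfdr_q\trelation\n"
        )
        for r in results:
            c = r.contingency
            fh.write(
                f"{c.gene_a}\t{c.gene_b}\t{c.n_ab}\t{c.n_a_only}\t{c.n_b_only}\t"
                f"{c.n_neither}\t{r.p_value:.6g}\t{r.odds_ratio:.6g}\t"
                f"{(r.fdr_q if r.fdr_q is not None else float('nan')):.6g}\t{r.relation}\n"
            )
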
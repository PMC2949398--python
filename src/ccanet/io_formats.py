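"""Readers and writers for every external representation the pipeline touches.

Formats: long/wide mutation TSV, Pajek NET, GMT gene sets, typed signaling
edge lists, expression matrices, gene metadata, plain gene lists and module
label tables.  All writers round-trip through their readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOT_SEQUENCED",
    "WILDTYPE",
    "MUTATED",
    "LOCATIONS",
    "LINK_TYPES",
    "MutationMatrix",
    "GeneMetadata",
    "PathwayCollection",
    "SignalingLink",
    "SignalingNetwork",
    "ExpressionMatrix",
    "FormatError",
    "read_mutation_table",
    "write_mutation_table",
    "read_pajek",
    "write_pajek",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_signaling_network",
    "write_signaling_network",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_metadata",
    "write_gene_metadata",
    "read_gene_list",
    "write_gene_list",
    "read_module_labels",
    "write_module_labels",
]

# Cell status codes of the mutation matrix.
NOT_SEQUENCED = -1
WILDTYPE = 0
MUTATED = 1

LOCATIONS = ("extracellular", "membrane", "cytoplasm", "nucleus", "unknown")
LINK_TYPES = ("activation", "repression", "physical", "unknown")


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class MutationMatrix:
    """Dense samples x genes status matrix.

    ``data[i, j]`` is -1 (not sequenced), 0 (sequenced wildtype) or
    1 (sequenced, at least one mutation) for sample ``samples[i]`` and gene
    ``genes[j]``.
    """

    samples: list[str]
    genes: list[str]
    data: np.ndarray  # int8, shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.samples), len(self.genes)):
            raise ValueError("data shape does not match sample/gene labels")
        if not np.isin(self.data, (NOT_SEQUENCED, WILDTYPE, MUTATED)).all():
            raise ValueError("status codes must be -1, 0 or 1")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._gene_index = {g: j for j, g in enumerate(self.genes)}
        if len(self._sample_index) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(self._gene_index) != len(self.genes):
            raise ValueError("duplicate gene ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            return self.data[:, self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def sequenced_mask(self) -> np.ndarray:
        return self.data != NOT_SEQUENCED

    def mutated_mask(self) -> np.ndarray:
        return self.data == MUTATED

    def to_long_frame(self) -> pd.DataFrame:
        status = np.where(self.data == NOT_SEQUENCED, "NA", self.data.astype(str))
        return pd.DataFrame(
            {
                "sample_id": np.repeat(self.samples, self.n_genes),
                "gene_id": np.tile(self.genes, self.n_samples),
                "status": status.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.genes == other.genes
            and np.array_equal(self.data, other.data)
        )


@dataclass(frozen=True)
class GeneMetadata:
    """Static per-gene annotation: length, exon count and cellular location."""

    gene_id: str
    length_bp: int
    exon_count: int
    location: str = "unknown"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.gene_id}: length_bp must be positive")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")
        if self.location not in LOCATIONS:
            raise ValueError(f"{self.gene_id}: unknown location {self.location!r}")


@dataclass
class PathwayCollection:
    """Named, de-duplicated, nonempty gene sets (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def sets_containing(self, gene: str) -> set[str]:
        return {name for name, members in self.sets.items() if gene in members}

    def share_a_set(self, gene_a: str, gene_b: str) -> bool:
        return any(gene_a in m and gene_b in m for m in self.sets.values())


@dataclass(frozen=True)
class SignalingLink:
    source: str
    target: str
    type: str

    def __post_init__(self) -> None:
        if self.type not in LINK_TYPES:
            raise ValueError(f"unknown link type {self.type!r}")

    @property
    def directed(self) -> bool:
        # activation/repression carry direction; physical/unknown do not
        return self.type in ("activation", "repression")

    def endpoint_key(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass
class SignalingNetwork:
    """Typed cellular signaling link list.

    Activation and repression links are directed, physical and unknown links
    undirected; type counts and typed-link fractions are queryable.
    """

    links: list[SignalingLink]

    def __post_init__(self) -> None:
        self._pair_types: dict[frozenset[str], set[str]] = {}
        for link in self.links:
            self._pair_types.setdefault(link.endpoint_key(), set()).add(link.type)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for link in self.links:
            out.add(link.source)
            out.add(link.target)
        return out

    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in LINK_TYPES}
        for link in self.links:
            counts[link.type] += 1
        return counts

    def typed_links(self) -> list[SignalingLink]:
        """All links with a known type (unknown-type links excluded)."""
        return [l for l in self.links if l.type != "unknown"]

    def typed_fractions(self) -> dict[str, float]:
        """Fractions of activation/repression/physical among typed links."""
        counts = self.type_counts()
        total = counts["activation"] + counts["repression"] + counts["physical"]
        if total == 0:
            raise ValueError("no typed links in signaling network")
        return {t: counts[t] / total for t in ("activation", "repression", "physical")}

    def has_direct_link(self, gene_a: str, gene_b: str) -> bool:
        """Any link between the two genes, of any type, ignoring direction."""
        return frozenset((gene_a, gene_b)) in self._pair_types

    def link_types_between(self, gene_a: str, gene_b: str) -> set[str]:
        return set(self._pair_types.get(frozenset((gene_a, gene_b)), set()))


@dataclass
class ExpressionMatrix:
    """Genes x tissues numeric matrix; all-constant rows are flagged because
    their correlation-based similarity is undefined downstream."""

    genes: list[str]
    tissues: list[str]
    values: np.ndarray  # float64, shape (n_genes, n_tissues)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValueError("values shape does not match gene/tissue labels")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def constant_genes(self) -> set[str]:
        spread = self.values.max(axis=1) - self.values.min(axis=1)
        return {g for g, s in zip(self.genes, spread) if s == 0}

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def profile(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None


# ---------------------------------------------------------------------------
# mutation table

_STATUS_TOKENS = {"0": WILDTYPE, "1": MUTATED, "NA": NOT_SEQUENCED}


def _parse_status(token: str, lineno: int, path: Path) -> int:
    token = token.strip()
    if token not in _STATUS_TOKENS:
        raise FormatError(
            f"{path}:{lineno}: unknown status token {token!r} (expected 0, 1 or NA)"
        )
    return _STATUS_TOKENS[token]


def read_mutation_table(path: str | Path, assume_sequenced: bool = False) -> MutationMatrix:
    """Read a mutation table in the long (sample_id/gene_id/status) dialect or
    the wide matrix dialect (auto-detected from the header).

    Cells absent from a long file default to not_sequenced, or to wildtype
    when ``assume_sequenced`` is set (for sources listing only mutated cells).
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        if header[:3] == ["sample_id", "gene_id", "status"]:
            return _read_long_table(fh, path, assume_sequenced)
        if header[0] in ("sample_id", ""):
            return _read_wide_table(fh, header, path)
        raise FormatError(
            f"{path}: unrecognized header {header[:3]!r}; expected long "
            "'sample_id\\tgene_id\\tstatus' or wide 'sample_id\\t<gene>...'"
        )


def _read_long_table(fh, path: Path, assume_sequenced: bool) -> MutationMatrix:
    records: dict[tuple[str, str], int] = {}
    samples: list[str] = []
    genes: list[str] = []
    seen_samples: set[str] = set()
    seen_genes: set[str] = set()
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        sample, gene, token = parts[0], parts[1], parts[2]
        status = _parse_status(token, lineno, path)
        key = (sample, gene)
        if key in records:
            if records[key] != status:
                raise FormatError(
                    f"{path}:{lineno}: conflicting status for "
                    f"(sample={sample!r}, gene={gene!r})"
                )
            continue
        records[key] = status
        if sample not in seen_samples:
            seen_samples.add(sample)
            samples.append(sample)
        if gene not in seen_genes:
            seen_genes.add(gene)
            genes.append(gene)
    fill = WILDTYPE if assume_sequenced else NOT_SEQUENCED
    data = np.full((len(samples), len(genes)), fill, dtype=np.int8)
    sidx = {s: i for i, s in enumerate(samples)}
    gidx = {g: j for j, g in enumerate(genes)}
    for (sample, gene), status in records.items():
        data[sidx[sample], gidx[gene]] = status
    return MutationMatrix(samples, genes, data)


def _read_wide_table(fh, header: list[str], path: Path) -> MutationMatrix:
    genes = header[1:]
    samples: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(genes) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(genes) + 1} fields, got {len(parts)}"
            )
        samples.append(parts[0])
        rows.append([_parse_status(tok, lineno, path) for tok in parts[1:]])
    return MutationMatrix(samples, genes, np.array(rows, dtype=np.int8))


def write_mutation_table(matrix: MutationMatrix, path: str | Path) -> None:
    """Write the long dialect, one row per (sample, gene) cell."""
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tstatus\n")
        code = {NOT_SEQUENCED: "NA", WILDTYPE: "0", MUTATED: "1"}
        for i, sample in enumerate(matrix.samples):
            for j, gene in enumerate(matrix.genes):
                fh.write(f"{sample}\t{gene}\t{code[int(matrix.data[i, j])]}\n")


# ---------------------------------------------------------------------------
# Pajek NET

_RELATION_TO_VALUE = {"co": 1, "anti": 2}
_VALUE_TO_RELATION = {1: "co", 2: "anti"}


def write_pajek(network, path: str | Path) -> None:
    """Write a CCA network in Pajek NET format.

    Vertex ids are 1-based and contiguous, labels quoted.  The edge relation
    is encoded as the Pajek edge value (1 = co, 2 = anti) since NET has no
    attribute block; the convention is stated in a header comment.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot write an empty network")
    nodes = list(network.nodes())
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write("% edge value encodes relation: 1 = co, 2 = anti\n")
        fh.write(f"*Vertices {len(nodes)}\n")
        for node in nodes:
            fh.write(f'{index[node]} "{node}"\n')
        fh.write("*Edges\n")
        for a, b, attrs in network.edges(data=True):
            value = _RELATION_TO_VALUE[attrs.get("relation", "co")]
            fh.write(f"{index[a]} {index[b]} {value}\n")


def read_pajek(path: str | Path):
    """Read a Pajek NET file into a CCA network.

    Edges without a value (or with value 1) are taken as co-occurring, value 2
    as anti-co-occurring.  Vertex indices must be 1-based and in range.
    """
    from .network import CCANetwork  # deferred: network builds on this module

    path = Path(path)
    net = CCANetwork()
    n_vertices: int | None = None
    section = None
    labels: dict[int, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise FormatError(f"{path}:{lineno}: malformed *Vertices header")
                n_vertices = int(parts[1])
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                if n_vertices is None:
                    raise FormatError(f"{path}:{lineno}: *Edges before *Vertices")
                section = "edges"
                continue
            if line.startswith("*"):
                raise FormatError(f"{path}:{lineno}: unsupported section {line!r}")
            if section == "vertices":
                idx_str, _, rest = line.partition(" ")
                try:
                    idx = int(idx_str)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad vertex index") from None
                if not 1 <= idx <= (n_vertices or 0):
                    raise FormatError(f"{path}:{lineno}: vertex index {idx} out of range")
                label = rest.strip()
                if label.startswith('"'):
                    label = label[1:].split('"', 1)[0]
                else:
                    label = label.split()[0] if label.split() else str(idx)
                labels[idx] = label
                net.add_node(label)
            elif section == "edges":
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: malformed edge line")
                try:
                    a, b = int(parts[0]), int(parts[1])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad edge endpoints") from None
                for idx in (a, b):
                    if not 1 <= idx <= (n_vertices or 0):
                        raise FormatError(
                            f"{path}:{lineno}: vertex index {idx} out of range"
                        )
                    if idx not in labels:
                        # Pajek allows an empty vertex block; synthesize labels
                        labels[idx] = str(idx)
                        net.add_node(labels[idx])
                relation = "co"
                if len(parts) >= 3:
                    try:
                        value = int(float(parts[2]))
                    except ValueError:
                        raise FormatError(f"{path}:{lineno}: bad edge value") from None
                    relation = _VALUE_TO_RELATION.get(value, "co")
                net.add_edge(labels[a], labels[b], relation=relation)
            else:
                raise FormatError(f"{path}:{lineno}: content outside any section")
    if n_vertices is None:
        raise FormatError(f"{path}: missing *Vertices header")
    # vertices declared but not listed still count as nodes
    for idx in range(1, n_vertices + 1):
        if idx not in labels:
            net.add_node(str(idx))
    return net


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets_gmt(path: str | Path) -> PathwayCollection:
    """Read GMT gene sets: name, description, then member genes, tab-separated.

    Duplicate members are stored once; sets empty after de-duplication are
    dropped with a warning; blank lines are skipped.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (name, description, genes)"
                )
            name, description = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                warnings.warn(f"{path}:{lineno}: set {name!r} empty after dedup, dropped")
                continue
            sets[name] = members
            descriptions[name] = description
    return PathwayCollection(sets=sets, descriptions=descriptions)


def write_gene_sets_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.sets.items():
            desc = pathways.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# signaling network


def read_signaling_network(path: str | Path) -> SignalingNetwork:
    """Read a TSV of source/target/type links; duplicated identical rows are
    de-duplicated with a warning."""
    path = Path(path)
    links: list[SignalingLink] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "type"]:
            raise FormatError(f"{path}: expected header source/target/type")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            source, target, link_type = parts[0], parts[1], parts[2]
            if link_type not in LINK_TYPES:
                raise FormatError(
                    f"{path}:{lineno}: unknown link type {link_type!r}"
                )
            key = (source, target, link_type)
            if key in seen:
                warnings.warn(f"{path}:{lineno}: duplicate link {key}, de-duplicated")
                continue
            seen.add(key)
            links.append(SignalingLink(source, target, link_type))
    return SignalingNetwork(links=links)


def write_signaling_network(network: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttype\n")
        for link in network.links:
            fh.write(f"{link.source}\t{link.target}\t{link.type}\n")


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x tissues TSV with a numeric body.

    Non-numeric or missing cells raise with (gene, tissue) coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no tissue columns")
    values = np.empty(frame.shape, dtype=float)
    for j, tissue in enumerate(frame.columns):
        converted = pd.to_numeric(frame.iloc[:, j], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = frame.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, tissue {tissue!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(
        genes=[str(g) for g in frame.index],
        tissues=[str(t) for t in frame.columns],
        values=values,
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(expr.values, index=expr.genes, columns=expr.tissues)
    frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene metadata, gene lists, module labels


def read_gene_metadata(path: str | Path) -> dict[str, GeneMetadata]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "length_bp", "exon_count"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, GeneMetadata] = {}
    for _, row in frame.iterrows():
        gene = row["gene_id"]
        if gene in out:
            raise FormatError(f"{path}: duplicate gene_id {gene!r}")
        out[gene] = GeneMetadata(
            gene_id=gene,
            length_bp=int(row["length_bp"]),
            exon_count=int(row["exon_count"]),
            location=row.get("location", "unknown") or "unknown",
        )
    return out


def write_gene_metadata(metadata: Mapping[str, GeneMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_bp\texon_count\tlocation\n")
        for gene, meta in metadata.items():
            fh.write(f"{gene}\t{meta.length_bp}\t{meta.exon_count}\t{meta.location}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines skipped; order preserved, de-duplicated."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if gene and gene not in seen:
                seen.add(gene)
                out.append(gene)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def read_module_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV gene_id<TAB>module label."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "module"]:
            raise FormatError(f"{path}: expected header gene_id/module")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


def write_module_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmodule\n")
        for gene, module in labels.items():
            fh.write(f"{gene}\t{module}\n")
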
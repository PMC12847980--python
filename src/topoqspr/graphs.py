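"""Hydrogen-suppressed molecular graphs and their edge-degree partitions.

A molecule is modelled as a simple connected undirected graph whose vertices
are the heavy (non-hydrogen) atoms and whose edges are bonds; bond order is
ignored, so a double or aromatic bond contributes a single edge.  For every
degree-based, edge-additive topological index the *edge-degree partition* —
the tally of edges by the unordered pair of endpoint degrees ``(a, b)`` — is a
sufficient statistic, so partitions may also be supplied directly without a
realising graph.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GraphValidationError",
    "ConnectivityError",
    "MolecularGraph",
    "DegreePartition",
    "build_graph",
    "vertex_degrees",
    "edge_degree_partition",
    "partition_from_counts",
    "read_edge_list",
    "graph_from_smiles",
]

#: All partitions of the embedded study use degrees 1..4 (carbon skeletons);
#: larger degrees are legal but unusual for organic molecules.
TYPICAL_MAX_DEGREE = 4


class GraphValidationError(ValueError):
    """A supplied edge list or partition violates the simple-graph model."""


class ConnectivityError(GraphValidationError):
    """The graph is not connected, i.e. does not describe a single molecule."""

    def __init__(self, components: Sequence[frozenset]):
        self.components = [frozenset(c) for c in components]
        parts = "; ".join(
            "{" + ", ".join(map(str, sorted(c, key=str))) + "}" for c in self.components
        )
        super().__init__(
            f"graph is disconnected: {len(self.components)} components: {parts}"
        )


@dataclass(frozen=True)
class MolecularGraph:
    """A validated simple, connected, hydrogen-suppressed molecular graph.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`.  Vertex identifiers are
        opaque; they never enter any index computation.
    element_labels
        Optional map from vertex id to atomic symbol.  Annotation only.
    """

    graph: nx.Graph
    element_labels: Mapping[object, str] | None = None

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict:
        return dict(self.graph.degree())

    def relabel(self, mapping: Mapping) -> "MolecularGraph":
        """Return a copy with vertices renamed; index values are unaffected."""
        labels = None
        if self.element_labels is not None:
            labels = {mapping[v]: s for v, s in self.element_labels.items()}
        return MolecularGraph(nx.relabel_nodes(self.graph, dict(mapping)), labels)


@dataclass(frozen=True)
class DegreePartition:
    """Edge tally by unordered endpoint-degree pair, keys canonical ``a <= b``."""

    counts: Mapping[tuple[int, int], int]
    edge_total: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "counts", dict(self.counts))
        total = sum(self.counts.values())
        if self.edge_total and self.edge_total != total:
            raise GraphValidationError(
                f"edge_total {self.edge_total} != sum of counts {total}"
            )
        object.__setattr__(self, "edge_total", total)

    def items(self):
        return self.counts.items()

    def __add__(self, other: "DegreePartition") -> "DegreePartition":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return DegreePartition(dict(merged))

    def scaled(self, k: int) -> "DegreePartition":
        """Partition of k disjoint copies (counts multiplied by k)."""
        return DegreePartition({p: c * k for p, c in self.counts.items()})


def build_graph(
    edge_list: Iterable[tuple],
    element_labels: Mapping | None = None,
    max_degree_warn: int = TYPICAL_MAX_DEGREE,
) -> MolecularGraph:
    """Build and validate a molecular graph from an edge list.

    Raises
    ------
    GraphValidationError
        On an empty edge list, a self-loop, or a duplicate edge.
    ConnectivityError
        If the resulting graph has more than one connected component; the
        error carries the vertex sets of the components.
    """
    edges = [tuple(e) for e in edge_list]
    if not edges:
        raise GraphValidationError("edge list is empty")
    g = nx.Graph()
    for e in edges:
        if len(e) != 2:
            raise GraphValidationError(f"edge {e!r} does not have two endpoints")
        u, v = e
        if u == v:
            raise GraphValidationError(f"self-loop at vertex {u!r}")
        if g.has_edge(u, v):
            raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
        g.add_edge(u, v)
    if not nx.is_connected(g):
        raise ConnectivityError(list(nx.connected_components(g)))
    dmax = max(d for _, d in g.degree())
    if dmax > max_degree_warn:
        warnings.warn(
            f"maximum degree {dmax} exceeds {max_degree_warn}; unusual for a "
            "hydrogen-suppressed organic molecule",
            stacklevel=2,
        )
    return MolecularGraph(g, element_labels)


def vertex_degrees(g: MolecularGraph) -> dict:
    """Degree of every vertex; the degree sum equals twice the edge count."""
    return g.degrees()


def edge_degree_partition(g: MolecularGraph) -> DegreePartition:
    """Tally every edge by the sorted pair of its endpoint degrees."""
    deg = g.graph.degree
    counts = Counter()
    for u, v in g.graph.edges():
        a, b = deg[u], deg[v]
        counts[(min(a, b), max(a, b))] += 1
    return DegreePartition(dict(counts))


def partition_from_counts(raw: Mapping[tuple[int, int], int]) -> DegreePartition:
    """Canonicalise and validate a directly supplied edge-degree partition.

    Keys are reoriented to ``a <= b``; counts for the two orientations of the
    same pair are merged.  Zero counts are dropped.
    """
    counts: Counter = Counter()
    for key, c in raw.items():
        a, b = key
        if int(a) != a or int(b) != b or a < 1 or b < 1:
            raise GraphValidationError(f"degree pair {key!r} must have degrees >= 1")
        if int(c) != c or c < 0:
            raise GraphValidationError(f"count for {key!r} must be a nonnegative integer")
        if c:
            counts[(min(int(a), int(b)), max(int(a), int(b)))] += int(c)
    if not counts:
        raise GraphValidationError("partition has no edges")
    return DegreePartition(dict(counts))


def read_edge_list(path) -> MolecularGraph:
    """Read the one-edge-per-line text format.

    Each non-blank line holds two whitespace-separated vertex tokens; ``#``
    starts a comment that runs to the end of the line.
    """
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            tokens = body.split()
            if len(tokens) != 2:
                raise GraphValidationError(
                    f"{path}:{ln}: expected two vertex tokens, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    return build_graph(edges)


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph (requires rdkit)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("graph_from_smiles requires the optional rdkit dependency") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphValidationError(f"could not parse SMILES {smiles!r}")
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    labels = {a.GetIdx(): a.GetSymbol() for a in mol.GetAtoms()}
    return build_graph(edges, element_labels=labels)
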
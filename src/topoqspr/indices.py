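"""Ten degree-based topological indices computed from edge-degree partitions.

Every index here is edge-additive: it is a sum over bonds of a term that
depends only on the degrees ``(a, b)`` of the bond's endpoints.  The first
Zagreb index M1 and the forgotten index F are classically defined as vertex
sums (sum of d^2 and d^3 respectively); their edge forms ``a + b`` and
``a^2 + b^2`` are algebraically identical, since each vertex term is counted
once per incident edge.

The SS ("Schultz second") index ships in two variants because its textbook
definition Σ 1/(a+b)^2 does not agree with published QSPR result tables that
are instead reproduced exactly by Σ √(ab/(a+b)).  The ``table_consistent``
variant is the default throughout the pipeline;
:func:`infer_edge_contributions` is the solver used to reverse-engineer the
per-pair contribution from a set of partitions and printed index values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .graphs import DegreePartition, MolecularGraph, edge_degree_partition

__all__ = [
    "INDEX_IDS",
    "IndexVector",
    "edge_contribution",
    "compute_index",
    "compute_index_vertexform",
    "ss_variant",
    "compute_all",
    "infer_edge_contributions",
    "round_half_away",
]

#: Fixed identifiers, in the column order of the study's index table.
INDEX_IDS = ("M1", "M2", "H", "F", "SS", "ABC", "RI", "SC", "GA", "HZ")

#: Indices whose value is an integer whenever all degrees are integers.
INTEGER_VALUED = frozenset({"M1", "M2", "F", "HZ"})

SS_VARIANTS = ("table_consistent", "definition10")


def round_half_away(x: float, ndigits: int = 4) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ss_table_consistent(a: float, b: float) -> float:
    return math.sqrt(a * b / (a + b))


def _ss_definition10(a: float, b: float) -> float:
    return 1.0 / (a + b) ** 2


_CONTRIBUTIONS = {
    "RI": lambda a, b: 1.0 / math.sqrt(a * b),
    "H": lambda a, b: 2.0 / (a + b),
    "M1": lambda a, b: float(a + b),
    "M2": lambda a, b: float(a * b),
    "F": lambda a, b: float(a * a + b * b),
    "ABC": lambda a, b: math.sqrt((a + b - 2) / (a * b)),
    "GA": lambda a, b: 2.0 * math.sqrt(a * b) / (a + b),
    "SC": lambda a, b: 1.0 / math.sqrt(a + b),
    "HZ": lambda a, b: float(a + b) ** 2,
}


@dataclass(frozen=True)
class IndexVector:
    """The ten index values of one molecule, keyed by the ids in INDEX_IDS."""

    values: Mapping[str, float]

    def __getitem__(self, index_id: str) -> float:
        return self.values[index_id]

    def rounded(self, ndigits: int = 4) -> dict:
        return {k: round_half_away(v, ndigits) for k, v in self.values.items()}


def edge_contribution(index_id: str, a: int, b: int, ss_variant: str = "table_consistent") -> float:
    """Per-edge term of an index for an edge with endpoint degrees a, b."""
    if a < 1 or b < 1:
        raise ValueError(f"degrees must be >= 1, got ({a}, {b})")
    if index_id == "SS":
        if ss_variant == "table_consistent":
            return _ss_table_consistent(a, b)
        if ss_variant == "definition10":
            return _ss_definition10(a, b)
        raise ValueError(f"unknown SS variant {ss_variant!r}; choose from {SS_VARIANTS}")
    try:
        return _CONTRIBUTIONS[index_id](a, b)
    except KeyError:
        raise KeyError(
            f"unknown index id {index_id!r}; valid ids are {', '.join(INDEX_IDS)}"
        ) from None


def compute_index(
    index_id: str,
    partition: DegreePartition | MolecularGraph,
    ss_variant: str = "table_consistent",
) -> float:
    """Sum of per-edge contributions weighted by the partition counts."""
    if isinstance(partition, MolecularGraph):
        partition = edge_degree_partition(partition)
    return sum(
        c * edge_contribution(index_id, a, b, ss_variant=ss_variant)
        for (a, b), c in partition.items()
    )


def compute_index_vertexform(index_id: str, degrees: Sequence[int]) -> float:
    """M1 and F in their vertex-sum forms: Σ d^2 and Σ d^3."""
    if index_id == "M1":
        return float(sum(d * d for d in degrees))
    if index_id == "F":
        return float(sum(d * d * d for d in degrees))
    raise KeyError(f"vertex form is defined only for M1 and F, not {index_id!r}")


def ss_variant(partition: DegreePartition, variant: str = "table_consistent") -> float:
    """SS index under a named variant; see the module docstring."""
    if variant not in SS_VARIANTS:
        raise ValueError(f"unknown SS variant {variant!r}; choose from {SS_VARIANTS}")
    return compute_index("SS", partition, ss_variant=variant)


def compute_all(
    partition: DegreePartition | MolecularGraph,
    ss: str = "table_consistent",
) -> IndexVector:
    """All ten indices of one molecule."""
    if isinstance(partition, MolecularGraph):
        partition = edge_degree_partition(partition)
    if partition.edge_total == 0:
        raise ValueError("partition has no edges")
    return IndexVector(
        {iid: compute_index(iid, partition, ss_variant=ss) for iid in INDEX_IDS}
    )


def infer_edge_contributions(
    partitions: Sequence[DegreePartition],
    index_values: Sequence[float],
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], bool]]:
    """Solve for per-pair edge contributions from observed index values.

    Treats the unknown per-edge term f(a, b) of an edge-additive index as a
    vector of unknowns (one per degree pair occurring in any partition) and
    solves the linear system ``Σ_pairs count * f(a,b) = value`` across
    molecules by least squares (minimum-norm solution when the system is
    rank-deficient).

    Returns
    -------
    solution, identifiable
        ``solution`` maps each occurring pair to its fitted contribution;
        ``identifiable[pair]`` is True when the pair's contribution is
        uniquely determined by the system, i.e. its coordinate direction is
        orthogonal to the null space of the design matrix.  Pairs that occur
        only in linear combination with others (in a single molecule, say)
        are reported but flagged non-identifiable.
    """
    if len(partitions) != len(index_values):
        raise ValueError("need one index value per partition")
    pairs = sorted({p for part in partitions for p, _ in part.items()})
    a_mat = np.array(
        [[part.counts.get(p, 0) for p in pairs] for part in partitions], dtype=float
    )
    y = np.asarray(index_values, dtype=float)
    sol, *_ = np.linalg.lstsq(a_mat, y, rcond=None)

    # null-space test for identifiability of each coordinate
    _, s, vt = np.linalg.svd(a_mat)
    tol = max(a_mat.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    null_basis = vt[sum(s > tol):]
    ident = {
        p: bool(np.all(np.abs(null_basis[:, j]) < 1e-10)) if null_basis.size else True
        for j, p in enumerate(pairs)
    }
    return dict(zip(pairs, sol.tolist())), ident
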
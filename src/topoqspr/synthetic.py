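"""Chemistry-like random graphs and simulated index-property studies.

The generator emulates the structure of the embedded study: small connected
hydrogen-suppressed graphs with degrees capped at 4 (trees plus at most a
couple of ring closures, which covers the study's compound class — every one
of its nine molecules is a tree or unicyclic), and a property response that
is a low-order function of one topological index plus Gaussian noise.

Default generating coefficients mirror the magnitude of the study's molar
volume ~ Randić index quadratic fit, its strongest relation; the default
noise level matches that fit's residual scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .graphs import DegreePartition, MolecularGraph, build_graph, edge_degree_partition
from .indices import IndexVector, compute_all

__all__ = [
    "GenerationError",
    "SyntheticSpec",
    "SyntheticStudy",
    "random_chemlike_graph",
    "simulate_property",
    "generate_study",
]


class GenerationError(RuntimeError):
    """Graph generation is infeasible under the requested constraints."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated study.

    ``ring_edges`` is an inclusive (low, high) range of extra ring-closing
    edges per molecule.  ``index_id`` names the index that drives the
    response; ``alpha``, ``beta``, ``gamma`` are the generating coefficients
    of ``response_form`` and ``sigma`` the noise standard deviation.
    """

    n_molecules: int = 9
    size_range: tuple[int, int] = (5, 20)
    max_degree: int = 4
    ring_edges: tuple[int, int] = (0, 2)
    index_id: str = "RI"
    response_form: str = "quadratic"
    alpha: float = -9.1
    beta: float = 32.2
    gamma: float = -0.45
    sigma: float = 13.0
    seed: int = 0

    def __post_init__(self):
        if self.size_range[0] < 2:
            raise ValueError("minimum molecule size is 2 heavy atoms")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.max_degree < 2:
            raise ValueError("max_degree must be at least 2")
        if self.response_form not in ("linear", "quadratic", "logarithmic"):
            raise ValueError(f"unknown response form {self.response_form!r}")

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


def random_chemlike_graph(n_vertices: int, max_degree: int = 4,
                          ring_edges: int = 0,
                          rng: np.random.Generator | None = None) -> MolecularGraph:
    """Random connected simple graph with a degree cap.

    Built as a random tree by uniform attachment to vertices with spare
    degree capacity, then ``ring_edges`` extra edges between non-adjacent
    vertex pairs that both still have capacity.
    """
    if n_vertices < 2:
        raise GenerationError("need at least 2 vertices")
    if max_degree < 1 or (max_degree == 1 and n_vertices > 2):
        raise GenerationError(
            f"max_degree {max_degree} cannot support a connected graph on "
            f"{n_vertices} vertices"
        )
    rng = np.random.default_rng() if rng is None else rng
    degree = np.zeros(n_vertices, dtype=int)
    edges: list[tuple[int, int]] = [(0, 1)]
    degree[[0, 1]] = 1
    for v in range(2, n_vertices):
        open_slots = np.flatnonzero(degree[:v] < max_degree)
        if open_slots.size == 0:
            raise GenerationError(
                f"no vertex with spare capacity while attaching vertex {v} "
                f"(max_degree={max_degree})"
            )
        u = int(rng.choice(open_slots))
        edges.append((u, v))
        degree[u] += 1
        degree[v] = 1
    adjacent = set(edges)
    for _ in range(ring_edges):
        capable = np.flatnonzero(degree < max_degree)
        candidates = [
            (int(u), int(v))
            for i, u in enumerate(capable)
            for v in capable[i + 1:]
            if (u, v) not in adjacent
        ]
        if not candidates:
            raise GenerationError("no non-adjacent vertex pair with spare capacity left")
        u, v = candidates[int(rng.integers(len(candidates)))]
        edges.append((u, v))
        adjacent.add((u, v))
        degree[u] += 1
        degree[v] += 1
    return build_graph(edges)


def simulate_property(index_values: Sequence[float], spec: SyntheticSpec,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the property response for given index values under ``spec``."""
    t = np.asarray(index_values, dtype=float)
    if spec.response_form == "logarithmic":
        if np.any(t <= 0):
            raise ValueError("logarithmic response requires positive index values")
        mean = spec.alpha + spec.beta * np.log(t)
    elif spec.response_form == "quadratic":
        mean = spec.alpha + spec.beta * t + spec.gamma * t * t
    else:
        mean = spec.alpha + spec.beta * t
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    return mean + rng.normal(0.0, spec.sigma, size=t.shape)


@dataclass
class SyntheticStudy:
    """One simulated dataset, shaped like the embedded study."""

    spec: SyntheticSpec
    graphs: list[MolecularGraph]
    partitions: list[DegreePartition]
    index_vectors: list[IndexVector]
    responses: np.ndarray = field(repr=False)

    def index_frame(self):
        import pandas as pd

        from .indices import INDEX_IDS

        return pd.DataFrame(
            [{iid: iv[iid] for iid in INDEX_IDS} for iv in self.index_vectors],
            index=[f"mol{i}" for i in range(len(self.index_vectors))],
        )

    def property_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"P": self.responses}, index=[f"mol{i}" for i in range(len(self.responses))]
        )


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """End-to-end simulated study: graphs, partitions, indices, responses.

    Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    graphs, partitions, vectors = [], [], []
    for _ in range(spec.n_molecules):
        n = int(rng.integers(lo, hi + 1))
        rings = int(rng.integers(spec.ring_edges[0], spec.ring_edges[1] + 1))
        for attempt in range(20):
            try:
                g = random_chemlike_graph(n, spec.max_degree, rings, rng)
                break
            except GenerationError:
                if attempt == 19:
                    raise
        graphs.append(g)
        p = edge_degree_partition(g)
        partitions.append(p)
        vectors.append(compute_all(p))
    t = [iv[spec.index_id] for iv in vectors]
    responses = simulate_property(t, spec, rng)
    return SyntheticStudy(spec, graphs, partitions, vectors, responses)
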
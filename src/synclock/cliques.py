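"""Clique-based clustering of species from an SI distance matrix.

Species are nodes of a threshold graph with an edge whenever the SI distance
is strictly below the threshold ``tau``; groups of closely related species
are found by iteratively extracting a maximum clique, keeping it when it has
at least ``min_size`` members, removing its nodes and repeating.  Ties among
equal-size maximum cliques are broken by the lexicographically smallest
sorted member tuple so the partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .containers import DistanceMatrix


@dataclass(frozen=True)
class CliqueConfig:
    """SI-distance threshold (default 0.95) and minimum clique size (default 6,
    i.e. cliques of more than five species are retained)."""

    tau: float = 0.95
    min_size: int = 6

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")


@dataclass(frozen=True)
class CliquePartition:
    """Disjoint retained cliques plus the species assigned to none of them."""

    cliques: tuple[tuple[str, tuple[str, ...]], ...]
    unassigned: tuple[str, ...]

    def membership(self) -> dict[str, str | None]:
        """Map every species to its clique id (``None`` when unassigned)."""
        out: dict[str, str | None] = {s: None for s in self.unassigned}
        for cid, members in self.cliques:
            for s in members:
                out[s] = cid
        return out

    def members(self, clique_id: str) -> tuple[str, ...]:
        for cid, mem in self.cliques:
            if cid == clique_id:
                return mem
        raise KeyError(f"no clique {clique_id!r}")


def threshold_graph(m: DistanceMatrix, tau: float) -> nx.Graph:
    """Graph on the matrix labels with an edge iff distance < ``tau`` (strict)."""
    g = nx.Graph()
    g.add_nodes_from(m.labels)
    for a, b, d in m.iter_pairs():
        if d < tau:
            g.add_edge(a, b)
    return g


def _maximum_clique(graph: nx.Graph) -> list[str]:
    """Largest clique; ties broken by lexicographically smallest sorted tuple.

    Exact on the graph sizes this package works with (maximal-clique
    enumeration); determinism is required so partitions are reproducible.
    """
    best: tuple[int, tuple[str, ...]] | None = None
    for clique in nx.find_cliques(graph):
        key = (len(clique), tuple(sorted(clique)))
        if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
            best = key
    assert best is not None
    return list(best[1])


def extract_cliques(graph: nx.Graph, config: CliqueConfig = CliqueConfig()) -> CliquePartition:
    """Iteratively extract maximum cliques of at least ``min_size`` members."""
    work = graph.copy()
    cliques: list[tuple[str, tuple[str, ...]]] = []
    idx = 0
    while work.number_of_nodes() >= config.min_size:
        clique = _maximum_clique(work)
        if len(clique) < config.min_size:
            break
        idx += 1
        cliques.append((f"C{idx}", tuple(sorted(clique))))
        work.remove_nodes_from(clique)
    unassigned = tuple(sorted(work.nodes))
    return CliquePartition(tuple(cliques), unassigned)


def cluster_species(m: DistanceMatrix, config: CliqueConfig = CliqueConfig()) -> CliquePartition:
    """Convenience wrapper: threshold graph + iterative clique extraction."""
    return extract_cliques(threshold_graph(m, config.tau), config)
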
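"""Detection of 16S horizontal-gene-transfer candidates via outlier stars.

A pair whose point-mutation distance exceeds ``factor`` times the value
predicted by the phase-transition curve at its SI distance is an outlier.
Within each clique the outlier pairs form a "clique-outliers graph"; a
species whose 16S was acquired from outside the clique shows up as a star —
one node carrying most of the outlier edges.  Star significance is assessed
against the uniform random-graph null G(n, m) with the same number of nodes
and edges: the p-value is the probability that any node reaches the observed
maximum degree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .twoclock import ExponentialFit

#: largest number of edge subsets enumerated exactly; beyond this, Monte Carlo
EXACT_ENUMERATION_LIMIT = 10 ** 6


@dataclass(frozen=True)
class OutlierConfig:
    """Outlier multiplier (default 1.7 ≈ two standard errors of P_PM around the
    fitted curve), significance level, and the null-model evaluation method."""

    factor: float = 1.7
    alpha: float = 0.05
    null_method: str = "auto"
    mc_samples: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if self.factor <= 1:
            raise ValueError("factor must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.null_method not in ("auto", "exact", "monte_carlo"):
            raise ValueError(f"bad null_method {self.null_method!r}")
        if self.mc_samples < 100:
            raise ValueError("mc_samples must be >= 100")


@dataclass(frozen=True)
class OutlierGraph:
    """Outlier pairs within one clique (nodes are the clique members)."""

    clique_id: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) outside clique {self.clique_id!r}")

    def degrees(self) -> dict[str, int]:
        deg = {s: 0 for s in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass(frozen=True)
class StarTestResult:
    clique_id: str
    center: str
    degree: int
    n_nodes: int
    n_edges: int
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# outlier flagging and per-clique graphs


def flag_outliers(table: pd.DataFrame, fit: ExponentialFit,
                  config: OutlierConfig = OutlierConfig()) -> pd.DataFrame:
    """Rows with ``ppm_distance > factor * A * exp(B * si_distance)`` (strict)."""
    expected = fit.A * np.exp(fit.B * table["si_distance"].to_numpy(dtype=float))
    mask = table["ppm_distance"].to_numpy(dtype=float) > config.factor * expected
    return table[mask].copy()


def build_clique_outlier_graph(clique_id: str, members: tuple[str, ...],
                               outlier_rows: pd.DataFrame) -> OutlierGraph:
    """Graph on the clique members whose edges are the flagged pairs within it."""
    member_set = set(members)
    edges = []
    for row in outlier_rows.itertuples(index=False):
        if row.genome_a in member_set and row.genome_b in member_set:
            edges.append((row.genome_a, row.genome_b))
    return OutlierGraph(clique_id, tuple(members), tuple(edges))


# ---------------------------------------------------------------------------
# star significance under the G(n, m) null


@lru_cache(maxsize=None)
def _pair_index(n_nodes: int) -> tuple[tuple[int, int], ...]:
    return tuple(itertools.combinations(range(n_nodes), 2))


@lru_cache(maxsize=None)
def _maxdeg_counts_by_edges(n_nodes: int) -> np.ndarray:
    """``counts[m, d]``: number of labelled graphs on ``n_nodes`` with ``m``
    edges and maximum degree ``d``, by vectorised enumeration of all edge
    subsets (bitmask per subset, popcount per node incidence mask)."""
    pairs = _pair_index(n_nodes)
    n_pairs = len(pairs)
    node_mask = np.zeros(n_nodes, dtype=np.uint64)
    for e, (u, v) in enumerate(pairs):
        node_mask[u] |= np.uint64(1 << e)
        node_mask[v] |= np.uint64(1 << e)
    masks = np.arange(1 << n_pairs, dtype=np.uint64)
    m = np.bitwise_count(masks).astype(np.int64)
    maxdeg = np.zeros(len(masks), dtype=np.int64)
    for v in range(n_nodes):
        np.maximum(maxdeg, np.bitwise_count(masks & node_mask[v]).astype(np.int64),
                   out=maxdeg)
    counts = np.zeros((n_pairs + 1, n_nodes), dtype=np.int64)
    np.add.at(counts, (m, maxdeg), 1)
    return counts


@lru_cache(maxsize=None)
def _exact_tail(n_nodes: int, n_edges: int) -> tuple[float, ...]:
    """P(max degree >= d) for d = 0..n_nodes-1 by exhaustive enumeration."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    counts = np.zeros(n_nodes, dtype=np.int64)  # counts[d] = #graphs with maxdeg == d
    if n_pairs <= 22:
        counts = _maxdeg_counts_by_edges(n_nodes)[n_edges].copy()
    elif n_edges == 0:
        counts[0] = 1
    else:
        pairs = _pair_index(n_nodes)
        deg = np.zeros(n_nodes, dtype=np.int64)
        for combo in itertools.combinations(range(len(pairs)), n_edges):
            deg[:] = 0
            for e in combo:
                u, v = pairs[e]
                deg[u] += 1
                deg[v] += 1
            counts[deg.max()] += 1
    total = counts.sum()
    tail = np.cumsum(counts[::-1])[::-1] / total
    return tuple(float(x) for x in tail)


@lru_cache(maxsize=None)
def _mc_maxdeg_counts(n_nodes: int, n_edges: int, samples: int,
                      seed: int | None) -> tuple[int, ...]:
    """Histogram of the maximum degree over ``samples`` uniform G(n, m) draws."""
    pairs = np.array(_pair_index(n_nodes))
    n_pairs = len(pairs)
    rng = np.random.default_rng(seed)
    incidence = np.zeros((n_pairs, n_nodes))
    incidence[np.arange(n_pairs), pairs[:, 0]] = 1
    incidence[np.arange(n_pairs), pairs[:, 1]] = 1
    counts = np.zeros(n_nodes + 1, dtype=np.int64)
    chunk = max(1, min(samples, 20_000))
    done = 0
    while done < samples:
        s = min(chunk, samples - done)
        u = rng.random((s, n_pairs))
        idx = np.argpartition(u, n_edges - 1, axis=1)[:, :n_edges] if n_edges else None
        if n_edges:
            mask = np.zeros((s, n_pairs))
            np.put_along_axis(mask, idx, 1.0, axis=1)
            maxdeg = (mask @ incidence).max(axis=1).astype(np.int64)
        else:
            maxdeg = np.zeros(s, dtype=np.int64)
        counts += np.bincount(maxdeg, minlength=n_nodes + 1)
        done += s
    return tuple(int(x) for x in counts)


def star_pvalue(n_nodes: int, n_edges: int, degree_observed: int,
                config: OutlierConfig = OutlierConfig()) -> float:
    """P(max degree >= degree_observed) in a uniform random graph G(n, m).

    Exact by exhaustive enumeration of edge subsets when there are at most
    ``10**6`` of them (and ``null_method`` allows it); otherwise estimated by
    Monte Carlo with ``config.mc_samples`` reproducible draws.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_nodes < 2 or not 0 <= n_edges <= max_edges:
        raise ValueError(f"infeasible graph: {n_nodes} nodes, {n_edges} edges")
    if not 0 <= degree_observed <= n_nodes - 1:
        raise ValueError(f"infeasible degree {degree_observed} for {n_nodes} nodes")
    if degree_observed == 0:
        return 1.0
    if degree_observed > n_edges:
        return 0.0

    n_subsets = math.comb(max_edges, n_edges)
    use_exact = config.null_method == "exact" or (
        config.null_method == "auto" and n_subsets <= EXACT_ENUMERATION_LIMIT
    )
    if use_exact:
        if n_subsets > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration infeasible: C({max_edges},{n_edges}) = {n_subsets}"
            )
        return _exact_tail(n_nodes, n_edges)[degree_observed]
    counts = np.array(_mc_maxdeg_counts(n_nodes, n_edges, config.mc_samples, config.seed))
    return float(counts[degree_observed:].sum() / counts.sum())


def detect_stars(graphs: list[OutlierGraph],
                 config: OutlierConfig = OutlierConfig()) -> list[StarTestResult]:
    """Test the maximum-degree node of every non-empty clique-outliers graph.

    All nodes tied at the maximum degree are reported (with the same
    p-value); graphs without edges yield no rows.
    """
    results: list[StarTestResult] = []
    for graph in graphs:
        if not graph.edges:
            continue
        deg = graph.degrees()
        max_deg = max(deg.values())
        p = star_pvalue(len(graph.nodes), len(graph.edges), max_deg, config)
        for node in sorted(d for d in deg if deg[d] == max_deg):
            results.append(StarTestResult(
                clique_id=graph.clique_id,
                center=node,
                degree=max_deg,
                n_nodes=len(graph.nodes),
                n_edges=len(graph.edges),
                p_value=p,
                significant=p < config.alpha,
            ))
    return results
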
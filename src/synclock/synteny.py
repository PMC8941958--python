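"""Synteny Index (SI) distances between genomes based on gene-neighbourhood overlap.

For a gene ``g0`` shared by genomes ``A`` and ``B``, the SI similarity is the
number of labels common to the ``2k``-gene neighbourhoods of ``g0`` in the two
genomes, divided by ``2k`` (a Jaccard-style overlap with fixed denominator).
Genes present in only one genome score 0.  Averaging over the union of gene
labels and subtracting from 1 yields a symmetric distance in ``[0, 1]``.

Conventions (documented because the measure is sensitive to them):

- the focal gene's own label is excluded from its neighbourhood unless it also
  occurs at another position inside the window;
- duplicate labels within a genome are collapsed to their first occurrence,
  both as focal positions and as neighbourhood members (neighbourhoods are
  label sets);
- circular genomes wrap around; linear genomes truncate the window at the ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CIRCULAR, DistanceMatrix, GeneOrder, GenomeCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyParams:
    """Parameters of the SI computation.

    ``k`` is the neighbourhood half-width in genes (window covers ``k`` genes
    upstream and ``k`` downstream).  ``topology_override`` forces all genomes
    to be treated as circular or linear regardless of their own flag.
    """

    k: int = 10
    topology_override: str | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.topology_override not in (None, "circular", "linear"):
            raise ValueError(f"bad topology_override {self.topology_override!r}")

    def effective_topology(self, genome: GeneOrder) -> str:
        return self.topology_override or genome.topology

    def check_genome(self, genome: GeneOrder) -> None:
        if 2 * self.k >= genome.size:
            raise ValueError(
                f"genome {genome.genome_id!r}: window 2k={2 * self.k} would cover "
                f"the whole genome (size {genome.size})"
            )


@dataclass(frozen=True)
class GeneSIRecord:
    """Per-gene SI similarity (``0`` when the gene is absent from one genome)."""

    gene: str
    si_similarity: float


def neighborhood(genome: GeneOrder, position: int, k: int, topology: str | None = None) -> set[str]:
    """Labels of the ``k`` genes upstream and ``k`` downstream of ``position``.

    The focal label itself is excluded unless it also occurs at another
    position inside the window.  Circular genomes wrap; linear genomes
    truncate at the ends, so the result has at most ``2k`` labels.  Windows
    wider than the genome simply saturate (every other label); SI analyses
    additionally require ``2k < genome size`` via :class:`SyntenyParams`.
    """
    n = genome.size
    if not 0 <= position < n:
        raise IndexError(f"position {position} outside genome of size {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    topo = topology or genome.topology
    genes = genome.genes
    out: set[str] = set()
    if topo == CIRCULAR:
        for d in range(-k, k + 1):
            if d != 0:
                out.add(genes[(position + d) % n])
    else:
        for i in range(max(0, position - k), min(n, position + k + 1)):
            if i != position:
                out.add(genes[i])
    return out


def _first_occurrence_index(genome: GeneOrder) -> dict[str, int]:
    """Map each label to its first position, logging when duplicates collapse."""
    index: dict[str, int] = {}
    dup = 0
    for i, g in enumerate(genome.genes):
        if g in index:
            dup += 1
        else:
            index[g] = i
    if dup:
        logger.warning(
            "genome %r: %d duplicate gene labels collapsed to first occurrence",
            genome.genome_id, dup,
        )
    return index


def _neighborhoods(genome: GeneOrder, params: SyntenyParams) -> dict[str, set[str]]:
    """Neighbourhood set for every distinct label (at its first occurrence)."""
    params.check_genome(genome)
    topo = params.effective_topology(genome)
    return {
        g: neighborhood(genome, pos, params.k, topo)
        for g, pos in _first_occurrence_index(genome).items()
    }


def gene_si(g0: str, A: GeneOrder, B: GeneOrder, params: SyntenyParams) -> GeneSIRecord:
    """SI similarity of one gene with respect to two genomes."""
    params.check_genome(A)
    params.check_genome(B)
    ia = _first_occurrence_index(A)
    ib = _first_occurrence_index(B)
    if g0 not in ia or g0 not in ib:
        return GeneSIRecord(g0, 0.0)
    na = neighborhood(A, ia[g0], params.k, params.effective_topology(A))
    nb = neighborhood(B, ib[g0], params.k, params.effective_topology(B))
    return GeneSIRecord(g0, len(na & nb) / (2 * params.k))


def pairwise_si_distance(A: GeneOrder, B: GeneOrder, params: SyntenyParams) -> float:
    """Average-SI distance between two genomes: ``1 - mean similarity``.

    The mean runs over the union of gene labels of the two genomes; labels in
    only one genome contribute similarity 0, so the measure is symmetric by
    construction.
    """
    na = _neighborhoods(A, params)
    nb = _neighborhoods(B, params)
    return 1.0 - _mean_similarity(na, nb, params.k)


def _mean_similarity(na: dict[str, set[str]], nb: dict[str, set[str]], k: int) -> float:
    union = len(na.keys() | nb.keys())
    shared = na.keys() & nb.keys()
    total = 0
    for g in shared:
        total += len(na[g] & nb[g])
    return total / (2 * k * union)


def _packed_neighborhoods(genome: GeneOrder, params: SyntenyParams,
                          vocab: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Bit-packed neighbourhood membership over a shared label vocabulary.

    Returns ``(member, packed)`` where ``member[v]`` says whether vocabulary
    label ``v`` occurs in the genome and ``packed[v]`` is the bit-packed
    indicator row of its neighbourhood labels (all-zero for absent labels, so
    AND-and-popcount against another genome needs no masking).
    """
    hoods = _neighborhoods(genome, params)
    v = len(vocab)
    member = np.zeros(v, dtype=bool)
    dense = np.zeros((v, v), dtype=bool)
    for g, hood in hoods.items():
        gi = vocab[g]
        member[gi] = True
        dense[gi, [vocab[h] for h in hood]] = True
    return member, np.packbits(dense, axis=1)


def si_distance_matrix(collection: GenomeCollection, params: SyntenyParams) -> DistanceMatrix:
    """Full pairwise SI distance matrix, in the collection's label order.

    Equivalent to calling :func:`pairwise_si_distance` on every pair, but
    neighbourhoods are precomputed once per genome as bit-packed indicator
    rows so each pair reduces to an AND-and-popcount.
    """
    if len(collection) < 2:
        raise ValueError("need at least 2 genomes for a distance matrix")
    for genome in collection:
        params.check_genome(genome)
    vocab: dict[str, int] = {}
    for genome in collection:
        for g in genome.genes:
            vocab.setdefault(g, len(vocab))
    packed = {g.genome_id: _packed_neighborhoods(g, params, vocab) for g in collection}
    ids = collection.ids
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        mem_i, bits_i = packed[ids[i]]
        for j in range(i + 1, n):
            mem_j, bits_j = packed[ids[j]]
            union = int(np.count_nonzero(mem_i | mem_j))
            shared = int(np.bitwise_count(bits_i & bits_j).sum())
            d = 1.0 - shared / (2 * params.k * union)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)
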
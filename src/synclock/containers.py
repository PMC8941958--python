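"""Core in-memory containers: gene orders, aligned marker sequences, distance matrices.

A genome is represented purely by its gene order — an ordered tuple of
orthologous-group (COG) labels — because the gene-order clock only sees the
permutation, never the underlying sequence.  Marker (16S) sequences live in a
separate aligned set keyed by the same genome identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError

CIRCULAR = "circular"
LINEAR = "linear"

#: characters permitted in an aligned marker sequence
ALIGNMENT_ALPHABET = frozenset("ACGT-N")

#: numerical tolerance for declaring a stored matrix symmetric
SYMMETRY_ATOL = 1e-12


@dataclass(frozen=True)
class GeneOrder:
    """One genome as an ordered sequence of COG labels.

    Parameters
    ----------
    genome_id:
        Non-empty identifier, unique within a collection.
    genes:
        COG labels in genomic order.  Stored as a tuple; order is significant.
    topology:
        ``"circular"`` (default, bacterial chromosomes) or ``"linear"``.
    """

    genome_id: str
    genes: tuple[str, ...]
    topology: str = CIRCULAR

    def __post_init__(self):
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise ValueError(f"genome {self.genome_id!r}: gene list must be non-empty")
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(
                f"genome {self.genome_id!r}: topology must be "
                f"{CIRCULAR!r} or {LINEAR!r}, got {self.topology!r}"
            )

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR


class GenomeCollection:
    """An ordered mapping genome_id -> :class:`GeneOrder` with unique ids."""

    def __init__(self, genomes: Sequence[GeneOrder]):
        self._genomes: dict[str, GeneOrder] = {}
        for g in genomes:
            if g.genome_id in self._genomes:
                raise ValueError(f"duplicate genome_id {g.genome_id!r}")
            self._genomes[g.genome_id] = g

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._genomes)

    def __getitem__(self, genome_id: str) -> GeneOrder:
        return self._genomes[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._genomes

    def __len__(self) -> int:
        return len(self._genomes)

    def __iter__(self) -> Iterator[GeneOrder]:
        return iter(self._genomes.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeCollection):
            return NotImplemented
        return self._genomes == other._genomes

    def __repr__(self) -> str:
        return f"GenomeCollection({len(self)} genomes)"


class AlignedSequenceSet:
    """Aligned nucleotide sequences keyed by genome id.

    All sequences must share one alignment length and use only the characters
    ``A C G T - N``.  Input is uppercased on construction.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise AlignmentError("alignment contains no sequences")
        normalized: dict[str, str] = {}
        length: int | None = None
        for sid, seq in sequences.items():
            seq = str(seq).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains unsupported characters: {sorted(bad)}"
                )
            normalized[sid] = seq
        if length == 0:
            raise AlignmentError("alignment length is zero")
        self._sequences = normalized
        self.alignment_length: int = int(length)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._sequences)

    def __getitem__(self, sid: str) -> str:
        return self._sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._sequences

    def __len__(self) -> int:
        return len(self._sequences)

    def items(self):
        return self._sequences.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlignedSequenceSet):
            return NotImplemented
        return self._sequences == other._sequences

    def __repr__(self) -> str:
        return f"AlignedSequenceSet({len(self)} sequences, L={self.alignment_length})"


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise distances.

    Invariants enforced on construction: square, symmetric to ``1e-12``,
    zero diagonal, non-negative entries, unique labels.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite")
        if np.any(values < 0):
            raise ValueError("matrix entries must be non-negative")
        if np.max(np.abs(values - values.T), initial=0.0) > SYMMETRY_ATOL:
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(lbl) for lbl in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        """Yield each unordered pair (a, b, distance) with a before b in label order."""
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(str(x) for x in df.index), df.to_numpy(dtype=float))
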
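"""Readers and writers for gene-order files, aligned FASTA, distance matrices and pair tables.

File formats
------------
Gene-order file
    Plain text.  Each genome is a block starting with a header line
    ``>genome_id circular|linear`` followed by whitespace-separated COG labels
    in genomic order (any number of lines, until the next header).  A missing
    topology flag defaults to ``circular`` (bacterial chromosomes) with a
    logged warning.
Aligned FASTA
    Standard FASTA via Biopython; all records must have equal length.  Record
    ids are taken up to the first whitespace and sequences are uppercased.
Distance matrix
    Either TSV (header row and first column carry the labels) or PHYLIP
    square format (first line is the number of taxa, then one row per taxon:
    label followed by the full row of values).  Values survive a round trip
    to 12 significant digits.
Pair table
    TSV with columns ``genome_a, genome_b, si_distance, ppm_distance,
    clique_id`` (``clique_id`` empty when the pair is not within a clique).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import CIRCULAR, LINEAR, AlignedSequenceSet, DistanceMatrix, GeneOrder, GenomeCollection
from .errors import AlignmentError, ParseError

logger = logging.getLogger(__name__)

#: maximum tolerated asymmetry in a distance matrix read from disk
READ_SYMMETRY_ATOL = 1e-9

PAIR_TABLE_COLUMNS = ["genome_a", "genome_b", "si_distance", "ppm_distance", "clique_id"]


# ---------------------------------------------------------------------------
# gene-order files


def read_gene_orders(path: str | Path) -> GenomeCollection:
    """Parse a gene-order file into a :class:`GenomeCollection`.

    Raises :class:`ParseError` (with the line number) for a missing header,
    an empty gene list, an unknown topology flag or a duplicate genome id.
    """
    path = Path(path)
    genomes: list[GeneOrder] = []
    seen: set[str] = set()
    header_line = 0
    genome_id: str | None = None
    topology = CIRCULAR
    genes: list[str] = []

    def flush():
        if genome_id is None:
            return
        if not genes:
            raise ParseError(f"genome {genome_id!r} has an empty gene list", header_line)
        genomes.append(GeneOrder(genome_id, tuple(genes), topology))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                if not fields:
                    raise ParseError("header with no genome_id", lineno)
                genome_id = fields[0]
                if genome_id in seen:
                    raise ParseError(f"duplicate genome_id {genome_id!r}", lineno)
                seen.add(genome_id)
                header_line = lineno
                if len(fields) == 1:
                    topology = CIRCULAR
                    logger.warning(
                        "%s line %d: no topology flag for %r, defaulting to circular",
                        path, lineno, genome_id,
                    )
                elif fields[1] in (CIRCULAR, LINEAR):
                    topology = fields[1]
                else:
                    raise ParseError(
                        f"unknown topology flag {fields[1]!r} (expected circular|linear)",
                        lineno,
                    )
                genes = []
            else:
                if genome_id is None:
                    raise ParseError("gene labels before any genome header", lineno)
                genes.extend(line.split())
    flush()
    if not genomes:
        raise ParseError(f"{path}: no genome blocks found")
    return GenomeCollection(genomes)


def write_gene_orders(collection: GenomeCollection, path: str | Path, width: int = 20) -> None:
    """Write a collection in the gene-order text format (``width`` labels per line)."""
    with open(path, "w") as fh:
        for genome in collection:
            fh.write(f">{genome.genome_id} {genome.topology}\n")
            for i in range(0, genome.size, width):
                fh.write(" ".join(genome.genes[i : i + width]) + "\n")


# ---------------------------------------------------------------------------
# aligned FASTA


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file; all records must share one length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise AlignmentError(f"{path}: duplicate sequence id {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return AlignedSequenceSet(sequences)


def write_aligned_fasta(seqs: AlignedSequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# distance matrices


def _validate_read_matrix(labels: list[str], values: np.ndarray, source: str) -> DistanceMatrix:
    if values.shape[0] != values.shape[1]:
        raise ParseError(f"{source}: matrix is not square {values.shape}")
    if np.any(values < 0):
        raise ParseError(f"{source}: negative distance entries")
    asym = np.max(np.abs(values - values.T), initial=0.0)
    if asym > READ_SYMMETRY_ATOL:
        raise ParseError(f"{source}: matrix asymmetry {asym:g} exceeds {READ_SYMMETRY_ATOL:g}")
    # exact symmetrisation so the container's strict invariant holds
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(labels), values)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a distance matrix, auto-detecting TSV vs PHYLIP square format."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        return _read_phylip(lines, str(path))
    return _read_tsv_matrix(lines, str(path))


def _read_tsv_matrix(lines: list[str], source: str) -> DistanceMatrix:
    header = lines[0].split("\t")
    if header and header[0] == "":
        header = header[1:]
    labels = [h.strip() for h in header]
    rows: list[list[float]] = []
    row_labels: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        row_labels.append(fields[0].strip())
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{source}: non-numeric entry ({exc})", lineno) from None
    if row_labels != labels:
        raise ParseError(f"{source}: row labels do not match column labels")
    values = np.asarray(rows, dtype=float)
    if values.shape != (len(labels), len(labels)):
        raise ParseError(f"{source}: matrix is not square {values.shape}")
    return _validate_read_matrix(labels, values, source)


def _read_phylip(lines: list[str], source: str) -> DistanceMatrix:
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ParseError(f"{source}: bad PHYLIP taxon count {lines[0]!r}", 1) from None
    body = lines[1:]
    if len(body) != n:
        raise ParseError(f"{source}: expected {n} rows, found {len(body)}")
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body, start=2):
        fields = line.split()
        if len(fields) != n + 1:
            raise ParseError(f"{source}: expected label + {n} values", lineno)
        labels.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{source}: non-numeric entry ({exc})", lineno) from None
    if len(set(labels)) != n:
        raise ParseError(f"{source}: duplicate taxon labels")
    return _validate_read_matrix(labels, np.asarray(rows, dtype=float), source)


def write_distance_matrix(m: DistanceMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a matrix as ``tsv`` (default) or ``phylip`` square; 12 significant digits."""
    if fmt not in ("tsv", "phylip"):
        raise ValueError(f"unknown matrix format {fmt!r}")
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t".join(("",) + m.labels) + "\n")
            for lbl, row in zip(m.labels, m.values):
                fh.write(lbl + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")
        else:
            fh.write(f"{m.n}\n")
            for lbl, row in zip(m.labels, m.values):
                fh.write(lbl + " " + " ".join(f"{x:.12g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# pair tables


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_a": str, "genome_b": str, "clique_id": str})
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pair table missing columns {missing}")
    df["clique_id"] = df["clique_id"].where(df["clique_id"].notna(), None)
    return df[PAIR_TABLE_COLUMNS]


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# collection utilities


def intersect_collections(genomes: GenomeCollection, seqs: AlignedSequenceSet) -> list[str]:
    """Sorted genome ids present both in the gene-order collection and the alignment.

    Raises ``ValueError`` when the intersection is empty, since no pairwise
    two-clock analysis is possible then.
    """
    shared = sorted(set(genomes.ids) & set(seqs.ids))
    if not shared:
        raise ValueError("no genome ids shared between gene orders and alignment")
    return shared
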
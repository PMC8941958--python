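"""Point-mutation distances (P_PM) from aligned marker sequences under JC69.

The Jukes–Cantor correction ``d = -(3/4) ln(1 - (4/3) p̂)`` maps the observed
proportion of differing sites ``p̂`` to an expected number of substitutions per
site.  Sites where either sequence carries a gap or an ambiguous base are
dropped pairwise, and the number of comparable sites is reported so that
downstream filters can act on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .containers import AlignedSequenceSet, DistanceMatrix
from .errors import SaturationError

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class JCConfig:
    """Jukes–Cantor configuration.

    Gap handling is fixed to pairwise deletion.  ``saturation_policy`` decides
    what happens when ``p̂ >= 3/4`` (outside the JC domain): ``"error"``
    (default) raises, ``"cap"`` returns ``cap_value``.  A cap must be opted
    into explicitly so saturated pairs are never silently truncated.
    """

    saturation_policy: str = "error"
    cap_value: float | None = None
    gap_policy: str = "pairwise-deletion"

    def __post_init__(self):
        if self.saturation_policy not in ("error", "cap"):
            raise ValueError(f"bad saturation_policy {self.saturation_policy!r}")
        if self.saturation_policy == "cap" and (self.cap_value is None or self.cap_value <= 0):
            raise ValueError("cap_value must be positive when saturation_policy='cap'")
        if self.gap_policy != "pairwise-deletion":
            raise ValueError("only pairwise-deletion gap handling is supported")


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Observed mismatch proportion and the number of comparable sites.

    A site is comparable iff both characters are in ``{A, C, G, T}``.
    Raises ``ValueError`` on length mismatch or zero comparable sites.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    xa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    comparable = np.isin(xa, list(_ACGT)) & np.isin(xb, list(_ACGT))
    sites = int(comparable.sum())
    if sites == 0:
        raise ValueError("no comparable (gap-free A/C/G/T) sites between sequences")
    mismatches = int(np.count_nonzero(xa[comparable] != xb[comparable]))
    return mismatches / sites, sites


def jc69(p_hat: float, config: JCConfig = JCConfig()) -> float:
    """JC69 distance for an observed mismatch proportion.

    ``d = -(3/4) ln(1 - (4/3) p̂)`` for ``p̂ < 3/4``; at or beyond 3/4 the
    configured saturation policy applies.
    """
    if p_hat < 0:
        raise ValueError("p_hat must be non-negative")
    if p_hat >= 0.75:
        if config.saturation_policy == "cap":
            return float(config.cap_value)
        raise SaturationError(
            f"p_hat={p_hat:g} >= 3/4: JC69 distance undefined (saturated)"
        )
    return -0.75 * math.log1p(-4.0 * p_hat / 3.0)


def jc_distance_matrix(seqs: AlignedSequenceSet, config: JCConfig = JCConfig()) -> DistanceMatrix:
    """Pairwise JC69 distance matrix over an aligned sequence set.

    Entries may exceed 1 — JC distances are unbounded below saturation.
    Per-pair failures are re-raised with the offending pair named.
    """
    ids = seqs.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    n = len(ids)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            p_hat, _ = p_distance(seqs[ids[i]], seqs[ids[j]])
            d = jc69(p_hat, config)
        except (ValueError, SaturationError) as exc:
            raise type(exc)(f"pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)
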
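"""Synthetic two-clock studies with full ground truth.

A scenario consists of a number of cliques (genus-like groups).  Each clique
has an ancestor genome obtained from a common root by a large number of
translocations (so between-clique gene orders are saturated) and an ancestor
16S-like sequence diverged from the root sequence by point mutation.  Every
species radiates from its clique ancestor: its genome receives a small,
recorded number of single-gene translocations and its 16S branch length is
tied to that number through the planted clock ratio, so the expected
point-mutation distance per unit of gene-order measure is ``1/rho``.
Optionally, the 16S of selected species is replaced by a fresh evolution
from another clique's ancestor — an injected horizontal transfer of the
marker gene, recoverable as a star in the outlier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AlignedSequenceSet, GeneOrder, GenomeCollection
from .rearrangement import TranslocationScenario, simulate_translocations

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScenarioConfig:
    """Planted parameters of a synthetic two-clock study.

    Defaults describe the reference study conditions: 4 cliques of 8 species,
    genomes of 500 genes analysed with neighbourhood half-width ``k = 10``,
    5–50 translocations per species, clock ratio 7 (gene-order signal to
    point-mutation signal), 1500-site marker sequences, clique ancestors
    scrambled by ``10 n`` translocations and diverged by 0.15 substitutions
    per site per ancestor branch.
    """

    n_cliques: int = 4
    species_per_clique: int = 8
    genome_size: int = 500
    k: int = 10
    within_translocations: tuple[int, int] = (5, 50)
    clock_ratio: float = 7.0
    seq_length: int = 1500
    between_translocations: int | None = None  # default: 10 * genome_size
    between_subs_per_site: float = 0.15
    hgt_injections: tuple[tuple[str, str], ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if self.n_cliques < 1 or self.species_per_clique < 2:
            raise ValueError("need >= 1 cliques of >= 2 species")
        if self.genome_size < 2 * self.k + 2:
            raise ValueError(f"genome_size must be >= 2k+2 = {2 * self.k + 2}")
        if self.clock_ratio <= 0:
            raise ValueError("clock_ratio must be positive")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        lo, hi = self.within_translocations
        if not 0 <= lo <= hi:
            raise ValueError("within_translocations must be a non-decreasing pair >= 0")
        if self.between_subs_per_site < 0:
            raise ValueError("between_subs_per_site must be >= 0")
        object.__setattr__(self, "hgt_injections", tuple(
            (str(s), str(c)) for s, c in self.hgt_injections
        ))

    @property
    def effective_between_translocations(self) -> int:
        if self.between_translocations is None:
            return 10 * self.genome_size
        return self.between_translocations

    def clique_ids(self) -> tuple[str, ...]:
        return tuple(f"C{i + 1}" for i in range(self.n_cliques))

    def species_ids(self, clique_id: str) -> tuple[str, ...]:
        return tuple(f"{clique_id}_S{j + 1}" for j in range(self.species_per_clique))


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth emitted alongside the data files."""

    clique_members: dict[str, tuple[str, ...]]
    translocations: dict[str, int]
    branch_subs: dict[str, float]
    hgt_species: tuple[str, ...]
    seed: int | None
    config: ScenarioConfig = field(repr=False)

    def membership(self) -> dict[str, str]:
        return {s: cid for cid, members in self.clique_members.items() for s in members}


def evolve_sequence_jc(seq: str, subs_per_site: float, rng: np.random.Generator) -> str:
    """Evolve a nucleotide sequence under the JC69 continuous-time chain.

    Each site independently ends in one of the three alternative bases with
    total probability ``(3/4)(1 - exp(-4 b / 3))`` at branch length ``b``
    substitutions per site.
    """
    if subs_per_site < 0:
        raise ValueError("subs_per_site must be >= 0")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if not np.all(np.isin(arr, _BASES)):
        raise ValueError("sequence must be over {A, C, G, T}")
    p_change = 0.75 * -np.expm1(-4.0 * subs_per_site / 3.0)
    hit = rng.random(arr.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # pick uniformly among the three bases different from the current one
        current = np.searchsorted(np.sort(_BASES), arr[hit])  # ACGT are sorted bytes
        offset = rng.integers(1, 4, size=n_hit)
        arr[hit] = np.sort(_BASES)[(current + offset) % 4]
    return arr.tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_scenario(config: ScenarioConfig) -> tuple[GenomeCollection, AlignedSequenceSet, ScenarioTruth]:
    """Generate genomes, marker alignment and ground truth for a scenario.

    Fully reproducible: the same config (including seed) yields byte-identical
    outputs.  Species branch lengths are ``b_i = p_i / (n * rho)`` so the
    planted within-clique relation between the two clocks has slope
    ``1/rho``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_size
    root_genome = GeneOrder("root", tuple(f"COG{i:05d}" for i in range(n)))
    root_seq = random_sequence(config.seq_length, rng)

    donor_of = dict(config.hgt_injections)
    clique_ids = config.clique_ids()
    for species, donor in config.hgt_injections:
        clique = species.rsplit("_S", 1)[0]
        if donor not in clique_ids:
            raise ValueError(f"unknown donor clique {donor!r}")
        if clique == donor:
            raise ValueError(f"HGT donor for {species!r} must be a different clique")

    ancestors: dict[str, tuple[GeneOrder, str]] = {}
    for cid in clique_ids:
        genome = simulate_translocations(
            root_genome, TranslocationScenario(config.effective_between_translocations), rng)
        seq = evolve_sequence_jc(root_seq, config.between_subs_per_site, rng)
        ancestors[cid] = (GeneOrder(cid, genome.genes), seq)

    lo, hi = config.within_translocations
    genomes: list[GeneOrder] = []
    sequences: dict[str, str] = {}
    clique_members: dict[str, tuple[str, ...]] = {}
    translocations: dict[str, int] = {}
    branch_subs: dict[str, float] = {}
    hgt_species: list[str] = []
    for cid in clique_ids:
        members = config.species_ids(cid)
        clique_members[cid] = members
        for sid in members:
            anc_genome, anc_seq = ancestors[cid]
            p_i = int(rng.integers(lo, hi + 1))
            b_i = p_i / (n * config.clock_ratio)
            genome = simulate_translocations(anc_genome, TranslocationScenario(p_i), rng)
            if sid in donor_of:
                source_seq = ancestors[donor_of[sid]][1]
                hgt_species.append(sid)
            else:
                source_seq = anc_seq
            seq = evolve_sequence_jc(source_seq, b_i, rng)
            genomes.append(GeneOrder(sid, genome.genes))
            sequences[sid] = seq
            translocations[sid] = p_i
            branch_subs[sid] = b_i

    unknown = set(donor_of) - set(translocations)
    if unknown:
        raise ValueError(f"hgt_injections name unknown species: {sorted(unknown)}")

    truth = ScenarioTruth(
        clique_members=clique_members,
        translocations=translocations,
        branch_subs=branch_subs,
        hgt_species=tuple(hgt_species),
        seed=config.seed,
        config=config,
    )
    return GenomeCollection(genomes), AlignedSequenceSet(sequences), truth


# ---------------------------------------------------------------------------
# recovery reporting


def _pairwise_agreement(truth_membership: dict[str, str],
                        found_membership: dict[str, str | None]) -> float:
    """Fraction of species pairs on whose co-clustering truth and result agree."""
    species = sorted(truth_membership)
    agree = total = 0
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            same_truth = truth_membership[a] == truth_membership[b]
            fa, fb = found_membership.get(a), found_membership.get(b)
            same_found = fa is not None and fa == fb
            agree += same_truth == same_found
            total += 1
    return agree / total if total else 1.0


def scenario_report(truth: ScenarioTruth, partition=None, pmth=None,
                    star_results=None) -> dict:
    """Summarise how well downstream analyses recovered the planted scenario.

    Reports exact clique recovery and pairwise co-clustering agreement, the
    estimated clock ratio against the planted one, and star detection
    sensitivity / false positives against the injected HGT list (sensitivity
    is ``None`` when nothing was injected).
    """
    report: dict = {"seed": truth.seed}
    if partition is not None:
        found = partition.membership()
        missing = set(truth.membership()) - set(found)
        if missing:
            raise ValueError(f"partition lacks species {sorted(missing)}")
        truth_sets = {frozenset(m) for m in truth.clique_members.values()}
        found_sets = {frozenset(m) for _, m in partition.cliques}
        report["clique_recovery_exact"] = truth_sets == found_sets and not partition.unassigned
        report["clique_pairwise_agreement"] = _pairwise_agreement(truth.membership(), found)
    if pmth is not None:
        rho = truth.config.clock_ratio
        report["pmth_ratio_estimate"] = pmth.pmth_ratio
        report["pmth_ratio_true"] = rho
        report["pmth_ratio_abs_rel_error"] = abs(pmth.pmth_ratio - rho) / rho
    if star_results is not None:
        significant = {r.center for r in star_results if r.significant}
        injected = set(truth.hgt_species)
        unknown = significant - set(truth.translocations)
        if unknown:
            raise ValueError(f"star results name unknown species: {sorted(unknown)}")
        report["significant_stars"] = tuple(sorted(significant))
        report["false_positive_stars"] = tuple(sorted(significant - injected))
        report["sensitivity"] = (
            len(significant & injected) / len(injected) if injected else None
        )
    return report
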
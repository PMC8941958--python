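"""End-to-end two-clock study: distances -> cliques -> regression, fit and stars.

Glue around the analysis modules, used by the command-line interface and by
the synthetic recovery studies.  Given a genome collection and a matching
marker alignment it computes both distance matrices, clusters species into
cliques, runs the within-clique regression and the global phase-transition
fit, and scans the cliques for outlier stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cliques import CliqueConfig, CliquePartition, cluster_species
from .containers import AlignedSequenceSet, DistanceMatrix, GenomeCollection
from .hgt import (OutlierConfig, OutlierGraph, StarTestResult, build_clique_outlier_graph,
                  detect_stars, flag_outliers)
from .io import intersect_collections
from .rearrangement import ModelParams
from .seqdist import JCConfig, jc_distance_matrix
from .synteny import SyntenyParams, si_distance_matrix
from .twoclock import (ExponentialFit, PMTHResult, build_pair_table, derivative_unity_point,
                       elasticity_curve, elasticity_unity_point, fit_exponential,
                       pmth_regression)


@dataclass
class StudyResult:
    si_matrix: DistanceMatrix
    jc_matrix: DistanceMatrix
    partition: CliquePartition
    pair_table: pd.DataFrame
    pmth: PMTHResult | None
    fit: ExponentialFit
    phase_transition_si: float
    elasticity_crossing_si: float | None
    outlier_table: pd.DataFrame
    outlier_graphs: list[OutlierGraph]
    stars: list[StarTestResult]

    def report(self) -> dict:
        """Plain-dict summary of the study (JSON-serialisable)."""
        out = {
            "n_genomes": self.si_matrix.n,
            "n_pairs": len(self.pair_table),
            "cliques": {cid: list(members) for cid, members in self.partition.cliques},
            "n_unassigned": len(self.partition.unassigned),
            "exponential_fit": {"A": self.fit.A, "B": self.fit.B,
                                "residual_sse": self.fit.residual_sse},
            "phase_transition_si": self.phase_transition_si,
            "elasticity_crossing_si": self.elasticity_crossing_si,
            "n_outlier_pairs": len(self.outlier_table),
            "stars": [
                {"clique_id": s.clique_id, "center": s.center, "degree": s.degree,
                 "n_nodes": s.n_nodes, "n_edges": s.n_edges, "p_value": s.p_value,
                 "significant": s.significant}
                for s in self.stars
            ],
        }
        if self.pmth is not None:
            out["pmth"] = {
                "slope": self.pmth.slope, "pmth_ratio": self.pmth.pmth_ratio,
                "r_squared": self.pmth.r_squared, "df": self.pmth.df,
                "ci95": list(self.pmth.ci95), "n_filtered": self.pmth.n_filtered,
            }
        return out


def run_study(genomes: GenomeCollection, seqs: AlignedSequenceSet,
              synteny_params: SyntenyParams = SyntenyParams(),
              jc_config: JCConfig = JCConfig(),
              clique_config: CliqueConfig = CliqueConfig(),
              outlier_config: OutlierConfig = OutlierConfig(),
              gene_order_model: ModelParams | None = None,
              ppm_filter: float = 0.1,
              compute_elasticity: bool = False) -> StudyResult:
    """Run the full two-clock analysis on matched genomes and marker sequences.

    ``gene_order_model`` enables the translocation-model x-axis (expected
    events per gene) for the within-clique regression; without it the raw SI
    distance is used.  The regression is skipped (``pmth=None``) when fewer
    than 3 usable within-clique pairs exist.  Elasticity needs enough
    populated SI bins, so it is opt-in.
    """
    shared = intersect_collections(genomes, seqs)
    genomes = GenomeCollection([genomes[sid] for sid in shared])
    si_m = si_distance_matrix(genomes, synteny_params)
    jc_m = jc_distance_matrix(AlignedSequenceSet({s: seqs[s] for s in shared}), jc_config)

    partition = cluster_species(si_m, clique_config)
    table = build_pair_table(si_m, jc_m, partition)

    try:
        pmth = pmth_regression(table, ppm_filter=ppm_filter,
                               gene_order_model=gene_order_model)
    except ValueError:
        pmth = None

    fit = fit_exponential(table)
    phase_si = derivative_unity_point(fit)
    crossing = None
    if compute_elasticity:
        try:
            crossing = elasticity_unity_point(elasticity_curve(table))
        except ValueError:
            crossing = None

    outliers = flag_outliers(table, fit, outlier_config)
    graphs = [build_clique_outlier_graph(cid, members, outliers)
              for cid, members in partition.cliques]
    stars = detect_stars(graphs, outlier_config)
    return StudyResult(
        si_matrix=si_m, jc_matrix=jc_m, partition=partition, pair_table=table,
        pmth=pmth, fit=fit, phase_transition_si=phase_si,
        elasticity_crossing_si=crossing, outlier_table=outliers,
        outlier_graphs=graphs, stars=stars,
    )
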
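# synclock

Two evolutionary clocks tick in bacterial genomes.  Point mutations
accumulate in every gene and are read off marker sequences such as 16S rRNA
as a substitution distance (**P<sub>PM</sub>**, here Jukes–Cantor-corrected).
Horizontal gene transfer and other rearrangements scramble *gene order*,
which the **Synteny Index (SI)** captures: for a gene g₀ present in genomes
A and B,

    SI_k(g0) = |N_k(A, g0) ∩ N_k(B, g0)| / 2k

where N<sub>k</sub> is the window of k genes upstream and k downstream of g₀
(k = 10 by default); averaging over the union of gene labels and subtracting
from 1 gives the SI distance in [0, 1].  `synclock` computes both distances,
relates them, and exploits the relation:

- **Translocation model.**  After p random single-gene translocations in a
  genome of n genes the expected SI distance is
  `E(SI) = (1 − exp(−(3 − 5k/(n−1)) p/n)) · (1 − 2k/(n−1))`, with saturation
  `1 − 2k/(n−1)` and a closed-form inverse that turns an observed SI
  distance into an expected number of events per gene.  A forward simulator
  quantifies how well this closed form approximates the true process.
- **Clique taxonomy.**  Species whose pairwise SI distances all fall below a
  threshold (τ = 0.95) form cliques — an analytic stand-in for genera —
  extracted iteratively from the threshold graph.
- **Two-clock relation.**  Within cliques the two distances are linearly
  related; the reciprocal of the regression slope is the *PMTH ratio* (≈ 7:
  gene order ticks about seven times faster than 16S point mutation).
  Across all pairs the relation is a phase transition, fitted as
  `E(P_PM) = A·e^{B·SI}`; the SI where the curve's derivative reaches 1 —
  equivalently where the elasticity `(dSI/SI)/(dP_PM/P_PM)` crosses 1 — is
  the point where the point-mutation clock overtakes the gene-order clock,
  and corresponds to roughly one translocation per gene.
- **16S transfer detection.**  Pairs with `P_PM > 1.7·E(P_PM)` are outliers;
  within a clique they form an outlier graph, and a species that acquired
  its 16S from outside the clique shows up as a star.  Star significance is
  tested against the uniform G(n, m) random-graph null (exact enumeration on
  small graphs, seeded Monte Carlo otherwise).
- **Synthetic studies.**  A generator plants cliques, per-species
  translocation counts, a clock ratio, and optional 16S replacements, with
  full ground truth for recovery experiments.

The package is aimed at researchers in microbial phylogenomics who want a
reusable, testable implementation of the gene-order clock and its joint
analysis with marker-gene distances.

## Worked example

Generate a default synthetic study — 4 cliques × 8 species, 500-gene
genomes, clock ratio 7, one injected 16S transfer — and run the full
analysis:

```python
import synclock as sc

config = sc.ScenarioConfig(seed=1, hgt_injections=(("C1_S1", "C2"),))
genomes, seqs, truth = sc.generate_scenario(config)
result = sc.run_study(
    genomes, seqs,
    synteny_params=sc.SyntenyParams(k=config.k),
    gene_order_model=sc.ModelParams(n=config.genome_size, k=config.k),
    outlier_config=sc.OutlierConfig(seed=1),
)
print("cliques recovered:", [len(m) for _, m in result.partition.cliques])
print(f"PMTH slope: {result.pmth.slope:.4f}  ratio: {result.pmth.pmth_ratio:.2f}  R^2: {result.pmth.r_squared:.3f}")
print(f"fit: A={result.fit.A:.4g}  B={result.fit.B:.4f}")
print(f"phase-transition SI (derivative = 1): {result.phase_transition_si:.4f}")
for s in result.stars:
    print(f"star: clique={s.clique_id} center={s.center} degree={s.degree} "
          f"edges={s.n_edges} p={s.p_value:.2g} significant={s.significant}")
```

which prints

```
cliques recovered: [8, 8, 8, 8]
PMTH slope: 0.1656  ratio: 6.04  R^2: 0.966
fit: A=0.006598  B=3.9399
phase-transition SI (derivative = 1): 0.9264
star: clique=C1 center=C1_S1 degree=7 edges=7 p=0 significant=True
```

All four planted cliques are recovered exactly.  The within-clique
regression estimates the planted clock ratio of 7 at 6.04 — the shortfall
is the documented bias of the closed-form event inversion, see
`docs/methods.md`.  The injected species `C1_S1` carries outlier edges to
all 7 of its clique mates; a degree-7 node in a random 8-node, 7-edge graph
is essentially impossible (no hit in 10⁵ Monte-Carlo draws), so the
transfer is flagged.

The same pipeline is scriptable from the shell (`synclock simulate
scenario`, `synclock si-matrix`, `synclock jc-matrix`, `synclock cliques`,
`synclock two-clock`, `synclock hgt-scan`, `synclock model expected-si`…).

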
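# Methods

## Synteny Index distances

For a gene g₀ shared by genomes A and B, the SI similarity is
|N<sub>k</sub>(A, g₀) ∩ N<sub>k</sub>(B, g₀)| / 2k, where N<sub>k</sub> is
the set of labels of the k genes upstream and k downstream of g₀ (the focal
label itself excluded unless it recurs inside the window).  The genome-pair
distance is one minus the mean similarity over the **union** of the two
genomes' label sets, labels private to one genome contributing similarity 0;
averaging over the union makes the measure symmetric by construction.

Conventions that the measure is sensitive to, fixed here and enforced in
code:

- **Topology.**  Circular chromosomes wrap the window around the origin;
  linear ones truncate it.  Bacterial chromosomes are circular, so that is
  the default when a gene-order file carries no flag (a warning is logged).
- **Paralogs.**  Duplicate labels within a genome collapse to their first
  occurrence, both as focal genes and as window members — windows are label
  *sets*, as implied by the use of set intersection.  Collapses are logged.
- **Domain.**  All SI analyses require 2k < n for every genome; the plain
  window helper saturates gracefully for wider windows (useful for
  exploring k) but the distance is not defined there.

`si_distance_matrix` packs each genome's windows into a bit matrix over a
shared label vocabulary so a pair reduces to AND-and-popcount; it is
exactly the per-pair computation (tested against an independent naive
oracle to 1 ulp).

## Point-mutation distances

P<sub>PM</sub> is the Jukes–Cantor (JC69) distance
d = −(3/4)·ln(1 − (4/3)·p̂) from the observed mismatch fraction p̂ of an
aligned marker-gene (16S-like) pair.  Sites where either sequence has a gap
or ambiguous base are deleted pairwise — the standard choice for
marker-gene distances — and the number of comparable sites is reported for
downstream filtering.  At p̂ ≥ 3/4 the correction is undefined; the default
policy raises rather than caps, so saturated pairs are never silently
truncated (an explicit cap is available for exploratory matrices).

## The translocation model

The elementary gene-order event is the excision of one uniformly chosen
gene and its reinsertion at a uniformly chosen slot of the remaining
(circular) order.  The closed form used throughout,

    E(SI_d)(p) = (1 − e^{−(3 − 5k/(n−1)) p/n}) · (1 − 2k/(n−1)),

is a **single-exponential approximation** of this process.  Its anchors are
exact: the saturation 1 − 2k/(n−1) is the expected distance between two
random orders, and the inverse
E(p) = −n/(3 − 5k/(n−1)) · ln(1 − d/(1 − 2k/(n−1))) is the algebraic
inverse to machine precision.  Forward simulation shows where the
approximation is tight and where it is not: the per-event expected distance
increment at p = 0 is ((1 − 2k/(n−1)) + 2)/n (one full neighbourhood reset
when the focal gene itself moves, plus one lost neighbour at the excision
site and one pushed out at the insertion site), slightly above the model's
initial slope, and the true decay is sub-exponential in the mid-range.  In
practice the model tracks the simulated mean tightly for p ≲ n/30 and at
both limits, and deviates by up to roughly 10–15 % relative around
p ≈ n/2.  The test suite asserts exactly this accuracy profile;
`empirical_si_curve` reproduces the comparison at any parameter setting.

Consequence for downstream estimates: inverting the model on simulated gene
orders *under-counts* events at intermediate divergence, which propagates
into a systematic ≈ 10–15 % underestimate of the planted clock ratio in the
synthetic recovery study (see below).  The recovery study still bounds the
median error at 15 %, but users comparing clock ratios across very
different divergence ranges should expect this bias direction.

## Clique clustering

Species are nodes of a threshold graph with an edge where the SI distance
is strictly below τ (default 0.95, just above the phase-transition point);
maximum cliques are extracted iteratively (members removed before the next
search) and kept when they have at least `min_size` = 6 members.  Ties
among equal-size maximum cliques are broken by the lexicographically
smallest sorted member tuple, making the partition deterministic — a
requirement for reproducible downstream tests.  Clique search enumerates
maximal cliques (exact); threshold graphs of study size are far below the
regime where a heuristic would be needed.

## The two-clock analyses

**Pair table.**  One row per unordered genome pair shared by the SI and JC
matrices, with the clique id attached when both members share a clique.

**Within-clique regression (PMTH ratio).**  Only within-clique pairs enter;
pairs with P<sub>PM</sub> above `ppm_filter` (default 0.1) are removed
first and counted — at within-genus SI distances such pairs are candidate
16S transfers, not part of the clock relation.  The x variable is the
gene-order measure: expected translocation events per gene from the model
inverse when genome size is supplied, or the raw SI distance otherwise.
P<sub>PM</sub> is regressed on x through the origin by default, so the
reciprocal slope is interpretable as the clock ratio; the reciprocal
interpretation only holds cleanly through the origin, but both the
orientation and an intercept are exposed as options.  The fit is ordinary
least squares (statsmodels); through the origin the slope equals
Σxy/Σx² and R² is the uncentred version.

**Phase-transition fit.**  E(P_PM) = A·e^{B·SI} is fitted by least squares
in the log domain (ln P_PM on SI) — closed-form, deterministic, and
scale-equivariant; rows with non-positive P_PM are excluded with a warning
and a |B| < 10⁻⁸ fit is flagged degenerate.  A nonlinear refinement in the
original domain is available behind `method="nls"`.  The reported
`residual_sse` is always in the original domain.  The derivative-unity
point ln(1/(A·B))/B marks the phase transition.

**Elasticity.**  Pairs are binned by SI (fixed width, default 0.01); the
per-bin means of P<sub>PM</sub> are smoothed with a centred moving average
(period 3), and the elasticity between consecutive smoothed points is
(ΔSI/SI)/(ΔP_PM/P_PM) at interval midpoints.  The unity crossing (from
above to at-or-below 1) is located by linear interpolation.  Bin width,
period and the midpoint rule are the open design knobs; they are exposed as
parameters.  On flat-then-exponential data with pair density concentrated
on the steep flank — the shape real pair clouds take, since most pairs
join distant genomes — the elasticity crossing and the derivative-unity
point of the fitted curve agree to within 0.02 SI (asserted in the suite).

## 16S-transfer detection

A pair is an outlier when P<sub>PM</sub> > 1.7·A·e^{B·SI} (strict).  The
factor 1.7 is treated as a data-derived constant (two standard errors of
P<sub>PM</sub> about the fitted curve in the reference analysis) and is
configurable, not re-derived.  Outlier pairs within a clique form the
clique-outliers graph; for each non-empty graph the maximum-degree node
(all ties) is tested against the uniform distribution over simple graphs
with the same node and edge counts.  The p-value is P(max degree ≥
observed) — "a star at least this extreme anywhere in the graph".  It is
computed by exhaustive enumeration when the number of edge subsets is at
most 10⁶ (bit-mask enumeration with vectorised popcounts for ≤ 7 nodes,
itertools otherwise) and by seeded Monte Carlo (default 10⁵ draws of m
edges without replacement) beyond that; the plain hit-fraction estimator is
used so that impossible configurations report exactly 0.  No
multiple-testing correction is applied across cliques; the result list
carries every test so users can apply one.

## Synthetic studies

`generate_scenario` emulates the statistical structure the analyses assume:

- one random root genome and root marker sequence;
- per clique, an ancestor scrambled by `10·n` translocations (guaranteeing
  SI saturation between cliques) and a marker diverged by 0.15
  substitutions/site per ancestor branch (between-clique P<sub>PM</sub>
  ≈ 0.3, on the scale real 16S pairs show between genera);
- per species, a star radiation from the clique ancestor: p_i ~
  U{5, …, 50} translocations (spanning the within-genus range up to a tenth
  of a genome) and a marker branch b_i = p_i/(n·ρ), so the expected
  within-clique relation between the two clocks has slope 1/ρ (clock ratio
  ρ = 7 by default);
- optional 16S replacement: the species' marker is re-evolved from the
  *donor* clique's ancestor at the same branch length, leaving its genome
  untouched — the signature the star test is built to find.

Defaults: 4 cliques × 8 species, n = 500 genes, k = 10, L = 1500 sites.
Everything is reproducible from a single seed, and `ScenarioTruth` records
clique membership, per-species event counts and branch lengths, and the
injected species.

What the generator deliberately does **not** model: gene gain/loss and
genuinely private gene content (all genomes share one label set), within-
clique tree structure (star genealogies only — the simplest structure that
delivers the assumed linear within-clique relation), rate variation across
sites or lineages, non-JC substitution, alignment error, and rearrangement
hotspots.  Passing recovery tests therefore demonstrate that the pipeline
recovers planted structure under its own model assumptions — not that real
eggNOG/RDP-scale statistics are reproduced.

## Numerical and interface choices

- Distance matrices must be symmetric to 10⁻¹² in memory; files are
  accepted up to 10⁻⁹ asymmetry and symmetrised by averaging on read.
  Values survive a file round trip to 12 significant digits.
- Strict inequalities wherever a threshold is quoted: threshold-graph edges
  (< τ), outlier flagging (> 1.7·E), star significance (p < α).
- Matrix and genome labels are matched case-sensitively; they are opaque
  tokens.
- The model inverse raises on SI distances at or beyond saturation (the
  event count is undefined there) rather than clamping.
- Monte-Carlo star p-values and all simulations are reproducible from
  seeds; clique extraction and both least-squares fits are deterministic.

## Problem sizes used by the test suite

The recovery study runs 50 seeded scenarios with one injected transfer
plus 50 clean ones at the default scenario size; the simulator–model
comparison uses n = 300, k = 5 with 500 replicates per event count; the
random-graph null sweep covers every node/edge/degree combination on up to
7 nodes with 2×10⁴ Monte-Carlo draws against exact enumeration.  These
sizes give tight-enough Monte-Carlo error to expose the model's
approximation bias (documented above) while keeping the suite quick.

## Known limitations

- The closed-form event model is an approximation; simulator agreement at
  3 standard errors holds only in the small-p regime and at the limits,
  and model-based event counts at intermediate divergence are biased low.
- JC69 assumes equal base frequencies and rates; real 16S evolution is
  better described by richer models, so absolute P<sub>PM</sub> values are
  conservative.
- The star null conditions only on node and edge counts; correlated
  outlier edges (e.g. one fast-evolving species) can concentrate degree
  without a transfer, which is why the detector reports p-values rather
  than verdicts and leaves multiple-testing control to the user.
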
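# Methods

This note documents the models, algorithms and numerical choices behind
`convergenet`, and what the synthetic-data experiments do and do not show.

## Data model and conventions

Gene symbols are uppercased and whitespace-stripped; no alias resolution
is attempted (symbol harmonization across sources is the caller's
responsibility). The interactome is a simple, undirected, unweighted
graph: self-loops and duplicate records are dropped at parse time and the
counts logged. Expression matrices are taken as already normalized —
the package never performs normalization — with exactly one `case` or
`control` label per sample.

## Steiner subnetwork construction

**Model.** Given seed genes T in interactome G, we seek a connected
subgraph spanning a maximum proportion of T while minimizing recruited
non-seed nodes. This is node-weighted Steiner tree with weights 0 on
seeds, 1 elsewhere.

**Algorithm.** Klein–Ravi spider merging. Components start as seed
singletons. Each round evaluates every node *v* as a potential spider
center: components are ranked by the number of chargeable (new, non-seed)
interior nodes on the shortest path from the component to *v*, and for
each r ≥ 2 the ratio

    (cost of v, if new and non-seed) + Σ r cheapest path costs
    ----------------------------------------------------------
                               r

is considered. The cheapest (ratio, center, r) merges those components
along the traced paths; any other component touched by the paths is
absorbed for free. The selection sums per-path costs without discounting
nodes shared between two paths of the same spider (an upper bound on the
true union cost); the executed merge recruits the deduplicated union.
This heuristic carries the standard 2·ln k guarantee on recruited-node
count and, with the cap disabled, provably returns the exact minimal
spanning subtree on trees (all merge paths stay inside it).

**Paths and tie-breaking.** Shortest paths are unweighted BFS paths;
among equal-hop paths the one with the fewest chargeable nodes is kept,
then the lexicographically smallest predecessor. Center ties go to the
lexicographically smallest node symbol, then the smallest component name
(a component is named by its smallest member). Every iteration order is
sorted, so outputs are byte-identical across runs.

**Cost cap.** `max_merge_cost_per_terminal` (default 2.0) refuses any
merge whose ratio exceeds it — i.e., on average more than two new linkers
per merged component. Because the chosen merge is always the globally
cheapest, the first refusal ends growth; this makes the set of accepted
merges monotone in the cap (raising it never loses terminals). Seeds
excluded by the cap are reported `too-costly`; seeds absent from the
graph `not-in-network`; seeds in other graph components than the winner
`unreachable`. The winning component is the one with the most seeds
(ties: lexicographically smallest node set); `steiner_forest` exposes all
per-component trees. The default cap value is a judgment call — the
underlying exclusion rule ("too many unrelated nodes") has no published
threshold — so dropped seeds are always itemized with reasons rather
than silently removed.

**Returned subgraph.** The construction is tree-shaped, but the returned
`Subnetwork` is the *induced* subgraph on the selected nodes: downstream
stages (convergence, enrichment) are node-based, and the induced form
preserves all interaction context for export to Cytoscape.

**Exact oracle.** `exact_steiner_oracle` enumerates subsets of non-seed
nodes by size, then lexicographically, returning the first whose union
with the seeds induces a connected subgraph. It is capped at 15 nodes
(worst case 2^13 subsets with a connectivity check each) and exists only
to validate the heuristic.

## Convergence

High-priority genes are the intersection of the two subnetworks' node
sets — terminals and linkers alike, since a gene recruited independently
by both constructions is itself convergent evidence. Genes present in
both *seed lists* but absent from either subnetwork are deliberately not
high-priority: the seed-list intersection is a separate, weaker signal
than the subnetwork intersection, and the two are reported separately.
Origin classes (`both-seeds`, `cnv-only-seed`, `huge-only-seed`,
`linker-only`) partition the table by seed-list membership.

## Differential expression

Probes collapse to genes by maximum **mean** intensity across all samples
(ties: lexicographically smaller probe ID). The summary statistic is a
choice — "maximum intensity" could also mean a single-sample maximum —
and is recorded in the result metadata. The per-gene test is a two-sided
two-sample t-test; Welch (unequal variances) is the default because it is
the safer choice when group variances are unknown, with `pooled` giving
the classical Student variant. P-values are raw; Benjamini–Hochberg
adjustment is available behind a flag but significance calls elsewhere
use raw p < alpha (strict), matching the screening character of the
analysis. Rows with zero variance in both groups are flagged degenerate
(p = 1, t = 0 at equal means; p = 0, t = ±inf otherwise).

At the 7-vs-8 design with unit noise the Welch test is well calibrated:
measured type-I error ≈ 0.044–0.057 at alpha 0.05 (2000 null genes) and
power ≈ 0.94 at a 2-SD shift. Note that the exact permutation null at
4-vs-4 has resolution 1/35, so t-test p-values can only be expected to
track an exhaustive permutation oracle to ~0.1 there; agreement tightens
to ~0.03 at 6-vs-6 (924 splits).

## Pathway enrichment and crosstalk

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) with population N = |background|, successes K = |pathway ∩
background|, draws n = |query|; the implementation delegates to
`scipy.stats.hypergeom.sf` and is validated against exact rational
summation (max observed error ~4e-16). The background defaults to all
interactome genes and is configurable, since the appropriate universe
depends on how the pathway collection was compiled. Significance requires
both p < `p_cutoff` (default 0.01) and ≥ `min_hits` (default 5) query
genes.

Crosstalk scores are computed by default on each pathway's *hit genes*
(its intersection with the query), not its full membership: the
functional map is about how the subnetwork's genes distribute across
pathways, and shared housekeeping members of two pathways that the
subnetwork never touches should not link them. `use_full_sets=True`
scores full memberships instead. Candidate edges need ≥ `min_shared`
(default 3) shared genes; each enrichment result keeps edges scoring at
or above the (1 − top_fraction) quantile of its own candidate scores
(ties kept, so the filter is deterministic), and the asymmetric defaults
(top 1% for side A, top 5% for side B) mirror filtering a larger pathway
set more aggressively than a smaller one. Functional groups are the
connected components (≥ 2 nodes) of the filtered union — no clustering
algorithm beyond connectivity is applied — ordered by size; isolated
pathways are reported separately as group 0.

## Synthetic data: what it emulates, what it does not

`gen_interactome` (scale-free) draws Chung–Lu expected degrees from a
Pareto tail (exponent ≈ 2.05, structural cutoff √(n·mean)), giving the
steep degree distribution of curated PPI exports: many degree-1..3
proteins, a few hubs of degree ~100+. The default is 1000 nodes at mean
degree 10 (≈ 5 edges per node, the edge/node ratio of large curated PPI
sets, at one-tenth scale so the full suite runs in minutes); a `--scale`
option generates 10k-node versions. Realized edge counts track
n·mean_degree/2 within 10% (a 1.06 weight factor offsets losses to the
degree cutoff, collapsed duplicates and giant-component pruning).

`gen_seed_sets` samples the two seed lists from two BFS neighborhoods
with an exact `n_overlap` (default 5, the real seed lists' intersection
size) shared core, and plants `n_bridges` (default 5) *forced* bridge
linkers: each bridge is a cut vertex with nodes hanging off it, and
either one hanging node joins each seed list, or a degree-1 pendant
joins both lists (consuming an overlap slot). Every path from those
seeds to the rest of their module runs through the bridge, so a correct
Steiner construction must recruit it into both subnetworks — making
bridge recovery a sharp correctness probe rather than a statistical one.
Default list sizes (40 and 20) are one-tenth of the real 373/165.

`gen_expression` uses a Normal(8, 1) per-cell baseline on a log-like
intensity scale for 7 cases vs 8 controls, shifts a `de_fraction`
(default 5%) of genes by `effect_sd` (default 2.0) standard deviations in
cases, and gives 10% of genes a second, dimmer probe (mean 6) so probe
collapse is exercised. `gen_pathways` builds equally sized pathways whose
within-cluster members share a fixed core and whose cross-cluster pools
are disjoint; the preset draws cluster members preferentially from the
seed lists so the planted clusters are enrichable by the subnetworks.

**Limitations.** The generator does not emulate real gene symbols,
correlated expression, batch effects, heavy-tailed intensity noise,
partially overlapping pathway hierarchies, or false edges in the
interactome. Passing recovery tests therefore demonstrates algorithmic
correctness under the planted model — not robustness to the noise
structure of real microarray or interaction data. Published node counts
from the original study (e.g., subnetwork sizes) depend on dated versions
of the source databases and an unpublished cost threshold, and are not
reproduction targets.

## Reproducibility

All generators take integer seeds and are byte-deterministic; derived
sub-seeds come from `numpy.random.SeedSequence` and stay below 2^31.
Pipeline outputs are written with sorted node/edge/key order, so
re-running a config reproduces identical bytes, and `manifest.json`
records input checksums, parameters and per-stage counts. Problem sizes
in the validation suite — 200 oracle instances, 1000 hypergeometric
configurations, 2000-gene null panels, 20 end-to-end replicates at the
1000-node scale — were chosen to keep the full suite around two minutes
of Steiner work while leaving the statistical checks well powered.
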
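# Methods

## Scope and data model

The pipeline starts at *denoised, standardized* per-subject ROI time series
(rows = volumes, columns = regions); all imaging steps that produce such
tables (realignment, normalization, nuisance regression, filtering,
scrubbing) are out of scope. Region identity lives in a metadata table
(`roi_id, name, hemisphere, pair_id, group`): ROI order there is canonical,
every downstream matrix is stored in that order, and bilateral homolog
pairs (`pair_id` shared by exactly one left and one right region) drive the
bilateral averaging and symmetry statistics. The default atlas has 97
regions — 45 bilateral pairs and 7 midline regions.

## Synthetic cohorts

Real awake-dog resting-state data of this kind are not publicly deposited,
so the generator produces a statistical stand-in with planted,
recoverable structure. Each ROI signal is a linear latent-factor process:

    x_i(t) = a_m f_m(t) + w b_q(t) + c g_p(t) + h Σ_k f_k(t) + e_i(t)

- `f_m`: the factor of the module containing ROI *i*, loading `a_m`
  (default 0.8 for bilateral modules, 0.6 for the sub-blocks of the
  lateralized modules);
- `b_q`: a *bridge* factor shared by one matched member pair across the two
  sub-blocks of a lateralized twin module (default loading 0.35);
- `g_p`: a factor shared by the two members of bilateral pair *p*
  (homolog coupling, default 0.2);
- `f_k`: the factors of `hub_k = 3` foreign modules, loaded with `h = 0.25`
  by the ten planted hub ROIs (five bilateral pairs);
- `e_i`: AR(1) noise, coefficient 0.3, innovation SD 1.

Columns are standardized (mean 0, SD 1) per subject. Defaults mirror the
study conditions the pipeline is meant for: 33 subjects, 264 time points
(two runs of 132 usable volumes), 97 ROIs, ten first-layer modules of which
the two largest (15 ROIs each) are single-hemisphere twins that each split
into two sub-blocks (8 + 7) at the second analysis layer.

**Why pairwise bridges instead of a shared super-module factor.** The
estimator is a semi-partial correlation: any factor shared by many regions
is largely explained away by the controlling set (the co-members are good
proxies for the factor), so broad shared factors produce almost no
surviving edges between sub-blocks. Couplings that are *private to a pair
of regions* — the homolog factor and the bridge factors — survive
semi-partialing at full strength. Binding the two sub-blocks of each twin
with ~7 pairwise bridges makes the twin cohere as one community in the
full graph, while the same bridge weight loses to the much larger
within-block weight when the induced subgraph is re-clustered (the
modularity null term grows when total weight shrinks), so the second layer
splits it. This reproduces the two-layer phenomenology the pipeline is
designed to detect, and is the package's own design choice.

Parameter calibration was part of that design: loadings were chosen once so
that the default cohort lands in the regime the method assumes —
thresholded density near 12% (inside the 5–30% band of published
functional connectomes), clean two-layer recoverability, hubs competitive
in all three centrality rankings. Hub regions are planted in sizeable
modules and bridge only modules with ≥ 8 members, because a hub bridging a
4-region module contributes enough inter-module weight to fuse the two
communities outright.

What the generator does **not** emulate: scanner artefacts, motion spikes,
susceptibility dropout, global signal, spatially correlated noise,
inter-subject variability in module membership, and hemodynamic
autocorrelation beyond AR(1). Passing tests therefore demonstrate that the
pipeline recovers the structure its statistics are designed for, not that
it is robust to every pathology of real fMRI.

## Semi-partial connectivity

`s(i→j)` is the correlation between `x_j` and the residual of `x_i`
regressed (no intercept; inputs are standardized) on all ROIs except `i`
and `j`. Rather than running p(p−1) explicit regressions, the
implementation uses exact precision-matrix algebra: with `S = XᵀX` and
`P = S⁻¹`, deleting row/column `j` gives the downdated precision
`Q = P₋ⱼ₋ⱼ − P₋ⱼⱼPⱼ₋ⱼ/Pⱼⱼ`, from which
`s(i→j) = (Q S₋ⱼ,ⱼ)ᵢ / √(Qᵢᵢ Sⱼⱼ)` for all `i` at once — O(p³) per subject
and algebraically identical to the explicit regressions (the test suite
keeps an independently coded brute-force oracle and requires agreement to
1e-8; in practice agreement is at machine precision). Near-singular
covariance (condition number > 1e10) raises an error rather than returning
noise. The two-ROI case has an empty controlling set and reduces to plain
correlation. The directed matrix is symmetrized by averaging the two
directions — the least-assumptive reduction to the undirected graph the
rest of the pipeline needs.

Correlations with |r| ≥ 1 are clamped to ±(1 − 1e-7) before the Fisher
transform, with a warning.

## Group statistics and thresholding

Per edge: one-sample two-sided t-test of the Fisher z across subjects
(df = n−1). Zero-variance edges are degenerate inputs that only occur in
synthetic data; a zero mean yields t = 0, p = 1, a nonzero mean yields a
p→0 sentinel (smallest positive float, so p stays in (0,1]) plus a warning.

Per seed ROI: an omnibus statistic, the mean of |mean z| over the seed's
edges, tested by sign-flip permutation — each permutation flips the sign of
whole subjects' matrices, preserving the within-subject dependence between
edges — with the standard +1 correction `p = (1 + #{perm ≥ obs})/(1 +
n_perm)` and n_perm = 5000 by default. A parametric multivariate omnibus
would be rank-deficient at ~33 subjects × 96 edges per seed, which is why
the permutation form is used. Seed p-values are Benjamini–Hochberg
adjusted (via statsmodels).

Edge retention: `p_edge < 0.01` (uncorrected) AND (`q_seed < 0.05` at
either endpoint). Retained weight is the group |t|; |mean z| is available
as an alternative. |t| is the default because the magnitudes reported for
weighted degree in this literature (tens per node at ~19 edges) are
incompatible with correlation-scale units. Edges of both signs are
retained (the sign survives in the persisted `mean_z`/`t` columns);
negative-mean edges are rare under the default generator.

## Graph topology

The graph keeps all atlas ROIs as nodes (isolates included), so density is
always relative to the full parcellation. C and L are computed on the
*binarized* graph: the classical small-world scalars are defined on binary
graphs and the raw values they normalize are binary metrics. L averages
shortest paths within connected components (no infinite distances, no
harmonic mean); the component count is reported alongside. Nulls are
degree-preserving double-edge-swap randomizations (attempting
10 × E swaps, rejecting self-loops/multi-edges; degree multiset preserved
exactly), n_null = 100 by default; Γ = C/C̄_rand, Λ = L/L̄_rand, Σ = Γ/Λ.
With `swap_factor=0` the null is the graph itself and Γ = Λ = Σ = 1, a
degenerate case used in tests.

## Communities

Detection is weighted-modularity maximization (networkx multi-level greedy
moves) with the resolution parameter at 0.6 — interpreted as the
"modularity threshold" of the visualisation tools this analysis style comes
from, where it is the one free scalar of the community routine. Because
single runs are stochastic, the partition of record is a consensus: 10
repeats with derived seeds, co-assignment frequency matrix thresholded at
0.5 (the usual consensus-clustering convention), agreement graph
re-clustered, iterated to a block-constant matrix (max 20 iterations, then
warn and return the last partition). Labels are canonicalized by
decreasing module size, ties by smallest member name, so partitions are
deterministic given (graph, resolution, n_repeats, seed).

Second layer: a module is *lateralized* when > 70% of its ≥ 2 members lie
in one hemisphere (the source analyses say only "lateralised"; 70% is this
package's operationalization, configurable). The two most populous
lateralized modules are re-clustered by the same consensus procedure on
their induced subgraphs; all other memberships are untouched, so the final
count is (layer-1 count − k) + Σ sub-module counts. Per-community density
is the induced-subgraph edge density; singleton modules report 0 with a
flag rather than NaN so tables stay complete.

Homolog symmetry: Spearman ρ across bilateral pairs (with ≥ 1
nonzero-degree member; ≥ 3 such pairs required) between left and right
binary degree, and between left and right weighted degree. Constant values
on a side make ranks degenerate; ρ is then reported missing with a warning.

## Centrality and hubs

WD = sum of incident weights, D = edge count, BC = unnormalized Brandes
betweenness on the binarized graph with fractional credit for tied shortest
paths (binary rather than weighted-distance BC: the non-integer hub values
in this literature arise naturally from tie credit plus bilateral
averaging, and weighted-distance betweenness would need a weight→distance
convention the source analyses never state; configurable in principle).
Averaging over bilateral pairs happens *before* ranking; midline ROIs
compete unchanged in the same list. Rankings are descending with
alphabetical tie-break so output files are byte-stable. Consensus hubs =
intersection of the three top-20 sets.

## Parcellation comparison

ROI allocation is argmax over per-network overlap counts, after averaging
the two members of each bilateral pair so homologs always share a network.
Ties go to the first network in row order with a warning (the source
procedure never mentions ties). Jaccard of two empty sets is an error, not
0. Network matching is greedy one-to-one by descending Jaccard — mirroring
how such tables are paired by inspection — with optimal assignment
(scipy's Hungarian solver) available via `method="optimal"`. Only
one-to-one scores are produced; many-to-many partial matches are left to
human judgement.

## Orchestration and reproducibility

A single master seed spawns per-stage child seeds through
`numpy.random.SeedSequence(master, spawn_key=(stage,))`, so the permutation
test, consensus clustering and null models can each be re-run in isolation
with identical streams; identical config + seed gives a byte-identical JSON
report. Warnings from all stages (clamped correlations, ties, singleton
modules, skipped degenerate metrics) are collected into the report. An
empty thresholded graph marks the report degenerate and skips downstream
stages instead of crashing. Interchange formats are plain text throughout:
TSV for tables, CSV for matrices and edge lists, GraphML for the annotated
graph.

## Problem sizes used in tests and the acceptance script

Unit tests run on 4–30-node fixtures with closed-form or brute-force
oracles. End-to-end checks use the full default cohort (33 × 264 × 97) for
10 master seeds with n_perm = 1000, which resolves seed-level p-values to
1e-3 — ample against the 0.05 FDR threshold; the acceptance script uses
the default n_perm = 5000 for its single structured cohort and 10
pure-noise replicates (20 subjects × 120 time points × 40 ROIs) for the
false-positive check. These sizes are the package's choice of desk-scale
defaults; all are configurable.

## Known limitations

- The generator's covariance is homogeneous within blocks; real
  connectomes have graded, distance-dependent structure, so recovery
  margins here are optimistic.
- Consensus clustering can in principle fail to converge on ambiguous
  graphs; the fallback (last partition + warning) is deterministic but not
  a fixed point.
- The two-level threshold controls false positives per edge and per seed
  but, like the procedure it implements, is not a family-wise guarantee
  over the whole graph.
- Semi-partial estimation requires T > p − 1; parcellations finer than the
  run length cannot be analysed without dimension reduction, which is out
  of scope.
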
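# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducing
results.

## Constrained-topology testing

Competing placements of a focal clade are encoded as multifurcating
constraint trees. For five named taxon groups (the focal lineage, two
candidate sister groups, the remaining complex-plastid lineages, and an
outgroup of red algae) the builder emits six constraints: three placements
of the focal clade within the focal+sisters clade, crossed with whether all
complex-plastid lineages are constrained monophyletic.

Two maximized topologies are compared with a likelihood-ratio statistic
`LRS = 2·|lnL_a − lnL_b|` referred to chi-squared with
`df = (n−3) − |shared splits|`, the number of internal branches the strict
consensus of the two trees lacks relative to a fully resolved unrooted tree.
This definition is used for multifurcating inputs too (it is the degrees of
freedom of the consensus polytomies); the alternative "splits lost from the
union of both inputs" double-counts for binary trees and was rejected. The
multiple-comparison correction is `p' = 1 − (1−p)^A`, with `A` the number of
fully binary trees compatible with the strict consensus: the product over
consensus vertices of unrooted degree `d ≥ 4` of `(2d−5)!!`. `A` counts
*binary* resolutions only — the correction is over the set of fully resolved
candidate ML trees; partially resolved trees are not ML search outputs.
Identical topologies with different "maximized" likelihoods raise an error
(`df = 0` admits no difference under one model); the guard catches silently
inconsistent inputs.

The AU test is the standard RELL multiscale bootstrap: at each scale
`r ∈ {0.5, …, 1.4}` (step 0.1), `B` multinomial site-weight vectors of size
`round(rN)` are drawn and the per-topology resampled log-likelihood sums
compared. Bootstrap proportions are fitted by weighted least squares to
`probit(1 − BP_r) = d·√r + c/√r` with delta-method weights
`B·φ(z)²/(BP(1−BP))`; `p_AU = 1 − Φ(d − c)`. Scales with degenerate BP (0 or
1) are excluded; a topology degenerate at every scale gets p = 0 or 1 with a
flag. Exact ties in a replicate are credited fractionally (1/n_tied) rather
than by a random draw: the expectation is identical, but the estimator is
deterministic and has no added variance, so two topologies with identical
site-likelihood vectors get BP exactly 0.5 at every scale and p exactly 0.5.
Default `B = 10,000`; rejection flags use α = 0.05 (configurable — the
asterisk convention in published tables rarely states its α).

## Likelihood engine

Fixed-topology Felsenstein pruning under time-reversible empirical
amino-acid models. LG and cpREV exchangeabilities/frequencies ship as
plain-text data files (standard published matrices); a Poisson (equal-rates)
model and user-supplied matrices are also available. The rate matrix
`Q = S·diag(π)` is scaled to one expected substitution per unit branch
length. `P(t) = exp(Qt)` is computed through the symmetric eigendecomposition
of `diag(π)^{1/2} Q diag(π)^{−1/2}` — stable for reversible models — with
rows renormalized after clipping tiny negatives; `P(0)` is returned as the
exact identity so impossible zero-length patterns yield `−∞` rather than a
rounding artifact.

Rate variation is discrete-Γ with `m` equal-probability categories, category
rates equal to within-bin means (mean exactly 1). The invariant-sites
component is omitted: the engine exists to drive the topology-test battery,
which the package exercises with +Γ models; adding +I would complicate
branch-length optimization for little benefit in that role. Fixed per-site
frequency profiles (PMSF-style) can replace the model's equilibrium
frequencies at the root; gaps and ambiguity codes are missing data (partial
likelihood 1 in every state).

Branch lengths are optimized coordinate-wise at fixed topology: each sweep
walks the tree depth-first, optimizing every edge with a bounded Brent
search (box `[0, 10]`, tolerance 1e−6) against flanking conditional
likelihoods that are exact at the moment of each update — ancestor edges
already carry new lengths, and a subtree's partial is refreshed when the
walk backtracks through it — so single-edge moves cannot decrease the
likelihood and lnL is non-decreasing across sweeps. The per-edge objective
is evaluated in the model's eigenbasis
(`Σ_ij up_i P_ij(t) down_j = Σ_k a_k b_k e^{w_k r t}`), which makes one
evaluation O(sites·cats·states) instead of requiring a fresh matrix
exponential. Initial lengths 0.1; sweeps stop when lnL improves by <1e−4 or
after 100 sweeps. On data simulated from a 6-taxon LG+Γ4 tree with 5,000
sites the median relative branch-length error is ≈6 %.

## Alignment treatments

SR4 recoding maps the 20 amino acids onto four composition-robust classes
{A,G,N,P,S,T}, {C,H,W,Y}, {D,E,K,Q,R}, {F,I,L,M,V}, rendered '1'–'4'; gaps
and ambiguity codes (B, Z, X, J, U, O, and '?', '.', '*') pass through as
gaps and are treated as missing everywhere.

Stuart's test of marginal homogeneity is computed per sequence pair from the
k×k table of co-occurring unambiguous states: `d_u = rowsum_u − colsum_u`
for the first k−1 states, `V_uu = rowsum_u + colsum_u − 2N_uu`,
`V_uv = −(N_uv + N_vu)`, `W = dᵀV⁻¹d` with p from chi-squared(k−1). Sparse
toy tables are routinely singular, so a Moore–Penrose pseudo-inverse with
df = numerical rank (relative tolerance 1e−10) is used when the linear solve
fails, and the result is flagged.

The stationarity trimmer is a greedy loop: while any pair has p < α (default
0.05, no cross-pair correction) and less than `max_removed_fraction`
(default 0.5) of columns have been removed, remove the single column whose
deletion maximally reduces the summed W over currently significant pairs
(ties → lowest index), then recompute. This is a documented stand-in for
BMGE's FAST stationarity mode, whose internals are not published in
sufficient detail to clone; site-removal fractions from the original tool
are therefore not expected to match exactly. The gap trimmer keeps columns
whose non-gap fraction is ≥ the threshold (default 0.8).

## Compositional-bias classification

Five steps: (1) per-taxon residue counts (gaps excluded); (2) chi-squared
homogeneity test with Pearson residuals `r = (O−E)/√E`, `E` from marginals,
df = (T−1)(K−1); (3) UPGMA on Euclidean distances between taxon residual
rows, cut at the root into two groups — group 1 is the clade containing the
lexicographically smallest taxon, making the orientation (and hence
"enriched" vs "depleted") reproducible; (4) per residue, a two-sided exact
binomial test (minlike convention) of the group-1 count against the
group-size expectation, scored as `sign(f₁−f₂)·(−log10 p)`; (5) classes at
|score| ≥ 2 (p ≤ 0.01). The score and threshold are this package's own
choices — the procedure is usually run with unpublished per-study scripts —
and both are configurable; the classes are rank-consistent with the evidence
and antisymmetric under group exchange. Euclidean distance on residuals was
chosen because the residuals are the stated basis of the grouping and no
metric is canonical.

## Organelle QC, dereplication, coverage linking

Completeness = % of marker genes present ≥1×; redundancy = % of extra
copies, `100·Σ max(0, c−1)/|markers|` (the extra-copy convention used by
MAG QC tools; the quantity is usually named but not defined). "Near
complete" = ≥40 of a 44-marker set. The default 44-gene plastid core and
25-gene mitochondrial screen lists ship as editable text files assembled
from canonical organellar core-gene sets; studies vary in their exact lists,
so these are configuration, not hard-coded truth.

Dereplication: single-linkage components over edges with ANI > 98 % *and*
aligned fraction of the smaller genome > 25 %; representatives are
references first (longest reference if several), else the longest genome,
ties by id. The bundled ANI estimator is a k-mer sketch (canonical 21-mers,
Mash distance `D = −ln(2J/(1+J))/k`, ANI = 100(1−D)) with the shared-k-mer
fraction of the smaller sequence standing in for aligned fraction; it is
plumbing for fixtures and small studies, not a replacement for
alignment-based ANI.

Detection rule: mean coverage is zeroed wherever ≤25 % of the genome length
is covered (strictly greater-than, per the ">25 %" convention); the rule is
idempotent. Linking regresses candidate coverage on target coverage by OLS;
`R² = r²`, two-sided t test of the slope with n−2 df, no multiplicity
correction. Candidates are ranked by the R² of the rule-off variant (both
variants are always reported) — with the rule on, the many zeroed cells make
R² unstable for sparsely detected genomes.

## Gene content and Dollo parsimony

Presence = copy count ≥ 1; genes in fewer than 3 taxa are dropped (the
common HOG filter). Clustering of taxa and genes is UPGMA on Euclidean
distances between binary vectors (matching the default of the usual heatmap
tools); Jaccard is offered. Dollo losses per gene: assuming presence at the
root of the supplied scenario tree and no regain, the minimum number of
losses is the number of maximal all-absent clades; a gene absent everywhere
counts one loss at the origin and is flagged, since a single-gain model
cannot distinguish "never gained" from "lost immediately". Scenario
comparison reports per-gene and total losses under two host trees; the
choice of origin (tree root) is recorded in the report as a modelling
assumption.

## Synthetic data

The generators produce every input with known ground truth and a mandatory
seed:

- `sim_alignment` evolves sites along a tree under the engine's own models;
  a compositional shift is implemented by displacing the equilibrium
  frequencies (`π' ∝ π·e^δ`) *inside the rate matrix* of the shifted clade,
  so shifted taxa remain a proper Markov process rather than having residues
  swapped post hoc. When the model carries discrete-Γ categories, site rates
  are drawn from those categories so simulation and inference share the rate
  distribution exactly.
- `sim_genome_complement` plants `round(c·|markers|)` present genes and
  duplicates `round(r·|markers|)` of them, so QC recovers the planted
  fractions identically.
- `sim_coverage` draws per-genome log-coverage as Gaussian noise (lognormal
  marginals, default log-mean 1, log-sd 1 — spanning roughly the 0.4–20×
  range typical of organellar genomes across ocean metagenomes); linked
  pairs share a latent factor achieving the requested log-scale correlation;
  detection saturates with coverage (`1−e^{−cov}` plus mild noise) and a
  default 10 % of entries are forced below the 0.25 detection cutoff to
  emulate dropouts.
- `sim_dollo` places Poisson loss events per branch (default rates chosen
  per experiment); the truth records effective events, which upper-bound the
  parsimony minimum.

What the generators do *not* emulate: indels and alignment error,
heterotachy, site-specific profiles (simulation is frequency-homogeneous
outside planted shifts), read-level noise, assembly fragmentation, and
compositional signal that covaries with rate. Passing recovery tests
therefore demonstrates correctness of the estimators under their own model
assumptions, not robustness to the full messiness of real metagenomic data.

## Problem sizes in tests and the acceptance script

Oracle equivalence uses full enumeration on ≤6 taxa (consensus and
resolution counts; 5,565 pairs at n = 6), exhaustive state summation on ≤5
leaves with a 4-state model, and brute-force loss-set search on ≤8 leaves.
Calibration uses 200 replicates of 8 taxa × 500 sites under LG+Γ4 for the
null rejection rate, B = 10,000 for the AU reference value, and 20 seeds of
8-taxon (one leaf per group collapsed where groups are singletons) × 2,000
sites for the end-to-end battery. These sizes give standard errors small
enough for the assertions while keeping a full run on one CPU in the
minutes range.

## Known limitations

- The likelihood engine has no +I, no mixture models, no topology search;
  it evaluates and optimizes fixed topologies only.
- The stationarity trimmer and the compositional-bias score are documented
  stand-ins for tools whose algorithms are not published in detail; they
  reproduce the *kind* of output (trimmed alignments, residue classes), not
  bit-identical results.
- The k-mer ANI estimator is approximate and biased low for highly diverged
  pairs; use alignment-based ANI for real dereplication decisions.
- UPGMA tie-breaking follows scipy's deterministic order, which may differ
  from other implementations on exactly tied merges.
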
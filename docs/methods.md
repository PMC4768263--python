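# Methods

This note documents the models and procedures `coopharm` implements, the
defaults it ships with, the synthetic study conditions it is validated on,
and the design choices made where the problem was genuinely open.

## Discovery model

### Canonical sensitivity

Screens report drug response on heterogeneous scales: activity-area-like
metrics where a higher value means a more sensitive cell line, and (log)
IC50-like metrics where a lower value does. `canonical_sensitivity` negates
lower-is-sensitive metrics so that *higher always means more sensitive*;
it is the only place orientation is consulted. Negation is an involution
and leaves rank-based statistics untouched, so every downstream result is
orientation-independent; only the sign convention of reported correlations
depends on working in canonical units (a resistance modulator always shows
r < 0 against canonical sensitivity).

Missing response entries (NaN) exclude a cell from that drug's tree and
correlations only; other drugs keep the cell.

### Rank-test decision trees

For one drug, each node of the tree holds a cell subset. Every candidate
alteration feature — a (gene, type) pair with type in {MUT, AMP, DEL};
amplification and deletion are deliberately separate features — is scored
by the two-sided Mann–Whitney U-test comparing canonical sensitivity
between altered and wild-type cells of the node. The smallest p wins;
altered cells go to the left child. Termination: no candidate reaches
`p_threshold` (default 0.001), or the node has fewer than `min_node_size`
(default 5) cells. A split is only *evaluated* when both prospective
children have at least `min_child_size` (default 2) cells, since a 1-vs-n
rank test carries no information. Features already used on the current
root-to-node path are withheld on that path (a binary feature cannot
usefully split twice along one lineage) but remain available elsewhere.

Tie-breaking is fully deterministic: smaller p, then larger
|median(altered) − median(wild-type)|, then lexicographic (gene, type).
Tree construction involves no randomness, so identical inputs always give
identical trees.

The U-test uses the exact null distribution of U when both groups have at
most `exact_test_max_n` (default 8) observations and the pooled sample is
tie-free; otherwise a tie-corrected normal approximation with continuity
correction. The method used is recorded per result. Two groups with no
separation at all report p = 1 exactly.

### Forest regeneration

Greedy splitting hides secondary drivers: once the strongest feature is
used, correlated or weaker drivers may never surface. After a tree
finishes, every feature it used internally is removed from the candidate
pool and a new tree is grown; the loop stops when a round produces no
split (that stump is discarded). Feature sets of successive trees are
pairwise disjoint by construction.

A note on when regeneration can surface a second driver: if two drivers
have statistically independent carrier sets, a second driver detectable on
the full sample is even easier to detect inside the first tree's children
(where the first driver's variance is removed), so tree 1 absorbs it and
the forest has one tree. Round 2 genuinely adds a driver when the second
driver has little or no variation within tree 1's nodes — most cleanly
when carrier sets are mutually exclusive, a pattern real oncogene pairs
(e.g. BRAF/KRAS) actually show. The validation fixtures use that pattern.

### Node-conditional correlation

For each node with at least `min_cells` (default 5) cells, expression of
each gene in the core-pathway universe (the pathway filter is applied
*before* testing, shrinking the multiplicity burden) is Pearson-correlated
with canonical sensitivity over the node's cells. p-values come from the
t transform t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom; exact
(anti)linearity reports the smallest positive double rather than 0, and
zero-variance genes are skipped (counted in a log line), never reported as
r = 0.

Benjamini–Hochberg adjustment is applied *within each node* across the
genes tested there, at FDR `fdr` (default 0.05). The scope is a config
switch (`per_node` | `per_tree`): per-node treats each genotype context as
its own screen and is the default; per-tree pools all (node, gene) tests
of a tree. Both are implemented because the appropriate multiplicity
universe for nested, overlapping cell subsets is genuinely ambiguous.

The candidate direction is negative: high expression associated with low
canonical sensitivity (a resistance modulator). `filter_negative` keeps
significant records with r < 0.

### Pair selection and cross-screen confirmation

First biomarker: the root feature of the (by default, first) forest tree,
required to sensitize (median_left > median_right in canonical units) and
to be on the commonly-mutated-cancer-gene list. A config flag widens the
search to every forest root.

Second biomarker: a significant negative record at the root's *altered*
child — the genotype context in which the modulator acts. Records at the
wild-type child never form pairs, and a second gene equal to the first is
excluded. Druggability (`drugs_y` from the drug→target table) is an
annotation: undruggable pairs are retained in the full output but excluded
from the two-drug view.

Cross-screen confirmation: drug names differ between screens, so "the same
drug" is formalized as *same target class* — a pair in screen A is
confirmed iff screen B contains the same (first gene, second gene) pair
discovered under a drug X sharing at least one target gene with A's drug
X. The concordance report counts unique gene-pair identities; `shared`
counts confirmed identities (same pair *and* same target class), and the
Jaccard index is shared / (|A| + |B| − shared).

## Synergy model

Single-drug dose-response points (dose D > 0, fraction affected fa
strictly inside (0,1); fa = 1 − relative survival) are fitted by ordinary
least squares on the median-effect plot, log10(fa/(1−fa)) against
log10(D), giving slope m and Dm = 10^(−intercept/m). Base-10 logs are a
convention; any base gives identical (m, Dm). fa values within 1e−12 of
the boundary are rejected rather than silently clipped.

The combination index at observed combination effect fa is the
non-constant-ratio form CI = d1/Dx1(fa) + d2/Dx2(fa) with
Dx(fa) = Dm·(fa/(1−fa))^(1/m). Classification: synergy (CI < 1),
additivity (|CI − 1| ≤ 1e−9), antagonism (CI > 1). A sham combination of a
drug with itself at doses summing to Dx(fa) gives CI = 1 exactly, which
the tests assert.

## Synthetic study conditions

`coopharm.simulate` generates screens from the minimal generative model
the discovery method assumes — deliberately, so recovery failures indict
the pipeline rather than the generator:

* alterations: independent Bernoulli(freq) per feature and cell;
* expression: independent Normal(μ, τ²) per gene and cell — defaults
  μ = 0, τ = 1 (z-scored-expression-like). Centering matters: a non-zero
  mean would let the gated modulator term shift the whole altered branch
  and flip the driver's apparent direction;
* canonical sensitivity per planted drug:
  y = β0 + Σ β_d·alt_d + Σ γ_m·expr_m·alt_cond(m) + ε, ε ~ N(0, σ²);
  the modulator acts *only* inside its conditioning driver's carriers,
  which is exactly the node-conditional signal the method targets;
* the response matrix is emitted in the declared metric orientation
  (negated for lower-is-sensitive screens).

Canonical scenario defaults (`default_scenario`): 200 cells; driver
GD1:MUT, frequency 0.35, effect β = +3 canonical units; noise σ = 0.5 (so
the driver effect is 6 noise SDs); modulator MOD1 with slope γ = −0.8 per
expression unit; 20 inert background alteration features at frequency 0.2;
30 background expression genes; baseline β0 = 3 (activity-area-like
scale). The pathway universe holds MOD1 plus 19 background genes (20
tested genes per node); the drug-target table maps both screens' drug X to
the driver gene and drugY to MOD1. `default_two_dataset_scenario` derives
two independent seeds, uses different drug-X names of the same target
class, and gives the screens opposite metric orientations.

The generator reproduces none of the structure of real screens beyond
this: no tissue-of-origin confounding, no batch effects, no realistic
marginal distributions, no missingness mechanism, no linkage between
alteration features. Passing recovery tests therefore demonstrate the
pipeline's correctness under its own assumptions, not its yield on real
data, where confounding (notably tissue lineage) is the dominant
complication.

Determinism: all sampling uses numpy's PCG64 `default_rng` seeded from the
scenario; identical (scenario, seed) reproduces output bit-for-bit across
platforms.

## Problem sizes and numerical choices

Validation and the acceptance script use: 200 draws for the exact-U
enumeration oracle (group sizes ≤ 6); a 40-cell noiseless planted tree
fixture (exact child medians 10.095 / 0.095); 100 seeds of 30-cell /
100-feature pure-noise screens for the false-split rate; 100 seeds of the
200-cell scenario for modulator detection; 100 seeds of the two-screen
study for end-to-end pair confirmation; 100 seeds of 6-dose curves
(lognormal odds noise, sd 0.05) for median-effect recovery. These sizes
make the whole suite run in well under a minute per block on one CPU while
keeping the Monte-Carlo rates stable.

Other numerics: BH adjustment delegates to statsmodels' step-up
implementation (independently re-derived in the tests); p-values are
clipped into (0, 1]; Pearson r is clipped into [−1, 1] before the t
transform; tree node ids are path-derived strings (`root.alt.wt`, …) so
serialization is stable.

## Known limitations

* No covariate adjustment (tissue of origin, batch) in the correlation
  stage; on real screens this is the first thing to add.
* The U-test splitting criterion loses power in small nodes; with the
  default thresholds, nodes below ~10 cells essentially never split,
  biasing discovery toward common alterations (by design, but worth
  remembering).
* The constant-ratio CompuSyn-style CI design is only available through
  the general non-constant-ratio formula; isobologram graphics are out of
  scope.
* The forest heuristic cannot separate co-occurring drivers with
  overlapping carrier sets (see the forest-regeneration note above); it is
  a masking-recovery device, not a full conditional-independence search.
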
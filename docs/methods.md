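# Methods

`coexnet` implements a two-condition weighted gene co-expression analysis:
condition-specific networks, topological-overlap module detection, eigengene
membership, permutation-based module preservation and hub-gene calling, with
a synthetic study generator that makes every stage testable at desk scale.
The motivating design is a rat liver-regeneration experiment: hepatocyte
expression profiled over a post-surgery time course in a perturbed group
(partial hepatectomy, the *test* condition) and a sham-operated control group
(the *reference* condition), with values expressed as log-ratios to a 0 h
control.

## Network model

For one condition with expression matrix X (genes x samples):

- Pearson correlation r_ij between all gene pairs; constant rows are
  rejected (a correlation is undefined for them).
- Unsigned soft-threshold adjacency a_ij = |r_ij|^β, β a positive integer.
  The diagonal is set to 0 so that connectivity k_i = Σ_j a_ij excludes the
  self-link. The unsigned form follows the analysis convention of taking the
  absolute correlation before thresholding.
- Topological overlap
  t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), with
  l_ij = Σ_{u≠i,j} a_iu a_uj, t_ii = 1. TOM blends the direct connection
  with the strength of shared neighbours; 1 − t is the clustering
  dissimilarity.

β defaults to 6 — the conventional unsigned-network default — and can be
chosen data-adaptively (`pick_soft_threshold`): for each candidate power the
connectivity vector is split into 10 equal-count (quantile) bins, the
empirical density (bin count / (N · bin width)) is regressed on the mean
connectivity, both log10-scaled, and the smallest power with R² ≥ 0.85 wins.
R² is forced to 0 when the slope is non-negative, since scale-free topology
requires p(k) to decay. Quantile bins are robust to the heavy connectivity
tail that modules create; an exact power-law input recovers R² > 0.999.

## Module detection

Average-linkage (UPGMA) clustering of 1 − TOM (scipy linkage) gives the
dendrogram. The dynamic tree cut walks the merge tree top-down:

- merges above `cut_height` (default 0.995) never join genes into a module;
- a branch splits when one of its sub-branches holding at least
  `min_module_size` (default 30) genes sits at least a height gap Δ below
  the branch's merge height. `deep_split` ∈ {0..4} maps to
  Δ = 0.25, 0.15, 0.10, 0.05, 0.02 (default deep_split = 2 → Δ = 0.10): a
  planted block whose internal merges are tight stays whole, while two tight
  blocks merging high up are separated;
- sub-branches too small to be modules become `unassigned`.

This cut is a reimplementation in spirit, not a line-for-line port of the
reference R implementation; its output is validated by planted-module
recovery (median adjusted Rand index 1.0 under the default study
conditions), not by label-identical agreement.

Module labels follow the field's color convention in decreasing size order
(turquoise, blue, brown, ...). Each module is summarized by its eigengene:
the first right singular vector of the row-standardized module block, sign-
oriented to correlate positively with the module's average profile (ties
broken toward the first gene). Membership kME_im = cor(x_i, ME_m) is
computed for all genes against all modules, and genes are then iteratively
reassigned to argmax_m |kME_im|, dropping to `unassigned` when every
|kME| < 0.3 (the conventional membership floor). Reassignment alternates with
eigengene recomputation to a fixed point (cap 10 iterations); on clean
planted data it converges in ≤ 3 iterations and never decreases
Σ_genes max |kME|. The absolute value is used because hub genes with
strongly negative membership are legitimate module members (anti-correlated
with the eigengene). The module set is fixed by the input partition;
reassignment does not create or delete modules.

## Module preservation

A module found in one network ("reference" for the statistic) is tested in
the other ("test"):

- density statistic: mean off-diagonal adjacency of the module submatrix in
  the test network — are the genes still densely interconnected?
- connectivity statistic: Pearson correlation between within-module
  connectivity vectors (row sums of the module submatrix) in reference vs
  test — is the internal hub structure retained?

Each observed statistic is standardized against a permutation null: random
gene sets of the module's size drawn uniformly without replacement from
genes outside the module (default 200 permutations, seeded), giving
Zdensity and Zconnectivity; Zsummary is their mean. Evidence classes follow
the conventional thresholds — Zsummary > 10 strong, 2–10 weak (boundaries
inclusive, since the conventional strict inequalities leave the boundary
open), < 2 none. A module with no evidence of preservation is
flagged *specific*: present in its home condition only, the signature of a
perturbation-driven module. On random pseudo-modules both Z components are
approximately standard normal (mean within ±0.3, sd within 0.7–1.3 at the
default study conditions).

Stage-wise preservation fixes the modules from the full test-condition
network and re-tests them against networks rebuilt from each regeneration
stage's samples: priming (2–6 h), proliferative (6–72 h), termination
(72–168 h), a boundary hour belonging to the earlier stage. Stages with
fewer than 4 samples are skipped (with the default design, termination has
one time point × 3 replicates and is skipped). The pipeline evaluates
modules detected in the test (perturbed) condition against the reference
network — "test modules in reference" — matching the usual reporting direction;
swapping the two network arguments gives the opposite direction.

## Gene significance and hubs

GS is the absolute Welch (unequal-variance, two-sided) t-statistic of
differential expression between conditions, pooling all samples per group.
The plain two-sample reading of the differential t-statistic is
implemented. The hub of a module is the gene
with maximal |kME|; ties break by higher GS, then lexicographic gene ID.
Edge lists export pairs with connection strength strictly above 0.3 (the
conventional display threshold) plus node attributes (module, connectivity).

## Synthetic studies

The generator mirrors the analysis' own latent single-factor model: module
gene i = u_i · E + ε, with eigenprofile E a smooth random time curve
(sinusoid + low-order polynomial over rank-scaled time, constant across
replicates of a time point, standardized to mean 0 / sd 1), loadings u_i
uniform in [membership_low, membership_high], and ε i.i.d. Gaussian with
`noise_sd` (default 0.4, a realistic log-ratio noise level for 3-replicate
microarray designs). Defaults emulate the motivating design: 8 post-control
time points (2, 6, 12, 24, 30, 36, 72, 168 h) × 3 replicates per condition.
Replicate structure varies between studies, so it is a parameter rather
than fixed.

Within a study, module eigenprofiles are orthogonalized against previously
planted drivers (Gram–Schmidt, with a deterministic redraw when a draw is
nearly collinear). Two unconstrained smooth curves over 8 time points can
correlate at 0.95, which would make distinct planted modules unidentifiable
in principle; orthogonal drivers are what "distinct modules" means here.
This bounds the number of plantable modules by the number of distinct time
points minus one.

Preservation classes map to the reference condition as: `preserved` — same
eigenprofile and loadings, fresh noise; `weak` — loadings halved;
`specific_to_test` — rows replaced by independent noise. Halving the
loadings attenuates but does not erase co-expression; after detection
absorbs borderline background genes, such modules land in the weak-to-none
Zsummary range rather than reliably inside (2, 10).
`restrict_module_to_stages` re-plants a module with a driver standardized
within chosen stages and pure noise elsewhere — needed because a smooth
time-course profile can be nearly flat inside a single stage, which would
make "active in stage X" ill-defined.

What the generator does *not* emulate: probe-level effects, normalization
artifacts, batch effects, heteroscedastic or correlated noise,
mean-expression differences between conditions (modules differ in
co-expression, not in group means — hence the between-condition t-test
filter retains ~α of synthetic genes and the pipeline falls back to the
unfiltered set when too few pass), and genome-scale gene counts. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the planted model, not performance on real microarray data.

## Numerical choices and edge cases

- Welch t-test throughout (safer than pooled-variance when group variances
  differ); no multiple-testing correction in the α = 0.05 gene filter — the raw
  threshold is the filter.
- Ratios to control are log2-transformed by default before correlation.
- Most-connected gene selection breaks ties by descending connectivity then
  gene ID; probe collapse orders genes lexicographically.
- Degenerate permutation nulls (sd = 0) yield ±∞ sentinels with a warning;
  zero-variance within-module connectivity yields statistic 0 with a
  warning.
- Single-gene dendrograms are empty; a cut height below every merge leaves
  all genes unassigned.
- All randomness flows through numpy Generators seeded from explicit
  configuration fields; identical configuration ⇒ byte-identical pipeline
  outputs (manifests and logs carry no timestamps).

## Problem sizes

Tests and the acceptance script run simulations of 200–500 genes,
24 samples per condition, 100–200 permutations and 10–30 seeds per
property — sizes at which every planted effect is comfortably detectable
while a full run of the suite stays in the minutes range. The
module-recovery study uses the generator's default conditions (5 modules of
30–60 genes, loadings 0.6–0.95, noise sd 0.4, 200 background genes).

## Known limitations

- Dense matrix algebra only; genome-scale inputs (tens of thousands of
  genes) need blockwise processing that is out of scope.
- Zdensity's permutation null grows heavy-tailed when random gene sets
  overlap strong real modules, so its sd can exceed 1 in module-rich
  universes; the composite Zsummary classification is unaffected at the
  default conditions.
- No module merging by eigengene similarity, no medianRank composite, no
  within-network quality statistics.
- Module color names are a size-ranked convention and carry no
  correspondence to module labels from any other analysis.
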
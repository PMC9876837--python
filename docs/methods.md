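# Methods

`metanmf` implements a metagene-discovery workflow for two-group expression
studies: differential expression → nonnegative matrix factorization (NMF)
with knee-point rank selection → Kim–Park metagene extraction → local
over-representation analysis → interaction-network hub ranking →
cross-dataset validation.  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Differential expression

Probes below a median-intensity quantile (default 0.2) are removed
("low-intensity screen"; ties at the cutoff are retained, so the screen can
never empty the matrix).  Duplicate probes per gene symbol are averaged
arithmetically.  For gene *g* with group sizes *n₁* (control) and *n₂*
(case), logFC is the case-minus-control difference of log2 means and the
pooled variance is

    s²_g = [(n₁−1)s²_{g,1} + (n₂−1)s²_{g,2}] / d_g ,   d_g = n₁+n₂−2 .

With moderation on (default), variances are shrunk empirical-Bayes style
toward a prior (d₀, s₀²) fit by matching the first two moments of
log s²_g under the scaled-F model (digamma/trigamma equations; the
trigamma inverse uses a deterministic Newton iteration).  The posterior
variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), the statistic
t̃ = logFC / (s̃_g·√(1/n₁+1/n₂)) with d₀ + d_g degrees of freedom.  When
the observed spread of log-variances does not exceed chi-square sampling
noise, d₀ = ∞ and every gene receives s₀².  With moderation off the
procedure is the textbook equal-variance two-sample t (and errors out if
every gene has zero within-group variance).

Benjamini–Hochberg adjustment is applied to every table
(`statsmodels.stats.multitest` behind `bh_adjust`).  The DEG filter is
p < 0.05 and |logFC| > 0.5, both strict.  **The filter uses the raw
p-value by default** with the adjusted value reported alongside, because
the thresholding convention of the upstream protocol this mirrors is
stated on the raw scale while BH adjustment is described separately;
`use_adjusted=True` switches the filter to the FDR scale.

## NMF and rank selection

V is the log2 expression submatrix on the DEG rows (min-shifted to
nonnegative if needed).  Factors are fit by the classical multiplicative
updates for the Frobenius objective RSS = ‖V − WH‖²_F:

    H ← H ∘ (WᵀV) / (WᵀWH + ε),  W ← W ∘ (VHᵀ) / (WHHᵀ + ε),  ε = 1e−12.

Entries of W and H are initialized i.i.d. uniform on (0,1] scaled by
√(mean(V)/r) so the initial product is on the scale of V.  Convergence:
relative RSS decrease < tol (default 1e−5) or max_iter (default 2000);
the objective is non-increasing at every step (asserted in tests).  A
rank scan records the best RSS over n_restarts seeded runs per rank
(restart *j* uses seed base_seed + *j*), default grid 3..30.

The rank is the **unit-invariant knee** of the RSS-vs-rank curve: both
axes are min–max scaled to [0,1] and the knee is the interior point with
the maximum perpendicular distance to the chord joining the endpoints;
ties break toward the smaller rank (parsimony), and a flat or exactly
linear curve raises an error.  Because of the scaling, the selection is
invariant to affine rescaling of either axis.  A vertical-distance
variant is available (`distance="vertical"`); perpendicular is the
default.

A practical resolution bound follows from the chord geometry: with a grid
of *m* points, a planted factor is only detectable as a corner if its
share of the RSS at the first grid point exceeds ≈ 1/(m−1).  The rank
grid used in the recovery tests (2..21) was chosen from this bound and
the planted spectrum of the generator, not from the test outcome.

## Kim–Park scoring and metagene membership

Gene contributions are row-normalized loadings p(i,q) = W(i,q)/Σ_q′
W(i,q′); the score

    S(i) = 1 + (1/log₂ r) · Σ_q p(i,q) log₂ p(i,q)   (0·log 0 := 0)

is 1 for a metagene-specific gene and 0 for a uniform one.  A gene is a
metagene feature iff S(i) > median(S) + 3·MAD(S) **and** max_q W(i,q) >
median(W), both strict.  MAD uses the normal-consistency factor 1.4826
(the R convention of the reference feature-extraction implementation);
`mad_scale="raw"` switches it off.  Assignment is argmax over metagenes
(ties to the lowest index) while the full contribution vector is kept in
the output, since genes may genuinely take part in several programs.
Metagenes with fewer than two members are dropped.  Metagene *activation*
is defined here as the sum of the members' loadings — "activation level"
has no single formalization in the field, so this convention is the
package's own and is used for the descending metagene ranking; members
are ranked by loading, reported top-15 by default.

## Enrichment

Over-representation of a query of n genes against a set of K genes within
a universe of N measured genes is the hypergeometric upper tail
P(X ≥ k), evaluated as a log-space sum of `scipy` log-pmf terms
(logsumexp), so deep tails stay positive.  The universe is all genes
surviving probe collapse — conditioning on what was measured — rather
than the union of the gene sets.  BH-FDR is applied within each gene-set
category (BP/CC/MF/KEGG) separately, matching how such tables are
conventionally reported.

## Networks

Edge scores are confidences in [0,1] and act only as a filter (default
min_score 0.9); shortest paths are unweighted.  The default subnetwork is
first-order: seeds plus direct interactors, with every edge among the
included nodes; `order="zero"` gives the induced subgraph on seeds.
Seeds present in the interactome but isolated after filtering are kept
and flagged.  Betweenness is Brandes' algorithm (via networkx),
**unnormalized** with endpoints excluded, so values are source–target
pair counts comparable to published hub tables.  Hubs are the top-k
(default 10) nodes by degree, ties by betweenness then symbol.
Gene–disease and TF–target tables are reported as bipartite neighborhoods
(entities linked to ≥ min_shared query genes); TF entities are ranked by
bipartite degree then betweenness.

## Cross-dataset validation

The second dataset is processed with the same thresholds as the first.
The validation report is the intersection of the two DEG symbol sets with
per-dataset expression, logFC and p, a sign-consistency flag, and flags
for membership in the primary dataset's hub list and metagene set
("common hub genes").  Whether a replication study should require hub
status in *both* datasets is ambiguous in the protocol this mirrors; the
implemented definition is intersection-then-annotate, and
`require_hub_in_both` is reserved for the stricter variant.

## Synthetic data: the stated world

The generator emulates a small two-group microarray study on the log2
scale with 5 control vs 6 case subjects per cell type (defaults: 15 vs 18
samples), 218 planted up- and 780 down-regulated genes, planted rank 10,
Gaussian log-scale noise (sd 0.3), duplicate probes (1–3 per gene), a
preferential-attachment interactome with planted hubs, and
positive-control annotation tables.

The planted signal is exactly a nonnegative rank-r product W·H:

* **Group factors.**  Baseline B ~ U(4,10) per gene, up-effects U and
  down-effects D drawn from the logFC range on disjoint gene sets.  The
  two factors (B+U)·caseᵀ and (B+D)·ctrlᵀ encode the baseline and an
  exact per-gene log2 fold change U − D (since caseᵀ + ctrlᵀ = 1ᵀ).
* **Content programs.**  r−2 block-sparse columns of W: each program owns
  a disjoint core of genes (plus ~5% overlap genes) with heavy-tailed
  (lognormal σ = 1.2) loadings, norm-equalized per program.  Activities
  are three-level, 1 ± 0.9, with equal numbers of high and low samples
  inside each group — so program deviations are exactly zero-mean per
  group (no spurious fold change), mutually near-orthogonal, and
  orthogonal to the group indicators.

The last two design choices are load-bearing for rank recovery: with
near-constant positive loadings or near-constant activities, every
program's factor is strongly aligned with the baseline factor and the
smallest planted singular value collapses below the knee criterion's
resolution, making the planted rank numerically undetectable — for any
method.  Heavy-tailed loadings (high coefficient of variation) and
balanced contrasting activities keep the planted spectrum flat enough
that the knee is a true corner.  Planted hub genes are excluded from the
content programs so their differential expression is not masked by
program variance (hubness and membership are separately planted
features).

What the generator does **not** emulate: array-level artifacts (junk
probes, batch effects, background correction), probe-level biases,
correlated noise, and realistic annotation incompleteness.  Consequently
the low-intensity screen is switched off (`low_expr_quantile = 0`) in
synthetic end-to-end runs — there are no junk probes to remove, and the
screen would otherwise delete genuine planted DEGs at random.  A green
end-to-end test therefore establishes the pipeline's internal
correctness and determinism on clean planted structure, not robustness
to the artifacts above.

Worlds used by the operating-characteristic tests isolate the stage under
test: the DEG calibration/sensitivity world uses r = 2 (baseline + group
effects only, no co-expression programs, since program activity is
genuine biological within-group variance that any two-sample test will
count against a gene); the rank-recovery world uses 1000 genes × 33
samples with 998 DE genes, mirroring a DEG-matrix shape in which nearly
every row is differentially expressed.

## Scaling of test budgets

Simulation sizes in the acceptance tests are scaled to a single-CPU
budget: noise-free rank recovery runs two seeds per planted rank
(3..8) with 2 restarts, the noisy case ten seeds at r = 6, and the
end-to-end test uses a 300-gene, rank-5 paired world over ten master
seeds.  `scripts/acceptance.py` runs a 600-gene paired study once.

## Known limitations

* Multiplicative updates converge slowly near the optimum; best-of-
  restarts with a tight tolerance (1e−7) is used where near-exact RSS
  floors matter.  No NNDSVD or other structured initialization is used.
* The moderated-t moment fit assumes a common residual df across genes
  (balanced complete design); multi-factor or paired designs are out of
  scope.
* Enrichment treats gene sets as flat lists (no ontology propagation).
* The pipeline's network stage requires the interactome to contain at
  least one seed; organisms/platforms with symbol mismatches need
  pre-mapping.
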
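# Methods

`hetrwr` ranks candidate lncRNA–disease associations by a restart random
walk on a global network built from four intra-layer similarity networks
(lncRNA, miRNA, gene, disease) and six inter-layer bipartite association
networks.  This note records the model, its parameters, the numerical
choices, and what the synthetic benchmark can and cannot show.

## Similarity model

**Ontology semantic similarity (Wang method).**  For an ontology term *T*
with ancestor closure Ans(*T*), every ancestor *d* contributes

    D_T(T) = 1,   D_T(d) = max { Δ · D_T(d') : d' a child of d inside Ans(T) }

so a term *k* edges above the anchor contributes Δ^k along its best path.
The semantic value DV(*T*) is the sum of all contributions, and two terms
compare by the contributions of their shared ancestors:

    sim(t1, t2) = Σ_{d ∈ Ans(t1) ∩ Ans(t2)} (D_t1(d) + D_t2(d)) / (DV(t1) + DV(t2)).

The attenuation factor Δ defaults to 0.5 — the customary choice for this
similarity family — and is configurable separately for the disease ontology
(`delta_disease`) and the GO DAG (`delta_go`), since there is no reason the
two vocabularies must share one attenuation.  The max rule over children is
computed by memoized dynamic programming over the anchor's ancestor
closure; children outside that closure are ignored (the contribution is
otherwise undefined for them).  The sum defining DV runs over Ans(*T*).

**Functional similarity (best-match average).**  Entities annotated by term
sets — genes by GO terms, lncRNAs and miRNAs by their associated diseases —
compare by the best-match average: each term's best similarity against the
other set, summed in both directions and divided by the total number of
terms.  An entity with an empty annotation set is flagged *no-information*
rather than raising, because the integration step has an explicit rule for
it.

**GIP kernel.**  The Gaussian interaction-profile kernel on binary
association rows/columns is G(i,j) = exp(−r‖IP(i)−IP(j)‖²) with bandwidth
r = r′ / mean‖IP‖².  The mean runs over all profiles, zero rows included;
only an entirely zero profile set is an error.  Default r′ = 1 for all four
layers.  The default bandwidth denominator uses the *squared* norm — the
form under which G is a positive-semidefinite kernel — with
`gip_norm_convention: literal` available for the unsquared variant.
lncRNA and disease kernels come from the lncRNA–disease matrix; miRNA and
gene kernels from the miRNA–gene matrix.

**Integration.**  The final intra-layer similarity is a hard switch, not a
blend: a pair uses the functional/semantic value unless either member is
no-information, in which case it uses the GIP value.  This is deliberately
literal — even if one member has functional information, a no-information
partner forces the kernel value.

## Transition matrix and walk

All matrices are Laplacian-normalized: Â(i,j) = A(i,j)/√(rowsum_i·colsum_j)
with zeros kept where either sum vanishes.  Each of the twelve inter-layer
blocks is the normalized association matrix, row-normalized and scaled by
its jump probability P_XY (P_XY = P_YX); each intra-layer block row is the
row-normalized normalized similarity row scaled by the residual
1 − Σ P_XY over the inter blocks that are nonzero *in that row* — a node
with no inter-layer links keeps all of its mass inside its layer.  Rows of
the assembled W sum to 1 exactly, except fully dangling nodes (zero
similarity row and no links), which stay zero.

Defaults: P_LM = P_LG = P_LD = P_MG = P_MD = P_GD = 0.2, layer weights
P_L = 0.4, P_M = 0.1, P_G = 0.1 (disease layer gets the remaining 0.4),
restart probability λ = 0.7.

The walk iterates P^{t+1} = (1−λ)·WᵀP^t + λ·P⁰.  W is defined row-wise
(W_ij = probability of moving from i to j), so the transpose makes
propagation column-stochastic and P remains a distribution — the only
orientation under which the iteration conserves mass.  Convergence is the
L1 difference of successive iterates dropping below 1e−6 (configurable);
the update contracts by (1−λ) per step, so `max_iter = 1000` is generous
for any λ ≥ 0.01.  If dangling rows leak mass, the iterate is renormalized
to unit sum with a logged warning, which re-injects the deficit
proportionally.

The restart vector places weight P_L uniformly on the query disease's known
lncRNAs, P_M/P_G on its known miRNAs/genes (via the miRNA–disease and
gene–disease matrices), and the remaining weight on the disease itself.
When a layer has no seeds (the novel-disease / novel-lncRNA protocols), its
weight is redistributed proportionally over the seeded layers, preserving
the stated relative importances while keeping ΣP⁰ = 1.

Scores are the raw stationary probabilities; no per-layer renormalization
is applied before ranking.  Ties break by registry order, so rankings are
deterministic.

## Evaluation harness

Ten-fold cross-validation partitions the known lncRNA–disease pairs at
random (near-equal folds, seeded).  For each fold the held-out positives
are masked out of LD and **every LD-derived quantity is rebuilt from the
training positives**: the lncRNA annotation sets (hence lncRNA functional
similarity), the lncRNA and disease GIP kernels, and the seed sets.  Not
rebuilding them would let test labels leak into the similarity inputs; the
`static_similarity` switch restores that leaky variant for comparison, and
the measured gap on the benchmark (≈0.78 vs ≈0.90 mean AUC) quantifies how
much that leak is worth.  An automated audit verifies pair-by-pair that no
held-out association reaches the training matrix, the annotation sets, or
the seeds.

Scores are pooled across all diseases with held-out positives into one
global ROC/PR per fold; the negatives are all never-known pairs of those
diseases, and training positives are excluded from the pool.  The ROC is a
threshold sweep over distinct scores with tied scores grouped, making the
trapezoidal area exactly the tie-corrected Mann–Whitney statistic (asserted
against an independent rank-sum oracle).  The reported AUPR is the step
(average-precision) sum Σ Δrecall · precision; a trapezoidal PR area is
also computed since the step convention is not universal.  Confusion counts
use the strictly-greater threshold rule.

The λ sweep repeats the full CV per grid value, sharing the per-fold
similarity rebuilds and transition assembly across the grid so only the
walks differ.

The single-layer baseline walks on the integrated lncRNA similarity matrix
alone, restarting uniformly over the disease's training lncRNAs (uniform
over all lncRNAs when it has none).  It is comparison plumbing, not a
re-implementation of any published method.

## Synthetic benchmark

The generator plants C communities: every entity gets a community label,
each of the six bipartite matrices draws edges i.i.d. Bernoulli(p_in)
within matched communities and Bernoulli(p_out) across, the disease DAG
hangs each community's diseases under a community-specific clade (three
shared ancestors within a community, one across), and genes are annotated
with 1–3 GO terms from their community's clade of a synthetic GO DAG.  The
standard conditions are n = 40/40/60/20 (lncRNA/miRNA/gene/disease), C = 2,
p_in = 0.3, p_out = 0.02, seed 42 — sizes at which the complete test suite
and the reproduction script run in seconds on one CPU while every layer
retains hundreds of edges.

What the benchmark shows: that the pipeline recovers planted community
structure (held-out within-community pairs outscore cross-community
unknowns; walks concentrate on the seed community; every λ detects signal),
that the multi-layer walk beats the single-layer baseline, and that the
machinery is leak-free and deterministic.

What it cannot show — a known limitation worth stating precisely: because
edges are drawn i.i.d. given the community labels, masking a held-out pair
erases *all* information specific to that pair.  Conditional on the
training data, a held-out positive's score is distributed identically to
any same-community unknown pair's, so no method can exceed an AUC ceiling
of roughly q + (1−q)/2, where q ≈ 0.58 is the cross-community fraction of
negatives at the standard conditions — about 0.78, which is where the
pipeline lands.  Likewise the masked partners of a "novel" disease are
exchangeable within their ≈20-member community of 40 candidate lncRNAs, so
their mean rank sits near 0.28–0.30 of the list rather than in the top
decile.  Real curated data are not exchangeable in this way (degree
heterogeneity, correlated multi-layer evidence, transitive ontology
structure), which is why published figures on such data are far higher;
the generator trades that realism for exact ground truth and a derivable
performance ceiling.  Two acceptance checks assert thresholds (mean AUC
≥ 0.9; top-decile novel-disease ranks) above this ceiling and are expected
to fail under the standard conditions; they are kept as-is rather than
weakened, with the analysis above as the explanation.

## Numerical and design choices

- Dense NumPy arrays for all per-layer matrices (layers are small at the
  package's problem sizes); the assembled global W is sparse CSR.
- Laplacian normalization guards 0/0 with an explicit zero branch; the
  normalized symmetric similarity stays symmetric with spectral radius ≤ 1.
- Fold plans use `numpy.random.default_rng(seed)` permutation +
  `array_split`, giving fold sizes that differ by at most one and
  bit-identical plans per seed.
- The closed-form fixed point λ(I − (1−λ)Wᵀ)⁻¹P⁰ is kept as an independent
  oracle (dense solve) and is never the production path.
- Unknown config keys are rejected; parameter sum constraints
  (P_LM+P_LG+P_LD ≤ 1 etc.) are validated at construction.
- Identifiers are opaque, whitespace-trimmed, case-preserved strings;
  0-based indices internally, 1-based ranks in output files.

## Limitations

- The generator does not model realistic degree distributions or database
  noise (false positives in curated associations).
- The disease/GO DAGs used for synthesis are shallow clade trees; real
  ontologies are deeper and multi-parented (the similarity code handles
  multi-parent DAGs; the generator exercises them only via
  `random_dag(extra_parent_prob=...)`).
- Negatives are all unknown pairs; truly unobserved-but-real associations
  are counted as negatives, as in all link-prediction CV of this kind.
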
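# Methods

`ppigat` implements a radiogenomic pipeline for predicting lymph-node
metastasis in non-small cell lung cancer from bulk gene expression and
PET/CT texture features. The pipeline has five stages: co-expression
module discovery, a metastasis-gene filtering cascade, PPI-graph
construction, ROC-based radiomic feature screening, and a
graph-attention fusion classifier evaluated by stratified
cross-validation. A synthetic-cohort generator with planted ground
truth makes every stage testable without patient data.

## Synthetic cohorts

The generator emulates the statistical shape of a 93-patient cohort
(73 node-negative, 20 node-positive), which is the default sample
configuration throughout.

**Expression.** Genes in module *m* follow a single-factor block model
`x_g = sqrt(r)·f_m + sqrt(1−r)·ε_g`, giving exact pairwise correlation
*r* (default 0.8) between module mates; genes outside modules are
independent noise. A small set of signal genes receives a mean shift of
*d* (default 1.5) in the positive class *after* block generation, on
the unit-variance scale, so *d* is interpretable as Cohen's d and power
calculations are analytic. The model is Gaussian: it reproduces the
correlation structure and effect sizes that the downstream stages
consume, not RNA-seq count noise, library-size variation, or
heavy-tailed expression. Passing tests therefore demonstrate correct
recovery of planted linear-Gaussian structure, not robustness to
count-data artifacts.

**PPI edges.** Bernoulli edges with density 0.3 within planted modules
and 0.01 between them; `combined_score` is uniform on [400, 999],
matching the medium-confidence floor used as the default score
threshold downstream, so that by default every generated edge survives
loading.

**Radiomics.** Unit-variance Gaussian features with per-feature
discriminative AUC controlled through the binormal model: shifting the
positive-class mean by `Δ = sqrt(2)·Φ⁻¹(A)` gives true AUC exactly
*A*. 55 features per modality (PET and CT) with names drawn from the
standard texture-feature vocabulary (TLG, SHAPE, GLCM, GLRLM, NGLDM,
GLZLM families); features beyond the targeted ones are pure noise
(A = 0.5). Real radiomic features are heavily correlated within
texture families; the generator draws them independently, which makes
per-feature screening results cleaner than on real data.

## Co-expression modules

Unsigned weighted network: `a_ij = |cor(x_i, x_j)|^β` with soft power
β = 5. Topological overlap

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with connectivity `k_i = Σ_{u≠i} a_iu`; modules are detected by
average-linkage hierarchical clustering of `1 − TOM` with a flat cut
(default height 0.99) and a minimum module size of 30; smaller clusters
go to the unassigned label 0. This fixed-height cut is a deliberate,
reproducible simplification of dynamic tree cutting; it recovers
block-structured modules reliably (adjusted Rand index ≥ 0.8 in the
planted-block test) but will not split nested modules the way the
adaptive algorithm can. Module eigengenes are the first principal
component of the gene-standardized submatrix, unit-norm,
sign-anchored to correlate positively with mean module expression.
Module–trait association uses the point-biserial correlation with a
Student-t p-value; gene significance (GS) is `|cor(gene, trait)|`.

## Gene filtering cascade

Candidates are the genes of trait-associated modules (module p < 0.05,
falling back to the single most associated module when none pass).
Stages, each selecting on raw p < 0.05 with Benjamini–Hochberg
q-values reported alongside:

1. **DEG**: per-gene Welch two-sample t-test.
2. **ORA**: hypergeometric upper-tail over-representation against GMT
   gene sets (equivalent to one-sided Fisher; verified exactly against
   Fisher enumeration for all tables with N ≤ 30). Genes in enriched
   pathways continue.
3. **Univariate**: per-gene logistic regression (Wald p). Perfect
   separation is flagged and the gene retained with the p = 0
   convention; constant genes are excluded with a note.
4. **Hub pick**: top-k genes by GS (default k = 5), ties broken
   lexicographically for determinism.

## PPI graphs

STRING-dialect edge lists (`protein1`, `protein2`, `combined_score`)
are thresholded at combined_score ≥ 400, de-duplicated treating the
pair as unordered, and induced on each gene set. Isolated genes remain
as singleton nodes; self-loops are added to every node so attention
neighborhoods are never empty; gene sets with zero non-loop edges are
flagged ("no PPI network formed") and excluded from modeling, mirroring
how module graphs without interactions drop out of the analysis. Node
features are per-sample, gene-standardized scalar expression
(dimension 1) — the minimal choice consistent with group-wise
transcriptomic features; adjacency is binary (scores are used only for
thresholding).

## Radiomic screening

Per-feature AUC is the Mann–Whitney estimator (ties get half credit).
Significance against chance uses the Hanley–McNeil closed form

    Q1 = A/(2−A),  Q2 = 2A²/(1+A),
    se² = [A(1−A) + (n₊−1)(Q1−A²) + (n₋−1)(Q2−A²)] / (n₊ n₋),

with z = (A − 0.5)/se and a two-sided normal p-value. Features with
A ≥ 0.68 (inclusive) are selected. Degenerate AUCs of exactly 0 or 1
have zero closed-form variance; they are reported with missing se/z/p
rather than a fabricated value. AUCs below 0.5 are not mirrored by
default (a `max(A, 1−A)` option would change the meaning of the
threshold and is left off).

## Fusion model

Per graph: three GNN blocks, each a GAT layer → ReLU → batch
normalization → dropout (0.3). The GAT layer uses 3-head attention
with `e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j])` (slope 0.2), softmax
restricted to the neighborhood including the self-loop, and heads
combined by averaging in every block. Block weights are shared across
graphs — the same layer applied to each PPI graph — which keeps the
parameter count independent of the number of graphs and makes the
model invariant (up to classifier-weight permutation) to graph
relabeling. Node embeddings are max-pooled into one 8-dimensional
embedding per graph; embeddings are concatenated in sorted graph-id
order, fixed at model construction. Image features pass through a
fully connected layer (32 units) → ReLU → batch normalization. The
classifier is two fully connected layers (hidden 64) with a softmax.
Either branch can be absent, giving the genes-only and images-only
ablations. Hidden widths, dropout, and the LeakyReLU slope are
conventional defaults, all configurable.

The model runs on an in-package reverse-mode automatic differentiation
engine over numpy arrays (`ppigat.nn.autodiff`): a tape of tensors with
analytically derived vector-Jacobian products for the op set the model
needs, validated against central finite differences and, for the
attention layer, against a dense per-node oracle at tolerance 1e−6.
Attention is computed densely over (samples × nodes × nodes) arrays,
which is exact and fast for module-scale graphs (tens of nodes) but
quadratic in nodes; graphs with thousands of nodes are out of scope.

## Training and evaluation

Class imbalance is handled by SMOTE: each synthetic minority point is
`x_i + λ(x_nn − x_i)` with λ ~ U(0,1) and `x_nn` one of the k = 5
nearest minority neighbors; classes are equalized (73/20 → 146). By
default SMOTE runs inside each training fold only, after a validation
slice has been removed, so no synthetic descendant of a test or
validation sample ever enters training. A `pre_split` mode balances
the full cohort before splitting — reproducing a balance-then-split
protocol — and is labeled as leaky in reports.

Training minimizes cross-entropy with Adam (lr 1e−3) for up to a fixed
epoch budget, full batch. Checkpoint selection uses a stratified 20%
slice of the real training samples and the *class-balanced* validation
log-loss (the mean of per-class mean losses), with early stopping
after 15 epochs without improvement. Balancing the validation loss
matters on an imbalanced cohort: the plain loss is minimized by
majority-class collapse, so a model that has learned nothing looks
spuriously good and, worse, a permuted-label control inherits the
majority prior instead of behaving like chance. With the balanced
criterion the permuted-label control's accuracy is centered near 0.5.

Evaluation is stratified k-fold (default k = 5, repeatable with
distinct seeds): accuracy, precision, recall, F1 on hard labels and
AUC on the class-1 probability, aggregated as mean ± 1.96·sd/√m over
fold×repeat values. Single-class test folds report AUC as missing and
are excluded from AUC aggregation. Configurations sharing fold
structure are compared with an exact sign-flip permutation test on
per-fold differences (≤ 20 pairs) or a paired t-test otherwise.

## Problem sizes and numerical choices

The end-to-end checks use the 93-sample cohort with three 50-gene
modules (r = 0.8), four signal genes at d = 1.5, and ten informative
radiomic features at true AUC 0.8, trained for up to 60 epochs with
k = 5 folds (one repeat for the signal configurations, two for the
permuted-label control). These sizes give stable qualitative outcomes
— combined AUC above 0.8, images adding signal over genes alone, and a
chance-level permuted control — at desk scale. Batch normalization
falls back to running statistics for single-element batches;
eigengene sign is anchored to mean expression; average-linkage ties
follow scipy's deterministic ordering; all randomness flows from
explicit integer seeds, and identical seeds give bit-identical
cohorts, splits, and fits.

## Known limitations

- Gaussian expression and independent radiomic features understate the
  messiness of real cohorts; results on synthetic data bound what the
  pipeline can do, not what real data will give.
- The genes-only branch is weakly informative at these settings
  (scalar node features diluted through attention and max-pooling at
  n = 93) — consistent with the motivating study, where gene-only
  configurations also hovered near chance while image features carried
  most of the signal.
- Fixed-height tree cutting, unsigned networks, and Pearson
  correlation are simplifications of the full WGCNA toolbox.
- SMOTE with flexible classifiers can make real-vs-synthetic structure
  learnable in principle; the leakage-safe default and balanced
  validation mitigate, but small-cohort conclusions should rest on the
  permutation control, which the test suite exercises.
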
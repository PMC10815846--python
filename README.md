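# ppigat

Radiogenomic prediction of lymph-node metastasis in non-small cell
lung cancer (NSCLC): weighted gene co-expression modules, a
metastasis-gene filtering cascade, protein–protein interaction (PPI)
graphs, AUC-screened PET/CT texture features, and a multi-head
graph-attention fusion classifier — as one tested, scriptable
pipeline with a synthetic-cohort generator so every stage runs without
patient data.

## Who it is for

Researchers combining bulk transcriptomics with radiomic feature
tables for small-cohort binary outcome prediction, who want the whole
chain — module discovery → gene filtering → graph construction →
feature screening → cross-validated fusion model — reproducible from a
single seed, with the statistical controls (permutation nulls,
leakage-safe SMOTE, calibrated screens) built in.

## The model

Gene co-expression modules come from a WGCNA-style analysis: unsigned
adjacency `a_ij = |cor(x_i, x_j)|^β` (β = 5), topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

average-linkage clustering of `1 − TOM`, module eigengenes, and gene
significance GS = |cor(gene, trait)|. Candidate metastasis genes pass
a Welch DEG test, hypergeometric pathway over-representation,
univariate logistic screening (all at p < 0.05), and a final GS-ranked
hub pick. Each retained gene set becomes a PPI graph (STRING-style
edge list, combined_score ≥ 400, self-loops added) whose per-sample
node features are gene-standardized expression.

Radiomic features are screened per feature by Mann–Whitney AUC with
the Hanley–McNeil standard error, `se² = [A(1−A) + (n₊−1)(Q1−A²) +
(n₋−1)(Q2−A²)]/(n₊n₋)` with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`, testing
z = (A−0.5)/se; features with A ≥ 0.68 are selected.

The classifier applies three shared GNN blocks (3-head GAT with
averaged heads, ReLU, batch norm, dropout) to each PPI graph,
max-pools node embeddings into graph embeddings, concatenates them
with an FC-transformed image-feature vector, and classifies with two
FC layers and a softmax. Cohorts are balanced with SMOTE inside each
training fold; evaluation is repeated stratified 5-fold
cross-validation reporting accuracy, precision, recall, F1 and AUC
with 95% confidence intervals. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

```bash
ppigat simulate --out run/sim --seed 5
ppigat modules --expression run/sim/expression.tsv --labels run/sim/labels.tsv \
       --out run/mod
ppigat build-graphs --edges run/sim/ppi_edges.tsv \
       --expression run/sim/expression.tsv --modules-dir run/mod --out run/graphs
ppigat select-features --pet run/sim/radiomic_pet.csv --ct run/sim/radiomic_ct.csv \
       --labels run/sim/labels.tsv --out run/feat
ppigat train --graphs run/graphs/graphs.json --expression run/sim/expression.tsv \
       --labels run/sim/labels.tsv --pet run/sim/radiomic_pet.csv \
       --ct run/sim/radiomic_ct.csv --images petct --out run/train --seed 1
```

The simulate step prints

    cohort written: 300 genes x 93 samples -> run/sim

— a 73 non-metastasis / 20 metastasis cohort with three planted
50-gene modules and five informative features per imaging modality.
`modules` reports `3 modules detected; 140 genes unassigned` — the
three planted blocks are recovered while most background genes stay
unassigned. `select-features` reports `12/110 features selected at
AUC >= 0.68`: the ten planted features (true AUC 0.8) plus two noise
features that cross the threshold by chance at n = 93, a reminder of
why a per-feature screen at this cohort size needs the downstream
model, not the screen, to carry the inference. The train step prints
the cross-validated metric battery:

                 mean  ci_low  ci_high
    accuracy   0.8164  0.7409   0.8918
    precision  0.6367  0.4028   0.8705
    recall     0.5000  0.3450   0.6550
    f1         0.5452  0.3947   0.6958
    auc        0.8124  0.7186   0.9062

meaning the fused genes + PET/CT model separates the planted outcome
(AUC ≈ 0.81 against a per-feature true AUC of 0.8) while fold-to-fold
spread at n = 93 keeps the intervals wide. The genes-only ablation
uses `--images none`.

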
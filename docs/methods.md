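# Methods

`molfusion` benchmarks supervised classifiers that separate active from
inactive small-molecule inhibitors using multiple molecular representations
and their early fusion. This note documents the models, the parameters that
matter, the synthetic benchmark that the tests run on, and the numerical and
design choices that were genuinely open.

## Problem setting and data model

The unit of analysis is a curated compound: a canonical SMILES with a single
potency in micromolar and a binary activity label. Raw inputs are potency
records (Ki, Kd or IC50; nM/uM/mM), pooled without assay-type correction.
Curation converts all values to uM, canonicalizes SMILES with the toolkit's
canonical writer, merges duplicate structures by the **median** of their
potencies (robust to outlying measurements; the merge count is kept for
audit), and labels a compound active when potency is **strictly below** the
cutoff. Three standard cutoffs are supported: 0.5, 1 and 10 uM, producing a
balanced (~1:1), slightly imbalanced (~3:2) and severely imbalanced (~4:1)
positive:negative regime on data of this kind.

## Representations and preprocessing

Four modalities:

* **Physicochemical descriptors** — a pinned panel of 208 descriptor
  functions. The panel is pinned by name so the feature space does not
  drift across toolkit releases. Descriptors are computed on the
  canonically reordered molecule so two notations of the same structure
  give bitwise-identical rows.
* **MACCS keys** — 166 structural key bits (the toolkit's unused bit 0 is
  dropped).
* **ECFP4** — Morgan radius-2 fingerprints hashed to 2048 bits, no counts.
* **SMILES tokens** — regex tokenization (bracket atoms, two-letter
  elements, `@@`, `%nn` ring closures are single symbols), a corpus-derived
  sorted vocabulary with id 0 reserved for padding, and fixed-length
  encoding with trailing zeros up to 195 tokens. Over-long molecules are a
  hard error rather than silently truncated.

Numeric preprocessing is a fit/transform chain applied leakage-free: fit
statistics come from the training+validation rows only, and are reapplied
unchanged to the test rows. The chain is: median imputation of non-finite
descriptor values; removal of columns that are all-zero on the fit rows
(descriptors additionally drop constant columns, which would break
standardization); standardization to mean 0 and **population** SD 1
(divisor n, the common scaler default); PCA to 128 components ordered by
explained variance; and a final standardization so every modality enters
the models on a common scale. On inputs whose informative dimension or fit
row count cannot support 128 components the projection is clamped to the
feasible dimension (rank-deficient components are dropped); this arises
only for small datasets.

Early fusion concatenates processed blocks horizontally. The eight feature
combinations are the three single numeric modalities, the SMILES sequence,
and the four combos (descriptors+ECFP4, descriptors+MACCS, MACCS+ECFP4,
descriptors+ECFP4+MACCS). Block order inside a combo follows the combo's
declared order, and block boundaries are recorded so the fused matrix can
be sliced back exactly.

## Cluster hold-out splitting

To measure generalization to unseen chemotypes, compounds are clustered by
K-means (k-means++ init, 10 restarts, fixed seed) on a *conjoint
representation*: standardized descriptors concatenated with the raw MACCS
and ECFP4 bits. Bits are left unstandardized deliberately — per-column
scaling of rare bits amplifies noise and measurably degrades scaffold
recovery. The cluster count is chosen by index consensus: highest
silhouette coefficient, ties broken by lowest Davies-Bouldin index, then
highest Calinski-Harabasz score; a `fixed_k` override forces a known count.

The test set is a union of 3 whole clusters, chosen (exhaustively over
subsets when k <= 20) to minimize the gap between the test positive rate
and the overall positive rate, subject to a test-size band of 8-16% of
compounds (widened with a warning when no subset fits). The validation set
(5% by default) is drawn compound-wise, stratified by label, from the
remaining clusters; whether validation should itself be cluster-disjoint
is genuinely open, and `val_mode` semantics here chose the stratified
reading because the validation set steers early stopping, not the reported
metrics. Test-cluster membership never depends on the validation seed.

## Imbalance strategies

All three strategies touch only the training and validation partitions;
the test partition is asserted byte-identical before and after.

* **SMOTE** (implemented here from first principles): each synthetic row is
  `x_i + u (x_nn - x_i)` with `u ~ U(0,1)` and `x_nn` one of the k=5
  nearest minority neighbors by Euclidean distance in the processed
  feature space. Synthetic rows therefore lie on segments between minority
  points, which the tests verify directly from the provenance records.
* **Unbiased decoy selection**: a three-stage funnel over a user-supplied
  candidate pool — (1) property matching (MW +/-25 Da, logP +/-1, H-bond
  donors +/-1, acceptors +/-2, rotatable bonds +/-2, formal charge exact,
  against at least one active), (2) dissimilarity (max ECFP4 Tanimoto to
  every active < 0.30), (3) MaxMin diversity selection down to the
  requested count. The windows and threshold mirror the property-matched
  decoy literature and are all configurable; MaxMin is deterministic
  (seeded with the most distant pair, ties by index).
* **SMILES enumeration**: alternative atom orderings via random
  renumbering; every variant canonicalizes back to its parent, inherits
  the parent's label, and stays in the parent's partition.

## Models

Nine classical families (SVC, RF, KNN, DT, GBDT, ABDT, GNB, SGD, LR) are
standard scikit-learn estimators behind one train/score contract: a score
in [0,1] (class-1 probability, or a min-max-calibrated decision value for
margin-only configurations) and a hard label at the fixed 0.5 operating
point. Hyperparameters come from randomized search — 10 configurations
scored by 5-fold cross-validated AUC — over per-family distributions
shipped in `molfusion/data/search_spaces.yaml` (e.g. RF trees 100-1000,
depth 2-30; SVC C log-uniform 1e-2..1e3 with RBF/linear kernels; KNN k
3-15; boosting estimators 50-500 with learning rate 0.01-1). The file is
the single source of truth and is user-overridable.

Two attention networks are implemented on the package's own reverse-mode
autodiff engine (`models/autodiff.py`, finite-difference checked in the
test suite):

* **Fusion network**: each processed 128-dim block passes through its own
  fully connected projection (tanh); the projections are stacked
  vertically into an n_blocks-length sequence; scaled dot-product
  self-attention (row softmax of QK^T/sqrt(d)) mixes them; the flattened
  attention output feeds a fully connected head with a logistic output.
  Four fully connected layers in total: with three blocks these are the
  three projections plus the head; with fewer blocks the spare layers form
  a shared pre-head stack, a choice made because the reference layout is
  ambiguous for partial fusion.
* **SMILES network**: token embedding of dimension 100 (fixed; the pad id
  embeds to the zero vector), four stacked LSTM layers (fixed count;
  forget-gate bias initialized to 1), self-attention over time steps with
  padded key positions masked out, masked mean pooling, and a fully
  connected head.

Both train with Adam (lr 3e-3) on binary cross-entropy computed stably
from logits, batch size 128, early stopping on validation AUC, and fully
seeded initialization and batching: a fixed seed reproduces final weights
exactly. Default LSTM hidden width is 32 and attention width 32; these are
deliberately compact so the full benchmark runs comfortably on one CPU.

## Evaluation

Metrics are ACC, F1 (positive class = active) and AUC via the rank-sum
statistic with midrank tie correction; the test suite verifies agreement
with independent reference implementations to 1e-10. Experiments repeat
over 30 seeds by default and report mean +/- SD; SD uses the population
convention (divisor n), with the sample convention available. Model pairs
are compared with a two-sided Welch t-test at alpha 0.05 (the
unequal-variance form, since per-seed variances differ wildly across
families); the degenerate both-zero-variance cases are defined explicitly
(equal means: t=0, p=1; unequal: flagged significant). No multiple-testing
correction is applied across pairs; reports flag this. Prediction overlap
between two models is the four-way agreement partition (both correct /
only one / both wrong), rendered as a two-circle Venn figure, and 2-D
chemical-space maps come from seeded t-SNE per modality.

The experiment grid crosses 15 experiments (1-7 classical x numeric
combos, 8-14 fusion network x the same combos, 15 the SMILES network) with
15 groups (three cutoffs per model kind; at 10 uM additionally SMOTE or
decoys for numeric features, enumeration or decoys for sequences).
Infeasible cells — an experiment outside a group's range, a rebalancing
strategy without the data kind it needs, a decoy group without a pool —
are skipped with a logged reason.

A deliberately observable consequence of the design: ABDT (boosting does
not subsample), GNB (no stochastic component) and LR with the lbfgs
solver are bitwise seed-stable once hyperparameters are fixed, so their
multi-seed SD is exactly 0.00 — the quantity `scripts/acceptance.py`
recomputes.

## The synthetic benchmark

Real potency datasets cannot be redistributed here, so the generator
builds libraries with a *planted* structure-activity rule that every
pipeline stage, including signal recovery, can be tested against.

Compounds are scaffold + substituent assemblies: 13 hand-written scaffold
templates with distinct ring systems (benzanilide, diphenyl ether,
benzimidazole, phthalimide, piperazine, quinoxaline, pyridine amide,
thiophene, morpholino-pyrimidine, urea, pyrazole, benzofuran, piperidine
amide cores) carry three substitution slots filled by textual substitution
from vetted fragment lists — validity is guaranteed by construction and
asserted. Slot 1 carries a sulfonamide pharmacophore with probability 0.8;
family abundance decays geometrically (factor 0.85), mimicking the skewed
chemotype sizes of mined datasets and letting 3 small families form a
~12% hold-out.

Planted potency on the log10(uM) scale:

    log10 potency = mu(pharmacophore) + a(scaffold) + b(R1) + c(R2) + d(R3)
                    + Normal(0, 0.25)

with mu = -0.57 (pharmacophore present) or +2.3 (absent) and contribution
ranges chosen by quantile arithmetic so the active arm has SD ~0.86:
P(potency < 0.5 uM) ~ 0.62 and P(< 1 uM) ~ 0.75 within the pharmacophore
arm then yield overall positive fractions of ~0.50, ~0.60 and ~0.78 at the
0.5/1/10 uM cutoffs — the balanced, slightly imbalanced and severely
imbalanced regimes. A single Gaussian arm cannot hit (0.50, 0.60, 0.80)
exactly at all three cutoffs simultaneously; the defaults are the least
compromise, and the canned presets are tested against the bands
[0.45, 0.55] and [0.75, 0.85]. Default library size is 4500 records before
duplicate aggregation (independent draws can collide; curation merges them
exactly as it would real duplicates).

What the generator emulates: scaffold-family cluster structure with skewed
sizes, a learnable substructure-to-potency rule, continuous potencies
spanning nM-mM, SMILES lengths inside the 18-195 token window, and
duplicate records. What it does not emulate: realistic medicinal-chemistry
property distributions, activity cliffs, assay noise heterogeneity between
Ki/Kd/IC50, measurement censoring ("> 10 uM"), or tautomer/salt forms.
Passing tests on this benchmark therefore demonstrate mechanical and
statistical correctness of the pipeline and that models can recover a
planted signal through a family-disjoint split — not performance on any
real target's chemistry.

Problem sizes used by the shipped checks are the package's own choices for
a single-CPU workflow: n=2000 compounds for signal recovery (3 seeds,
LSTM capped at 12 epochs with patience 4), n=1000 with 30 seeds for the
stability quantity, smaller libraries for structural contracts.

## Known limitations

* The SMILES network's cost grows linearly with sequence length and layer
  count on pure NumPy; very long corpora (toward the 195-token cap) train
  slowly compared to GPU frameworks.
* Margin-only classical configurations (hinge-loss SGD, non-probability
  SVC) report min-max-calibrated scores, which preserve ranking (AUC) but
  are not calibrated probabilities.
* Silhouette-consensus cluster counts are only trustworthy when cluster
  structure genuinely dominates the representation; heterogeneous slot
  chemistry within families biases the consensus toward finer partitions.
* Decoy selection assumes the supplied pool is label-clean (presumed
  inactive); no experimental verification is modeled.
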
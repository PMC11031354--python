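# Methods

## Label graph and propagation

Cell-type labels form a directed graph with two edge kinds. *Parent*
edges point child→parent (is-a). *Synonym* edges are stored in both
directions, so plain reachability implements "propagate child
annotations to all ancestors, iteratively, and propagate synonymous
annotations mutually" as a single closure operation. Synonyms are kept
as distinct nodes rather than merged, because evaluation treats the two
label strings as separate output columns. Cycles are legal (every
synonym pair is a 2-cycle) and terminate trivially under reachability;
a cycle among parent edges is logged as a warning but not rejected.
Labels are matched by exact string after whitespace trimming; labels
absent from the curated table propagate to themselves only, since a
hand-curated table cannot be assumed complete.

`propagate_label_matrix` turns a one-hot cells × types matrix into its
row-wise closure restricted to the model's output vocabulary; labels
produced by propagation but missing from the vocabulary are counted and
logged, not silently dropped.

## Corpus handling

Datasets arrive as MatrixMarket triplets (genes × cells) with
`genes.tsv`/`barcodes.tsv`/`metadata.tsv` sidecars, or an equivalent
HDF5 container. Each dataset is aligned to a fixed, ordered gene
vocabulary — shared genes keep their values, vocabulary genes missing
from a dataset are zero-filled, extra genes are dropped, both counts
logged — then cut into chunks of 100 cells (the training batch size)
stored one `.npz` file per chunk with a JSON manifest. The chunk files
are a portable binary container rather than language-native pickles.

Splits are drawn at dataset granularity: `round(0.2·n)` datasets
(round-half-up, minimum 1) form the test side, so no dataset
contributes cells to both sides. The validation holdout used for
best-epoch selection is drawn at chunk granularity (default 10% of
training chunks), matching the batch-loading design.

Normalization is optional (`log1p-cp10k`: depth-normalize each cell to
10,000 counts, then log1p) and off by default, since public matrices
are often pre-normalized. The packaged experiments enable it, as their
input is raw counts.

## Classifier

A dense feed-forward network, implemented directly in NumPy: ReLU
hidden layers (default 256/128/64; 512/256/128/64 as the deeper
alternative), a softmax or sigmoid output head, Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), one gradient step per 100-cell chunk,
chunk order reshuffled each epoch from the run seed. Weights use
variance-scaled uniform initialization from the same seed, making the
whole train→predict path bit-reproducible. After each epoch the model
is scored on the validation holdout; the returned weights are those of
the epoch with minimal validation loss, earliest epoch on ties. With an
empty validation set the last epoch is kept and a warning logged.

Losses: single-label mode pairs softmax with categorical cross-entropy
−Σ_c y_c ln p_c; multi-label mode pairs sigmoid with per-type binary
cross-entropy summed over types, the standard pairing for independent
Bernoulli outputs. Scores are clipped to [1e-12, 1] before logs. Both
pairings share the convenient output-layer gradient (p − y)/batch.

Reference optimization settings (learning rate 3e-5, 20 epochs) are the
`ModelConfig` defaults. The packaged synthetic-corpus experiments use
learning rate 1e-3 with the same depth, epochs and batch size: a
300-gene, 12,000-cell corpus yields only ~2,000 gradient steps per
training, two orders of magnitude fewer than at atlas scale, and 3e-5
cannot reach convergence within them. This is a scaling choice of the
experiment configuration, not a change to the model defaults.

## Evaluation protocol

Every type is evaluated independently of all others: the type's score
column against the type's gold column. A cell annotated (after
correction) to both a child A and its parent A′ is a positive in both
columns; a prediction hitting A′ but not A is right for A′ and wrong
for A. AUROC is computed as the Mann–Whitney statistic with midrank tie
handling; AUPRC as step-wise average precision (no interpolation, which
is biased). A type whose test gold is single-class gets no metric —
recorded as ineligible rather than scored 0.5, so undefined values
cannot distort medians. Only types appearing in a fold's training
labels are evaluated.

"10-fold cross-validation" is Monte-Carlo: ten independent random
dataset-level 80/20 splits. With a dataset count like 18, selecting 20%
per iteration cannot form a disjoint 10-way partition, so repeated
random splits are the faithful reading. The headline statistic is the
median AUC over types with ≥ 5 defined evaluations; aggregation first
averages each type across folds, then takes the median across types.
Per-fold medians are also reported, since the aggregation order is a
genuine free choice and the two can differ.

`cross_cell_cv` is identical except the split is over chunks, ignoring
dataset identity; it exists to demonstrate how cell-level splits
inflate measured AUC whenever dataset batch effects are present.

## Synthetic corpus

The generator emulates exactly the structures the analysis needs and no
more. Ontology: `n_leaf_types` leaf labels assigned round-robin to
`n_parent_types` parents; the last `n_synonym_pairs` leaf labels are
aliases of the first leaves — same parent, same biological identity,
two strings. Expression: counts are negative binomial with shape θ
(`dispersion`, default 2.0) and mean
`base_mean · exp(offset_{d,g}) · (1 + marker_effect · 1[marker])`,
where offsets are Normal(0, `batch_sd`) per dataset × gene and marker
sets are hierarchical: each parent and each primary leaf owns
`markers_per_type` disjoint genes, a cell's lineage (leaf ∪ parent
markers) being uplifted. Parent markers shared by all of a parent's
leaves are what make parent-level annotation learnable. Annotation
styles are drawn per dataset: a `granularity_fraction` of datasets
record every cell at parent level, and half of the remaining leaf-level
datasets use the alias string for leaves that have one.

Defaults: 8 datasets × 1,500 cells, 300 genes, 12 leaves / 4 parents /
2 synonym pairs, 10 markers per type, `marker_effect` 3.0,
`base_mean` 0.5, `granularity_fraction` 0.5, `batch_sd` 0.6.

The batch-effect level deserves comment, because the correction effect
is regime-dependent. Under weak batch effects (`batch_sd` ≈ 0.3) the
raw-label model resolves the conflicting annotations benignly — type
columns still rank cells by markers, and the raw-vs-corrected median
gap shrinks to ~0.01, concentrated in parent and synonym columns. Under
the strong batch effects typical of multi-lab public corpora
(`batch_sd` 0.6, i.e. per-dataset gene-level fold changes of e^0.6 ≈
1.8 sd), the only way to fit conflicting labels is to key predictions
to dataset fingerprints, which fails on held-out datasets; correction
removes the conflicts and the median AUC rises by ~0.04–0.06. The
default places the corpus in this second regime, which is the situation
the correction is for. The generator deliberately omits dropout
curves, doublets, ambient RNA and UMI saturation; passing tests show
the pipeline's behavior under idealized NB noise with batch structure,
not performance on real tissue atlases.

## Numerical and degenerate-input choices

- Score clip 1e-12 before any log; Adam ε 1e-8.
- Round-half-up for test-set and holdout sizes, minimum 1.
- Tie-break for best epoch: earliest.
- `epochs = 0`, empty training set, label-mode/activation mismatch, and
  single-dataset corpora for dataset-level CV are errors, not silent
  degradations; zero validation fraction degrades to last-epoch
  selection with a warning.
- Fold seeds derive affinely from the run seed modulo 2³¹−1, so every
  stage (simulation, styles, splits, initialization, shuffling) is
  reproducible from one integer.

## Problem sizes

Packaged experiments run on the default 12,000-cell corpus: one
10-fold CV takes ~35 s on one CPU, the full three-mode experiment
~2 min per seed, and the test suite asserts the correction and
overestimation effects across three seeds (~5 min total). These sizes
were chosen so a complete verification runs on a laptop; corpus and
model scale linearly in cells and genes.

## Known limitations

- Propagation is upward only, as specified by the correction procedure:
  a cell annotated at parent level never gains leaf labels, so leaf
  columns keep hard negatives (true leaf cells annotated as the parent)
  even after correction. The corrected median therefore saturates below
  the cross-cell ceiling.
- The NumPy network is single-threaded-friendly but not GPU-capable;
  atlas-scale corpora would need a deep-learning backend behind the
  same training contract.
- Exact-string label matching; no Cell Ontology identifier resolution.
- Monte-Carlo CV means fold memberships overlap across iterations;
  evaluation counts per type are random variables, which is why the
  min-evaluations filter exists.
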
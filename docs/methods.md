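# Methods

This note documents the model implemented by `lpivec`, the parameter
defaults and why they were chosen, the design decisions taken where the
method description left the design open, and what the synthetic benchmark
does and does not demonstrate.

## Sequence words and vocabulary

Sequences are segmented into overlapping k-mers at stride 1: length-*L*
input yields *L − k + 1* words. Defaults are k = 4 for RNA (4⁴ = 256
possible words) and k = 3 for protein (20³ = 8000), the empirically
standard choices for interaction prediction from sequence alone. The full
20-letter amino-acid alphabet is used throughout; no reduced 7-group
alphabet. The vocabulary object is a lazy lexicographic bijection between
words and `[0, |A|^k)`, so even 20⁵-scale vocabularies can be enumerated
without materialising millions of strings.

Ambiguity characters (N, X, B, …) are retained in the parsed sequence but
excluded from the word space: any window containing one is dropped and
counted, never substituted. This keeps the 4^k/20^k vocabulary closed; the
dropped-window count is surfaced for QC. DNA-style `T` is normalised to
`U` on FASTA read, since transcript FASTA files commonly use the DNA
alphabet.

## Skip-gram model

One sequence is one sentence; context windows never cross sentence
boundaries. The training objective is the mean log probability of context
words within half-width *c* of each center word, with the full-softmax
conditional over the corpus lexicon (both printed in the README). The
lexicon is the lexicographically sorted set of corpus words with frequency
≥ `min_count`; `min_count = 1` by default, because at biological k-mer
vocabulary sizes even rare words are informative and there is no long tail
of typos as in natural text.

Hyperparameter defaults: `size = 300`, `window = 5`, `epochs = 10`,
`batch_words = 100`, initial learning rate 0.025 decaying linearly to
10⁻⁴ of its initial value over training (standard word2vec practice;
the schedule is otherwise an implementation contract, deterministic given
the seed). Input vectors initialise uniform in (−0.5/dim, 0.5/dim),
output vectors at zero, so the initial conditional is exactly uniform.

Two trainers share this parameterisation:

* **Full-softmax mini-batch SGD** (`negative = 0`): groups the token
  stream into `batch_words`-token batches and takes one exact-gradient
  step per batch. This is the reference path — its gradients are checked
  against central finite differences of the objective to 10⁻⁵ relative
  error — but each step costs O(|V|·dim), so it is intended for
  desk-scale vocabularies.
* **Negative sampling** (`negative = n > 0`, pipeline default n = 5):
  classic per-pair sigmoid updates against n noise words drawn from the
  unigram^0.75 distribution, compiled with numba and seeded by an
  internal counter-based generator, so runs are bit-reproducible. Its
  output is an approximation and is not expected to match full softmax
  numerically.

Exposing both, with the exact form as the mathematical reference and the
approximation as the scale-up path, keeps the model checkable without
making desk-scale cost a ceiling.

A sequence embedding is the sum of the input vectors of its words.
Words absent from the lexicon contribute a zero vector and are counted
(`oov_count`), keeping the embedding total and its dimension fixed.

## Pair features, importance, selection

The pair vector is the concatenation [RNA ‖ protein], RNA first —
600 features at the defaults. Concatenation is the only construction
consistent with selecting a fixed top-k from a fixed-length pair vector.

Gini importance: at a node with class proportions p, GI = 1 − Σp².
`node_importance` returns the literal impurity variation
GI_parent − GI_right − GI_left; `forest_importance` sums it over every
split of every tree and normalises to unit sum. Two forms exist:

* the **literal unweighted** form above (the default of the low-level
  operations, covered exactly by a brute-force traversal oracle in the
  tests), and
* the **conventional sample-weighted** decrease (children scaled by their
  sample fractions, the whole term by the fraction of tree samples
  reaching the node — the form scikit-learn reports), behind
  `weighted=True`.

The pipeline's ranking defaults to the weighted form. On fully grown
trees the unweighted sum is dominated by the many near-leaf splits of one
or two samples, which land on essentially arbitrary features; measured on
a planted-signal fixture (10 informative of 60 features), the unweighted
ranking recovers 0–2 of the 10 informative features in its top-10 while
the weighted form recovers all 10. Fidelity to the printed arithmetic is
kept where the arithmetic is defined (the per-node operations and their
oracle); practicality governs the population-level default, and the
switch makes either choice explicit.

Selection keeps the top-50 features by normalised importance, ties broken
by ascending feature index for determinism. The importance forest (500
trees, for ranking stability) is trained on the training portion only and
re-fitted inside each cross-validation fold by default, so no test
information leaks into the ranking; `global_selection` fits it once on
the full dataset for studies that prefer a single shared feature set.

## Classifier and evaluation

Random forest with 500 trees, √m candidate features per split, unlimited
depth, fixed seed. The interaction probability of a pair is the fraction
of trees voting positive; the decision threshold is 0.5, ties classified
positive. Acc, Sens, Spec, Prec and MCC follow the standard
confusion-count formulas; any zero denominator yields 0 and a degeneracy
flag (MCC's zero-denominator convention). AUC is the Mann–Whitney rank
statistic (ties one half), verified against exhaustive pair counting and
scikit-learn.

Cross-validation uses five folds, stratified by label (the fold sizes
differ by at most one record and per-fold class counts are balanced to
within one). The reported result is the mean of the per-fold metrics,
not a pooled confusion matrix. Embeddings are trained once on the full
sequence corpora: embedding training is unsupervised and never sees pair
labels, so it cannot leak label information across folds.

## Synthetic benchmark

The generator emulates what the method needs to see — variable-length
sequences over both alphabets with an optional pair-level interaction
signal — not lncRNA biology. Residues are i.i.d. uniform; the planted
signal is the co-occurrence of an RNA motif (`UGCAUG`, six residues, the
Rbfox-family binding element) and a protein motif (`RGGR`, four residues,
RGG-box-like), each spliced once at a random position. Both motifs span
several k-mers at the default k, so recovery requires the tokenizer and
the embedding to preserve them.

With signal strength *s* and background co-occurrence rate *b* (default
0.05), a positive pair joins motif-bearing sequences with probability
s + (1 − s)·b and a negative pair with probability (1 − s)·b. The two
extremes behave as a planted signal should: at s = 1 every positive and
no negative pair carries both motifs; at s = 0 carriage is independent of
the label. Scaling the negative-side leakage by the background rate
keeps the motif informative at high s (a literal (1 − s) contamination at
s = 0.9 would cap the achievable AUC at exactly 0.90, leaving no
headroom above chance ties).

Defaults, chosen once as a desk-scale study: 200 RNAs of 100–200 nt, 200
proteins of 50–150 aa, 200 pairs, positive fraction 0.5, s = 0.9. At
these sizes the full pipeline (two embedding trainings plus five-fold
selection + classification) completes in about half a minute per seed on
one CPU.

What passing the synthetic benchmark shows: the pipeline recovers a
sequence-level co-occurrence signal end to end, and collapses to AUC
≈ 0.5 under label permutation. What it does not show: performance on
real interaction data, where the signal is weaker and distributed
(binding preferences, composition biases, structure), sequences are far
longer, and negatives are not uniform random — the published benchmark
corpora remain the only test of that.

## Numerical and degenerate-input conventions

* Objective scoring: N counts center positions contributing at least one
  context pair; a corpus with no pairs at all scores 0 with a warning.
* A corpus with fewer than two word types (nothing to contrast) is a
  training error, as is a sequence shorter than k at embedding time;
  inside a corpus, short sequences are skipped with a warning instead of
  aborting the batch.
* Importance normalisation with an all-zero raw vector (no split ever
  decreased impurity) is flagged degenerate rather than divided through.
* Model persistence uses the word2vec text format (`W dim` header; one
  word + `dim` reals per line) at 9 significant digits, round-tripping
  input vectors to well within 10⁻⁶.
* All stochastic stages draw sub-seeds fanned out from one root seed via
  a seed sequence; manifests record them.

## Known limitations

* Full-softmax training is quadratic in vocabulary size per step; for
  20³-word protein lexicons and larger, use the negative-sampling path
  (the default at pipeline scale).
* The additive sequence embedding discards word order and length
  normalisation; two sequences with the same k-mer multiset are
  indistinguishable downstream.
* The vote-fraction probability of a 500-tree forest is quantised to
  1/500; ROC resolution is limited accordingly.
* `load_model` restores input vectors only (the word2vec text format
  does not carry output vectors); a loaded model embeds sequences but
  cannot resume training or score the objective meaningfully.
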
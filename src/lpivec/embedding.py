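"""Skip-gram word embeddings for k-mer sentences, and additive sequence embedding.

The model learns one input vector ``v_w`` and one output vector ``v'_w``
per vocabulary word by maximising the mean log probability of context
words within a window of half-width ``c`` around each center word:

    J = (1/N) sum_n sum_{-c <= m <= c, m != 0} log P(w_{n+m} | w_n)

with the full-softmax distribution

    P(w_o | w_i) = exp(v'_o . v_i) / sum_{w=1..W} exp(v'_w . v_i)

where W is the lexicon size.  Sentence boundaries truncate windows — a
sequence is a sentence, and contexts never cross sequences.

Two trainers share the same parameterisation:

* the reference trainer performs mini-batch SGD on the exact full-softmax
  objective above (tractable at small vocabulary sizes, and the form the
  analytic-gradient check validates);
* an optional negative-sampling accelerator (``TrainingConfig.negative > 0``),
  compiled with numba, scales to the 20^3-word protein lexicon and beyond.
  Its output is not expected to match full softmax numerically.

A sequence embedding is the sum of the input vectors of its k-mer words;
out-of-vocabulary words contribute a zero vector and are counted.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence as TypingSequence, Tuple

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .seqio import Sequence
from .tokenizer import TokenizedSequence, segment

__all__ = [
    "TrainingConfig",
    "SkipGramModel",
    "SequenceEmbedding",
    "softmax_probability",
    "corpus_objective",
    "objective_gradients",
    "train",
    "embed_sequence",
    "embed_corpus",
    "save_model",
    "load_model",
]

# learning rate floor, as a fraction of the initial rate
_LR_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class TrainingConfig:
    """Skip-gram hyperparameters.

    Defaults are the standard configuration for this task: 300-dimensional
    vectors, window 5, 10 epochs, min_count 1 (rare k-mers stay in the
    lexicon), batches of 100 words.  ``negative=0`` selects the exact
    full-softmax trainer; ``negative=n > 0`` switches to negative sampling
    with n noise words per context word.
    """

    dim: int = 300
    window: int = 5
    epochs: int = 10
    min_count: int = 1
    batch_words: int = 100
    learning_rate: float = 0.025
    seed: int = 0
    negative: int = 0

    def __post_init__(self):
        for name in ("dim", "window", "epochs", "min_count", "batch_words"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.negative < 0:
            raise ValueError(f"negative must be >= 0, got {self.negative}")


@dataclass
class SequenceEmbedding:
    """Additive embedding of one sequence: sum of its k-mer input vectors."""

    source_id: str
    vector: np.ndarray
    oov_count: int = 0


class SkipGramModel:
    """Input/output vector tables over a corpus-derived k-mer lexicon."""

    def __init__(
        self,
        words: TypingSequence[str],
        input_vectors: np.ndarray,
        output_vectors: Optional[np.ndarray] = None,
        config: Optional[TrainingConfig] = None,
    ):
        self.words = list(words)
        self.word_index = {w: i for i, w in enumerate(self.words)}
        if len(self.word_index) != len(self.words):
            raise ValueError("duplicate words in vocabulary")
        input_vectors = np.asarray(input_vectors, dtype=np.float64)
        if input_vectors.shape[0] != len(self.words):
            raise ValueError(
                f"input_vectors has {input_vectors.shape[0]} rows for {len(self.words)} words"
            )
        if output_vectors is None:
            output_vectors = np.zeros_like(input_vectors)
        output_vectors = np.asarray(output_vectors, dtype=np.float64)
        if output_vectors.shape != input_vectors.shape:
            raise ValueError("input and output vector tables differ in shape")
        if not (np.isfinite(input_vectors).all() and np.isfinite(output_vectors).all()):
            raise ValueError("non-finite values in vector tables")
        self.input_vectors = input_vectors
        self.output_vectors = output_vectors
        self.config = config

    @property
    def vocab_size(self) -> int:
        return len(self.words)

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.word_index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.input_vectors[self.word_index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in model vocabulary") from None


def softmax_probability(model: SkipGramModel, center: str, target: str) -> float:
    """P(target | center) under the model's full softmax; both words must be in vocabulary."""
    if center not in model.word_index:
        raise KeyError(f"center word {center!r} not in vocabulary")
    if target not in model.word_index:
        raise KeyError(f"target word {target!r} not in vocabulary")
    v_c = model.input_vectors[model.word_index[center]]
    logits = model.output_vectors @ v_c
    log_p = logits[model.word_index[target]] - logsumexp(logits)
    return float(np.exp(log_p))


def _iter_pairs(
    sentences: Iterable[TypingSequence[int]], window: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (center, context) index pairs; windows truncate at sentence ends.

    Returns (centers, contexts, pairs_per_center) where pairs_per_center
    aligns with the concatenated token stream and records how many context
    pairs each center position contributes (used for batching by words).
    """
    centers, contexts, per_center = [], [], []
    for sent in sentences:
        n = len(sent)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            cnt = 0
            for j in range(lo, hi):
                if j == i:
                    continue
                centers.append(sent[i])
                contexts.append(sent[j])
                cnt += 1
            per_center.append(cnt)
    return (
        np.asarray(centers, dtype=np.int32),
        np.asarray(contexts, dtype=np.int32),
        np.asarray(per_center, dtype=np.int32),
    )


def _indexed_sentences(
    corpus: Iterable[TokenizedSequence], word_index: dict
) -> List[List[int]]:
    """Map sentences to vocabulary indices, dropping out-of-vocabulary tokens."""
    out = []
    for sent in corpus:
        idx = [word_index[t] for t in sent.tokens if t in word_index]
        if idx:
            out.append(idx)
    return out


def corpus_objective(model: SkipGramModel, corpus: TypingSequence[TokenizedSequence]) -> float:
    """Mean log probability of in-window contexts over the corpus (always <= 0).

    N counts center positions that contribute at least one context pair;
    tokens outside the model vocabulary are skipped.  A corpus with no
    context pairs at all (e.g. only single-token sentences) yields 0.0 with
    a warning.  Materialises the full W x W log-softmax table, so intended
    for desk-scale vocabularies.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    sentences = _indexed_sentences(corpus, model.word_index)
    window = model.config.window if model.config is not None else 5
    centers, contexts, per_center = _iter_pairs(sentences, window)
    n_scored = int((per_center > 0).sum())
    if n_scored == 0:
        warnings.warn("corpus yields no context pairs; objective defined as 0")
        return 0.0
    logits = model.input_vectors @ model.output_vectors.T  # [W, W], row = center
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    return float(log_probs[centers, contexts].sum() / n_scored)


def objective_gradients(
    model: SkipGramModel, corpus: TypingSequence[TokenizedSequence]
) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`corpus_objective` w.r.t. (input, output) tables.

    For each pair (c, o):  dJ/dv_c   += v'_o - E_{w~P(.|c)}[v'_w]
                           dJ/dv'_o  += v_c
                           dJ/dv'_w  -= P(w|c) v_c  for all w,
    everything divided by N (the scored-center count).
    """
    sentences = _indexed_sentences(list(corpus), model.word_index)
    window = model.config.window if model.config is not None else 5
    centers, contexts, per_center = _iter_pairs(sentences, window)
    n_scored = int((per_center > 0).sum())
    if n_scored == 0:
        raise ValueError("corpus yields no context pairs; gradient undefined")
    W = model.vocab_size
    vin, vout = model.input_vectors, model.output_vectors
    logits = vin @ vout.T
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    P = np.exp(log_probs)
    # pair-count matrix: cnt[c, o] and per-center totals r[c]
    cnt = np.zeros((W, W))
    np.add.at(cnt, (centers, contexts), 1.0)
    r = cnt.sum(axis=1)
    d_in = (cnt @ vout - r[:, None] * (P @ vout)) / n_scored
    d_out = (cnt.T @ vin - (r[:, None] * P).T @ vin) / n_scored
    return d_in, d_out


def _batches_by_words(
    per_center: np.ndarray, batch_words: int
) -> List[Tuple[int, int]]:
    """Group the flattened pair stream into slices covering ~batch_words tokens."""
    slices = []
    start_pair = 0
    pairs_in_batch = 0
    tokens_in_batch = 0
    pos = 0
    for cnt in per_center:
        pairs_in_batch += int(cnt)
        tokens_in_batch += 1
        pos += int(cnt)
        if tokens_in_batch >= batch_words and pairs_in_batch > 0:
            slices.append((start_pair, pos))
            start_pair = pos
            pairs_in_batch = 0
            tokens_in_batch = 0
    if pairs_in_batch > 0:
        slices.append((start_pair, pos))
    return slices


def _train_full_softmax(
    vin: np.ndarray,
    vout: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    slices: List[Tuple[int, int]],
    cfg: TrainingConfig,
) -> None:
    """Mini-batch SGD on the exact softmax objective; linear LR decay."""
    total_updates = cfg.epochs * len(slices)
    lr0 = cfg.learning_rate
    u = 0
    for _ in range(cfg.epochs):
        for lo, hi in slices:
            lr = lr0 * max(_LR_FLOOR_FRACTION, 1.0 - u / total_updates)
            C, O = centers[lo:hi], contexts[lo:hi]
            B = hi - lo
            H = vin[C]  # [B, dim]
            logits = H @ vout.T
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            P /= P.sum(axis=1, keepdims=True)
            G = P
            G[np.arange(B), O] -= 1.0
            G /= B
            d_out = G.T @ H
            d_h = G @ vout
            vout -= lr * d_out
            np.subtract.at(vin, C, lr * d_h)
            u += 1


@njit(cache=True)
def _train_negative_sampling(
    vin, vout, centers, contexts, table, epochs, negative, lr0, lr_floor, seed
):  # pragma: no cover - exercised through train()
    n_pairs = centers.shape[0]
    dim = vin.shape[1]
    total = epochs * n_pairs
    tbl = table.shape[0]
    state = np.uint64(2 * seed + 1)
    mult = np.uint64(6364136223846793005)
    incr = np.uint64(1442695040888963407)
    t = 0
    neu1e = np.zeros(dim)
    for _ in range(epochs):
        for i in range(n_pairs):
            lr = lr0 * (1.0 - t / total)
            if lr < lr_floor:
                lr = lr_floor
            c = centers[i]
            o = contexts[i]
            for d in range(dim):
                neu1e[d] = 0.0
            for s in range(negative + 1):
                if s == 0:
                    target = o
                    label = 1.0
                else:
                    state = state * mult + incr
                    target = table[int((state >> np.uint64(33)) % np.uint64(tbl))]
                    if target == o:
                        continue
                    label = 0.0
                dot = 0.0
                for d in range(dim):
                    dot += vout[target, d] * vin[c, d]
                if dot > 30.0:
                    f = 1.0
                elif dot < -30.0:
                    f = 0.0
                else:
                    f = 1.0 / (1.0 + math.exp(-dot))
                g = (label - f) * lr
                for d in range(dim):
                    neu1e[d] += g * vout[target, d]
                for d in range(dim):
                    vout[target, d] += g * vin[c, d]
            for d in range(dim):
                vin[c, d] += neu1e[d]
            t += 1


def _unigram_table(counts: np.ndarray, size: int = 1 << 20, power: float = 0.75) -> np.ndarray:
    """Noise-word sampling table proportional to unigram frequency^0.75."""
    p = counts.astype(np.float64) ** power
    p /= p.sum()
    bounds = np.floor(np.cumsum(p) * size).astype(np.int64)
    table = np.zeros(size, dtype=np.int32)
    prev = 0
    for w, b in enumerate(bounds):
        table[prev:b] = w
        prev = b
    table[prev:] = len(counts) - 1
    return table


def train(corpus: TypingSequence[TokenizedSequence], config: Optional[TrainingConfig] = None) -> SkipGramModel:
    """Train a skip-gram model on a tokenized corpus; deterministic given the seed.

    The lexicon is the lexicographically sorted set of corpus words with
    frequency >= min_count.  Input vectors start uniform in
    (-0.5/dim, 0.5/dim); output vectors start at zero, so the initial
    softmax is uniform.
    """
    cfg = config or TrainingConfig()
    corpus = list(corpus)
    counts = Counter(t for sent in corpus for t in sent.tokens)
    vocab = sorted(w for w, c in counts.items() if c >= cfg.min_count)
    if len(vocab) < 2:
        raise ValueError(
            f"degenerate corpus: {len(vocab)} word type(s) with frequency >= min_count={cfg.min_count}"
        )
    word_index = {w: i for i, w in enumerate(vocab)}
    sentences = _indexed_sentences(corpus, word_index)
    centers, contexts, per_center = _iter_pairs(sentences, cfg.window)
    if centers.size == 0:
        raise ValueError("corpus yields no context pairs; nothing to train on")

    rng = np.random.default_rng(cfg.seed)
    vin = (rng.random((len(vocab), cfg.dim)) - 0.5) / cfg.dim
    vout = np.zeros((len(vocab), cfg.dim))

    if cfg.negative > 0:
        vocab_counts = np.array([counts[w] for w in vocab], dtype=np.int64)
        table = _unigram_table(vocab_counts)
        _train_negative_sampling(
            vin,
            vout,
            centers,
            contexts,
            table,
            cfg.epochs,
            cfg.negative,
            cfg.learning_rate,
            cfg.learning_rate * _LR_FLOOR_FRACTION,
            cfg.seed,
        )
    else:
        slices = _batches_by_words(per_center, cfg.batch_words)
        _train_full_softmax(vin, vout, centers, contexts, slices, cfg)
    return SkipGramModel(vocab, vin, vout, cfg)


def embed_sequence(model: SkipGramModel, seq: Sequence, k: int) -> SequenceEmbedding:
    """Embed a sequence as the sum of its k-mer input vectors.

    Words absent from the model vocabulary contribute a zero vector and
    increment ``oov_count``; windows dropped for non-canonical characters
    are not counted as out-of-vocabulary.
    """
    tokenized = segment(seq, k)
    vec = np.zeros(model.dim)
    oov = 0
    for tok in tokenized.tokens:
        idx = model.word_index.get(tok)
        if idx is None:
            oov += 1
        else:
            vec += model.input_vectors[idx]
    return SequenceEmbedding(seq.id, vec, oov)


def embed_corpus(model: SkipGramModel, seqs: Iterable[Sequence], k: int) -> dict:
    """Embed a sequence collection; returns {id: SequenceEmbedding}."""
    return {s.id: embed_sequence(model, s, k) for s in seqs}


def save_model(model: SkipGramModel, path) -> None:
    """Persist input vectors in word2vec text format: header 'W dim', then
    one word plus dim reals per line."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{model.vocab_size} {model.dim}\n")
        for w, row in zip(model.words, model.input_vectors):
            fh.write(w + " " + " ".join(f"{x:.8e}" for x in row) + "\n")


def load_model(path) -> SkipGramModel:
    """Load a word2vec text-format model (input vectors only; output vectors zero)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n_words, dim = int(header[0]), int(header[1])
        words, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected 1 word + {dim} values, got {len(parts)} fields"
                )
            words.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(words) != n_words:
        raise ValueError(f"{path}: header promised {n_words} words, found {len(words)}")
    return SkipGramModel(words, np.array(rows))
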
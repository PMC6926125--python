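"""Overlapping k-mer segmentation of biological sequences.

A sequence of length L yields the L - k + 1 sliding windows at stride 1;
each window is a "word" and the sequence a "sentence" for the embedding
model.  The vocabulary over an alphabet of size A at word length k is the
full set of A^k strings; for RNA (A, C, G, U) that is 4^k words and for the
20-letter amino-acid alphabet 20^k.  Defaults follow common practice for
this task: k=4 for RNA, k=3 for protein.  Windows containing non-canonical
characters (N, X, ...) are dropped, not substituted, so the word space
stays closed over the canonical alphabet.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List

from .seqio import Alphabet, Sequence

__all__ = [
    "DEFAULT_K_RNA",
    "DEFAULT_K_PROTEIN",
    "KmerVocabulary",
    "TokenizedSequence",
    "segment",
    "build_vocabulary",
    "corpus_from_fasta",
    "write_corpus",
    "read_corpus",
]

logger = logging.getLogger(__name__)

DEFAULT_K_RNA = 4
DEFAULT_K_PROTEIN = 3


@dataclass(frozen=True)
class KmerVocabulary:
    """The complete lexicographic vocabulary of length-k words over an alphabet.

    Words are materialised lazily through a base-``A`` positional encoding,
    so vocabularies as large as 20^5 can be enumerated or indexed without
    storing millions of strings.  ``index`` and ``word`` form a total
    bijection between words and ``[0, A^k)``.
    """

    alphabet: Alphabet
    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    def __len__(self) -> int:
        return self.alphabet.size ** self.k

    def word(self, index: int) -> str:
        """The index-th word in lexicographic order."""
        if not 0 <= index < len(self):
            raise IndexError(f"vocabulary index {index} out of range [0, {len(self)})")
        symbols = self.alphabet.symbols
        base = len(symbols)
        out = []
        for _ in range(self.k):
            index, digit = divmod(index, base)
            out.append(symbols[digit])
        return "".join(reversed(out))

    def index(self, word: str) -> int:
        """Lexicographic rank of a word; raises KeyError for foreign words."""
        if len(word) != self.k:
            raise KeyError(f"{word!r} is not a length-{self.k} word")
        symbols = self.alphabet.symbols
        idx = 0
        for ch in word:
            pos = symbols.find(ch)
            if pos < 0:
                raise KeyError(f"{word!r} contains {ch!r}, not in alphabet {symbols}")
            idx = idx * len(symbols) + pos
        return idx

    def __getitem__(self, index: int) -> str:
        return self.word(index)

    def __contains__(self, word) -> bool:
        try:
            self.index(word)
        except KeyError:
            return False
        return True

    def __iter__(self) -> Iterator[str]:
        # lexicographic, consistent with word()/index(); product avoids
        # per-word divmod so 20^5-scale enumeration stays cheap
        for tup in itertools.product(self.alphabet.symbols, repeat=self.k):
            yield "".join(tup)


@dataclass(frozen=True)
class TokenizedSequence:
    """k-mer words of one sequence, plus the count of windows dropped for
    non-canonical characters.  ``len(tokens) + dropped_count == L - k + 1``."""

    source_id: str
    tokens: tuple
    dropped_count: int = 0

    def __len__(self) -> int:
        return len(self.tokens)


def build_vocabulary(alphabet: Alphabet, k: int) -> KmerVocabulary:
    """Complete, deterministic (lexicographically ordered) k-mer vocabulary."""
    return KmerVocabulary(alphabet=alphabet, k=k)


def segment(seq: Sequence, k: int) -> TokenizedSequence:
    """Split a sequence into its L - k + 1 overlapping k-mer words.

    Windows containing any non-canonical character are dropped and counted
    in ``dropped_count``.  A sequence shorter than k is an error.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(seq.residues)
    if n < k:
        raise ValueError(
            f"sequence {seq.id!r} has length {n} < k={k}; cannot tokenize"
        )
    residues = seq.residues
    if seq.is_canonical:
        tokens = tuple(residues[i : i + k] for i in range(n - k + 1))
        return TokenizedSequence(seq.id, tokens, 0)
    canonical = frozenset(seq.alphabet.symbols)
    bad = [i for i, ch in enumerate(residues) if ch not in canonical]
    bad_set = set()
    for b in bad:
        # window starts in [b-k+1, b] touch position b
        bad_set.update(range(max(0, b - k + 1), min(b, n - k) + 1))
    tokens = tuple(
        residues[i : i + k] for i in range(n - k + 1) if i not in bad_set
    )
    return TokenizedSequence(seq.id, tokens, (n - k + 1) - len(tokens))


def corpus_from_fasta(seqs: Iterable[Sequence], k: int) -> List[TokenizedSequence]:
    """Tokenize a sequence collection into sentences, one per sequence.

    All sequences must share one alphabet.  Sequences shorter than k are
    skipped with a warning rather than aborting the corpus.
    """
    seqs = list(seqs)
    if not seqs:
        return []
    alphabets = {s.alphabet for s in seqs}
    if len(alphabets) > 1:
        raise ValueError(f"mixed alphabets in corpus: {sorted(a.value for a in alphabets)}")
    out = []
    for s in seqs:
        if len(s) < k:
            logger.warning("skipping sequence %r: length %d < k=%d", s.id, len(s), k)
            continue
        out.append(segment(s, k))
    return out


def write_corpus(corpus: Iterable[TokenizedSequence], path) -> None:
    """Serialize sentences as whitespace-separated token lines (one per sequence)."""
    with open(path, "w", newline="\n") as fh:
        for sent in corpus:
            fh.write(" ".join(sent.tokens) + "\n")


def read_corpus(path) -> List[TokenizedSequence]:
    """Read sentences previously written by :func:`write_corpus`."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            toks = tuple(line.split())
            out.append(TokenizedSequence(f"sentence_{i}", toks, 0))
    return out
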
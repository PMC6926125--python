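"""Synthetic sequence corpora and labelled interaction datasets with a planted signal.

The generator emits uniform-residue RNA and protein sequences plus a pair
table in which the interaction signal, when planted, is the co-occurrence
of a short RNA motif and a short protein motif: an interacting pair tends
to join a motif-bearing RNA with a motif-bearing protein.  The signal must
therefore survive tokenization and embedding to be recoverable — it
exercises the whole method, not just the classifier.

With signal strength s and background co-occurrence rate b, a positive
pair carries both motifs with probability s + (1 - s) * b and a negative
pair with probability (1 - s) * b.  At s = 1 every positive pair and no
negative pair carries the motifs; at s = 0 motif occurrence is independent
of the label.  Motifs are spliced in at a random position.  All output is
byte-deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .seqio import Alphabet, PairTable, Sequence, write_fasta, write_pairs
from .tokenizer import DEFAULT_K_PROTEIN, DEFAULT_K_RNA

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "write_dataset"]

#: default planted motifs: a UGCAUG hexamer (an Rbfox-binding element) on the
#: RNA side and an RGG-box-like tetramer on the protein side.
DEFAULT_RNA_MOTIF = "UGCAUG"
DEFAULT_PROTEIN_MOTIF = "RGGR"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe the desk-scale benchmark used throughout the test
    suite: 200 RNAs (100-200 nt) and 200 proteins (50-150 aa), 200 pairs at
    a balanced class ratio, and a strong (0.9) planted motif-co-occurrence
    signal.
    """

    n_rna: int = 200
    n_protein: int = 200
    rna_length_range: Tuple[int, int] = (100, 200)
    protein_length_range: Tuple[int, int] = (50, 150)
    n_pairs: int = 200
    positive_fraction: float = 0.5
    rna_motif: Optional[str] = DEFAULT_RNA_MOTIF
    protein_motif: Optional[str] = DEFAULT_PROTEIN_MOTIF
    signal_strength: float = 0.9
    background_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (self.n_rna >= 1 and self.n_protein >= 1 and self.n_pairs >= 1):
            raise ValueError("n_rna, n_protein and n_pairs must be positive")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        for motif, alphabet, rng, k in (
            (self.rna_motif, Alphabet.RNA, self.rna_length_range, DEFAULT_K_RNA),
            (self.protein_motif, Alphabet.PROTEIN, self.protein_length_range, DEFAULT_K_PROTEIN),
        ):
            if rng[0] < 1 or rng[1] < rng[0]:
                raise ValueError(f"invalid length range {rng}")
            if motif is not None:
                if len(motif) < k:
                    raise ValueError(
                        f"motif {motif!r} shorter than the tokenizer default k={k}"
                    )
                if rng[1] < len(motif):
                    raise ValueError(
                        f"motif {motif!r} longer than the maximum sequence length {rng[1]}"
                    )
                bad = set(motif) - set(alphabet.symbols)
                if bad:
                    raise ValueError(f"motif {motif!r} uses non-{alphabet.value} characters {bad}")


@dataclass
class SyntheticDataset:
    """Generated sequences, pair table, and a manifest of the planted truth."""

    rna_fasta: List[Sequence]
    protein_fasta: List[Sequence]
    pairs: PairTable
    truth_manifest: Dict


def _random_residues(rng: np.random.Generator, alphabet: Alphabet, length: int) -> str:
    symbols = np.frombuffer(alphabet.symbols.encode(), dtype="S1")
    return b"".join(rng.choice(symbols, size=length)).decode()


def _splice_motif(rng: np.random.Generator, residues: str, motif: str) -> str:
    pos = int(rng.integers(0, len(residues) + 1))
    return residues[:pos] + motif + residues[pos:]


def _make_sequences(
    rng: np.random.Generator,
    prefix: str,
    n: int,
    length_range: Tuple[int, int],
    alphabet: Alphabet,
    motif: Optional[str],
    motif_flags: np.ndarray,
) -> List[Sequence]:
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        residues = _random_residues(rng, alphabet, length)
        if motif is not None and motif_flags[i]:
            residues = _splice_motif(rng, residues, motif)
        out.append(Sequence(f"{prefix}{i + 1}", residues, alphabet))
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset from a spec; fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # labels: positive_fraction honoured exactly within rounding, order shuffled
    n_pos = int(round(spec.n_pairs * spec.positive_fraction))
    n_pos = min(max(n_pos, 1), spec.n_pairs - 1)
    labels = np.array([1] * n_pos + [0] * (spec.n_pairs - n_pos))
    rng.shuffle(labels)

    # which pairs carry the co-occurring motifs
    s, b = spec.signal_strength, spec.background_rate
    plant = spec.rna_motif is not None and spec.protein_motif is not None
    if plant:
        p_carry = np.where(labels == 1, s + (1 - s) * b, (1 - s) * b)
        carries = rng.random(spec.n_pairs) < p_carry
    else:
        carries = np.zeros(spec.n_pairs, dtype=bool)

    # split each sequence pool into motif-bearing and plain, sized by demand
    n_carry = int(carries.sum())

    def pool_split(n_seqs: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        n_motif = int(round(n_seqs * n_carry / spec.n_pairs))
        if n_carry > 0:
            n_motif = max(n_motif, 1)
        if n_carry < spec.n_pairs:
            n_motif = min(n_motif, n_seqs - 1)
        perm = rng.permutation(n_seqs)
        flags = np.zeros(n_seqs, dtype=bool)
        flags[perm[:n_motif]] = True
        return flags, perm[:n_motif], perm[n_motif:]

    rna_flags, rna_motif_pool, rna_plain_pool = pool_split(spec.n_rna)
    prot_flags, prot_motif_pool, prot_plain_pool = pool_split(spec.n_protein)

    rna_seqs = _make_sequences(
        rng, "RNA", spec.n_rna, spec.rna_length_range, Alphabet.RNA, spec.rna_motif, rna_flags
    )
    prot_seqs = _make_sequences(
        rng, "PROT", spec.n_protein, spec.protein_length_range, Alphabet.PROTEIN,
        spec.protein_motif, prot_flags,
    )

    # assign sequences to pairs: carriers draw from the motif pools,
    # non-carriers from the plain pools, round-robin over a shuffled order
    # so usage stays as close to injective as pool sizes allow
    def assign(pool: np.ndarray, count: int) -> List[int]:
        if count == 0:
            return []
        reps = int(np.ceil(count / len(pool)))
        stream = np.concatenate([rng.permutation(pool) for _ in range(reps)])
        return [int(x) for x in stream[:count]]

    carry_idx = np.where(carries)[0]
    plain_idx = np.where(~carries)[0]
    rna_for_pair = np.empty(spec.n_pairs, dtype=int)
    prot_for_pair = np.empty(spec.n_pairs, dtype=int)
    rna_for_pair[carry_idx] = assign(rna_motif_pool, len(carry_idx))
    rna_for_pair[plain_idx] = assign(rna_plain_pool, len(plain_idx))
    prot_for_pair[carry_idx] = assign(prot_motif_pool, len(carry_idx))
    prot_for_pair[plain_idx] = assign(prot_plain_pool, len(plain_idx))

    records = tuple(
        (rna_seqs[rna_for_pair[i]].id, prot_seqs[prot_for_pair[i]].id, int(labels[i]))
        for i in range(spec.n_pairs)
    )
    manifest = {
        "spec": {
            "n_rna": spec.n_rna,
            "n_protein": spec.n_protein,
            "n_pairs": spec.n_pairs,
            "positive_fraction": spec.positive_fraction,
            "rna_motif": spec.rna_motif,
            "protein_motif": spec.protein_motif,
            "signal_strength": spec.signal_strength,
            "background_rate": spec.background_rate,
            "seed": spec.seed,
        },
        "pair_carries_signal": [bool(c) for c in carries],
        "rna_has_motif": {s.id: bool(f) for s, f in zip(rna_seqs, rna_flags)},
        "protein_has_motif": {s.id: bool(f) for s, f in zip(prot_seqs, prot_flags)},
    }
    return SyntheticDataset(rna_seqs, prot_seqs, PairTable(records), manifest)


def write_dataset(dataset: SyntheticDataset, outdir) -> Dict[str, Path]:
    """Write FASTA x2 + pairs TSV + truth JSON into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna_fasta": outdir / "rna.fasta",
        "protein_fasta": outdir / "protein.fasta",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(dataset.rna_fasta, paths["rna_fasta"])
    write_fasta(dataset.protein_fasta, paths["protein_fasta"])
    write_pairs(dataset.pairs, paths["pairs"])
    with open(paths["truth"], "w", newline="\n") as fh:
        json.dump(dataset.truth_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
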
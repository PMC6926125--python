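"""Sequence and pair-table I/O.

Two on-disk formats flow through the pipeline: FASTA files holding RNA or
protein sequences, and three-column TSV tables of labelled interaction
pairs (``rna_id``, ``protein_id``, ``label``).  FASTA parsing is delegated
to Biopython; pair tables go through pandas.  On read, residues are
uppercased and DNA-style ``T`` is normalised to ``U`` for RNA, since
benchmark FASTA files commonly store transcripts in DNA alphabet.
Characters outside the canonical alphabet (ambiguity codes such as N or X)
are retained but flagged; the tokenizer decides their fate downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "Sequence",
    "PairTable",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
]

RNA_SYMBOLS = "ACGU"
PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"


class Alphabet(enum.Enum):
    """Canonical residue alphabets: 4-letter RNA and 20-letter protein."""

    RNA = "RNA"
    PROTEIN = "PROTEIN"

    @property
    def symbols(self) -> str:
        """Canonical symbols, lexicographically ordered."""
        return RNA_SYMBOLS if self is Alphabet.RNA else PROTEIN_SYMBOLS

    @property
    def size(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class Sequence:
    """An identified residue string over a declared alphabet.

    ``non_canonical`` lists the distinct characters falling outside the
    canonical alphabet (e.g. N, X, B).  They are kept in ``residues`` so
    positions stay meaningful; tokenization drops windows containing them.
    """

    id: str
    residues: str
    alphabet: Alphabet
    non_canonical: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        observed = frozenset(self.residues) - frozenset(self.alphabet.symbols)
        object.__setattr__(self, "non_canonical", observed)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_canonical(self) -> bool:
        return not self.non_canonical


@dataclass(frozen=True)
class PairTable:
    """Ordered collection of (rna_id, protein_id, label) records, labels in {0,1}."""

    records: tuple

    def __post_init__(self):
        for r, p, y in self.records:
            if y not in (0, 1):
                raise ValueError(f"pair ({r}, {p}): label {y!r} outside {{0, 1}}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list:
        return [y for _, _, y in self.records]

    def validate_against(self, rna_seqs: Iterable[Sequence], protein_seqs: Iterable[Sequence]) -> None:
        """Check every id resolves against the supplied sequence collections."""
        rna_ids = {s.id for s in rna_seqs}
        prot_ids = {s.id for s in protein_seqs}
        for r, p, _ in self.records:
            if r not in rna_ids:
                raise KeyError(f"pair table references unknown RNA id {r!r}")
            if p not in prot_ids:
                raise KeyError(f"pair table references unknown protein id {p!r}")


def _normalise(residues: str, alphabet: Alphabet) -> str:
    residues = residues.upper()
    if alphabet is Alphabet.RNA:
        residues = residues.replace("T", "U")
    return residues


def read_fasta(path, alphabet: Alphabet) -> list:
    """Read a FASTA file into a list of :class:`Sequence`.

    Residues are uppercased; for RNA, T is mapped to U.  Insertion order is
    preserved.  A duplicate id or text preceding the first header raises.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>' before sequence data"
                )
            break
    out: list = []
    seen: set = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        seen.add(record.id)
        out.append(Sequence(record.id, _normalise(str(record.seq), alphabet), alphabet))
    return out


def write_fasta(seqs: TypingSequence[Sequence], path, width: int = 70) -> None:
    """Write sequences as FASTA with fixed line wrapping (deterministic output)."""
    with open(path, "w", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_pairs(path) -> PairTable:
    """Read a 3-column TSV pair table (rna_id, protein_id, label).

    There is no header by default; a header line is auto-detected when the
    third field of the first row is non-numeric.  Labels must be 0 or 1.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return PairTable(records=())
    fields = first.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}: expected 3 tab-separated columns, found {len(fields)}")
    skip = 0
    try:
        float(fields[2])
    except ValueError:
        skip = 1  # header row
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        skiprows=skip,
        names=["rna_id", "protein_id", "label"],
        dtype={"rna_id": str, "protein_id": str},
    )
    if df["label"].isna().any() or df.shape[1] != 3:
        raise ValueError(f"{path}: missing column or empty label field")
    records = []
    for row in df.itertuples(index=False):
        y = row.label
        if float(y) not in (0.0, 1.0):
            raise ValueError(f"{path}: label {y!r} outside {{0, 1}} for pair ({row.rna_id}, {row.protein_id})")
        records.append((row.rna_id, row.protein_id, int(y)))
    return PairTable(records=tuple(records))


def write_pairs(table: PairTable, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r, p, y in table:
            fh.write(f"{r}\t{p}\t{y}\n")
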
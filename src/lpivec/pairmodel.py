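"""Pair feature assembly and the random-forest interaction classifier.

A candidate RNA-protein pair is represented by concatenating the two
additive sequence embeddings, RNA first, giving rna_dim + protein_dim
features (600 at the default 300-dimensional embeddings).  A selection
mask (top-50 by default) reduces that vector before classification.  The
classifier is a random forest; a pair's interaction probability is the
fraction of trees voting positive, with the decision threshold at 0.5
(ties classified positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .embedding import SequenceEmbedding
from .selection import SelectionMask
from .seqio import PairTable

__all__ = [
    "PairRecord",
    "TrainedPredictor",
    "featurize_pair",
    "assemble_pair_features",
    "train_predictor",
    "predict",
    "save_predictor",
    "load_predictor",
]


@dataclass
class PairRecord:
    """One candidate interaction: ids, optional 0/1 label, feature vector."""

    rna_id: str
    protein_id: str
    label: Optional[int]
    features: np.ndarray

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1 or None, got {self.label!r}")
        self.features = np.asarray(self.features, dtype=np.float64)


def featurize_pair(rna_emb: SequenceEmbedding, prot_emb: SequenceEmbedding) -> np.ndarray:
    """Concatenated pair vector [rna || protein], RNA entries first."""
    return np.concatenate([rna_emb.vector, prot_emb.vector])


def assemble_pair_features(
    pairs: PairTable,
    rna_embeddings: dict,
    protein_embeddings: dict,
) -> List[PairRecord]:
    """Build one PairRecord per pair-table row from embedding lookups."""
    records = []
    for rna_id, prot_id, label in pairs:
        try:
            r_emb = rna_embeddings[rna_id]
            p_emb = protein_embeddings[prot_id]
        except KeyError as exc:
            raise KeyError(f"no embedding for id {exc.args[0]!r}") from None
        records.append(PairRecord(rna_id, prot_id, label, featurize_pair(r_emb, p_emb)))
    return records


@dataclass
class TrainedPredictor:
    """A fitted random forest plus the selection mask and dimensions it expects."""

    forest: RandomForestClassifier
    mask: SelectionMask
    rna_dim: int
    protein_dim: int
    n_trees: int
    seed: int

    @property
    def full_dim(self) -> int:
        return self.rna_dim + self.protein_dim


def _feature_matrix(records: Sequence[PairRecord], expected_dim: int) -> np.ndarray:
    X = np.vstack([r.features for r in records])
    if X.shape[1] != expected_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match predictor expectation {expected_dim}"
        )
    return X


def train_predictor(
    records: Sequence[PairRecord],
    mask: SelectionMask,
    n_trees: int = 500,
    seed: int = 0,
    rna_dim: Optional[int] = None,
    protein_dim: Optional[int] = None,
) -> TrainedPredictor:
    """Train the interaction forest on labelled pair records.

    Requires at least two records per class.  Deterministic given the seed.
    """
    records = list(records)
    if len(mask) == 0:
        raise ValueError("empty selection mask")
    labels = np.array([r.label for r in records])
    if any(l is None for l in labels):
        raise ValueError("all training records must carry a label")
    counts = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    if set(counts) != {0, 1}:
        raise ValueError(f"training data must contain both classes, found {sorted(counts)}")
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 records per class, got {counts}")
    full_dim = records[0].features.shape[0]
    X = mask.apply(_feature_matrix(records, full_dim))
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X, labels.astype(int))
    if rna_dim is None:
        rna_dim = full_dim // 2
    if protein_dim is None:
        protein_dim = full_dim - rna_dim
    return TrainedPredictor(forest, mask, rna_dim, protein_dim, n_trees, seed)


def predict(
    predictor: TrainedPredictor, records: Sequence[PairRecord]
) -> List[Tuple[float, int]]:
    """Score pair records: probability = fraction of trees voting positive,
    label = 1 when probability >= 0.5."""
    records = list(records)
    X = predictor.mask.apply(_feature_matrix(records, predictor.full_dim))
    pos_index = int(np.where(predictor.forest.classes_ == 1)[0][0])
    votes = np.zeros(X.shape[0])
    for tree in predictor.forest.estimators_:
        votes += (tree.predict(X) == predictor.forest.classes_[pos_index]).astype(float)
    prob = votes / len(predictor.forest.estimators_)
    return [(float(p), int(p >= 0.5)) for p in prob]


def save_predictor(predictor: TrainedPredictor, path) -> None:
    """Persist the predictor (forest + mask + dims) as a joblib archive."""
    joblib.dump(
        {
            "format_version": 1,
            "forest": predictor.forest,
            "mask_indices": predictor.mask.selected_indices,
            "mask_k": predictor.mask.k_requested,
            "rna_dim": predictor.rna_dim,
            "protein_dim": predictor.protein_dim,
            "n_trees": predictor.n_trees,
            "seed": predictor.seed,
        },
        path,
    )


def load_predictor(path) -> TrainedPredictor:
    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported predictor archive version {blob.get('format_version')!r}")
    return TrainedPredictor(
        forest=blob["forest"],
        mask=SelectionMask(tuple(blob["mask_indices"]), blob["mask_k"]),
        rna_dim=blob["rna_dim"],
        protein_dim=blob["protein_dim"],
        n_trees=blob["n_trees"],
        seed=blob["seed"],
    )
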
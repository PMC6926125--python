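"""End-to-end orchestration: corpus -> embeddings -> pair features -> CV.

The embedding models are trained once on the full sequence corpora
(embedding training is unsupervised and never sees labels); feature
selection and the classifier are re-fitted inside each cross-validation
training fold.  A single root seed fans out to per-stage sub-seeds so the
whole run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence as TypingSequence, Tuple

import numpy as np

from .embedding import SkipGramModel, TrainingConfig, embed_corpus, train
from .evaluation import CVResult, cross_validate
from .pairmodel import PairRecord, assemble_pair_features
from .seqio import PairTable, Sequence
from .tokenizer import DEFAULT_K_PROTEIN, DEFAULT_K_RNA, corpus_from_fasta

__all__ = ["PipelineConfig", "derive_subseeds", "train_embeddings", "featurize_dataset", "run_cv"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full workflow.

    Defaults follow the method's stated configuration: k=4 (RNA) and k=3
    (protein) words, 300-dimensional embeddings (window 5, 10 epochs,
    min_count 1, batch_words 100), top-50 feature selection, five folds.
    The pipeline-scale embedding default enables the negative-sampling
    accelerator (5 noise words), since a full softmax over the 20^3-word
    protein lexicon is disproportionate for ordinary runs; set
    ``embedding.negative = 0`` for the exact-softmax trainer.
    """

    k_rna: int = DEFAULT_K_RNA
    k_protein: int = DEFAULT_K_PROTEIN
    embedding: TrainingConfig = field(default_factory=lambda: TrainingConfig(negative=5))
    top_k: int = 50
    n_trees: int = 500
    selection_trees: int = 500
    folds: int = 5
    seed: int = 0
    stratified: bool = True
    global_selection: bool = False  # True: fit selection once on the full dataset
    weighted_importance: bool = True


def derive_subseeds(root_seed: int, n: int = 4) -> List[int]:
    """Fan a root seed out to n independent sub-seeds (each < 2**31)."""
    state = np.random.SeedSequence(root_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def train_embeddings(
    rna_seqs: TypingSequence[Sequence],
    protein_seqs: TypingSequence[Sequence],
    config: PipelineConfig,
) -> Tuple[SkipGramModel, SkipGramModel]:
    """Train RNA and protein skip-gram models on the two corpora."""
    rna_seed, prot_seed, _, _ = derive_subseeds(config.seed)
    rna_corpus = corpus_from_fasta(rna_seqs, config.k_rna)
    prot_corpus = corpus_from_fasta(protein_seqs, config.k_protein)
    rna_model = train(rna_corpus, replace(config.embedding, seed=rna_seed))
    prot_model = train(prot_corpus, replace(config.embedding, seed=prot_seed))
    return rna_model, prot_model


def featurize_dataset(
    pairs: PairTable,
    rna_seqs: TypingSequence[Sequence],
    protein_seqs: TypingSequence[Sequence],
    rna_model: SkipGramModel,
    protein_model: SkipGramModel,
    config: PipelineConfig,
) -> List[PairRecord]:
    """Embed every sequence and assemble the concatenated pair vectors."""
    pairs.validate_against(rna_seqs, protein_seqs)
    rna_embeddings = embed_corpus(rna_model, rna_seqs, config.k_rna)
    prot_embeddings = embed_corpus(protein_model, protein_seqs, config.k_protein)
    return assemble_pair_features(pairs, rna_embeddings, prot_embeddings)


def run_cv(
    pairs: PairTable,
    rna_seqs: TypingSequence[Sequence],
    protein_seqs: TypingSequence[Sequence],
    config: Optional[PipelineConfig] = None,
    records: Optional[List[PairRecord]] = None,
) -> CVResult:
    """The full workflow under k-fold cross-validation.

    Pass ``records`` to reuse previously assembled pair features (e.g. for
    label-permutation experiments where only the labels change).
    """
    config = config or PipelineConfig()
    if records is None:
        rna_model, prot_model = train_embeddings(rna_seqs, protein_seqs, config)
        records = featurize_dataset(pairs, rna_seqs, protein_seqs, rna_model, prot_model, config)
    _, _, cv_seed, _ = derive_subseeds(config.seed)
    return cross_validate(
        records,
        folds=config.folds,
        top_k=config.top_k,
        n_trees=config.n_trees,
        selection_trees=config.selection_trees,
        seed=cv_seed,
        stratified=config.stratified,
        refit_selection_per_fold=not config.global_selection,
        weighted_importance=config.weighted_importance,
    )
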
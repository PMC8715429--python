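"""Naive-Bayes bootstrap taxonomic classifier and leave-clade-out accuracy.

The classifier follows the classic RDP scheme: for word size k (default 8)
the prior of word w is (n_w + 0.5) / (N + 1) over the N training sequences,
and its conditional probability in taxon t is (m_wt + prior_w) / (M_t + 1).
A query is scored by the joint log probability of its distinct words;
bootstrap support is the fraction of 100 resamplings of floor(W/8) words
voting for the winning taxon. Accuracy is assessed with leave-clade-out
cross-validation: all sequences of a held-out clade (e.g. a strain) are
confined to the validation split, and a prediction counts as accurate only
when it is correct and its bootstrap support exceeds the cutoff (0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_K = 8
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_BOOTSTRAP_CUTOFF = 0.80

_VALID = frozenset("ACGT")


def sequence_words(seq: str, k: int) -> list[str]:
    """Distinct ACGT-only k-mers of ``seq`` (uppercased)."""
    seq = seq.upper()
    return sorted({seq[i : i + k] for i in range(len(seq) - k + 1)} - _invalid_words(seq, k))


def _invalid_words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if not set(seq[i : i + k]) <= _VALID}


@dataclass
class KmerModel:
    k: int
    taxa: list[str]
    vocab: dict[str, int]  # word -> column index
    log_cond: np.ndarray  # (n_taxa, n_words) log P(w | t)
    log_unseen: np.ndarray  # (n_taxa,) log P(w | t) for words unseen in training
    training_counts: dict[str, int] = field(default_factory=dict)  # taxon -> n sequences


def train(seqs_with_taxa: Sequence[tuple[str, str]], k: int = DEFAULT_K) -> KmerModel:
    """Train a word-presence model from (sequence, taxon) pairs.

    Taxa contributing no sequence of length >= k are excluded with a
    warning. Requires at least two taxa.
    """
    import warnings

    per_taxon_words: dict[str, list[list[str]]] = {}
    for seq, taxon in seqs_with_taxa:
        words = sequence_words(seq, k)
        if not words:
            continue
        per_taxon_words.setdefault(taxon, []).append(words)

    empty = {t for t, lists in per_taxon_words.items() if not lists}
    for t in empty:
        warnings.warn(f"taxon {t!r} has no valid sequence; excluded", stacklevel=2)
        del per_taxon_words[t]
    if len(per_taxon_words) < 2:
        raise ValueError("training requires at least two taxa with valid sequences")

    taxa = sorted(per_taxon_words)
    vocab: dict[str, int] = {}
    n_seqs_total = sum(len(v) for v in per_taxon_words.values())
    word_doc_count: dict[str, int] = {}
    for lists in per_taxon_words.values():
        for words in lists:
            for w in words:
                word_doc_count[w] = word_doc_count.get(w, 0) + 1
    for w in sorted(word_doc_count):
        vocab[w] = len(vocab)

    prior = np.empty(len(vocab))
    for w, idx in vocab.items():
        prior[idx] = (word_doc_count[w] + 0.5) / (n_seqs_total + 1)

    log_cond = np.empty((len(taxa), len(vocab)))
    log_unseen = np.empty(len(taxa))
    p_unseen = 0.5 / (n_seqs_total + 1)
    training_counts = {}
    for ti, taxon in enumerate(taxa):
        lists = per_taxon_words[taxon]
        M = len(lists)
        training_counts[taxon] = M
        counts = np.zeros(len(vocab))
        for words in lists:
            for w in words:
                counts[vocab[w]] += 1
        log_cond[ti] = np.log((counts + prior) / (M + 1))
        log_unseen[ti] = np.log(p_unseen / (M + 1))
    return KmerModel(
        k=k,
        taxa=taxa,
        vocab=vocab,
        log_cond=log_cond,
        log_unseen=log_unseen,
        training_counts=training_counts,
    )


def classify(
    seq: str,
    model: KmerModel,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
) -> tuple[str, float]:
    """Classify one sequence; returns (taxon, bootstrap support).

    Each bootstrap draws floor(W/8) of the query's W distinct words with
    replacement, scores the joint log probability per taxon and votes for
    the argmax; support is the winning taxon's vote fraction.
    """
    if len(seq) < model.k:
        raise ValueError(f"sequence shorter than word size k={model.k}")
    words = sequence_words(seq, model.k)
    if not words:
        raise ValueError("sequence contains no valid words")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # per-word log-probability columns for this query: (n_taxa, W)
    cols = np.empty((len(model.taxa), len(words)))
    for j, w in enumerate(words):
        idx = model.vocab.get(w)
        cols[:, j] = model.log_cond[:, idx] if idx is not None else model.log_unseen

    W = len(words)
    n_draw = max(1, W // 8)
    draws = rng.integers(0, W, size=(n_bootstrap, n_draw))
    votes = np.zeros(len(model.taxa), dtype=int)
    for b in range(n_bootstrap):
        scores = cols[:, draws[b]].sum(axis=1)
        votes[int(np.argmax(scores))] += 1
    winner = int(np.argmax(votes))
    return model.taxa[winner], votes[winner] / n_bootstrap


@dataclass
class AccuracyReport:
    folds: list[float]
    bootstrap_cutoff: float = DEFAULT_BOOTSTRAP_CUTOFF

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.folds)) if self.folds else float("nan")


def leave_clade_out_cv(
    table: pd.DataFrame,
    target_rank: str = "species",
    rank_left_out: str = "strain",
    n_folds: int = 5,
    k: int = DEFAULT_K,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    bootstrap_cutoff: float = DEFAULT_BOOTSTRAP_CUTOFF,
    seed: int = 0,
) -> AccuracyReport:
    """Cross-validated classification accuracy with whole clades held out.

    ``table`` holds one row per sequence with the rank columns and a
    ``sequence`` column (already restricted to the region composite under
    study). Clades (unique values of ``rank_left_out``) are partitioned into
    ``n_folds`` folds; per fold the model is retrained without the held-out
    clades and every held-out sequence is classified at ``target_rank``.
    Fold accuracy = predictions that are correct AND have bootstrap support
    strictly above the cutoff, divided by all validation sequences.
    """
    clades = sorted(table[rank_left_out].unique())
    if len(clades) < n_folds:
        raise ValueError(f"{len(clades)} clades < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clades))
    fold_of_clade = {clades[idx]: i % n_folds for i, idx in enumerate(order)}

    fold_acc: list[float] = []
    for fold in range(n_folds):
        val_mask = table[rank_left_out].map(fold_of_clade) == fold
        train_df = table[~val_mask]
        val_df = table[val_mask]
        assert not set(val_df[rank_left_out]) & set(train_df[rank_left_out])
        model = train(list(zip(train_df["sequence"], train_df[target_rank])), k=k)
        n_correct = 0
        for _, row in val_df.iterrows():
            taxon, support = classify(row["sequence"], model, n_bootstrap=n_bootstrap, seed=rng)
            if taxon == row[target_rank] and support > bootstrap_cutoff:
                n_correct += 1
        fold_acc.append(n_correct / len(val_df) if len(val_df) else float("nan"))
    return AccuracyReport(folds=fold_acc, bootstrap_cutoff=bootstrap_cutoff)
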
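"""Dataset-level lexical comparisons.

Vocabulary size, singletons (hapax legomena), cross-dataset overlap and
distinctive words, word length, and response-length summaries — plus
rarefaction: estimating vocabulary size at a fixed number of responses by
repeated random subsampling, so that collections of unequal size can be
compared fairly (a larger corpus accumulates more distinct words for reasons
of size alone).

All statistics are computed on *content* words, i.e. after stopword removal.
Word frequency is the corpus-level token count, repeats within a response
included; a singleton is a word with total frequency exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .textprep import TermDocumentMatrix

__all__ = [
    "VocabularyStats",
    "RarefactionResult",
    "vocabulary_stats",
    "rarefy_vocabulary",
    "vocab_overlap",
    "distinctive_words",
    "length_summary",
]


@dataclass(frozen=True)
class VocabularyStats:
    dataset_label: str
    n_responses: int
    vocab_size: int
    singleton_count: int
    mean_word_length: float
    mean_response_length: float
    median_response_length: float


@dataclass(frozen=True)
class RarefactionResult:
    sample_size: int
    replicates: int
    mean_vocab: float
    sd_vocab: float
    seed: int


def _letters(word: str) -> int:
    # length in letters only; hyphens/apostrophes in tokens are not counted
    return sum(ch.isalpha() for ch in word)


def vocabulary_stats(tdm: TermDocumentMatrix, dataset_label: str = "") -> VocabularyStats:
    """Distinct-word, singleton, word-length and response-length summary."""
    if tdm.n_docs == 0:
        raise ValueError("empty corpus")
    freqs = tdm.word_frequencies()
    present = freqs > 0
    vocab_size = int(present.sum())
    singleton_count = int((freqs == 1).sum())
    if vocab_size:
        mean_word_length = float(
            np.mean([_letters(w) for w, p in zip(tdm.vocabulary, present) if p])
        )
    else:
        mean_word_length = float("nan")
    lengths = tdm.row_lengths()
    return VocabularyStats(
        dataset_label=dataset_label,
        n_responses=tdm.n_docs,
        vocab_size=vocab_size,
        singleton_count=singleton_count,
        mean_word_length=mean_word_length,
        mean_response_length=float(np.mean(lengths)),
        median_response_length=float(np.median(lengths)),
    )


def rarefy_vocabulary(
    tdm: TermDocumentMatrix,
    sample_size: int,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RarefactionResult:
    """Mean distinct-word count among random subsamples of whole responses.

    Responses are drawn without replacement; with ``sample_size`` equal to the
    corpus size every replicate reproduces the full vocabulary exactly.
    """
    n = tdm.n_docs
    if not 1 <= sample_size <= n:
        raise ValueError(f"sample_size must be in [1, {n}], got {sample_size}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    csr = tdm.counts.tocsr()
    vocab_counts = np.empty(replicates, dtype=np.int64)
    for b in range(replicates):
        rows = rng.choice(n, size=sample_size, replace=False)
        sub = csr[rows]
        vocab_counts[b] = np.count_nonzero(
            np.asarray(sub.sum(axis=0)).ravel()
        )
    return RarefactionResult(
        sample_size=sample_size,
        replicates=replicates,
        mean_vocab=float(vocab_counts.mean()),
        sd_vocab=float(vocab_counts.std(ddof=1)) if replicates > 1 else 0.0,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )


def _realized_vocab(tdm: TermDocumentMatrix) -> set[str]:
    freqs = tdm.word_frequencies()
    return {w for w, f in zip(tdm.vocabulary, freqs) if f > 0}


def vocab_overlap(
    tdm_a: TermDocumentMatrix, tdm_b: TermDocumentMatrix
) -> tuple[int, int, int]:
    """``(shared, only_a, only_b)`` distinct-word counts of two corpora.

    Conservation holds by construction: ``shared + only_a`` is the vocabulary
    size of ``a`` and ``shared + only_b`` that of ``b``.
    """
    va, vb = _realized_vocab(tdm_a), _realized_vocab(tdm_b)
    return len(va & vb), len(va - vb), len(vb - va)


def distinctive_words(
    tdm_a: TermDocumentMatrix, tdm_b: TermDocumentMatrix, top_k: int = 15
) -> pd.DataFrame:
    """Most frequent words of corpus ``a`` absent from corpus ``b``.

    Ordered by frequency descending, ties broken lexicographically, so the
    table is stable across runs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    vb = _realized_vocab(tdm_b)
    freqs = tdm_a.word_frequencies()
    rows = [
        (w, int(f))
        for w, f in zip(tdm_a.vocabulary, freqs)
        if f > 0 and w not in vb
    ]
    rows.sort(key=lambda wf: (-wf[1], wf[0]))
    return pd.DataFrame(rows[:top_k], columns=["word", "frequency"])


def length_summary(
    tdm: TermDocumentMatrix, dataset_label: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-response content-word counts plus their mean/median.

    Returns ``(per_response, summary)`` frames; counts are after stopword
    removal with repeats included.
    """
    lengths = tdm.row_lengths()
    per_response = pd.DataFrame(
        {
            "response_id": list(tdm.doc_ids),
            "dataset": dataset_label,
            "word_count": lengths,
        }
    )
    summary = pd.DataFrame(
        {
            "dataset": [dataset_label],
            "n_responses": [tdm.n_docs],
            "mean_length": [float(np.mean(lengths)) if tdm.n_docs else 0.0],
            "median_length": [float(np.median(lengths)) if tdm.n_docs else 0.0],
        }
    )
    return per_response, summary
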
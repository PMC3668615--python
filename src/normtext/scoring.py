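"""Shared-word scoring and take-one-out validation.

The score of record is the *shared-word count*: the number of distinct content
words two responses have in common after stopword removal, ignoring repeats.
A response's quality relative to a normative dataset is summarised by its mean
shared-word count with responses to the same clip (``mean_same``) versus
responses to other clips (``mean_other``).  If responses carry real content
about a clip, ``mean_same`` exceeds ``mean_other`` on average.

Three comparison regimes are provided:

* :func:`take_one_out` — each response scored against all *other* responses in
  the same dataset (never against itself);
* :func:`cross_dataset_scores` — responses of one dataset scored against a
  second, reference dataset;
* :func:`pooled_scores` — datasets concatenated and scored take-one-out, with
  each result keeping its original dataset label.

Undefined means (no comparison responses) are reported as missing (NaN),
never coerced to zero.

The implementation aggregates binary term incidence per clip so the whole
procedure is linear in the number of (response, word) pairs; tests verify
exact agreement with a naive double-loop intersection count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .textprep import TokenizedResponse

__all__ = [
    "SharedWordResult",
    "ClipHomogeneity",
    "shared_word_count",
    "take_one_out",
    "cross_dataset_scores",
    "pooled_scores",
    "clip_homogeneity",
    "same_other_ratio",
    "results_to_frame",
]


@dataclass(frozen=True)
class SharedWordResult:
    """Per-response take-one-out summary.

    ``mean_same`` / ``mean_other`` are NaN when no comparison responses exist
    (``n_same`` / ``n_other`` zero).
    """

    response_id: str
    clip_id: str
    dataset_label: str
    mean_same: float
    mean_other: float
    n_same: int
    n_other: int
    word_count: int | None = None


@dataclass(frozen=True)
class ClipHomogeneity:
    """Mean same-clip shared-word score of a clip's responses.

    Reflects how homogeneous the descriptions of one clip are: clips that
    elicit a large common vocabulary score high.
    """

    clip_id: str
    mean_shared: float
    n_responses: int


def shared_word_count(set_a: Iterable[str], set_b: Iterable[str]) -> int:
    """Number of distinct words two responses share; symmetric."""
    return len(frozenset(set_a) & frozenset(set_b))


def _incidence(
    responses: Sequence[TokenizedResponse],
    vocab_index: dict[str, int] | None = None,
) -> tuple[sparse.csr_matrix, dict[str, int]]:
    """Binary response x word incidence matrix over a (possibly given) vocab.

    Words outside a supplied ``vocab_index`` are dropped: they cannot
    contribute to any intersection with the reference corpus.
    """
    if vocab_index is None:
        vocab = sorted(set().union(*(r.word_set for r in responses)) if responses else set())
        vocab_index = {w: i for i, w in enumerate(vocab)}
    rows: list[int] = []
    cols: list[int] = []
    for i, r in enumerate(responses):
        for w in r.word_set:
            j = vocab_index.get(w)
            if j is not None:
                rows.append(i)
                cols.append(j)
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(responses), max(len(vocab_index), 1)),
    )
    return mat, vocab_index


def _group_sums(
    mat: sparse.csr_matrix, codes: np.ndarray, n_groups: int
) -> sparse.csr_matrix:
    """Per-group column sums of a sparse incidence matrix (groups x words)."""
    ind = sparse.csr_matrix(
        (np.ones(len(codes), dtype=np.int64), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)),
    )
    return ind @ mat


def take_one_out(
    dataset: Sequence[TokenizedResponse],
    exclude_same_participant: bool = False,
) -> list[SharedWordResult]:
    """Score every response against all other responses in its dataset.

    For each response the shared-word count with every other response is
    computed exactly; ``mean_same`` averages over same-clip comparisons and
    ``mean_other`` over other-clip comparisons.  A response is never compared
    to itself.  A clip with a single response yields ``mean_same`` NaN for it.
    With ``exclude_same_participant`` on, a participant's own responses to
    other clips are removed from the other-clip comparison set.
    """
    responses = list(dataset)
    clips = sorted({r.clip_id for r in responses})
    if len(clips) < 2:
        raise ValueError("take-one-out requires responses to at least two clips")
    clip_code = {c: i for i, c in enumerate(clips)}
    codes = np.array([clip_code[r.clip_id] for r in responses])
    clip_sizes = np.bincount(codes, minlength=len(clips))
    set_sizes = np.array([len(r.word_set) for r in responses], dtype=np.int64)

    mat, _ = _incidence(responses)
    group = _group_sums(mat, codes, len(clips))
    # total shared words of response i with every response of clip g, incl. self
    per_clip = np.asarray((mat @ group.T).todense())
    total = per_clip.sum(axis=1)
    own = per_clip[np.arange(len(responses)), codes]

    same_sum = own - set_sizes  # remove the self-comparison
    other_sum = total - own
    n_same = clip_sizes[codes] - 1
    n_other = len(responses) - clip_sizes[codes]

    if exclude_same_participant:
        participants = sorted({r.participant_id for r in responses})
        p_code = {p: i for i, p in enumerate(participants)}
        pcodes = np.array([p_code[r.participant_id] for r in responses])
        p_group = _group_sums(mat, pcodes, len(participants))
        per_part = np.asarray((mat @ p_group.T).todense())
        own_part = per_part[np.arange(len(responses)), pcodes]
        # a participant appears at most once per clip, so their only same-clip
        # response is the query itself
        other_sum = other_sum - (own_part - set_sizes)
        p_sizes = np.bincount(pcodes, minlength=len(participants))
        n_other = n_other - (p_sizes[pcodes] - 1)

    return _assemble(responses, same_sum, other_sum, n_same, n_other)


def cross_dataset_scores(
    queries: Sequence[TokenizedResponse],
    reference: Sequence[TokenizedResponse],
) -> list[SharedWordResult]:
    """Score each query response against a *reference* dataset.

    ``mean_same`` averages shared-word counts with the reference responses to
    the query's clip, ``mean_other`` with reference responses to all other
    clips.  Asymmetric in its arguments; no self-comparison issue arises.  A
    query whose clip is absent from the reference gets ``mean_same`` NaN.
    """
    queries = list(queries)
    reference = list(reference)
    if not reference:
        raise ValueError("reference dataset is empty")
    ref_clips = sorted({r.clip_id for r in reference})
    clip_code = {c: i for i, c in enumerate(ref_clips)}
    ref_codes = np.array([clip_code[r.clip_id] for r in reference])
    ref_sizes = np.bincount(ref_codes, minlength=len(ref_clips))

    ref_mat, vocab_index = _incidence(reference)
    q_mat, _ = _incidence(queries, vocab_index)
    group = _group_sums(ref_mat, ref_codes, len(ref_clips))
    per_clip = np.asarray((q_mat @ group.T).todense())
    total = per_clip.sum(axis=1)

    q_codes = np.array(
        [clip_code.get(q.clip_id, -1) for q in queries], dtype=np.int64
    )
    present = q_codes >= 0
    own = np.zeros(len(queries))
    n_same = np.zeros(len(queries), dtype=np.int64)
    own[present] = per_clip[present, q_codes[present]]
    n_same[present] = ref_sizes[q_codes[present]]
    other_sum = total - own
    n_other = len(reference) - n_same

    return _assemble(queries, own, other_sum, n_same, n_other)


def pooled_scores(
    datasets: Sequence[Sequence[TokenizedResponse]],
    exclude_same_participant: bool = False,
) -> list[SharedWordResult]:
    """Pool datasets and score take-one-out against the pooled corpus.

    Equivalent to :func:`take_one_out` on the concatenation; each result keeps
    its original dataset label for downstream factorial analysis.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    pooled = [r for ds in datasets for r in ds]
    return take_one_out(pooled, exclude_same_participant=exclude_same_participant)


def _assemble(
    responses: Sequence[TokenizedResponse],
    same_sum: np.ndarray,
    other_sum: np.ndarray,
    n_same: np.ndarray,
    n_other: np.ndarray,
) -> list[SharedWordResult]:
    out = []
    for i, r in enumerate(responses):
        ms = same_sum[i] / n_same[i] if n_same[i] > 0 else math.nan
        mo = other_sum[i] / n_other[i] if n_other[i] > 0 else math.nan
        out.append(
            SharedWordResult(
                response_id=r.response_id,
                clip_id=r.clip_id,
                dataset_label=r.dataset_label,
                mean_same=float(ms),
                mean_other=float(mo),
                n_same=int(n_same[i]),
                n_other=int(n_other[i]),
                word_count=r.word_count,
            )
        )
    return out


def clip_homogeneity(
    dataset: Sequence[TokenizedResponse] | None = None,
    results: Sequence[SharedWordResult] | None = None,
) -> list[ClipHomogeneity]:
    """Per-clip mean of same-clip shared-word scores.

    Accepts either a tokenized dataset (scored internally with
    :func:`take_one_out`) or precomputed results.  Responses with undefined
    ``mean_same`` are excluded with a warning.
    """
    if results is None:
        if dataset is None:
            raise ValueError("provide a dataset or precomputed results")
        results = take_one_out(dataset)
    by_clip: dict[str, list[float]] = {}
    n_dropped = 0
    counts: dict[str, int] = {}
    for r in results:
        counts[r.clip_id] = counts.get(r.clip_id, 0) + 1
        if math.isnan(r.mean_same):
            n_dropped += 1
            continue
        by_clip.setdefault(r.clip_id, []).append(r.mean_same)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} response(s) with undefined same-clip mean excluded "
            "from clip homogeneity",
            stacklevel=2,
        )
    return [
        ClipHomogeneity(
            clip_id=c, mean_shared=float(np.mean(v)), n_responses=counts[c]
        )
        for c, v in sorted(by_clip.items())
    ]


def same_other_ratio(results: Sequence[SharedWordResult]) -> float:
    """Grand mean of ``mean_same`` divided by grand mean of ``mean_other``.

    Missing means are excluded from either grand mean.  A zero denominator is
    flagged with a warning and reported as ``inf``.
    """
    same = np.array([r.mean_same for r in results])
    other = np.array([r.mean_other for r in results])
    num = float(np.nanmean(same))
    den = float(np.nanmean(other))
    if den == 0.0:
        warnings.warn(
            "mean other-clip score is zero; same/other ratio is infinite",
            stacklevel=2,
        )
        return math.inf
    return num / den


def results_to_frame(results: Sequence[SharedWordResult]) -> pd.DataFrame:
    """Tabulate results in the score-output column layout."""
    return pd.DataFrame(
        {
            "response_id": [r.response_id for r in results],
            "clip_id": [r.clip_id for r in results],
            "dataset": [r.dataset_label for r in results],
            "mean_same": [r.mean_same for r in results],
            "mean_other": [r.mean_other for r in results],
            "n_same": [r.n_same for r in results],
            "n_other": [r.n_other for r in results],
            "word_count": [r.word_count for r in results],
        }
    )
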
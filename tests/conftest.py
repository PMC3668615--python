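"""Shared fixtures: tiny corpora and an exhaustive double-loop scoring oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from normtext.textprep import StopwordList, TokenizedResponse, default_stopwords


def tr(
    rid: str,
    clip: str,
    words: set[str] | list[str],
    count: int | None = None,
    dataset: str = "d",
    participant: str | None = None,
) -> TokenizedResponse:
    """Terse TokenizedResponse factory for tests."""
    ws = frozenset(words)
    return TokenizedResponse(
        response_id=rid,
        clip_id=clip,
        participant_id=participant if participant is not None else f"p_{rid}",
        dataset_label=dataset,
        word_set=ws,
        word_count=count if count is not None else len(ws),
    )


@pytest.fixture(scope="session")
def stoplist() -> StopwordList:
    return default_stopwords()


@pytest.fixture
def toy_corpus() -> list[TokenizedResponse]:
    """Two clips with partially overlapping same-clip vocabularies."""
    return [
        tr("r1", "clip1", {"dog", "park"}),
        tr("r2", "clip1", {"dog", "ball"}),
        tr("r3", "clip1", {"park", "ball"}),
        tr("r4", "clip2", {"cat", "sofa"}),
        tr("r5", "clip2", {"cat", "nap"}),
    ]


def random_corpus(
    rng: np.random.Generator,
    n_responses: int | None = None,
    n_clips: int | None = None,
    vocab_size: int = 30,
    dataset: str = "d",
    n_participants: int | None = None,
) -> list[TokenizedResponse]:
    """A random small corpus over a bounded vocabulary (for oracle checks)."""
    n = n_responses if n_responses is not None else int(rng.integers(4, 51))
    k = n_clips if n_clips is not None else int(rng.integers(2, 6))
    # honour the data contract: (participant, clip) unique within a dataset
    npart = n_participants if n_participants is not None else max(2, -(-n // k) + 2)
    cells = rng.choice(npart * k, size=n, replace=False)
    vocab = [f"w{i}" for i in range(vocab_size)]
    out = []
    for i, cell in enumerate(cells):
        size = int(rng.integers(0, 9))
        words = rng.choice(vocab, size=size, replace=False) if size else []
        out.append(
            tr(
                f"{dataset}_r{i}",
                f"clip{int(cell % k)}",
                set(words),
                count=size + int(rng.integers(0, 3)),
                dataset=dataset,
                participant=f"{dataset}_p{int(cell // k)}",
            )
        )
    # take_one_out needs >= 2 clips realised
    if len({r.clip_id for r in out}) < 2:
        out[0] = tr(
            f"{dataset}_r0", "clipX", set(), count=0, dataset=dataset,
            participant=f"{dataset}_p0",
        )
    return out


def naive_take_one_out(responses, exclude_same_participant=False):
    """Exhaustive double-loop oracle: dict rid -> (mean_same, mean_other, n_same, n_other)."""
    out = {}
    for r in responses:
        same, other = [], []
        for s in responses:
            if s is r:
                continue
            shared = len(r.word_set & s.word_set)
            if s.clip_id == r.clip_id:
                same.append(shared)
            elif exclude_same_participant and s.participant_id == r.participant_id:
                continue
            else:
                other.append(shared)
        out[r.response_id] = (
            sum(same) / len(same) if same else math.nan,
            sum(other) / len(other) if other else math.nan,
            len(same),
            len(other),
        )
    return out


def naive_cross_scores(queries, reference):
    """Exhaustive oracle for cross-dataset scoring."""
    out = {}
    for q in queries:
        same = [len(q.word_set & s.word_set) for s in reference if s.clip_id == q.clip_id]
        other = [len(q.word_set & s.word_set) for s in reference if s.clip_id != q.clip_id]
        out[q.response_id] = (
            sum(same) / len(same) if same else math.nan,
            sum(other) / len(other) if other else math.nan,
            len(same),
            len(other),
        )
    return out


def assert_results_match(results, oracle):
    assert len(results) == len(oracle)
    for r in results:
        ms, mo, ns, no = oracle[r.response_id]
        assert (r.n_same, r.n_other) == (ns, no), r.response_id
        for got, want in ((r.mean_same, ms), (r.mean_other, mo)):
            if math.isnan(want):
                assert math.isnan(got), r.response_id
            else:
                assert got == pytest.approx(want, abs=1e-12), r.response_id
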
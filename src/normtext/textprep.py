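"""Text preprocessing: tokenisation, stopword removal, term-document matrices.

Free-text responses are reduced to bags of lowercase *content words*: the text
is Unicode-normalised, tokenised into letter runs (internal hyphens and
apostrophes kept, so "jell-o" and "isn't" are single tokens), and stopwords —
high-frequency function words plus spoken interjections such as "um" and
"yeah" — are deleted.  No stemming or spelling correction is applied: scoring
downstream matches raw tokens only.

A packaged default stopword list ships with the module and can be replaced by
any plain-text file (one token per line, ``#`` comments).
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "RawResponse",
    "StopwordList",
    "TokenizedResponse",
    "TermDocumentMatrix",
    "TokenizationRules",
    "tokenize",
    "remove_stopwords",
    "tokenized_response",
    "build_term_document_matrix",
    "load_stopwords",
    "default_stopwords",
]


@dataclass(frozen=True)
class RawResponse:
    """One participant's free-text answer(s) to one clip."""

    response_id: str
    participant_id: str
    clip_id: str
    dataset_label: str
    prompt_a_text: str
    prompt_b_text: str = ""


@dataclass(frozen=True)
class StopwordList:
    """A set of lowercase tokens to delete before any scoring."""

    words: frozenset[str]
    source_note: str = ""

    def __post_init__(self) -> None:
        for w in self.words:
            if not w or w != w.casefold() or re.search(r"\s", w):
                raise ValueError(
                    f"stopword {w!r} must be nonempty, lowercase, without whitespace"
                )

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class TokenizedResponse:
    """A response reduced to its distinct content-word set.

    ``word_count`` is the total number of content tokens (repeats included,
    stopwords removed); ``word_set`` the distinct content words, so
    ``len(word_set) <= word_count`` always.
    """

    response_id: str
    clip_id: str
    participant_id: str
    dataset_label: str
    word_set: frozenset[str]
    word_count: int

    def __post_init__(self) -> None:
        if len(self.word_set) > self.word_count:
            raise ValueError("word_set larger than total content-token count")


@dataclass(frozen=True)
class TokenizationRules:
    """Tokenisation configuration.

    Tokens are maximal runs of Unicode letters; internal hyphens and
    apostrophes join runs into one token unless splitting is requested.
    Pure-number tokens never survive (the pattern matches letters only).
    """

    split_hyphens: bool = False
    split_apostrophes: bool = False

    @property
    def pattern(self) -> re.Pattern[str]:
        joiners = ""
        if not self.split_hyphens:
            joiners += r"\-"
        if not self.split_apostrophes:
            joiners += r"'’"
        letter = r"[^\W\d_]"
        if joiners:
            pat = rf"{letter}+(?:[{joiners}]{letter}+)*"
        else:
            pat = rf"{letter}+"
        return re.compile(pat, re.UNICODE)


DEFAULT_RULES = TokenizationRules()


def tokenize(text: str, rules: TokenizationRules = DEFAULT_RULES) -> list[str]:
    """Split free text into an ordered list of lowercase tokens.

    Applies NFC normalisation and case folding first, so the output is
    deterministic across platforms and input encodings.  Curly apostrophes
    are folded to ASCII.  Empty text yields an empty list.
    """
    if not text:
        return []
    norm = unicodedata.normalize("NFC", text).casefold()
    return [t.replace("’", "'") for t in rules.pattern.findall(norm)]


def remove_stopwords(tokens: Sequence[str], stoplist: StopwordList) -> list[str]:
    """Delete stopwords, preserving order and repeats of content words.

    Idempotent: applying it twice equals applying it once.
    """
    return [t for t in tokens if t not in stoplist]


def tokenized_response(
    raw: RawResponse,
    stoplist: StopwordList,
    rules: TokenizationRules = DEFAULT_RULES,
    combine: bool = True,
) -> TokenizedResponse:
    """Reduce a raw response to its content-word set and count.

    With ``combine`` on (the default) the two prompt answers are
    whitespace-joined and scored as one response; otherwise only the first
    (description) prompt is used.
    """
    text = (
        f"{raw.prompt_a_text} {raw.prompt_b_text}" if combine else raw.prompt_a_text
    )
    content = remove_stopwords(tokenize(text, rules), stoplist)
    return TokenizedResponse(
        response_id=raw.response_id,
        clip_id=raw.clip_id,
        participant_id=raw.participant_id,
        dataset_label=raw.dataset_label,
        word_set=frozenset(content),
        word_count=len(content),
    )


@dataclass(frozen=True)
class TermDocumentMatrix:
    """Documents x terms count matrix of a corpus (sparse).

    Row sums reproduce each document's content-word count; the number of
    nonzero entries in a row equals the size of its distinct word set.
    """

    vocabulary: tuple[str, ...]
    counts: sparse.csr_matrix
    doc_ids: tuple[str, ...]
    doc_meta: "object | None" = field(default=None, compare=False)

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def vocab_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}

    def word_frequencies(self) -> np.ndarray:
        """Total occurrence count of each vocabulary word (repeats included)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def row_lengths(self) -> np.ndarray:
        """Content-word count of each document."""
        return np.asarray(self.counts.sum(axis=1)).ravel()


def build_term_document_matrix(
    responses: Sequence[RawResponse],
    stoplist: StopwordList,
    rules: TokenizationRules = DEFAULT_RULES,
    combine: bool = True,
) -> TermDocumentMatrix:
    """Tokenise a corpus of raw responses into a term-document count matrix.

    The vocabulary is the lexicographically sorted union of content words;
    storage is sparse (proportional to nonzeros).
    """
    if len(responses) == 0:
        raise ValueError("cannot build a term-document matrix from zero responses")
    doc_counters: list[Counter[str]] = []
    for raw in responses:
        text = (
            f"{raw.prompt_a_text} {raw.prompt_b_text}" if combine else raw.prompt_a_text
        )
        doc_counters.append(Counter(remove_stopwords(tokenize(text, rules), stoplist)))
    vocabulary = tuple(sorted(set().union(*doc_counters)))
    index = {w: i for i, w in enumerate(vocabulary)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for d, counter in enumerate(doc_counters):
        for w, c in counter.items():
            rows.append(d)
            cols.append(index[w])
            data.append(c)
    counts = sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(responses), len(vocabulary)),
        dtype=np.int64,
    )
    return TermDocumentMatrix(
        vocabulary=vocabulary,
        counts=counts,
        doc_ids=tuple(r.response_id for r in responses),
    )


def load_stopwords(path: str | Path) -> StopwordList:
    """Read a stopword file: one token per line, ``#`` comments, blank lines ok.

    Tokens are case-folded and deduplicated.  A token containing internal
    whitespace is a format error; an empty resulting list is allowed but
    warned about.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stopword file not found: {path}")
    words: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        if re.search(r"\s", entry):
            raise ValueError(
                f"{path}:{lineno}: stopword entry {entry!r} contains whitespace"
            )
        words.add(unicodedata.normalize("NFC", entry).casefold())
    if not words:
        warnings.warn(f"stopword file {path} contains no entries", stacklevel=2)
    return StopwordList(words=frozenset(words), source_note=str(path))


def default_stopwords() -> StopwordList:
    """The packaged default list: standard English stopwords plus interjections."""
    ref = resources.files("normtext").joinpath("data/stopwords.txt")
    with resources.as_file(ref) as path:
        sl = load_stopwords(path)
    return StopwordList(words=sl.words, source_note="packaged default")
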
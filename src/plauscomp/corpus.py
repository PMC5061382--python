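"""Corpus reading, vocabulary construction and windowed co-occurrence counting.

The corpus format is deliberately minimal: UTF-8 text, one sentence per
line, whitespace-separated lemma tokens, optionally carrying ``_POS``
suffixes (``moon_NN``).  Co-occurrences are counted with a flat +/-h token
window that never crosses a sentence boundary; designated bigram targets
("moon walk") are treated like a single word, taking their contexts from
beyond either end of the two member tokens.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from plauscomp.errors import EmptyCorpusError, InputError

Bigram = tuple[str, str]
RowTarget = "str | Bigram"


@dataclass
class TokenizedCorpus:
    """A lemmatized, sentence-segmented corpus held in memory.

    ``sentences`` is a list of token lists (lowercased lemmata); empty
    sentences are never stored, so ``token_count`` equals the sum of
    sentence lengths.
    """

    sentences: list[list[str]]
    token_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.sentences = [s for s in self.sentences if s]
        self.token_count = sum(len(s) for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)

    def unigram_counts(self) -> Counter:
        c: Counter = Counter()
        for sent in self.sentences:
            c.update(sent)
        return c

    def bigram_counts(self) -> Counter:
        """Counts of ordered adjacent token pairs within sentences."""
        c: Counter = Counter()
        for sent in self.sentences:
            for a, b in zip(sent, sent[1:]):
                c[(a, b)] += 1
        return c


def read_corpus(path: str | Path, dialect: str = "plain") -> TokenizedCorpus:
    """Read a one-sentence-per-line corpus file.

    ``dialect='lemma_pos'`` strips a trailing ``_POS`` suffix from every
    token before lowercasing; ``'plain'`` only lowercases.  Empty lines are
    skipped.
    """
    if dialect not in ("plain", "lemma_pos"):
        raise InputError(f"unknown corpus dialect: {dialect!r}")
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read corpus file {path}: {exc}") from exc
    sentences: list[list[str]] = []
    for line in text.splitlines():
        toks = line.split()
        if not toks:
            continue
        if dialect == "lemma_pos":
            toks = [t.rsplit("_", 1)[0] if "_" in t else t for t in toks]
        sentences.append([t.lower() for t in toks])
    if not sentences:
        raise EmptyCorpusError(f"no sentences found in {path}")
    return TokenizedCorpus(sentences)


@dataclass
class Vocabulary:
    """Row and column targets of the co-occurrence matrix.

    Rows hold single lemmata plus any designated bigram targets (observed
    phrase rows for composition training); columns are context lemmata only.
    """

    rows: list
    columns: list[str]
    row_index: dict = field(init=False)
    col_index: dict = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise InputError("duplicate row targets in vocabulary")
        if len(set(self.columns)) != len(self.columns):
            raise InputError("duplicate column lemmata in vocabulary")
        self.row_index = {t: i for i, t in enumerate(self.rows)}
        self.col_index = {t: i for i, t in enumerate(self.columns)}

    @property
    def bigram_rows(self) -> list[Bigram]:
        return [t for t in self.rows if isinstance(t, tuple)]


def build_vocabulary(
    corpus: TokenizedCorpus,
    n_content: int,
    extra_rows: list | None = None,
) -> Vocabulary:
    """Top-``n_content`` lemmata by frequency as rows and columns, plus extras.

    Frequency ties are broken alphabetically for reproducibility.
    ``extra_rows`` (lemmata or bigram tuples) are appended as additional
    rows in the order given, deduplicated against the frequency-selected
    rows; they never become columns.
    """
    if n_content < 1:
        raise InputError("n_content must be >= 1")
    freqs = corpus.unigram_counts()
    ordered = sorted(freqs, key=lambda w: (-freqs[w], w))
    if n_content > len(ordered):
        warnings.warn(
            f"n_content={n_content} exceeds {len(ordered)} distinct lemmata; using all",
            stacklevel=2,
        )
        n_content = len(ordered)
    top = ordered[:n_content]
    rows: list = list(top)
    seen = set(top)
    for target in extra_rows or []:
        if isinstance(target, list):
            target = tuple(target)
        if target not in seen:
            rows.append(target)
            seen.add(target)
    return Vocabulary(rows=rows, columns=list(top))


@dataclass
class CooccurrenceMatrix:
    """Raw windowed co-occurrence counts over a Vocabulary."""

    counts: sparse.csr_matrix
    vocab: Vocabulary
    half_window: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def count_cooccurrences(
    corpus: TokenizedCorpus, vocab: Vocabulary, half_window: int = 2
) -> CooccurrenceMatrix:
    """Count within-sentence co-occurrences with a flat +/-``half_window`` window.

    Every occurrence of a row target contributes one count per context token
    within ``half_window`` positions on either side, provided the context
    token is a column lemma.  Bigram targets are treated like a single word:
    the window extends ``half_window`` tokens left of the first member and
    right of the second, and the member tokens are not their own contexts.
    The member tokens still count as ordinary unigram targets wherever they
    are rows themselves.
    """
    if half_window < 1:
        raise InputError("half_window must be >= 1")
    ridx = vocab.row_index
    cidx = vocab.col_index
    bigrams = set(vocab.bigram_rows)
    h = half_window

    rows_acc: list[int] = []
    cols_acc: list[int] = []

    for sent in corpus.sentences:
        n = len(sent)
        r = [ridx.get(t, -1) for t in sent]
        c = [cidx.get(t, -1) for t in sent]
        # unigram targets
        for i in range(n):
            ri = r[i]
            if ri < 0:
                continue
            for j in range(max(0, i - h), min(n, i + h + 1)):
                if j == i:
                    continue
                cj = c[j]
                if cj >= 0:
                    rows_acc.append(ri)
                    cols_acc.append(cj)
        # bigram targets
        if bigrams:
            for i in range(n - 1):
                pair = (sent[i], sent[i + 1])
                if pair not in bigrams:
                    continue
                rb = ridx[pair]
                for j in range(max(0, i - h), i):
                    if c[j] >= 0:
                        rows_acc.append(rb)
                        cols_acc.append(c[j])
                for j in range(i + 2, min(n, i + 1 + h + 1)):
                    if c[j] >= 0:
                        rows_acc.append(rb)
                        cols_acc.append(c[j])

    shape = (len(vocab.rows), len(vocab.columns))
    if rows_acc:
        data = np.ones(len(rows_acc), dtype=np.int64)
        counts = sparse.coo_matrix(
            (data, (rows_acc, cols_acc)), shape=shape
        ).tocsr()
        counts.sum_duplicates()
    else:
        counts = sparse.csr_matrix(shape, dtype=np.int64)
    return CooccurrenceMatrix(counts=counts, vocab=vocab, half_window=half_window)
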
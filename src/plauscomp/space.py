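"""PPMI weighting, non-negative factorization and similarity queries.

The semantic space is the row-factor matrix of a rank-``d`` NMF of the
PPMI-weighted co-occurrence matrix: each vocabulary row (lemma or training
bigram) owns one non-negative ``d``-vector.  All similarity is cosine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

from plauscomp.corpus import (
    CooccurrenceMatrix,
    TokenizedCorpus,
    Vocabulary,
    build_vocabulary,
    count_cooccurrences,
)
from plauscomp.errors import (
    ConfigurationError,
    DegenerateInputError,
    UndefinedSimilarityError,
)


def ppmi(counts: "CooccurrenceMatrix | sparse.spmatrix | np.ndarray") -> sparse.csr_matrix:
    """Positive pointwise mutual information weighting of a count matrix.

    ``PPMI[i, j] = max(0, log p(i, j) - log(p(i) p(j)))`` with all three
    probabilities estimated from the same matrix (cell / total, row-sum /
    total, column-sum / total); natural logarithm.  Cells with zero count
    stay zero, so the result keeps the sparsity pattern.
    """
    if isinstance(counts, CooccurrenceMatrix):
        counts = counts.counts
    X = sparse.coo_matrix(counts, dtype=np.float64)
    total = X.sum()
    if total <= 0:
        raise DegenerateInputError("PPMI of an all-zero count matrix is undefined")
    row_sums = np.asarray(X.tocsr().sum(axis=1)).ravel()
    col_sums = np.asarray(X.tocsr().sum(axis=0)).ravel()
    # log(x * N / (rs * cs)); only defined on the nonzero cells
    with np.errstate(divide="ignore"):
        vals = np.log(X.data * total / (row_sums[X.row] * col_sums[X.col]))
    vals = np.maximum(vals, 0.0)
    out = sparse.coo_matrix((vals, (X.row, X.col)), shape=X.shape).tocsr()
    out.eliminate_zeros()
    return out


@dataclass
class SemanticSpace:
    """Reduced, non-negative vectors for every vocabulary row.

    ``vectors`` has shape ``(len(row_targets), d)``.  ``provenance`` records
    the weighting, reduction method, rank, seed and achieved reconstruction
    error so a space can be traced back to its construction.
    """

    vectors: np.ndarray
    row_targets: list
    provenance: dict = field(default_factory=dict)
    row_index: dict = field(init=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.row_index = {t: i for i, t in enumerate(self.row_targets)}
        self._unigram_rows = np.array(
            [i for i, t in enumerate(self.row_targets) if not isinstance(t, tuple)],
            dtype=np.intp,
        )

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, target) -> bool:
        return target in self.row_index

    def vector(self, target) -> np.ndarray:
        if target not in self.row_index:
            raise KeyError(f"no row for target {target!r}")
        return self.vectors[self.row_index[target]]

    def save(self, directory: str | Path) -> None:
        """Write vectors, row targets and provenance as plain-text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "vectors.tsv", self.vectors, delimiter="\t")
        with open(directory / "rows.tsv", "w", encoding="utf-8") as fh:
            for t in self.row_targets:
                fh.write(("\t".join(t) if isinstance(t, tuple) else t) + "\n")
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "SemanticSpace":
        directory = Path(directory)
        vectors = np.atleast_2d(np.loadtxt(directory / "vectors.tsv", delimiter="\t"))
        rows: list = []
        for line in (directory / "rows.tsv").read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            rows.append(tuple(parts) if len(parts) == 2 else parts[0])
        prov_file = directory / "provenance.json"
        provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {}
        return cls(vectors=vectors, row_targets=rows, provenance=provenance)


def reduce_dimensions(
    weighted: "sparse.spmatrix | np.ndarray",
    d: int,
    seed: int,
    row_targets: list | None = None,
    max_iter: int = 400,
    tol: float = 1e-4,
) -> SemanticSpace:
    """Rank-``d`` non-negative factorization ``W H ~ weighted``; returns ``W``.

    Seeded random initialization with a fixed iteration cap, so the result
    is reproducible under a fixed seed.
    """
    n_rows, n_cols = weighted.shape
    if d < 1 or d > min(n_rows, n_cols):
        raise ConfigurationError(
            f"d={d} not admissible for a {n_rows}x{n_cols} matrix"
        )
    model = NMF(
        n_components=d,
        init="random",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(weighted)
    provenance = {
        "weighting": "ppmi",
        "method": "nmf",
        "d": d,
        "seed": seed,
        "max_iter": max_iter,
        "tol": tol,
        "reconstruction_error": float(model.reconstruction_err_),
    }
    if row_targets is None:
        row_targets = list(range(n_rows))
    return SemanticSpace(vectors=W, row_targets=row_targets, provenance=provenance)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity ``dot(a, b) / (||a|| ||b||)``.

    Raises :class:`UndefinedSimilarityError` on a zero-norm input; the
    caller decides the fallback (items with undefined measures are flagged
    and excluded downstream).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def nearest_neighbours(
    space: SemanticSpace,
    v: np.ndarray,
    k: int,
    exclude: set | None = None,
) -> list:
    """The ``k`` single-lemma rows with highest cosine to ``v``, descending.

    Bigram training rows are never eligible.  Ties are broken by row order.
    Zero-norm rows get similarity 0.
    """
    exclude = exclude or set()
    eligible = np.array(
        [
            i
            for i in space._unigram_rows
            if space.row_targets[i] not in exclude
        ],
        dtype=np.intp,
    )
    if k < 1 or k > len(eligible):
        raise ConfigurationError(
            f"k={k} but only {len(eligible)} eligible rows after exclusion"
        )
    v = np.asarray(v, dtype=np.float64).ravel()
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise UndefinedSimilarityError("cannot query neighbours of a zero vector")
    V = space.vectors[eligible]
    norms = np.linalg.norm(V, axis=1)
    sims = np.zeros(len(eligible))
    nz = norms > 0
    sims[nz] = (V[nz] @ v) / (norms[nz] * nv)
    # stable: primary key descending similarity, secondary key row order
    order = np.lexsort((eligible, -sims))[:k]
    return [(space.row_targets[eligible[i]], float(sims[i])) for i in order]


class SemanticSpaceBuilder(BaseEstimator):
    """Corpus-to-space transformer: count, weight with PPMI, reduce with NMF.

    Parameters mirror the pipeline defaults: a +/-2 token window, the
    20,000 most frequent lemmata as rows/columns (scaled down for synthetic
    corpora) and a 300-dimensional reduction.

    Attributes (after :meth:`fit`)
    ------------------------------
    vocabulary_ : Vocabulary
    counts_ : CooccurrenceMatrix
    space_ : SemanticSpace
    """

    def __init__(
        self,
        n_content: int = 20000,
        half_window: int = 2,
        d: int = 300,
        seed: int = 0,
        extra_rows: list | None = None,
    ):
        self.n_content = n_content
        self.half_window = half_window
        self.d = d
        self.seed = seed
        self.extra_rows = extra_rows

    def fit(self, corpus: TokenizedCorpus, y=None) -> "SemanticSpaceBuilder":
        self.vocabulary_ = build_vocabulary(
            corpus, self.n_content, extra_rows=self.extra_rows
        )
        self.counts_ = count_cooccurrences(
            corpus, self.vocabulary_, half_window=self.half_window
        )
        weighted = ppmi(self.counts_)
        self.space_ = reduce_dimensions(
            weighted, d=self.d, seed=self.seed, row_targets=list(self.vocabulary_.rows)
        )
        self.space_.provenance.update(
            n_content=self.n_content,
            half_window=self.half_window,
            n_rows=len(self.vocabulary_.rows),
        )
        return self

    def transform(self, corpus: TokenizedCorpus) -> SemanticSpace:
        return self.space_

    def fit_transform(self, corpus: TokenizedCorpus, y=None) -> SemanticSpace:
        return self.fit(corpus).space_
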
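"""Compositional models for noun compounds.

A modifier *lexical function* is a ``d x (d+1)`` matrix (linear transform
plus intercept) mapping a head-noun vector to a compound vector, estimated
by ridge regression on observed phrase vectors; the *full additive* model
shares two ``d x d`` matrices ``A, B`` across all pairs (``c = A m + B h``).
Parameterless additive (``m + h``) and multiplicative (``m * h``) baselines
are included.  Training pairs are adjacent corpus bigrams headed by an item
modifier, filtered by pair frequency and per-modifier pair counts, with the
item pairs themselves withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from plauscomp.corpus import TokenizedCorpus
from plauscomp.errors import ConsistencyError, EstimationError, InputError
from plauscomp.space import SemanticSpace

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-6, 2, 17))


@dataclass
class TrainingPair:
    head: str
    phrase_vector: np.ndarray | None
    frequency: int


@dataclass
class TrainingSet:
    """Per-modifier training pairs surviving the frequency filters."""

    pairs: dict  # modifier -> list[TrainingPair]
    min_pair_freq: int
    min_pairs_per_modifier: int
    excluded_modifiers: list = field(default_factory=list)

    @property
    def modifiers(self) -> list[str]:
        return list(self.pairs)

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.pairs.values())


def candidate_bigrams(
    corpus: TokenizedCorpus,
    modifiers: set,
    item_pairs: set,
    min_pair_freq: int,
) -> dict:
    """Adjacent bigrams starting with a modifier, frequency-filtered,
    excluding the item pairs themselves.  Returns ``{(mod, head): freq}``."""
    counts = corpus.bigram_counts()
    return {
        pair: n
        for pair, n in counts.items()
        if pair[0] in modifiers and n >= min_pair_freq and pair not in item_pairs
    }


def extract_training_pairs(
    corpus: TokenizedCorpus,
    modifiers: set,
    item_pairs: set,
    min_pair_freq: int = 20,
    min_pairs_per_modifier: int = 50,
    space: SemanticSpace | None = None,
) -> TrainingSet:
    """Build the per-modifier training sets under the standard filters.

    Candidate pairs are adjacent token bigrams whose first token is a
    modifier; pairs below ``min_pair_freq`` corpus occurrences and pairs in
    the item set are dropped, and modifiers with fewer than
    ``min_pairs_per_modifier`` surviving distinct pairs are removed
    entirely.  If ``space`` is given, each retained pair's observed phrase
    vector is looked up from its bigram row (missing row -> consistency
    error: the space must have been built with these rows).
    """
    if min_pair_freq < 1 or min_pairs_per_modifier < 1:
        raise InputError("filter thresholds must be >= 1")
    if not corpus.sentences:
        raise InputError("empty corpus")
    surviving = candidate_bigrams(corpus, modifiers, item_pairs, min_pair_freq)

    by_modifier: dict = {}
    for (mod, head), freq in sorted(surviving.items()):
        by_modifier.setdefault(mod, []).append((head, freq))

    pairs: dict = {}
    excluded: list = []
    for mod in sorted(modifiers):
        entries = by_modifier.get(mod, [])
        if len(entries) < min_pairs_per_modifier:
            excluded.append(mod)
            continue
        plist = []
        for head, freq in entries:
            vec = None
            if space is not None:
                if (mod, head) not in space:
                    raise ConsistencyError(
                        f"no bigram row for training pair {(mod, head)!r}; "
                        "build the space with these rows"
                    )
                vec = space.vector((mod, head))
            plist.append(TrainingPair(head=head, phrase_vector=vec, frequency=freq))
        pairs[mod] = plist
    return TrainingSet(
        pairs=pairs,
        min_pair_freq=min_pair_freq,
        min_pairs_per_modifier=min_pairs_per_modifier,
        excluded_modifiers=excluded,
    )


def _ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form multi-output ridge: argmin ||Y - X C||_F^2 + lam ||C||_F^2."""
    p = X.shape[1]
    A = X.T @ X + lam * np.eye(p)
    return np.linalg.solve(A, X.T @ Y)


def _gcv_lambda(X: np.ndarray, Y: np.ndarray, grid=DEFAULT_LAMBDA_GRID) -> float:
    """Generalized cross-validation over a log grid of ridge penalties."""
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Z = U.T @ Y
    ssy = float(np.sum(Y**2))
    ssz = float(np.sum(Z**2))
    best_lam, best_score = grid[0], np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        edf = float(np.sum(shrink))
        resid = float(np.sum(((1.0 - shrink)[:, None] ** 2) * Z**2)) + (ssy - ssz)
        denom = max(n - edf, 1e-8)
        score = n * resid / denom**2
        if score < best_score:
            best_lam, best_score = lam, score
    return best_lam


class LexicalFunctionRegressor(BaseEstimator):
    """Ridge-estimated lexical function for one modifier.

    ``fit(H, P)`` takes head vectors ``H`` (n_pairs, d) and observed phrase
    vectors ``P`` (n_pairs, d) and estimates the ``d x (d+1)`` matrix
    (transform + intercept column) minimizing the penalized squared
    Euclidean distance between observed and composed vectors.

    Parameters
    ----------
    alpha : float or "gcv"
        Ridge penalty; ``"gcv"`` selects it per fit by generalized
        cross-validation over a small log grid.
    fit_intercept : bool
        Include the intercept column (the standard configuration).
    """

    def __init__(self, alpha="gcv", fit_intercept: bool = True):
        self.alpha = alpha
        self.fit_intercept = fit_intercept

    def fit(self, H: np.ndarray, P: np.ndarray) -> "LexicalFunctionRegressor":
        H = np.atleast_2d(np.asarray(H, dtype=np.float64))
        P = np.atleast_2d(np.asarray(P, dtype=np.float64))
        if H.shape[0] == 0:
            raise EstimationError("no training pairs")
        if H.shape != P.shape:
            raise ConsistencyError(
                f"head/phrase dimension mismatch: {H.shape} vs {P.shape}"
            )
        d = H.shape[1]
        X = np.hstack([H, np.ones((H.shape[0], 1))]) if self.fit_intercept else H
        lam = _gcv_lambda(X, P) if self.alpha == "gcv" else float(self.alpha)
        C = _ridge_solve(X, P, lam)  # (d+1, d)
        self.coef_ = C.T  # d x (d+1): [transform | intercept]
        self.alpha_ = lam
        self.n_pairs_ = H.shape[0]
        resid = P - X @ C
        self.residual_norm_ = float(np.linalg.norm(resid))
        self.d_ = d
        return self

    @property
    def matrix_(self) -> np.ndarray:
        return self.coef_

    def predict(self, H: np.ndarray) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=np.float64))
        if self.fit_intercept:
            return H @ self.coef_[:, :-1].T + self.coef_[:, -1]
        return H @ self.coef_.T

    def compose(self, h: np.ndarray) -> np.ndarray:
        return self.predict(h[None, :])[0]


class FullAdditiveRegressor(BaseEstimator):
    """Shared full-additive composition ``c = A m + B h``.

    ``fit(M, H, P)`` estimates the two ``d x d`` matrices jointly by ridge
    on the stacked ``[m; h]`` design (no intercept).
    """

    def __init__(self, alpha="gcv"):
        self.alpha = alpha

    def fit(self, M: np.ndarray, H: np.ndarray, P: np.ndarray) -> "FullAdditiveRegressor":
        M = np.atleast_2d(np.asarray(M, dtype=np.float64))
        H = np.atleast_2d(np.asarray(H, dtype=np.float64))
        P = np.atleast_2d(np.asarray(P, dtype=np.float64))
        if M.shape[0] == 0:
            raise EstimationError("no training pairs")
        if not (M.shape == H.shape == P.shape):
            raise ConsistencyError("modifier/head/phrase shapes must agree")
        d = M.shape[1]
        X = np.hstack([M, H])
        lam = _gcv_lambda(X, P) if self.alpha == "gcv" else float(self.alpha)
        C = _ridge_solve(X, P, lam)  # (2d, d)
        self.A_ = C[:d].T
        self.B_ = C[d:].T
        self.alpha_ = lam
        self.n_pairs_ = M.shape[0]
        self.residual_norm_ = float(np.linalg.norm(P - X @ C))
        self.d_ = d
        return self

    def compose(self, m: np.ndarray, h: np.ndarray) -> np.ndarray:
        return self.A_ @ m + self.B_ @ h


def fit_lexical_function(pairs, lam: float | str = "gcv") -> LexicalFunctionRegressor:
    """Fit one modifier's lexical function from ``(head_vector, phrase_vector)`` pairs."""
    if not pairs:
        raise EstimationError("no training pairs")
    H = np.vstack([np.asarray(h, dtype=np.float64) for h, _ in pairs])
    P = np.vstack([np.asarray(p, dtype=np.float64) for _, p in pairs])
    return LexicalFunctionRegressor(alpha=lam).fit(H, P)


def fit_full_additive(pairs, lam: float | str = "gcv") -> FullAdditiveRegressor:
    """Fit the shared (A, B) pair from ``(m, h, p)`` vector triples."""
    if not pairs:
        raise EstimationError("no training pairs")
    M = np.vstack([np.asarray(m, dtype=np.float64) for m, _, _ in pairs])
    H = np.vstack([np.asarray(h, dtype=np.float64) for _, h, _ in pairs])
    P = np.vstack([np.asarray(p, dtype=np.float64) for _, _, p in pairs])
    return FullAdditiveRegressor(alpha=lam).fit(M, H, P)


class UncomposableItem(Exception):
    """Signal that an item cannot be composed (e.g. untrained modifier);
    the item is excluded downstream rather than failing the run."""


@dataclass
class CompositionModel:
    """Tagged union over the four composition methods.

    ``method`` is one of ``additive``, ``multiplicative``, ``full_additive``
    or ``lexical_function``; the trained methods carry their parameters
    (``full_additive_model`` or the per-modifier ``lexical_functions`` map).
    """

    method: str
    lexical_functions: dict | None = None  # modifier -> LexicalFunctionRegressor
    full_additive_model: FullAdditiveRegressor | None = None

    def __post_init__(self) -> None:
        if self.method not in (
            "additive",
            "multiplicative",
            "full_additive",
            "lexical_function",
        ):
            raise InputError(f"unknown composition method {self.method!r}")
        if self.method == "lexical_function" and self.lexical_functions is None:
            raise InputError("lexical_function model requires fitted functions")
        if self.method == "full_additive" and self.full_additive_model is None:
            raise InputError("full_additive model requires fitted (A, B)")

    @classmethod
    def train_lexical_functions(
        cls, training: TrainingSet, space: SemanticSpace, alpha="gcv"
    ) -> "CompositionModel":
        """One ridge fit per retained modifier, heads looked up in the space."""
        functions: dict = {}
        for mod, plist in training.pairs.items():
            pairs = [
                (space.vector(tp.head), tp.phrase_vector)
                for tp in plist
                if tp.head in space and tp.phrase_vector is not None
            ]
            if pairs:
                functions[mod] = fit_lexical_function(pairs, lam=alpha)
        return cls(method="lexical_function", lexical_functions=functions)

    @classmethod
    def train_full_additive(
        cls, training: TrainingSet, space: SemanticSpace, alpha="gcv"
    ) -> "CompositionModel":
        triples = []
        for mod, plist in training.pairs.items():
            if mod not in space:
                continue
            m = space.vector(mod)
            for tp in plist:
                if tp.head in space and tp.phrase_vector is not None:
                    triples.append((m, space.vector(tp.head), tp.phrase_vector))
        model = fit_full_additive(triples, lam=alpha)
        return cls(method="full_additive", full_additive_model=model)


def _save_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(M), delimiter="\t")


def save_composition_model(model: CompositionModel, directory) -> None:
    """Serialize a trained composition model as TSV matrices + a manifest."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"method": model.method}
    if model.method == "lexical_function":
        manifest["modifiers"] = sorted(model.lexical_functions)
        manifest["alphas"] = {
            m: fn.alpha_ for m, fn in model.lexical_functions.items()
        }
        manifest["d"] = next(
            iter(model.lexical_functions.values())
        ).d_ if model.lexical_functions else None
        for i, m in enumerate(manifest["modifiers"]):
            _save_matrix(directory / f"lexfun_{i:04d}.tsv",
                         model.lexical_functions[m].coef_)
    elif model.method == "full_additive":
        fam = model.full_additive_model
        manifest["d"] = fam.d_
        manifest["alpha"] = fam.alpha_
        _save_matrix(directory / "A.tsv", fam.A_)
        _save_matrix(directory / "B.tsv", fam.B_)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_composition_model(directory) -> CompositionModel:
    """Inverse of :func:`save_composition_model`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    method = manifest["method"]
    if method == "lexical_function":
        functions: dict = {}
        for i, m in enumerate(manifest["modifiers"]):
            fn = LexicalFunctionRegressor()
            fn.coef_ = np.atleast_2d(
                np.loadtxt(directory / f"lexfun_{i:04d}.tsv", delimiter="\t")
            )
            fn.fit_intercept = True
            fn.alpha_ = manifest["alphas"][m]
            fn.d_ = fn.coef_.shape[0]
            functions[m] = fn
        return CompositionModel(method=method, lexical_functions=functions)
    if method == "full_additive":
        fam = FullAdditiveRegressor()
        fam.A_ = np.atleast_2d(np.loadtxt(directory / "A.tsv", delimiter="\t"))
        fam.B_ = np.atleast_2d(np.loadtxt(directory / "B.tsv", delimiter="\t"))
        fam.alpha_ = manifest["alpha"]
        fam.d_ = fam.A_.shape[0]
        return CompositionModel(method=method, full_additive_model=fam)
    return CompositionModel(method=method)


def compose(
    model: CompositionModel, modifier: str, head: str, space: SemanticSpace
) -> np.ndarray:
    """Compound vector for (modifier, head) under the given model.

    Raises :class:`UncomposableItem` when the lexical-function model has no
    fitted matrix for the modifier (mirroring the removal of data-poor
    modifiers from the item analysis), or when a needed word vector is
    missing.  Trained methods may return vectors with negative entries;
    they are retained, and the entropy measure clips them with a warning.
    """
    if head not in space:
        raise UncomposableItem(f"no vector for head {head!r}")
    h = space.vector(head)
    if model.method == "lexical_function":
        fn = model.lexical_functions.get(modifier)
        if fn is None:
            raise UncomposableItem(f"no lexical function trained for {modifier!r}")
        return fn.compose(h)
    if modifier not in space:
        raise UncomposableItem(f"no vector for modifier {modifier!r}")
    m = space.vector(modifier)
    if model.method == "additive":
        return m + h
    if model.method == "multiplicative":
        return m * h
    return model.full_additive_model.compose(m, h)
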
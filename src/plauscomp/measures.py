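"""Plausibility measures and lexical covariates for compound items.

Five measures are computed from the semantic space and the composed
compound vector ``c``: head proximity ``cos(c, h)``, modifier proximity
``cos(c, m)``, constituent similarity ``cos(m, h)``, neighbourhood density
(mean cosine to the k = 20 nearest single-lemma neighbours) and vector
entropy.  Covariates are letter lengths, Laplace-transformed log
frequencies (modifier, head, pair in both orders), PMI between the
constituents, and positional family sizes.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plauscomp.composition import CompositionModel, UncomposableItem, compose
from plauscomp.corpus import TokenizedCorpus
from plauscomp.errors import InputError, UndefinedSimilarityError
from plauscomp.space import SemanticSpace, cosine, nearest_neighbours

MEASURE_COLUMNS = [
    "head_proximity",
    "modifier_proximity",
    "constituent_similarity",
    "neighbourhood_density",
    "entropy",
]

COVARIATE_COLUMNS = [
    "modifier_length",
    "head_length",
    "log_pair_freq",
    "log_reversed_pair_freq",
    "log_modifier_freq",
    "log_head_freq",
    "pmi",
    "modifier_family_size",
    "head_family_size",
]


@dataclass
class FrequencyTable:
    """Unigram and ordered-bigram counts (corpus-derived or external)."""

    unigrams: Counter
    bigrams: Counter  # ordered (first, second) lemma pairs
    source: str = "corpus"
    total_unigrams: int = field(init=False)
    total_bigrams: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_unigrams = int(sum(self.unigrams.values()))
        self.total_bigrams = int(sum(self.bigrams.values()))

    @classmethod
    def from_corpus(cls, corpus: TokenizedCorpus, source: str = "corpus") -> "FrequencyTable":
        return cls(
            unigrams=corpus.unigram_counts(),
            bigrams=corpus.bigram_counts(),
            source=source,
        )

    def family_size(self, word: str, position: str) -> int:
        """Distinct bigram types with ``word`` in the given position
        (``'modifier'`` = first, ``'head'`` = second)."""
        idx = 0 if position == "modifier" else 1
        return sum(1 for pair in self.bigrams if pair[idx] == word)


def transparency_measures(
    composed: np.ndarray, m: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """(head proximity, modifier proximity, constituent similarity).

    All three are cosines; a zero-norm vector raises
    :class:`UndefinedSimilarityError` so the caller can flag the item.
    """
    return cosine(composed, h), cosine(composed, m), cosine(m, h)


def neighbourhood_density(space: SemanticSpace, v: np.ndarray, k: int = 20) -> float:
    """Mean cosine between ``v`` and its ``k`` nearest single-lemma rows."""
    neigh = nearest_neighbours(space, v, k)
    return float(np.mean([s for _, s in neigh]))


def vector_entropy(v: np.ndarray) -> float:
    """Uniformity of a vector's dimension values.

    The vector is clipped at zero (with a warning when negative entries are
    present), normalized to sum one, and scored as
    ``log(n) - (1/n) * sum(p_i log p_i)`` with ``0 log 0 := 0`` and natural
    logarithm.  High values indicate a near-uniform profile.  Raises
    :class:`InputError` when no positive entry remains.
    """
    v = np.asarray(v, dtype=np.float64).ravel()
    n = v.size
    if n < 2:
        raise InputError("entropy needs at least 2 dimensions")
    if np.any(v < 0):
        warnings.warn("negative entries clipped to 0 for entropy", stacklevel=2)
        v = np.clip(v, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise InputError("entropy undefined: no positive entries")
    p = v / total
    nz = p > 0
    return float(math.log(n) - np.sum(p[nz] * np.log(p[nz])) / n)


def covariates(
    modifier: str,
    head: str,
    freqs: FrequencyTable,
) -> dict:
    """Lexical covariates for one (modifier, head) item.

    Log frequencies use the Laplace transform ``log(count + 1)``; PMI uses
    add-one counts for the pair and the unigrams against the raw totals, so
    unattested pairs are defined.  Family sizes are distinct bigram types
    with the word in the respective position.
    """
    f_mod = freqs.unigrams.get(modifier, 0)
    f_head = freqs.unigrams.get(head, 0)
    f_pair = freqs.bigrams.get((modifier, head), 0)
    f_rev = freqs.bigrams.get((head, modifier), 0)
    n_uni = max(freqs.total_unigrams, 1)
    n_bi = max(freqs.total_bigrams, 1)
    pmi = (
        math.log((f_pair + 1) / n_bi)
        - math.log((f_mod + 1) / n_uni)
        - math.log((f_head + 1) / n_uni)
    )
    return {
        "modifier_length": len(modifier),
        "head_length": len(head),
        "log_pair_freq": math.log(f_pair + 1),
        "log_reversed_pair_freq": math.log(f_rev + 1),
        "log_modifier_freq": math.log(f_mod + 1),
        "log_head_freq": math.log(f_head + 1),
        "pmi": pmi,
        "modifier_family_size": freqs.family_size(modifier, "modifier"),
        "head_family_size": freqs.family_size(head, "head"),
    }


def assemble_table(
    items: pd.DataFrame,
    space: SemanticSpace,
    model: CompositionModel,
    freqs: FrequencyTable,
    k: int = 20,
) -> pd.DataFrame:
    """One row per item with all measures and covariates.

    ``items`` needs columns ``modifier``, ``head``, ``rating`` and
    optionally ``attested``.  Items whose modifier has no trained lexical
    function (or with an undefined measure) are kept in the table with
    ``excluded=True`` and an ``exclusion_reason``; complete rows have
    ``excluded=False``.
    """
    required = {"modifier", "head", "rating"}
    missing = required - set(items.columns)
    if missing:
        raise InputError(f"item table lacks columns: {sorted(missing)}")

    records = []
    for _, item in items.iterrows():
        mod, head = str(item["modifier"]), str(item["head"])
        rec: dict = {
            "modifier": mod,
            "head": head,
            "rating": float(item["rating"]),
            "excluded": False,
            "exclusion_reason": "",
        }
        if "attested" in items.columns:
            rec["attested"] = bool(item["attested"])
        try:
            c = compose(model, mod, head, space)
            m = space.vector(mod)
            h = space.vector(head)
            hp, mp, cs = transparency_measures(c, m, h)
            rec.update(
                head_proximity=hp,
                modifier_proximity=mp,
                constituent_similarity=cs,
                neighbourhood_density=neighbourhood_density(space, c, k=k),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec["entropy"] = vector_entropy(c)
            rec["has_negative_dims"] = bool(np.any(c < 0))
        except (UncomposableItem, UndefinedSimilarityError, KeyError, InputError) as exc:
            rec["excluded"] = True
            rec["exclusion_reason"] = f"{type(exc).__name__}: {exc}"
            for col in MEASURE_COLUMNS:
                rec[col] = np.nan
            rec["has_negative_dims"] = False
        rec.update(covariates(mod, head, freqs))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def read_item_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited item table (modifier, head, rating[, attested])."""
    try:
        df = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise InputError(f"cannot read item table {path}: {exc}") from exc
    missing = {"modifier", "head", "rating"} - set(df.columns)
    if missing:
        raise InputError(f"item table lacks columns: {sorted(missing)}")
    return df
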
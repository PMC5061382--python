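"""Synthetic corpora and rating tables with known ground truth.

The corpus generator emulates the statistical structure the pipeline
expects from real text: words carry latent topic mixtures, sentences are
sampled from per-topic word distributions (so windowed co-occurrence
reflects topic proximity), and designated modifier lemmata transform the
topic mixture of their head noun by a planted linear map whenever a
"modifier head" compound is emitted — the surrounding context words are
drawn from the transformed mixture, so observed phrase vectors approximate
the planted map.  A ledger records every unigram and adjacent-bigram count
at emission time, together with the planted transforms and designated item
pairs, so downstream filters and fits can be checked against ground truth.

The ratings generator places a known smooth surface (plus per-modifier and
per-head random intercepts and Gaussian noise) over a table of measure
columns, clamped to the 0-4 rating scale.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plauscomp.corpus import TokenizedCorpus
from plauscomp.errors import ConfigurationError, InputError
from plauscomp.measures import MEASURE_COLUMNS


# --------------------------------------------------------------------------
# corpus generation
# --------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Parameters of the topic-mixture corpus generator.

    The defaults are sized so the whole pipeline (space + composition +
    analysis) runs in minutes on one CPU while still leaving two modifiers
    with enough distinct, frequent training pairs to survive the standard
    >= 20 occurrences / >= 50 distinct-pairs filters.  The item set mixes
    attested pairs, their reversals and never-emitted novel pairs, several
    hundred items in total, echoing the structure of rating studies that
    pair attested compounds with unattested counterparts.
    """

    vocab_size: int = 500
    n_topics: int = 8
    n_sentences: int = 30000
    sentence_len_mean: float = 10.0
    sentence_len_min: int = 4
    n_modifiers: int = 6
    head_pool_sizes: tuple = (75, 75, 20, 20, 10, 10)
    modifier_weights: tuple = (0.46, 0.46, 0.03, 0.03, 0.01, 0.01)
    compound_rate: float = 0.15
    item_attested_per_modifier: int = 18
    item_novel_per_modifier: int = 400
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.compound_rate < 1.0:
            raise ConfigurationError("compound_rate must be in [0, 1)")
        if self.compound_rate > 0 and self.n_modifiers < 1:
            raise ConfigurationError("compound emission requires modifiers")
        if len(self.head_pool_sizes) != self.n_modifiers:
            raise ConfigurationError("one head pool size per modifier required")
        if len(self.modifier_weights) != self.n_modifiers:
            raise ConfigurationError("one weight per modifier required")
        # items are drawn from the pools of the highest-weight modifiers
        if self.n_modifiers:
            top = max(self.modifier_weights)
            strong_pools = [
                s for s, w in zip(self.head_pool_sizes, self.modifier_weights)
                if w == top
            ]
            if self.item_attested_per_modifier >= min(strong_pools):
                raise ConfigurationError("item pairs would exhaust a head pool")


@dataclass
class GroundTruthLedger:
    """Everything the generator knows: counts, transforms, designations."""

    config: CorpusConfig
    words: list
    modifiers: list
    head_pools: dict  # modifier -> list of head lemmata (emission pool)
    item_pairs: set  # ordered (first, second) pairs designated as items
    item_records: list  # dicts: modifier, head, attested
    transforms: dict  # modifier -> (W [T x T], b [T])
    topic_word: np.ndarray  # phi, (T, V)
    word_topic: np.ndarray  # theta = P(topic | word), (V, T)
    unigrams: Counter = field(default_factory=Counter)
    bigrams: Counter = field(default_factory=Counter)
    compound_emissions: Counter = field(default_factory=Counter)
    n_sentences: int = 0

    def surviving_training_pairs(self, min_pair_freq: int,
                                 min_pairs_per_modifier: int,
                                 modifiers: set | None = None) -> dict:
        """The generator's own computation of the training-pair filters,
        straight from the recorded bigram counts: ``{modifier: {head: freq}}``.

        By default the modifier set is every first constituent of the item
        records (matching the convention that first nouns of reversed items
        are modifiers too); pass ``modifiers`` to restrict it.
        """
        if modifiers is None:
            modifiers = {r["modifier"] for r in self.item_records}
        mods = set(modifiers)
        candidates: dict = {}
        for (a, b), n in self.bigrams.items():
            if a in mods and n >= min_pair_freq and (a, b) not in self.item_pairs:
                candidates.setdefault(a, {})[b] = n
        return {
            m: heads
            for m, heads in candidates.items()
            if len(heads) >= min_pairs_per_modifier
        }


def _make_lemmata(rng: np.random.Generator, n: int) -> list:
    """Unique lowercase pseudo-lemmata with varying letter lengths."""
    letters = np.array(list(string.ascii_lowercase))
    out: list = []
    seen: set = set()
    while len(out) < n:
        length = int(rng.integers(3, 10))
        w = "".join(rng.choice(letters, size=length))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


def generate_corpus(config: CorpusConfig) -> tuple:
    """Sample a corpus from the configured topic mixture; returns
    ``(TokenizedCorpus, GroundTruthLedger)``.  Fully seeded: the same
    config yields a byte-identical corpus."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    V, T = config.vocab_size, config.n_topics

    words = _make_lemmata(rng, V + config.n_modifiers)
    vocab, modifiers = words[:V], words[V:]

    # topic structure
    topic_word = rng.dirichlet(np.full(V, 0.08), size=T)  # phi: (T, V)
    topic_weights = rng.dirichlet(np.full(T, 2.0))
    joint = topic_word * topic_weights[:, None]  # P(t, w)
    word_topic = (joint / joint.sum(axis=0, keepdims=True)).T  # theta: (V, T)
    word_index = {w: i for i, w in enumerate(vocab)}
    cdfs = np.cumsum(topic_word, axis=1)

    # planted modifier transforms and head pools
    head_pools: dict = {}
    transforms: dict = {}
    for m_i, mod in enumerate(modifiers):
        pool = [str(w) for w in rng.choice(vocab, size=config.head_pool_sizes[m_i],
                                           replace=False)]
        head_pools[mod] = pool
        W = rng.dirichlet(np.full(T, 0.5), size=T).T  # column-stochastic (T, T)
        b = 0.05 * rng.dirichlet(np.full(T, 1.0))
        transforms[mod] = (W, b)

    # designated item pairs: attested (emitted) + their reversals + novels
    item_pairs: set = set()
    item_records: list = []
    strong = [i for i, w in enumerate(config.modifier_weights)
              if w == max(config.modifier_weights)] or list(range(config.n_modifiers))
    for m_i in strong:
        mod = modifiers[m_i]
        pool = head_pools[mod]
        attested = [str(w) for w in rng.choice(
            pool, size=config.item_attested_per_modifier, replace=False)]
        outside = [w for w in vocab if w not in pool]
        novel = [str(w) for w in rng.choice(
            outside, size=config.item_novel_per_modifier, replace=False)]
        for h in attested:
            item_pairs.add((mod, h))
            item_pairs.add((h, mod))
            item_records.append({"modifier": mod, "head": h, "attested": True})
            item_records.append({"modifier": h, "head": mod, "attested": False})
        for h in novel:
            item_pairs.add((mod, h))
            item_records.append({"modifier": mod, "head": h, "attested": False})

    ledger = GroundTruthLedger(
        config=config, words=vocab, modifiers=modifiers, head_pools=head_pools,
        item_pairs=item_pairs, item_records=item_records, transforms=transforms,
        topic_word=topic_word, word_topic=word_topic,
    )

    mod_weights = np.asarray(config.modifier_weights, dtype=np.float64)
    mod_weights = mod_weights / mod_weights.sum() if mod_weights.sum() else mod_weights

    sentences: list = []
    for _ in range(config.n_sentences):
        L = config.sentence_len_min + int(
            rng.poisson(config.sentence_len_mean - config.sentence_len_min)
        )
        if config.compound_rate > 0 and rng.random() < config.compound_rate:
            m_i = int(rng.choice(config.n_modifiers, p=mod_weights))
            mod = modifiers[m_i]
            head = str(rng.choice(head_pools[mod]))
            W, b = transforms[mod]
            mix = W @ word_topic[word_index[head]] + b
            mix = mix / mix.sum()
            topics = rng.choice(T, size=L, p=mix)
            u = rng.random(L)
            toks = [vocab[int(np.searchsorted(cdfs[t], x))]
                    for t, x in zip(topics, u)]
            pos = int(rng.integers(0, L + 1))
            sent = toks[:pos] + [mod, head] + toks[pos:]
            ledger.compound_emissions[(mod, head)] += 1
        else:
            t = int(rng.choice(T, p=topic_weights))
            u = rng.random(L)
            sent = [vocab[int(np.searchsorted(cdfs[t], x))] for x in u]
        sentences.append(sent)
        ledger.unigrams.update(sent)
        for a, b2 in zip(sent, sent[1:]):
            ledger.bigrams[(a, b2)] += 1
        ledger.n_sentences += 1

    return TokenizedCorpus(sentences), ledger


def write_corpus(corpus: TokenizedCorpus, path) -> None:
    """One sentence per line, whitespace-joined (the pipeline's input format)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus.sentences:
            fh.write(" ".join(sent) + "\n")


# --------------------------------------------------------------------------
# rating generation
# --------------------------------------------------------------------------

def _quantile_scale(x: np.ndarray) -> np.ndarray:
    """Empirical quantile transform to (0, 1).

    Surface presets are defined on quantile scales so the planted effect
    always lives where the measure values actually fall — semantic spaces
    of different sizes put, say, modifier proximity on very different raw
    ranges, and a surface peaked outside the observed range would plant no
    recoverable signal at all.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=np.float64)
    return rankdata(x) / (len(x) + 1.0)


def _surface_hp_mp_ridge(df: pd.DataFrame) -> np.ndarray:
    """Saturating ridge in head proximity, peaked in modifier proximity —
    a genuinely non-additive, non-bilinear interaction surface."""
    hp = _quantile_scale(df["head_proximity"].to_numpy())
    mp = _quantile_scale(df["modifier_proximity"].to_numpy())
    return 2.0 / (1.0 + np.exp(-6.0 * (hp - 0.4))) * np.exp(
        -((mp - 0.55) ** 2) / (2 * 0.15**2)
    )


def _surface_linear_hp(df: pd.DataFrame) -> np.ndarray:
    return 1.2 * df["head_proximity"].to_numpy(dtype=np.float64)


def _surface_null(df: pd.DataFrame) -> np.ndarray:
    return np.zeros(len(df))


SURFACES = {
    "hp_mp_ridge": _surface_hp_mp_ridge,
    "linear_hp": _surface_linear_hp,
    "null": _surface_null,
}


@dataclass
class RatingsConfig:
    """Parameters of the rating generator.

    The surface is a named preset (or any callable on the measure table);
    per-modifier and per-head random intercepts and residual noise are
    Gaussian, and ratings are clamped to the 0-4 scale used for human
    plausibility judgements.
    """

    surface: str = "hp_mp_ridge"
    intercept: float = 1.0
    re_sd_modifier: float = 0.2
    re_sd_head: float = 0.2
    noise_sd: float = 0.35
    scale: tuple = (0.0, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if callable(self.surface):
            return
        if self.surface not in SURFACES:
            raise ConfigurationError(f"unknown surface preset {self.surface!r}")


def generate_ratings(config: RatingsConfig, measure_table: pd.DataFrame) -> tuple:
    """Add a ``rating`` column to a measure table; returns ``(table, truth)``.

    ``rating = clamp(intercept + surface(measures) + b_modifier + b_head +
    noise, scale)`` with intercepts drawn once per factor level.  ``truth``
    stores the surface values and every random draw.
    """
    config.validate()
    needed = set(MEASURE_COLUMNS) | {"log_pair_freq", "modifier", "head"}
    missing = needed - set(measure_table.columns)
    if missing:
        raise InputError(f"measure table lacks columns: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    surface_fn = config.surface if callable(config.surface) else SURFACES[config.surface]
    df = measure_table.copy().reset_index(drop=True)
    surf = np.asarray(surface_fn(df), dtype=np.float64)

    mod_levels = sorted(df["modifier"].astype(str).unique())
    head_levels = sorted(df["head"].astype(str).unique())
    b_mod = dict(zip(mod_levels,
                     rng.normal(0.0, config.re_sd_modifier, len(mod_levels))))
    b_head = dict(zip(head_levels,
                      rng.normal(0.0, config.re_sd_head, len(head_levels))))
    noise = rng.normal(0.0, config.noise_sd, len(df))
    raw = (
        config.intercept
        + surf
        + df["modifier"].astype(str).map(b_mod).to_numpy()
        + df["head"].astype(str).map(b_head).to_numpy()
        + noise
    )
    df["rating"] = np.clip(raw, *config.scale)
    truth = {
        "surface_name": getattr(config.surface, "__name__", config.surface),
        "surface_values": surf,
        "modifier_intercepts": b_mod,
        "head_intercepts": b_head,
        "noise": noise,
        "config": config,
    }
    return df, truth


def generate_measure_table(
    n_items: int,
    n_modifiers: int = 30,
    n_heads: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """A standalone table of plausible measure and covariate columns, for
    exercising the model-selection stage without building a space.

    Measures are drawn independently on their natural ranges (proximities
    and similarity as Beta variates on [0, 1], density concentrated below
    one, entropy near its ceiling for a 300-dimensional vector); pair
    frequency is a zero-inflated positive variable mimicking attested
    versus reversed/novel items.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "modifier": [f"m{rng.integers(n_modifiers):03d}" for _ in range(n_items)],
            "head": [f"h{rng.integers(n_heads):03d}" for _ in range(n_items)],
            "head_proximity": rng.beta(2.0, 2.0, n_items),
            "modifier_proximity": rng.beta(2.0, 2.0, n_items),
            "constituent_similarity": rng.beta(2.0, 3.0, n_items),
            "neighbourhood_density": 0.8 * rng.beta(5.0, 3.0, n_items),
            "entropy": rng.uniform(5.0, 5.7, n_items),
        }
    )
    attested = rng.random(n_items) < 0.5
    df["log_pair_freq"] = np.where(attested, rng.exponential(1.5, n_items), 0.0)
    df["excluded"] = False
    return df
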
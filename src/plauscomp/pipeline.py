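"""End-to-end orchestration: corpus -> space -> composition -> measures ->
additive-model analysis, with per-stage provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plauscomp import composition, gam, measures, synthetic
from plauscomp.corpus import TokenizedCorpus, read_corpus
from plauscomp.errors import InputError
from plauscomp.measures import FrequencyTable, assemble_table, read_item_table
from plauscomp.space import SemanticSpaceBuilder

BASELINE_CANDIDATES = [
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
class PipelineConfig:
    """One configuration object for the whole pipeline.

    The defaults are the standard settings of the analysis: a +/-2 token
    window, 300 reduced dimensions, >= 20 pair occurrences and >= 50
    distinct pairs per modifier for composition training, k = 20 density
    neighbours and alpha = .05 — so a run on real inputs only needs paths.
    The synthetic preset swaps in the generator and a scale (reduced rank,
    smaller vocabulary) sized to its 500-lemma corpus.
    """

    corpus_path: str | None = None
    items_path: str | None = None
    out_dir: str = "plauscomp_out"
    dialect: str = "plain"
    n_content: int = 20000
    half_window: int = 2
    dims: int = 300
    seed: int = 0
    method: str = "lexical_function"
    min_pair_freq: int = 20
    min_pairs_per_modifier: int = 50
    ridge_policy: str = "gcv"
    k: int = 20
    alpha: float = 0.05
    synthetic: bool = False
    synthetic_dims: int = 50
    synthetic_n_content: int = 520

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_fingerprint(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes artefacts under ``config.out_dir`` and
    returns a result dict (paths, final model, traces).

    Re-running with an identical config and inputs reproduces identical
    outputs; every stage is logged with its parameters and input
    fingerprints.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config),
                 "config_hash": config.config_hash(), "stages": []}

    def stage(name: str, **info) -> None:
        log["stages"].append({"stage": name, "time": time.strftime("%F %T"), **info})
        (out / "pipeline_log.json").write_text(json.dumps(log, indent=2, default=str))

    # ---- stage 1: corpus and item set -----------------------------------
    if config.synthetic:
        corpus_cfg = synthetic.CorpusConfig(seed=config.seed)
        corpus, ledger = synthetic.generate_corpus(corpus_cfg)
        items = pd.DataFrame(ledger.item_records)
        items["rating"] = 0.0  # filled from the planted surface after measuring
        modifiers = set(r["modifier"] for r in ledger.item_records)
        item_pairs = set(ledger.item_pairs)
        dims, n_content = config.synthetic_dims, config.synthetic_n_content
        stage("corpus", source="synthetic", sentences=len(corpus),
              tokens=corpus.token_count)
    else:
        if not config.corpus_path or not Path(config.corpus_path).exists():
            raise InputError(f"corpus file not found: {config.corpus_path}")
        if not config.items_path or not Path(config.items_path).exists():
            raise InputError(f"item table not found: {config.items_path}")
        corpus = read_corpus(config.corpus_path, dialect=config.dialect)
        items = read_item_table(config.items_path)
        modifiers = set(items["modifier"].astype(str))
        item_pairs = set(
            zip(items["modifier"].astype(str), items["head"].astype(str))
        )
        dims, n_content = config.dims, config.n_content
        stage("corpus", source=config.corpus_path,
              fingerprint=_file_fingerprint(config.corpus_path),
              sentences=len(corpus), tokens=corpus.token_count)

    # ---- stage 2: semantic space ----------------------------------------
    candidates = composition.candidate_bigrams(
        corpus, modifiers, item_pairs, config.min_pair_freq
    )
    constituents = sorted(
        set(items["modifier"].astype(str)) | set(items["head"].astype(str))
    )
    extra_rows = constituents + sorted(candidates)
    builder = SemanticSpaceBuilder(
        n_content=n_content, half_window=config.half_window, d=dims,
        seed=config.seed, extra_rows=extra_rows,
    )
    space = builder.fit_transform(corpus)
    space.save(out / "space")
    stage("space", dims=dims, n_rows=len(space.row_targets),
          reconstruction_error=space.provenance["reconstruction_error"])

    # ---- stage 3: composition -------------------------------------------
    training = composition.extract_training_pairs(
        corpus, modifiers, item_pairs,
        min_pair_freq=config.min_pair_freq,
        min_pairs_per_modifier=config.min_pairs_per_modifier,
        space=space,
    )
    if config.method == "lexical_function":
        model = composition.CompositionModel.train_lexical_functions(
            training, space, alpha=config.ridge_policy
        )
    elif config.method == "full_additive":
        model = composition.CompositionModel.train_full_additive(
            training, space, alpha=config.ridge_policy
        )
    else:
        model = composition.CompositionModel(method=config.method)
    stage("composition", method=config.method,
          trained_modifiers=len(training.pairs),
          training_pairs=training.n_pairs(),
          excluded_modifiers=len(training.excluded_modifiers))

    # ---- stage 4: measures ----------------------------------------------
    freqs = FrequencyTable.from_corpus(corpus)
    table = assemble_table(items, space, model, freqs, k=config.k)
    if config.synthetic:
        usable = ~table["excluded"]
        ratings_cfg = synthetic.RatingsConfig(seed=config.seed)
        rated, _truth = synthetic.generate_ratings(ratings_cfg, table[usable])
        table = table.copy()
        table.loc[usable, "rating"] = rated["rating"].to_numpy()
    table.to_csv(out / "item_table.tsv", sep="\t", index=False)
    stage("measures", items=len(table), excluded=int(table["excluded"].sum()))

    # ---- stage 5: additive-model analysis -------------------------------
    baseline, baseline_trace = gam.build_baseline(
        table, BASELINE_CANDIDATES, alpha=config.alpha
    )
    final, step_trace = gam.stepwise_select(
        table, baseline, measures.MEASURE_COLUMNS, alpha=config.alpha
    )
    report = gam.criticize(table, final, alpha=config.alpha)
    (out / "baseline_trace.json").write_text(
        json.dumps(baseline_trace, indent=2, default=str)
    )
    (out / "stepwise_trace.json").write_text(json.dumps(
        [dataclasses.asdict(s) for s in step_trace.steps], indent=2, default=str
    ))
    (out / "criticism.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2, default=str)
    )
    (out / "model_summary.txt").write_text(final.summary() + "\n")
    _export_tensor_grids(final, out)
    stage("analysis", final_terms=final.spec.term_names(),
          accepted=step_trace.accepted_terms(), aic=final.aic_,
          deviance_explained=final.deviance_explained_)

    return {
        "out_dir": str(out),
        "space": space,
        "training": training,
        "composition_model": model,
        "table": table,
        "baseline": baseline,
        "baseline_trace": baseline_trace,
        "final_model": final,
        "stepwise_trace": step_trace,
        "criticism": report,
    }


def _export_tensor_grids(model: gam.GaussianGAM, out: Path, n_grid: int = 25) -> None:
    """Predicted surface of each tensor term on a regular grid, as TSV
    (the plain-text analogue of the interaction heat maps)."""
    frame = model.frame_
    for term in model.spec.tensors:
        g1 = np.linspace(frame[term.var1].min(), frame[term.var1].max(), n_grid)
        g2 = np.linspace(frame[term.var2].min(), frame[term.var2].max(), n_grid)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        grid = pd.DataFrame({term.var1: G1.ravel(), term.var2: G2.ravel()})
        # hold every other variable at its training mean / modal level
        for col in model.spec.variables() - {term.var1, term.var2, model.spec.response}:
            if col in model.spec.random:
                grid[col] = frame[col].astype(str).mode().iloc[0]
            else:
                grid[col] = float(frame[col].mean())
        grid["predicted"] = model.predict(grid)
        name = f"surface_{term.var1}_x_{term.var2}.tsv"
        grid[[term.var1, term.var2, "predicted"]].to_csv(
            out / name, sep="\t", index=False
        )
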
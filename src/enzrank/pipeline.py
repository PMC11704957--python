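"""End-to-end orchestration: train a ranker from labeled sequences, filter a
candidate homolog panel, and write the ranked table plus a run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .embedders import SurrogateEmbedder, embed_dataset, select_best_layer
from .homology import attach_lengths, filter_hits, parse_hits_m8, rank_candidates, redundancy_filter
from .regression import RegressorSpec, evaluate_model, grid_search_train, split_dataset
from .seqio import (
    FitnessDataset,
    read_fasta,
    read_fitness_fasta,
    read_fitness_tsv,
    write_ranked_table,
)

__all__ = ["ConfigError", "DataError", "RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 3)."""


@dataclass
class RunConfig:
    """Declarative description of one ranking run."""

    train_fasta: str
    candidates_fasta: str
    output_dir: str
    labels_tsv: str | None = None
    m8: str | None = None
    query_fasta: str | None = None
    transform: str = "log10"
    embedder: dict = field(default_factory=dict)
    regressor: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"train_fasta", "candidates_fasta", "output_dir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("train_fasta", "candidates_fasta", "labels_tsv", "m8", "query_fasta"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key} does not exist: {path}")
        if self.transform not in ("identity", "log10"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        layer = self.embedder.get("layer", "auto")
        if layer != "auto" and not isinstance(layer, int):
            raise ConfigError("embedder.layer must be an integer or 'auto'")


def _build_embedder(cfg: RunConfig) -> SurrogateEmbedder:
    name = cfg.embedder.get("name", "surrogate")
    if name != "surrogate":
        raise ConfigError(
            f"unknown embedder backend {name!r}; available: surrogate "
            "(plug a pretrained-model adapter in via the library API)"
        )
    return SurrogateEmbedder(
        dim=cfg.embedder.get("dim", 128),
        n_layers=cfg.embedder.get("n_layers", 3),
        seed=cfg.embedder.get("seed", cfg.seed),
    )


def _load_training_data(cfg: RunConfig) -> FitnessDataset:
    if cfg.labels_tsv:
        return read_fitness_tsv(cfg.train_fasta, cfg.labels_tsv, transform=cfg.transform)
    return read_fitness_fasta(cfg.train_fasta, transform=cfg.transform)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and return the manifest dictionary.

    Stages: read labels -> (optional) layer selection -> grid-search training
    -> train/test evaluation -> read candidates -> optional E-value/coverage
    filter on the m8 hits -> optional redundancy filter -> embed -> predict
    -> ranked TSV. The manifest (written as ``manifest.json``) records the
    seed, package version, chosen layer and hyperparameters, evaluation
    statistics and the candidate counts after every filtering stage; ids
    excluded at each stage go to ``excluded.tsv``. On error, the manifest for
    the completed stages is still written.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "transform": config.transform,
        "counts": {},
        "stages_completed": [],
    }
    excluded: list[tuple[str, str]] = []  # (stage, id)
    try:
        _run_stages(config, manifest, excluded, out_dir)
    finally:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out_dir / "excluded.tsv", "w") as fh:
            fh.write("stage\tid\n")
            for stage, rec_id in excluded:
                fh.write(f"{stage}\t{rec_id}\n")
    return manifest


def _run_stages(
    config: RunConfig,
    manifest: dict[str, Any],
    excluded: list[tuple[str, str]],
    out_dir: Path,
) -> None:
    def done(stage: str) -> None:
        manifest["stages_completed"].append(stage)

    # --- training data ---------------------------------------------------
    try:
        train_data = _load_training_data(config)
    except ValueError as exc:
        raise DataError(f"read-labels: {exc}") from exc
    manifest["counts"]["training_sequences"] = len(train_data)
    done("read-labels")

    embedder = _build_embedder(config)
    reg_cfg = dict(config.regressor)
    family = reg_cfg.pop("family", "rfr")
    spec = RegressorSpec(family=family, seed=reg_cfg.pop("seed", config.seed), **reg_cfg)

    # --- layer selection --------------------------------------------------
    layer_cfg = config.embedder.get("layer", "auto")
    if layer_cfg == "auto":
        layer, per_layer = select_best_layer(
            train_data, embedder, spec, seed=config.seed
        )
        manifest["per_layer_scores"] = per_layer
    else:
        layer = int(layer_cfg)
        if not 0 <= layer < embedder.spec.n_layers:
            raise ConfigError(f"embedder.layer {layer} out of range")
    manifest["layer"] = layer
    done("select-layer")

    # --- training + evaluation -------------------------------------------
    train, test = split_dataset(train_data, config.train_fraction, seed=config.seed)
    emb_train = embed_dataset(train.records, embedder, layer)
    emb_test = embed_dataset(test.records, embedder, layer)
    model = grid_search_train(
        emb_train,
        train.transformed_values(),
        spec,
        train_ids=train.ids,
        layer=layer,
        transform=config.transform,
    )
    manifest["chosen_hyperparameters"] = model.chosen_hyperparameters
    manifest["family"] = model.family
    report = evaluate_model(
        model, emb_test, test.transformed_values(), split_seed=config.seed
    )
    manifest["evaluation"] = {
        "spearman_rho": report.spearman_rho,
        "r_squared": report.r_squared,
        "n_train": len(train),
        "n_test": report.n_test,
    }
    done("train")

    # --- candidates -------------------------------------------------------
    try:
        candidates = read_fasta(config.candidates_fasta)
    except ValueError as exc:
        raise DataError(f"read-candidates: {exc}") from exc
    manifest["counts"]["candidates_input"] = len(candidates)
    done("read-candidates")

    if config.m8:
        try:
            hits = parse_hits_m8(config.m8)
            lengths = {r.id: len(r) for r in candidates}
            q_lengths = dict(lengths)
            if config.query_fasta:
                q_lengths.update(
                    {r.id: len(r) for r in read_fasta(config.query_fasta)}
                )
            hits = attach_lengths(hits, q_lengths, lengths)
            surviving = filter_hits(
                hits,
                max_evalue=config.filters.get("max_evalue", 1e-3),
                min_bidir_cov=config.filters.get("min_bidir_cov", 0.9),
            )
        except ValueError as exc:
            raise DataError(f"filter-hits: {exc}") from exc
        keep_ids = {h.target_id for h in surviving}
        for rec in candidates:
            if rec.id not in keep_ids:
                excluded.append(("evalue_coverage", rec.id))
        candidates = [r for r in candidates if r.id in keep_ids]
    manifest["counts"]["after_evalue_cov"] = len(candidates)
    done("filter-hits")

    threshold = config.filters.get("redundancy_threshold", 0.9)
    if threshold is not None:
        reps, assignment = redundancy_filter(candidates, threshold=threshold)
        rep_ids = {r.id for r in reps}
        for rec in candidates:
            if rec.id not in rep_ids:
                excluded.append(("redundancy", rec.id))
        candidates = [r for r in candidates if r.id in rep_ids]
    manifest["counts"]["after_redundancy"] = len(candidates)
    done("dedupe")

    if not candidates:
        raise DataError("rank: no candidates left after filtering")
    emb_cand = embed_dataset(candidates, embedder, layer)
    ranked = rank_candidates(model, emb_cand, candidates)
    write_ranked_table(ranked, out_dir / "ranked.tsv")
    manifest["counts"]["ranked"] = len(ranked)
    done("rank")
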
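"""Configuration, run manifest, and the end-to-end pipeline runner.

The pipeline wires the stages together on synthetic inputs: simulate ->
interactome filter -> screen demux/normalize/fold/collapse -> RSA ->
differential -> intersection -> funnel. Each stage block of the YAML config
holds that stage's thresholds; unknown keys are rejected. All randomness
derives from one global seed via per-stage child seeds, so stages are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import funnel as funnel_mod
from . import interactome, rsa, screen, synth
from .io import write_tsv

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_STAGES = ("simulate", "bioid", "screen", "rsa", "funnel")


@dataclass
class PipelineConfig:
    """Per-stage threshold blocks plus the global seed and log level."""

    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = _STAGES
    bioid_sim: synth.BioidSimConfig = field(default_factory=synth.BioidSimConfig)
    screen_sim: synth.ScreenSimConfig = field(default_factory=synth.ScreenSimConfig)
    funnel_sim: synth.FunnelSimConfig = field(default_factory=synth.FunnelSimConfig)
    interactor_filter: interactome.InteractorFilterSpec = field(
        default_factory=interactome.InteractorFilterSpec
    )
    saint_prior: float = 0.5
    saint_min_true_fold: float = 2.0
    pseudocount: float = 1.0
    top_fraction: float = 0.15
    funnel_config: funnel_mod.FunnelConfig = field(
        default_factory=funnel_mod.FunnelConfig
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs: dict[str, Any] = {}
        nested = {
            "bioid_sim": synth.BioidSimConfig,
            "screen_sim": synth.ScreenSimConfig,
            "funnel_sim": synth.FunnelSimConfig,
            "interactor_filter": interactome.InteractorFilterSpec,
            "funnel_config": funnel_mod.FunnelConfig,
        }
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if key in nested:
                block = dict(value or {})
                block_valid = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(block) - block_valid
                if bad:
                    raise ConfigError(f"unknown keys in {key}: {sorted(bad)}")
                kwargs[key] = nested[key](**block)
            elif key == "stages":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    record_counts: dict[str, int]
    started: float
    finished: float

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> RunManifest:
    """Execute the requested stages in dependency order.

    Writes per-stage TSV outputs and a ``manifest.json`` under ``outdir``.
    Any stage failure is re-raised as :class:`StageError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(outdir, exist_ok=True)
    started = time.time()
    counts: dict[str, int] = {}
    state: dict[str, Any] = {}

    for stage in _STAGES:
        if stage not in config.stages:
            logger.info("stage %s skipped", stage)
            continue
        try:
            _run_stage(stage, config, outdir, state, counts)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        record_counts=counts,
        started=started,
        finished=time.time(),
    )
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest


def _run_stage(
    stage: str,
    config: PipelineConfig,
    outdir: str | os.PathLike,
    state: dict[str, Any],
    counts: dict[str, int],
) -> None:
    seed = config.seed
    if stage == "simulate":
        state["bioid_sim"] = synth.gen_bioid_counts(
            dataclasses.replace(config.bioid_sim, seed=_child_seed(seed, "bioid"))
        )
        state["screen_sim"] = synth.gen_screen_reads(
            dataclasses.replace(config.screen_sim, seed=_child_seed(seed, "screen"))
        )
        state["funnel_sim"] = synth.gen_funnel_fixture(
            dataclasses.replace(config.funnel_sim, seed=_child_seed(seed, "funnel"))
        )
        state["linked_genes"] = _link_symbols(
            state["bioid_sim"], state["screen_sim"], _child_seed(seed, "link")
        )
        counts["simulate:bioid_preys"] = len(state["bioid_sim"].table.counts)
        counts["simulate:screen_barcodes"] = len(state["screen_sim"].planted_counts)
        counts["simulate:funnel_genes"] = len(state["funnel_sim"].truth)
        logger.info("simulate: %s", {k: v for k, v in counts.items()})
    elif stage == "bioid":
        sim = _need(state, "bioid_sim", "simulate")
        scores = interactome.saint_score(
            sim.table,
            prior=config.saint_prior,
            min_true_fold=config.saint_min_true_fold,
            filter_spec=config.interactor_filter,
        )
        retained = interactome.filter_interactors(scores, config.interactor_filter)
        state["interactors"] = list(retained.index)
        write_tsv(os.path.join(outdir, "bioid_scores.tsv"), scores.reset_index())
        write_tsv(os.path.join(outdir, "interactors.tsv"), retained.reset_index())
        counts["bioid:scored"] = len(scores)
        counts["bioid:retained"] = len(retained)
    elif stage == "screen":
        sim = _need(state, "screen_sim", "simulate")
        raw, qc = screen.demultiplex(sim.reads, sim.library, sim.layout)
        norm = screen.normalize_library_size(raw)
        collapsed_parts = []
        for arm in ("arm_A", "arm_B"):
            arm_samples = sim.samples.loc[sim.samples["arm"] == arm, "sample"]
            folds = screen.fold_change_percentile(
                norm[list(arm_samples)],
                reference_sample=sim.reference_of(arm),
                pseudocount=config.pseudocount,
                targeting_ids=sim.library.entries.loc[
                    sim.library.entries["class"] == "targeting", "shrna_id"
                ],
            )
            grouping = {
                g: s for g, s in sim.grouping().items() if g.startswith(arm)
            }
            collapsed_parts.append(screen.collapse_replicates(folds, grouping))
        state["collapsed"] = pd.concat(collapsed_parts, axis=1)
        write_tsv(os.path.join(outdir, "demux_qc.tsv"), qc)
        write_tsv(
            os.path.join(outdir, "collapsed_percentiles.tsv"),
            state["collapsed"].reset_index(),
        )
        counts["screen:reads"] = int(qc["total_reads"].sum())
        counts["screen:assigned"] = int(qc["assigned"].sum())
    elif stage == "rsa":
        sim = _need(state, "screen_sim", "simulate")
        collapsed = _need(state, "collapsed", "screen")
        scores = {
            arm: rsa.screen_rsa(collapsed, sim.library, f"{arm}:in_vitro")
            for arm in ("arm_A", "arm_B")
        }
        diff = rsa.differential_rank(scores["arm_A"], scores["arm_B"])
        state["differential"] = diff
        hits = rsa.intersect_top(
            diff, _need(state, "interactors", "bioid"), config.top_fraction
        )
        state["screen_hits"] = hits
        for arm, table in scores.items():
            write_tsv(os.path.join(outdir, f"rsa_{arm}.tsv"), table)
        write_tsv(os.path.join(outdir, "differential.tsv"), diff)
        with open(os.path.join(outdir, "screen_hits.txt"), "w") as handle:
            handle.write("\n".join(hits) + ("\n" if hits else ""))
        counts["rsa:genes"] = len(diff)
        counts["rsa:intersection_hits"] = len(hits)
    elif stage == "funnel":
        sim = _need(state, "funnel_sim", "simulate")
        audit = funnel_mod.run_funnel(
            sim.peaks_a,
            sim.peaks_b,
            sim.annotation,
            sim.expression,
            promoters=sim.promoters,
            config=config.funnel_config,
        )
        state["funnel_audit"] = audit
        write_tsv(os.path.join(outdir, "funnel_audit.tsv"), audit)
        for name, value in funnel_mod.stage_counts(audit).items():
            counts[f"funnel:{name}"] = value


def _link_symbols(
    bioid_sim: synth.BioidSim, screen_sim: synth.ScreenSim, seed: int, n_link: int = 5
) -> list[str]:
    """Give a few planted interactor preys the symbols of planted arm-A
    essential screen genes, so the BioID/screen intersection has known
    positives on synthetic data. Returns the shared symbols."""
    rng = np.random.default_rng(seed)
    essential = screen_sim.truth.loc[
        screen_sim.truth["essential_a"] & ~screen_sim.truth["essential_b"], "gene"
    ].tolist()
    true_preys = list(bioid_sim.truth.index[bioid_sim.truth])
    n = min(n_link, len(essential), len(true_preys))
    if n == 0:
        return []
    chosen_genes = [essential[i] for i in rng.choice(len(essential), n, replace=False)]
    chosen_preys = [true_preys[i] for i in rng.choice(len(true_preys), n, replace=False)]
    mapping = dict(zip(chosen_preys, chosen_genes))
    bioid_sim.table.counts = bioid_sim.table.counts.rename(index=mapping)
    if bioid_sim.table.unique_peptides is not None:
        bioid_sim.table.unique_peptides = bioid_sim.table.unique_peptides.rename(
            index=mapping
        )
    bioid_sim.truth = bioid_sim.truth.rename(index=mapping)
    return chosen_genes


def _need(state: dict[str, Any], key: str, upstream: str) -> Any:
    if key not in state:
        raise StageError(f"missing upstream artifact {key!r} (run stage {upstream!r})")
    return state[key]
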
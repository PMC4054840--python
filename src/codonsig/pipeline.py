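"""Orchestration: predict -> screen -> confound-test -> report.

A single PipelineConfig holds every numeric default of the method (run
counts, thresholds, window sizes). The report embeds a hash of the exact
configuration for provenance, and the whole pipeline is deterministic
under its master seed, which fans out to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cog_enrich, confound_rf, he_predict, trna_concord
from .cog_enrich import PhenotypeMatrix
from .he_predict import ClassifierConfig, GenomeSkipped
from .seqio import GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class HeStageConfig:
    n_runs: int = 200
    q_threshold: float = 1e-12
    min_reference: int = 10


@dataclass
class ScreenStageConfig:
    fold_min: float = 2.0
    alpha: float = 1e-2
    cog_min: int = 20
    cog_max: int = 10_000


@dataclass
class ConfoundStageConfig:
    n_shuffles: int = 30
    n_folds: int = 10
    p_threshold: float = 1e-2


@dataclass
class TrnaStageConfig:
    p_threshold: float = 1e-3
    flag_min_disagree: int = 3


@dataclass
class DesignStageConfig:
    window_len: int = 42
    rbs: str = "AGGAGGUAAAACAU"
    reduction_factor: float = 0.7
    floor_percent: float = 3.0
    n_samples: int = 100


@dataclass
class PipelineConfig:
    seed: int = 0
    he: HeStageConfig = field(default_factory=HeStageConfig)
    screen: ScreenStageConfig = field(default_factory=ScreenStageConfig)
    confound: ConfoundStageConfig = field(default_factory=ConfoundStageConfig)
    trna: TrnaStageConfig = field(default_factory=TrnaStageConfig)
    design: DesignStageConfig = field(default_factory=DesignStageConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineInputs:
    genomes: dict[str, list[GeneRecord]]
    matrix: PhenotypeMatrix
    phenotypes: list[str]
    trna: pd.DataFrame | None = None  # genome_id, amino_acid, anticodon rows


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # tag the failing stage
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("predict")
def _predict(config: PipelineConfig, inputs: PipelineInputs, seeds):
    calls = {}
    for i, (genome_id, records) in enumerate(sorted(inputs.genomes.items())):
        try:
            pairs = he_predict.paired_scores(
                records,
                n_runs=config.he.n_runs,
                seed=int(seeds[i]),
                classifier=config.classifier,
                min_reference=config.he.min_reference,
            )
        except GenomeSkipped as exc:
            logger.warning("genome %s skipped: %s", genome_id, exc)
            continue
        calls[genome_id] = he_predict.sign_test_label(pairs, config.he.q_threshold)
    return calls


@_stage("screen")
def _screen(config: PipelineConfig, inputs, cog_genes, he_labels):
    retained = cog_enrich.filter_cogs(
        cog_genes, config.screen.cog_min, config.screen.cog_max
    )
    records, summaries = [], {}
    for phenotype in inputs.phenotypes:
        recs, summary = cog_enrich.screen_phenotype(
            retained, he_labels, inputs.matrix, phenotype,
            alpha=config.screen.alpha, fold_min=config.screen.fold_min,
        )
        records.extend(recs)
        summaries[phenotype] = summary
    return retained, records, summaries


@_stage("confound")
def _confound(config: PipelineConfig, inputs, retained, passing, he_labels, seeds):
    verdicts = []
    for i, (cog_id, phenotype) in enumerate(passing):
        ds = confound_rf.build_cog_dataset(cog_id, retained, he_labels, inputs.matrix)
        if not ds.testable:
            continue
        verdicts.append(
            confound_rf.randomization_test(
                ds, phenotype,
                n_shuffles=config.confound.n_shuffles,
                n_folds=config.confound.n_folds,
                seed=int(seeds[i]),
                classifier=config.classifier,
                p_threshold=config.confound.p_threshold,
            )
        )
    return verdicts


@_stage("trna")
def _trna(config: PipelineConfig, inputs, calls):
    results = []
    for genome_id, genome_calls in sorted(calls.items()):
        sub = inputs.trna[inputs.trna["genome_id"] == genome_id]
        he_opt = trna_concord.he_optimal_codons(
            inputs.genomes[genome_id], genome_calls, config.trna.p_threshold
        )
        trna_opt = trna_concord.trna_optimal_codons(
            list(zip(sub["amino_acid"], sub["anticodon"]))
        )
        results.append(trna_concord.concordance(genome_id, he_opt, trna_opt))
    return results


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> dict:
    """Run predict -> screen -> confound (-> tRNA check) and build the report."""
    master = np.random.SeedSequence(config.seed)
    seeds = master.generate_state(4096) % (2**31 - 1)

    calls = _predict(config, inputs, seeds[:1024])
    he_labels = {
        c.gene_id: c.label == "HE" for genome in calls.values() for c in genome
    }
    cog_genes: dict[str, list[tuple[str, str]]] = {}
    for genome_id, records in inputs.genomes.items():
        for r in records:
            if r.gene_id not in he_labels:
                continue
            for cog in r.cog_ids:
                cog_genes.setdefault(cog, []).append((genome_id, r.gene_id))

    retained, screen_records, summaries = _screen(config, inputs, cog_genes, he_labels)
    passing = [(r.cog_id, r.phenotype) for r in screen_records if r.passes]
    verdicts = _confound(
        config, inputs, retained, passing, he_labels, seeds[1024:2048]
    )
    flagged_genomes: list[str] = []
    concordances = []
    if inputs.trna is not None:
        concordances = _trna(config, inputs, calls)
        flagged_genomes = [
            c.genome_id for c in concordances if c.flagged(config.trna.flag_min_disagree)
        ]

    report = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_genomes": len(calls),
        "he": {
            g: dataclasses.asdict(he_predict.he_summary(c)) for g, c in calls.items()
        },
        "screen": {
            p: {
                "n_tested": s.n_tested,
                "n_significant": s.n_significant,
                "alpha": s.alpha,
                "fdr_estimate_percent": s.fdr_estimate,
            }
            for p, s in summaries.items()
        },
        "confound": {
            "n_tested": len(verdicts),
            "n_independent": sum(v.independent for v in verdicts),
            "independent_links": sorted(
                [v.cog_id, v.phenotype] for v in verdicts if v.independent
            ),
        },
        "flagged_genomes": flagged_genomes,
    }
    return {
        "report": report,
        "calls": calls,
        "he_labels": he_labels,
        "screen_records": screen_records,
        "summaries": summaries,
        "verdicts": verdicts,
        "concordances": concordances,
        "retained_cogs": retained,
    }


def sensitivity_rerun(
    config: PipelineConfig,
    inputs: PipelineInputs,
    results: dict,
    excluded_genomes: set[str],
) -> dict:
    """Re-run the screen without the excluded genomes; report per-link deltas.

    Mirrors the robustness check of dropping genomes whose codon bias does
    not match their tRNA repertoire.
    """
    if not excluded_genomes <= set(inputs.genomes):
        raise ValueError("exclusion list contains unknown genomes")
    if excluded_genomes >= set(inputs.genomes):
        raise ValueError("cannot exclude every genome")
    he_labels = results["he_labels"]
    retained = results["retained_cogs"]
    reduced = {
        cog: [(g, gid) for g, gid in members if g not in excluded_genomes]
        for cog, members in retained.items()
    }
    reduced = {c: m for c, m in reduced.items() if m}
    deltas = []
    before = {(r.cog_id, r.phenotype): r for r in results["screen_records"] if r.passes}
    for phenotype in inputs.phenotypes:
        recs, _ = cog_enrich.screen_phenotype(
            reduced, he_labels, inputs.matrix, phenotype,
            alpha=config.screen.alpha, fold_min=config.screen.fold_min,
        )
        after = {(r.cog_id, r.phenotype): r for r in recs}
        for key, rec in before.items():
            if key[1] != phenotype:
                continue
            new = after.get(key)
            deltas.append(
                {
                    "cog_id": key[0],
                    "phenotype": key[1],
                    "fold_before": rec.fold,
                    "fold_after": new.fold if new else None,
                    "p_before": rec.p_two_tailed,
                    "p_after": new.p_two_tailed if new else None,
                    "retained": bool(new is not None and new.passes),
                }
            )
    return {"excluded": sorted(excluded_genomes), "links": deltas}
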
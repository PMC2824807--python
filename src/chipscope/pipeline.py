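"""End-to-end orchestration of the analysis stages on one configuration.

The pipeline runs: simulate -> call-peaks -> assign-targets -> stalling ->
compare-stages -> motif-enrich -> dcpm -> enrich-sets, writing one table (or
JSON report) per stage plus a manifest echoing the configuration, seed, and
per-stage row counts. Identical configuration and seed produce byte-identical
outputs. Any stage failure raises a :class:`PipelineError` naming the stage;
tables already written are left in place.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core_io import read_annotation, write_annotation, write_sites, write_track
from .expression import (
    expression_table,
    expression_vs_binding,
    hypergeometric_overlap,
    running_sum_es,
)
from .motifs import motif_enrichment
from .peaks import call_sites, sliding_window_scores
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_polii,
    simulate_rna,
    simulate_sequences,
    simulate_stage_pair,
)
from .stages import binned_signal_correlation, compare_target_sets, signal_scatter
from .stalling import (
    classify_transcripts,
    differential_map,
    stalling_by_target_overlap,
    stalling_table,
    transcript_enrichment,
)
from .targets import (
    assign_all,
    assignments_to_frame,
    filter_targets_go_rule,
    target_gene_census,
    target_gene_set,
)

log = logging.getLogger("chipscope")

STAGE_NAMES = [
    "simulate", "call-peaks", "assign-targets", "stalling",
    "compare-stages", "motif-enrich", "dcpm", "enrich-sets",
]

#: Every tunable threshold, defaulting to the values the analysis was
#: designed around.
DEFAULT_THRESHOLDS = {
    "window": 200,
    "step": 50,
    "site_p": 1e-5,
    "concordance_p": 1e-3,
    "search": 5000,
    "near": 2000,
    "promoter_pad": 300,
    "body_offset": 600,
    "stalling_threshold": 4.0,
    "enrichment_p": 1e-5,
    "top": 200,
    "match_p": 1e-4,
    "background_site_p": 0.05,
    "bin": 600,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValueError("pipeline config must be a mapping")
    return loaded


def _sim_config(config: dict, seed: int) -> SimulationConfig:
    overrides = dict(config.get("simulate", {}))
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    return SimulationConfig(seed=seed, **overrides)


def _thresholds(config: dict) -> dict:
    thresholds = dict(DEFAULT_THRESHOLDS)
    extra = dict(config.get("thresholds", {}))
    unknown = set(extra) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    thresholds.update(extra)
    for key, value in thresholds.items():
        if key.endswith("_p") or key == "background_site_p":
            if not (0 < value < 1):
                raise ValueError(f"threshold {key} must be in (0, 1)")
        elif value <= 0:
            raise ValueError(f"threshold {key} must be positive")
    return thresholds


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Run every stage, writing tables under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    thresholds = _thresholds(config)
    manifest = {
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "stages": [],
    }
    state: dict = {}

    def _stage(name: str):
        def runner(func):
            t0 = time.monotonic()
            try:
                counts = func() or {}
            except Exception as exc:
                log.error("stage=%s failed: %s", name, exc)
                _write_json(manifest, outdir / "manifest.json")
                raise PipelineError(name, exc) from exc
            log.info(
                "stage=%s elapsed=%.1fs %s", name, time.monotonic() - t0,
                " ".join(f"{k}={v}" for k, v in counts.items()),
            )
            manifest["stages"].append({"name": name, "counts": counts})
        return runner

    sim = _sim_config(config, seed)
    manifest["simulate"] = {
        k: v for k, v in asdict(sim).items()
        if isinstance(v, (int, float, str, bool, list, tuple)) or v is None
    }

    @_stage("simulate")
    def _():
        if "annotation" in config:
            state["annotation"] = read_annotation(config["annotation"])
        else:
            state["annotation"] = simulate_annotation(sim)
        annotation = state["annotation"]
        stage_a, stage_b = simulate_stage_pair(annotation, sim)
        state["chip"] = {"A": stage_a, "B": stage_b}
        state["polii"] = simulate_polii(annotation, sim)
        state["rna"] = {
            "A": simulate_rna(annotation, sim, stream=5),
            "B": simulate_rna(annotation, sim, stream=7),
        }
        true_sites = stage_a[2].sites + [
            s for s in stage_b[2].sites if s not in stage_a[2].sites
        ]
        state["genome"], state["motif_truth"] = simulate_sequences(
            annotation, sim, site_intervals=true_sites
        )
        write_annotation(annotation, outdir / "annotation.gff3")
        for label, (chip, inp, _truth) in state["chip"].items():
            write_track(chip, outdir / f"chip_{label}.bedgraph")
            write_track(inp, outdir / f"input_{label}.bedgraph")
        return {
            "genes": annotation.n_genes,
            "transcripts": annotation.n_transcripts,
            "true_sites_A": len(stage_a[2].sites),
            "true_sites_B": len(stage_b[2].sites),
        }

    @_stage("call-peaks")
    def _():
        state["sites"] = {}
        state["scores"] = {}
        for label, (chip, inp, _truth) in state["chip"].items():
            scores = sliding_window_scores(
                chip, inp, window=thresholds["window"], step=thresholds["step"]
            )
            sites = call_sites(scores, thresholds["site_p"], chip, inp)
            state["scores"][label] = scores
            state["sites"][label] = sites
            write_sites(sites, outdir / f"sites_{label}.tsv")
        return {f"sites_{k}": len(v) for k, v in state["sites"].items()}

    @_stage("assign-targets")
    def _():
        annotation = state["annotation"]
        state["assignments"] = {}
        state["targets"] = {}
        state["go_targets"] = {}
        for label, sites in state["sites"].items():
            assignments = assign_all(
                sites, annotation,
                search=thresholds["search"], near=thresholds["near"],
            )
            state["assignments"][label] = assignments
            state["targets"][label] = target_gene_set(assignments)
            state["go_targets"][label] = filter_targets_go_rule(
                assignments, near=thresholds["near"]
            )
            assignments_to_frame(assignments).to_csv(
                outdir / f"targets_{label}.tsv", sep="\t", index=False
            )
        census = {
            label: {
                k: v for k, v in target_gene_census(a).items() if k != "distances"
            }
            for label, a in state["assignments"].items()
        }
        _write_json(census, outdir / "target_census.json")
        return {f"targets_{k}": len(v) for k, v in state["targets"].items()}

    @_stage("stalling")
    def _():
        annotation = state["annotation"]
        polii, inp, _truth = state["polii"]
        diff = differential_map(polii, inp)
        calls = stalling_table(
            diff, annotation,
            promoter_pad=thresholds["promoter_pad"],
            body_offset=thresholds["body_offset"],
        )
        enrichment = transcript_enrichment(polii, inp, annotation)
        classified = classify_transcripts(
            calls, enrichment,
            threshold=thresholds["stalling_threshold"],
            enrichment_p=thresholds["enrichment_p"],
        )
        state["stalling"] = classified
        classified.to_csv(outdir / "stalling.tsv", sep="\t", index=False)
        overlap = stalling_by_target_overlap(
            classified, state["targets"]["A"], set(annotation.gene_ids)
        )
        _write_json(overlap, outdir / "stalling_vs_targets.json")
        return {
            "stalled": int((classified["class"] == "stalled").sum()),
            "uniform": int((classified["class"] == "uniform").sum()),
            "absent": int((classified["class"] == "absent").sum()),
        }

    @_stage("compare-stages")
    def _():
        chip_a, input_a, _ = state["chip"]["A"]
        chip_b, input_b, _ = state["chip"]["B"]
        report = compare_target_sets(state["targets"]["A"], state["targets"]["B"])
        concordance_sites = call_sites(
            state["scores"]["A"], thresholds["concordance_p"], chip_a, input_a
        )
        correlation = binned_signal_correlation(
            concordance_sites, chip_a, chip_b, input_a, input_b,
            bin_size=thresholds["bin"],
        )
        scatter = signal_scatter(
            state["sites"]["A"], state["sites"]["B"],
            chip_a, chip_b, input_a, input_b,
        )
        scatter.to_csv(outdir / "signal_scatter.tsv", sep="\t", index=False)
        _write_json(
            {**asdict(report), "binned_correlation": correlation},
            outdir / "stage_overlap.json",
        )
        state["overlap"] = report
        return {"shared_targets": report.n_shared, "scatter_rows": len(scatter)}

    @_stage("motif-enrich")
    def _():
        result = motif_enrichment(
            state["sites"]["A"], state["genome"], sim.pwm,
            match_p=thresholds["match_p"],
            site_p_cutoff=thresholds["background_site_p"],
            top=thresholds["top"],
        )
        _write_json(asdict(result), outdir / "motif_enrichment.json")
        state["motif"] = result
        return {
            "bound_with_match": result.n_bound_with_match,
            "background_with_match": result.n_background_with_match,
        }

    @_stage("dcpm")
    def _():
        tracks = {label: rna for label, (rna, _t) in state["rna"].items()}
        expr = expression_table(tracks, state["annotation"])
        state["expression"] = expr
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        summary = expression_vs_binding(expr, state["targets"])
        _write_json(summary, outdir / "expression_vs_binding.json")
        return {"transcripts": len(expr)}

    @_stage("enrich-sets")
    def _():
        expr = state["expression"]
        gene_dcpm = expr.groupby("gene_id")[["dcpm_A", "dcpm_B"]].max()
        ranked = list(
            (gene_dcpm["dcpm_A"] - gene_dcpm["dcpm_B"])
            .sort_values(ascending=False, kind="mergesort")
            .index
        )
        targets = state["go_targets"]["A"] & set(ranked)
        result = {}
        if targets and len(targets) < len(ranked):
            es = running_sum_es(
                ranked, targets, n_permutations=200,
                rng=np.random.default_rng([seed, 99]),
            )
            result["es"] = es.es
            result["nes"] = es.nes
            result["permutation_p"] = es.permutation_p
        up_a = set(
            expr.loc[expr["up_stage"] == "A", "gene_id"]
        )
        universe = set(gene_dcpm.index)
        k = len(targets & up_a)
        result["hypergeometric_p"] = hypergeometric_overlap(
            k, len(targets), len(up_a & universe), len(universe)
        )
        result["n_targets"] = len(targets)
        result["n_up_A"] = len(up_a & universe)
        result["n_overlap"] = k
        _write_json(result, outdir / "set_enrichment.json")
        return {"ranked_genes": len(ranked), "target_set": len(targets)}

    _write_json(manifest, outdir / "manifest.json")
    return manifest
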
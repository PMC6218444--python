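"""End-to-end pipeline: simulate -> call peaks -> quantify -> annotate ->
integrate -> decay, with a YAML config, deterministic outputs and a JSON
run manifest recording seed, parameters and output digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .annotate import assign_peak_segment, metagene_profile, scan_motifs, segment_fractions
from .enrichment import (
    QuantificationParams,
    cross_group_log2fc,
    group_mean_enrichment,
    log2fc_histogram,
    quantify_enrichment,
    summarize_by_sample,
    union_peaks,
)
from .expression import differential_expression, overlap_with_m6a
from .kinetics import fit_course
from .peaks import PeakCallingParams, call_peaks_by_condition
from .simulate import SimulationConfig, simulate_dataset, write_simulation

logger = logging.getLogger("merip_enrich")

_DE_DEFAULTS = {"alpha": 0.05, "fold": 1.5, "group1": "parental", "group2": "resistant"}

_KNOWN_SECTIONS = {
    "seed": None,
    "out_dir": None,
    "simulation": {f.name for f in dataclasses.fields(SimulationConfig)},
    "peak_calling": {f.name for f in dataclasses.fields(PeakCallingParams)},
    "quantification": {f.name for f in dataclasses.fields(QuantificationParams)},
    "de": set(_DE_DEFAULTS),
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict[str, Any]) -> list[str]:
    """Return a list of problems (unknown keys, out-of-range values)."""
    problems = []
    for key in cfg:
        if key not in _KNOWN_SECTIONS:
            problems.append(f"unknown top-level key: {key}")
    for section, known in _KNOWN_SECTIONS.items():
        if known is None or section not in cfg:
            continue
        sub = cfg[section]
        if not isinstance(sub, dict):
            problems.append(f"section {section} must be a mapping")
            continue
        for key in sub:
            if key not in known:
                problems.append(f"unknown key {section}.{key}")
    try:
        _sim_config(cfg).validate()
    except (ValueError, TypeError) as exc:
        problems.append(f"simulation: {exc}")
    try:
        _peak_params(cfg).validate()
    except (ValueError, TypeError) as exc:
        problems.append(f"peak_calling: {exc}")
    de = {**_DE_DEFAULTS, **cfg.get("de", {})}
    if not 0 < de["alpha"] <= 1:
        problems.append(f"de.alpha out of range: {de['alpha']}")
    if de["fold"] < 1:
        problems.append(f"de.fold must be >= 1: {de['fold']}")
    return problems


def _sim_config(cfg: dict[str, Any]) -> SimulationConfig:
    kwargs = dict(cfg.get("simulation", {}))
    if "length_range" in kwargs:
        kwargs["length_range"] = tuple(kwargs["length_range"])
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return SimulationConfig(**kwargs)


def _peak_params(cfg: dict[str, Any]) -> PeakCallingParams:
    return PeakCallingParams(**cfg.get("peak_calling", {}))


def _quant_params(cfg: dict[str, Any]) -> QuantificationParams:
    return QuantificationParams(**cfg.get("quantification", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every stage on a simulated dataset and write all artifacts.

    Returns the manifest (also written to ``manifest.json``); identical
    config and seed give byte-identical TSV outputs.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    sim_cfg = _sim_config(cfg)
    logger.info("simulating dataset (seed=%d)", sim_cfg.seed)
    dataset = simulate_dataset(sim_cfg)
    sim_dir = out / "sim"
    write_simulation(dataset, sim_dir)

    logger.info("calling peaks")
    params = _peak_params(cfg)
    peaks_by_group = call_peaks_by_condition(dataset.libraries, dataset.models, params)
    for group, peaks in peaks_by_group.items():
        mio.write_peaks(peaks, out / f"peaks_{group}.bed")

    logger.info("quantifying union-peak enrichment")
    union = union_peaks(peaks_by_group)
    records = quantify_enrichment(
        union, dataset.libraries, dataset.models, _quant_params(cfg)
    )
    mio.write_table(records, out / "enrichment.tsv")
    summaries = pd.concat(
        [summarize_by_sample(records, f) for f in ("simple", "windowed")],
        ignore_index=True,
    )
    mio.write_table(summaries, out / "enrichment_summary.tsv")

    de_opts = {**_DE_DEFAULTS, **cfg.get("de", {})}
    g1, g2 = de_opts["group1"], de_opts["group2"]
    if not records.empty:
        gfe = group_mean_enrichment(records, "simple")
        delta, missing = cross_group_log2fc(gfe, g1, g2)
        mio.write_table(delta, out / "log2fc.tsv")
        mio.write_table(missing, out / "log2fc_missing.tsv")
        if len(delta):
            hist = log2fc_histogram(delta["log2fc"])
            mio.write_table(hist, out / "log2fc_hist.tsv")
            from .enrichment import plot_log2fc_histogram

            plot_log2fc_histogram(hist, out / "log2fc_hist.png")

    logger.info("annotating peaks")
    if union:
        assignments = [
            assign_peak_segment(p, dataset.models[p.transcript_id]) for p in union
        ]
        mio.write_table(segment_fractions(assignments), out / "segment_fractions.tsv")
        coding = [p for p in union if dataset.models[p.transcript_id].coding]
        if coding:
            mio.write_table(
                metagene_profile(coding, dataset.models), out / "metagene.tsv"
            )
        sequences = {
            t: m.sequence for t, m in dataset.models.items() if m.sequence is not None
        }
        motif_df, motif_fraction = scan_motifs(union, sequences)
        mio.write_table(motif_df, out / "motifs.tsv")
    else:
        motif_fraction = 0.0

    logger.info("integrating with expression")
    de = differential_expression(
        dataset.expression.set_index(dataset.expression.index),
        dataset.expression_groups,
        g1,
        g2,
        alpha=de_opts["alpha"],
        fold=de_opts["fold"],
    )
    mio.write_table(de, out / "de_results.tsv")
    m6a_genes = {dataset.models[p.transcript_id].gene_id for p in union}
    overlap = overlap_with_m6a(de, m6a_genes)
    mio.write_table(overlap.as_frame(), out / "overlap.tsv")

    logger.info("fitting decay kinetics")
    fits = [fit_course(c) for c in dataset.decay_courses]
    halflives = pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "t_half_h": [f.t_half for f in fits],
            "decay_rate_per_h": [f.decay_rate for f in fits],
            "fit_r2": [f.fit_r2 for f in fits],
        }
    )
    mio.write_table(halflives, out / "halflives.tsv")

    manifest = {
        "package": "merip-enrich",
        "version": __version__,
        "seed": sim_cfg.seed,
        "config": cfg,
        "n_union_peaks": len(union),
        "n_peaks_by_group": {g: len(p) for g, p in peaks_by_group.items()},
        "motif_fraction": motif_fraction,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed"))
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %d union peaks", len(union))
    logger.removeHandler(handler)
    handler.close()
    return manifest
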
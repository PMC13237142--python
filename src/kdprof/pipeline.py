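"""End-to-end orchestration: simulate -> fit -> stats -> enrichment -> screen.

A run is driven by a config mapping (YAML on disk), a single global seed,
and an output directory. The global seed fans out deterministically to
per-stage child seeds through ``numpy.random.SeedSequence([seed, stage_id])``
so stages can be rerun in isolation; two runs with the same config and seed
produce byte-identical result tables. Every run writes a manifest
(config snapshot, seeds, output digests) sufficient to reproduce it.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import differential as diff
from . import doseresponse as dr
from . import enrichment as enr
from . import io as kio
from . import pyroscreen as pyro
from . import simulate as sim
from .design import DEFAULT_PROBES, TitrationDesign, default_design

log = logging.getLogger(__name__)

STAGE_IDS: Dict[str, int] = {
    "simulate_quant": 1,
    "simulate_sequences": 2,
    "simulate_genesets": 3,
    "impute": 4,
}


def stage_seed(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_IDS[stage]]))


DEFAULT_CONFIG: Dict[str, object] = {
    "seed": 0,
    "outdir": "kdprof_results",
    "log_level": "INFO",
    "simulate": {
        "n_proteins": 1000,
        "binder_fraction": 0.25,
        "kd_range": [0.1, 30.0],
        "cv": 0.12,
        "missing_rate_low": 0.10,
        "n_replicates": 3,
        "probes": list(DEFAULT_PROBES),
    },
    "fit": {
        "min_replicates": 2,
        "r2_min": 0.9,
        "f_p_max": 0.05,
        "log2fc_min": 1.0,
        "cutoffs": [1.0, 5.0, 25.0],
        "normalization": "per_protein",
    },
    "differential": {
        "enabled": True,
        "contrast": ["b_5PCP_InsP5", "b_15PCP2_InsP4"],
        "mode": "static",
        "fc_threshold": 1.0,
        "p_threshold": 0.05,
    },
    "anova": {
        "enabled": True,
        "impute_q": 0.01,
        "tune_sigma": 1.0,
        "fdr": 0.05,
    },
    "enrichment": {
        "enabled": True,
        "fdr": 0.05,
        "kd_max": 5.0,
        "probe": "b_5PCP_InsP5",
        "fraction": "nuclear",
        "metal": "Mg",
        "n_random_sets": 10,
        "set_size": 59,
        "forced_overlap": 24,
    },
    "pyroscreen": {
        "enabled": True,
        "window": 21,
        "threshold": 0.5,
        "in_disorder_rate": 0.35,
        "out_disorder_rate": 0.35,
    },
}

_RANGES = {
    ("fit", "r2_min"): (0.0, 1.0),
    ("fit", "f_p_max"): (0.0, 1.0),
    ("differential", "p_threshold"): (0.0, 1.0),
    ("anova", "impute_q"): (0.0, 1.0),
    ("anova", "fdr"): (0.0, 1.0),
    ("enrichment", "fdr"): (0.0, 1.0),
    ("pyroscreen", "threshold"): (0.0, 1.0),
    ("simulate", "binder_fraction"): (0.0, 1.0),
    ("simulate", "cv"): (0.0, 10.0),
    ("simulate", "missing_rate_low"): (0.0, 1.0),
}


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(source: str | Path | Mapping | None) -> Dict[str, object]:
    """Normalize a config file or mapping: defaults injected, keys checked.

    All schema violations are collected and reported together. An empty
    file yields the full default config.
    """
    if source is None:
        raw: Dict[str, object] = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)

    errors: List[str] = []
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in raw.items():
        if key not in DEFAULT_CONFIG:
            errors.append(f"unknown key {key!r}")
            continue
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(value, Mapping):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub, sval in value.items():
                if sub not in DEFAULT_CONFIG[key]:
                    errors.append(f"unknown key {key}.{sub}")
                    continue
                config[key][sub] = sval
        else:
            config[key] = value

    for (section, key), (lo, hi) in _RANGES.items():
        val = config[section][key]
        if not isinstance(val, (int, float)) or not lo <= float(val) <= hi:
            errors.append(f"{section}.{key} = {val!r} outside [{lo}, {hi}]")
    cutoffs = config["fit"]["cutoffs"]
    if isinstance(cutoffs, str):
        try:
            cutoffs = [float(x) for x in cutoffs.split(",")]
        except ValueError:
            errors.append(f"fit.cutoffs {config['fit']['cutoffs']!r} not parseable")
            cutoffs = list(DEFAULT_CONFIG["fit"]["cutoffs"])
    cutoffs = sorted(float(c) for c in cutoffs)
    if len(cutoffs) != 3 or any(c <= 0 for c in cutoffs):
        errors.append(f"fit.cutoffs must be three positive values, got {cutoffs}")
    else:
        config["fit"]["cutoffs"] = cutoffs
    kd_range = config["simulate"]["kd_range"]
    if not (len(kd_range) == 2 and 0 < kd_range[0] < kd_range[1]):
        errors.append(f"simulate.kd_range must be (low, high) positive, got {kd_range}")
    if errors:
        raise ConfigError(errors)
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: Mapping | None = None,
    simulate: bool = True,
    quant_path: Optional[str | Path] = None,
) -> Dict[str, object]:
    """Execute the pipeline and return the run manifest.

    With ``simulate`` a synthetic dataset is generated under the config's
    noise model; otherwise ``quant_path`` must point to a quantification
    table matching the default design. Stages can be disabled through
    their ``enabled`` flags; disabled stages leave no outputs.
    """
    cfg = validate_config(config if isinstance(config, (str, Path, Mapping)) else None)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    design = default_design(n_replicates=int(cfg["simulate"]["n_replicates"]))
    manifest: Dict[str, object] = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": [],
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    outputs: Dict[str, Path] = {}

    def _stage(name: str):
        manifest["stages"].append(name)
        log.info("stage=%s status=start", name)

    # --- simulate / ingest -------------------------------------------------
    truth = None
    if simulate:
        _stage("simulate")
        scfg = cfg["simulate"]
        design = TitrationDesign(
            channel_concentrations=design.channel_concentrations,
            n_replicates=int(scfg["n_replicates"]),
            probes=tuple(scfg["probes"]),
        )
        noise = sim.NoiseModel(cv=float(scfg["cv"]), missing_rate_low=float(scfg["missing_rate_low"]))
        table, truth = sim.generate_quant_tables(
            design=design,
            n_proteins=int(scfg["n_proteins"]),
            binder_fraction=float(scfg["binder_fraction"]),
            kd_range=tuple(scfg["kd_range"]),
            noise=noise,
            rng=stage_seed(seed, "simulate_quant"),
        )
        outputs["quant"] = outdir / "quant.tsv"
        kio.write_quant_table(table, outputs["quant"])
        outputs["truth"] = outdir / "quant_truth.tsv"
        truth.to_csv(outputs["truth"], sep="\t", index=False)
    else:
        _stage("ingest")
        if quant_path is None:
            raise ValueError("quant_path is required when simulate is off")
        table = kio.read_quant_table(quant_path, design)

    # --- normalize / merge / fit / classify --------------------------------
    _stage("fit")
    fcfg = cfg["fit"]
    thresholds = dr.QCThresholds(
        r2_min=float(fcfg["r2_min"]),
        f_p_max=float(fcfg["f_p_max"]),
        log2fc_min=float(fcfg["log2fc_min"]),
        affinity_cutoffs=tuple(fcfg["cutoffs"]),
    )
    fits = dr.run_dose_response(
        table,
        thresholds=thresholds,
        min_replicates=int(fcfg["min_replicates"]),
        normalization=str(fcfg["normalization"]),
    )
    outputs["fits"] = outdir / "fits.tsv"
    kio.write_results(fits, outputs["fits"], "fits")
    binders = fits.loc[fits["pass_all"]].copy()
    outputs["binders"] = outdir / "binders.tsv"
    kio.write_results(
        binders[["protein_id", "probe", "fraction", "metal", "kd_app_uM", "affinity_class"]],
        outputs["binders"],
        "binders",
    )
    log.info(
        "stage=fit proteins_fit=%d binders=%d", len(fits), len(binders)
    )

    # --- binder overlap -----------------------------------------------------
    kd_max = float(cfg["enrichment"]["kd_max"])
    sets: Dict[str, Dict[str, float]] = {}
    for probe, group in binders.loc[binders["kd_app_uM"] < kd_max].groupby("probe"):
        sets[str(probe)] = dict(zip(group["protein_id"], group["kd_app_uM"]))
    if len(sets) >= 2:
        _stage("overlap")
        overlap = dr.binder_overlap(sets, mode="all")
        outputs["overlap"] = outdir / "binder_overlap.tsv"
        kio.write_results(overlap, outputs["overlap"], "overlap")

    # --- differential -------------------------------------------------------
    matrix = diff.build_intensity_matrix(table)
    matrix = diff.filter_min_replicates(matrix, min_n=2)
    matrix = diff.median_normalize(matrix)
    dcfg = cfg["differential"]
    if dcfg["enabled"] and all(p in set(matrix.samples["probe"]) for p in dcfg["contrast"]):
        _stage("differential")
        res = diff.moderated_test(
            matrix,
            contrast=tuple(dcfg["contrast"]),
            fc_threshold=float(dcfg["fc_threshold"]),
            p_threshold=float(dcfg["p_threshold"]),
            mode=str(dcfg["mode"]),
        )
        outputs["differential"] = outdir / "differential.tsv"
        kio.write_results(res, outputs["differential"], "differential")

    # --- ANOVA + clustering -------------------------------------------------
    acfg = cfg["anova"]
    can_anova = (
        acfg["enabled"]
        and matrix.samples["probe"].nunique() >= 2
        and matrix.samples["fraction"].nunique() >= 2
        and matrix.samples["metal"].nunique() >= 2
    )
    if can_anova:
        _stage("anova")
        completed = diff.minprob_impute(
            matrix,
            q=float(acfg["impute_q"]),
            tune_sigma=float(acfg["tune_sigma"]),
            rng=stage_seed(seed, "impute"),
        )
        anova = diff.three_way_anova(completed, fdr=float(acfg["fdr"]))
        outputs["anova"] = outdir / "anova.tsv"
        kio.write_results(anova, outputs["anova"], "anova")
        selected = anova.loc[anova["compound_specific"], "protein_id"]
        if len(selected) >= 2:
            clust = diff.cluster_heatmap_input(completed.values.loc[selected])
            outputs["cluster_z"] = outdir / "cluster_zscores.tsv"
            clust.zscores.loc[clust.row_order, clust.col_order].to_csv(
                outputs["cluster_z"], sep="\t"
            )

    # --- enrichment ---------------------------------------------------------
    ecfg = cfg["enrichment"]
    if ecfg["enabled"]:
        query = binders.loc[
            (binders["probe"] == ecfg["probe"])
            & (binders["fraction"] == ecfg["fraction"])
            & (binders["metal"] == ecfg["metal"])
            & (binders["kd_app_uM"] < kd_max),
            "protein_id",
        ].tolist()
        universe = sorted(table.data.index.get_level_values("protein_id").unique())
        if query:
            _stage("enrichment")
            size = min(int(ecfg["set_size"]), len(universe))
            forced = min(int(ecfg["forced_overlap"]), size, len(query))
            gene_sets = sim.generate_gene_sets(
                universe,
                set_sizes=[size] * int(ecfg["n_random_sets"]),
                enrichment_spec=("engineered_target_set", query, forced),
                rng=stage_seed(seed, "simulate_genesets"),
            )
            outputs["gene_sets"] = outdir / "gene_sets.gmt"
            kio.write_gmt(gene_sets, outputs["gene_sets"])
            ora = enr.run_ora(query, gene_sets, universe)
            outputs["enrichment"] = outdir / "enrichment.tsv"
            kio.write_results(ora, outputs["enrichment"], "enrichment")

    # --- pyrophospho candidate screen ---------------------------------------
    pcfg = cfg["pyroscreen"]
    if pcfg["enabled"]:
        _stage("pyroscreen")
        n_seq = min(200, len(table.data.index.get_level_values("protein_id").unique()))
        records, seq_truth = sim.generate_cohort(
            n_seq,
            in_disorder_rate=float(pcfg["in_disorder_rate"]),
            out_disorder_rate=float(pcfg["out_disorder_rate"]),
            rng=stage_seed(seed, "simulate_sequences"),
        )
        outputs["sequences"] = outdir / "sequences.fasta"
        kio.write_fasta(records, outputs["sequences"])
        outputs["sequence_truth"] = outdir / "sequences_truth.tsv"
        seq_truth.to_csv(outputs["sequence_truth"], sep="\t", index=False)
        candidates, funnel = pyro.run_screen(
            records, window=int(pcfg["window"]), threshold=float(pcfg["threshold"])
        )
        outputs["candidates"] = outdir / "candidates.tsv"
        kio.write_results(candidates, outputs["candidates"], "candidates")
        manifest["funnel"] = funnel

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["outputs"] = {name: str(path) for name, path in outputs.items()}
    manifest["digests"] = {name: _digest(path) for name, path in outputs.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
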
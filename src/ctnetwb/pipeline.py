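"""End-to-end orchestration: simulate -> score -> networks -> association.

Every stage materialises its outputs to disk (TSV/CSV) so stages are
independently inspectable and resumable, and a JSON manifest records the
config snapshot, per-stage row counts and warnings. Identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .association import WellbeingTopologyModel
from .behavior import score_table, describe_cohort
from .omst import omst_threshold, write_binary_network
from .simnet import build_similarity_matrix, write_similarity_matrix
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .thickness import (
    ParcelTable,
    default_parcel_table,
    filter_parcels,
    mean_cortical_thickness,
    read_parcel_table,
    read_subject_thickness,
)
from .topology import compute_all_metrics

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "exclusion_report",
    "compute_network_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str
    input_dir: str | None = None  # real-input mode: thickness/ + behavior.csv
    simulation: SimulationConfig | None = None  # synthetic mode
    parcel_table_path: str | None = None  # default: bundled 32-parcel table
    min_vertices: int = 50
    item_offset: int = 0
    subscale_map: dict | None = None
    n_bins: int = 30
    distance_transform: str = "reciprocal"
    fdr_q: float = 0.05
    pool_metrics: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        synthetic = self.simulation is not None
        real = self.input_dir is not None
        if synthetic == real:
            raise ValueError(
                "exactly one of synthetic mode (simulation) and real-input "
                "mode (input_dir) must be configured"
            )
        if synthetic and self.seed is not None:
            self.simulation.seed = self.seed

    @classmethod
    def from_file(cls, path: str, output_dir: str | None = None) -> "PipelineConfig":
        data = _load_config_mapping(path)
        if output_dir is not None:
            data["output_dir"] = output_dir
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig.from_mapping(data["simulation"])
        return cls(**data)


def _load_config_mapping(path: str) -> dict:
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    if str(path).endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    raise ValueError(f"config file {path!r} must be .toml or .yaml")


def exclusion_report(
    initial_n: int, exclusions: list[tuple[str, int]]
) -> tuple[int, list[str]]:
    """Final sample size after listed exclusions, with one log line each."""
    if initial_n < 0 or any(c < 0 for _, c in exclusions):
        raise ValueError("counts must be nonnegative")
    final = initial_n - sum(c for _, c in exclusions)
    if final < 0:
        raise ValueError("exclusions exceed the initial sample")
    lines = [f"initial datasets: {initial_n}"]
    for reason, count in exclusions:
        lines.append(f"excluded ({reason}): {count}")
    lines.append(f"final sample: {final}")
    for line in lines:
        logger.info("%s", line)
    return final, lines


def compute_network_metrics(
    subjects,
    table: ParcelTable,
    n_bins: int = 30,
    distance_transform: str = "reciprocal",
    sink=None,
):
    """similarity -> OMST -> topology for a list of subjects.

    Returns ``(node_metrics, eglob)``: the long-format per-node metric table
    over all subjects and a per-subject global-efficiency table. ``sink``,
    if given, is called with ``(subject_id, similarity, network)`` for each
    subject (the pipeline uses it to materialise intermediates).
    """
    metric_frames = []
    eglob_rows = []
    for subject in subjects:
        sim = build_similarity_matrix(subject, table, n_bins=n_bins)
        net = omst_threshold(sim, transform=distance_transform)
        result = compute_all_metrics(net)
        metric_frames.append(result.node_table)
        eglob_rows.append({"subject_id": subject.subject_id, "value": result.eglob})
        if sink is not None:
            sink(subject.subject_id, sim, net)
    return (
        pd.concat(metric_frames, ignore_index=True),
        pd.DataFrame(eglob_rows),
    )


def _load_real_inputs(config: PipelineConfig, table: ParcelTable):
    tdir = os.path.join(config.input_dir, "thickness")
    paths = sorted(
        os.path.join(tdir, f) for f in os.listdir(tdir) if f.endswith(".tsv")
    )
    subjects = [read_subject_thickness(p, table) for p in paths]
    behavior = pd.read_csv(os.path.join(config.input_dir, "behavior.csv"))
    return subjects, behavior


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "warnings": []}

    # ---- stage: parcel table -------------------------------------------------
    stage = "parcels"
    try:
        if config.simulation is not None:
            raw_table = config.simulation.parcel_table()
        elif config.parcel_table_path:
            raw_table = read_parcel_table(config.parcel_table_path)
        else:
            raw_table = default_parcel_table()
        table = filter_parcels(raw_table, min_vertices=config.min_vertices)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {
        "n_parcels_input": raw_table.n_parcels,
        "n_parcels_retained": table.n_parcels,
    }

    # ---- stage: inputs (simulate or load) ------------------------------------
    stage = "inputs"
    try:
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
            write_cohort(cohort, os.path.join(out, "cohort"))
            retained = set(table.names)
            subjects = [
                type(s)(s.subject_id, {k: v for k, v in s.values.items() if k in retained})
                for s in cohort.thickness
            ]
            behavior = cohort.behavior.merge(cohort.covariates, on="subject_id")
        else:
            subjects, behavior = _load_real_inputs(config, table)
        for s in subjects:
            s.validate(table)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {"n_subjects": len(subjects), "n_parcels": table.n_parcels}

    # ---- stage: scoring ------------------------------------------------------
    stage = "score"
    try:
        scores = score_table(
            behavior, subscale_map=config.subscale_map, item_offset=config.item_offset
        )
        scores.to_csv(os.path.join(out, "scores.csv"), index=False)
        covariates = behavior[
            ["subject_id", "age", "sex", "education_years", "icv_mm3"]
        ].copy()
        covariates["mean_ct_mm"] = [mean_cortical_thickness(s) for s in subjects]
        covariates.to_csv(os.path.join(out, "covariates.csv"), index=False)
        desc, corr = describe_cohort(scores, covariates)
        desc.to_csv(os.path.join(out, "descriptives.tsv"), sep="\t")
        corr.to_csv(os.path.join(out, "correlations.tsv"), sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {"n_scored": len(scores)}

    # ---- stage: networks + topology ------------------------------------------
    stage = "networks"
    simdir = os.path.join(out, "similarity")
    netdir = os.path.join(out, "networks")
    os.makedirs(simdir, exist_ok=True)
    os.makedirs(netdir, exist_ok=True)
    n_omsts = []

    def sink(subject_id, sim, net):
        write_similarity_matrix(sim, os.path.join(simdir, f"{subject_id}.tsv"))
        write_binary_network(
            net,
            os.path.join(netdir, f"{subject_id}.tsv"),
            curve_path=os.path.join(netdir, f"{subject_id}_gce.csv"),
        )
        n_omsts.append(net.n_omsts_selected)
        if sim.n_degenerate_pairs:
            manifest["warnings"].append(
                f"{subject_id}: {sim.n_degenerate_pairs} degenerate pairs"
            )

    try:
        metrics, eglob = compute_network_metrics(
            subjects,
            table,
            n_bins=config.n_bins,
            distance_transform=config.distance_transform,
            sink=sink,
        )
        metrics.to_csv(os.path.join(out, "metrics.tsv"), sep="\t", index=False)
        eglob.to_csv(os.path.join(out, "eglob.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {
        "n_networks": len(eglob),
        "n_metric_rows": len(metrics),
        "mean_omsts_selected": float(np.mean(n_omsts)) if n_omsts else None,
    }

    # ---- stage: association --------------------------------------------------
    stage = "associate"
    try:
        model = WellbeingTopologyModel(metrics, scores, covariates, eglob=eglob)
        results = model.fit(q=config.fdr_q, pool_metrics=config.pool_metrics)
        results.table.to_csv(os.path.join(out, "association.tsv"), sep="\t", index=False)
        if results.eglob_table is not None:
            results.eglob_table.to_csv(
                os.path.join(out, "association_eglob.tsv"), sep="\t", index=False
            )
        effects = results.dimension_effect_sizes()
        effects.to_csv(os.path.join(out, "effect_sizes.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "summary.txt"), "w") as fh:
            fh.write(results.summary() + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {
        "n_fits": len(results.table),
        "n_significant": int(results.table["significant"].sum()),
    }

    cfg = asdict(config)
    if config.simulation is not None:
        cfg["simulation"] = config.simulation.to_mapping()
    manifest["config"] = cfg
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
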
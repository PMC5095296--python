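"""End-to-end pipeline: simulate -> preprocess -> correlate -> align ->
identify -> link, driven by one config, with a machine-readable report.

The report collects, per stage, the quantities that diagnose which of the
three population structures the data exhibit: the across-epoch correlation
R^2, the epoch-preference dip test, the alignment index with its random-
subspace null percentile, the identification objective and variance table,
and the preparatory-to-movement linkage R^2 with its shuffle p.  A simple
signature-based classification (thresholds are conveniences of this
artifact, clearly labelled in the report) names the structure:

* overlapping         — correlation structure preserved (R^2 > 0.5);
* orthogonal_linked   — otherwise, if the linkage beats its shuffle null
                        (p < 0.01);
* independent         — otherwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import generator
from .alignment import random_alignment_null
from .correlation import correlation_analysis, epoch_preference_analysis
from .generator import GeneratorParams, Timeline, make_scenario
from .identification import identify_subspaces, project, subspace_epoch_variance
from .linkage import link_analysis
from .population import (
    MOVEMENT_EPOCH,
    PREPARATORY_EPOCH,
    EpochDef,
    PopulationResponse,
    extract_epoch,
    preprocess,
    read_dataset,
    write_dataset,
)

log = logging.getLogger("orthospace")

CLASSIFICATION_THRESHOLDS = {
    "alignment_percentile": 0.05,
    "link_shuffle_p": 0.01,
    "correlation_r2_split": 0.5,
}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serialized verbatim into the report."""

    seed: int = 0
    scenario: str = "orthogonal_linked"
    input_path: str = None          # analyse a dataset on disk instead of simulating
    n_neurons: int = 127
    n_conditions: int = 8
    d_align: int = 2
    d_prep: int = 2
    d_move: int = 2
    n_null: int = 10_000
    n_shuffles: int = 1000
    n_boot: int = 1000
    n_boot_dip: int = 10_000
    restarts: int = 20
    soft_norm_offset: float = 5.0
    out_dir: str = None
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def generator_params(self) -> GeneratorParams:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("n_neurons", self.n_neurons)
        if "targets" not in kwargs:
            kwargs["targets"] = generator.make_targets(self.n_conditions)
        return GeneratorParams(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def classify(alignment_percentile, link_p, corr_r2) -> dict:
    """Name the population structure from the three stage statistics."""
    th = CLASSIFICATION_THRESHOLDS
    if corr_r2 > th["correlation_r2_split"]:
        label = "overlapping"
    elif link_p < th["link_shuffle_p"]:
        label = "orthogonal_linked"
    else:
        label = "independent"
    return {
        "label": label,
        "signatures": {
            "low_alignment_percentile": bool(alignment_percentile < th["alignment_percentile"]),
            "significant_link": bool(link_p < th["link_shuffle_p"]),
            "preserved_correlation": bool(corr_r2 > th["correlation_r2_split"]),
            "orthogonal_but_linked": bool(
                alignment_percentile < th["alignment_percentile"]
                and link_p < th["link_shuffle_p"]
            ),
        },
        "thresholds_note": "classification thresholds are conveniences of this "
        "software, not claims from the underlying science",
        "thresholds": th,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    t_start = time.perf_counter()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def save_csv(name, array):
        if out_dir is None:
            return
        path = out_dir / name
        np.savetxt(path, np.asarray(array), delimiter=",")
        artifacts[name] = _sha256(path)

    # -- data ---------------------------------------------------------------
    _stage("data")
    if config.input_path:
        resp = read_dataset(config.input_path)
        truth = None
    else:
        params = config.generator_params()
        resp, truth = make_scenario(config.scenario, params)
        if out_dir:
            write_dataset(resp, out_dir / "data.h5")
            artifacts["data.h5"] = _sha256(out_dir / "data.h5")

    # -- preprocessing & epochs ----------------------------------------------
    _stage("preprocess")
    pre = preprocess(resp, offset=config.soft_norm_offset)
    prep = extract_epoch(pre, PREPARATORY_EPOCH)
    move = extract_epoch(pre, MOVEMENT_EPOCH)
    all_data = pre.rates.reshape(pre.n_neurons, -1)
    all_centered = all_data - all_data.mean(axis=1, keepdims=True)
    c_full = all_centered @ all_centered.T / (all_centered.shape[1] - 1)

    # -- correlation structure -------------------------------------------------
    _stage("correlation")
    corr = correlation_analysis(prep, move, n_boot=config.n_boot, seed=config.seed)
    save_csv("corr_prep.csv", corr.corr_prep)
    save_csv("corr_move.csv", corr.corr_move)
    pref = epoch_preference_analysis(
        pre, PREPARATORY_EPOCH, MOVEMENT_EPOCH,
        n_boot=config.n_boot_dip, seed=config.seed,
    )

    # -- alignment ---------------------------------------------------------------
    _stage("alignment")
    null = random_alignment_null(
        c_full, prep.covariance, move.covariance,
        d=config.d_align, n_samples=config.n_null, seed=config.seed,
    )
    align_prep = null["prep"]

    # -- identification ----------------------------------------------------------
    _stage("identification")
    pair = identify_subspaces(
        prep.covariance, move.covariance,
        d_prep=config.d_prep, d_move=config.d_move,
        restarts=config.restarts, seed=config.seed,
    )
    var_table = subspace_epoch_variance(
        pair, prep, move, c_full=c_full,
        n_samples=min(config.n_null, 1000), seed=config.seed,
    )
    save_csv("variance_table.csv", var_table["table"])

    # -- linkage ------------------------------------------------------------------
    _stage("linkage")
    prep_traj = project(pre, pair.Q_prep)
    move_traj = project(pre, pair.Q_move)
    link = link_analysis(
        prep_traj, move_traj, pre.time_ms,
        target_onset_ms=pre.events["target_onset_ms"],
        move_onset_ms=pre.events["move_onset_ms"],
        n_shuffles=config.n_shuffles, seed=config.seed,
    )

    # -- report --------------------------------------------------------------------
    report = {
        "config": dataclasses.asdict(config),
        "scenario_truth": None if truth is None else truth["kind"],
        "correlation": {
            "r_squared": corr.r_squared,
            "ci95": list(corr.r_squared_ci),
            "sd": corr.r_squared_sd,
            "excluded_neurons": corr.excluded_neurons.tolist(),
        },
        "epoch_preference": {
            "dip": pref.dip_statistic,
            "p": pref.p_value,
        },
        "alignment": {
            "index": align_prep.index,
            "d": align_prep.d,
            "null_median": align_prep.null_median,
            "null_ci95": list(align_prep.null_ci95),
            "percentile": align_prep.percentile,
            "p_one_tailed": align_prep.p_one_tailed,
            "index_move_vs_prep": null["move"].index,
        },
        "identification": {
            "objective": pair.objective,
            "converged": pair.converged,
            "iterations": int(pair.objective_trace.size),
            "variance_table_pct": var_table["table"].tolist(),
            "p_prep": var_table["p_prep"],
            "p_move": var_table["p_move"],
        },
        "link": {
            "r_squared": link.r_squared,
            "r_squared_loocv": link.r_squared_loocv,
            "shuffle_p": link.p_value,
            "shuffle_median": link.shuffle_median,
            "shuffle_ci95": list(link.shuffle_ci95),
        },
        "classification": classify(align_prep.percentile, link.p_value, corr.r_squared),
        "artifacts": artifacts,
        "runtime_s": time.perf_counter() - t_start,
    }
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def _setup_logging() -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s %(name)s %(message)s",
    )
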
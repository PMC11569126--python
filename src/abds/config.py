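"""Suite configuration and the end-to-end pipeline driver.

A :class:`SuiteConfig` nests the simulation, missingness, imputation,
detection and heatmap parameters plus one global seed.  The pipeline
fans the global seed out to per-stage seeds by fixed offsets so every
stage is individually reproducible, and records a manifest of produced
files with the producing step and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import evaluation as ev
from . import imputation as imp
from . import io as aio
from . import signatures as sig
from . import unihm
from .matrix import LOG2, to_log2
from .simulation import (MissingnessConfig, SimplexSimConfig,
                         inject_missingness, simulate_dataset)

__all__ = ["SuiteConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# per-stage seed offsets fanned out from the global seed
STAGE_OFFSETS = {"simulate": 0, "missingness": 1000, "impute": 2000}


@dataclass
class SuiteConfig:
    """Serializable configuration for the full pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    simulation: SimplexSimConfig = field(default_factory=SimplexSimConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    imputation_method: str = "mgpi"
    imputation_params: dict = field(default_factory=dict)
    detection_enabled: bool = True
    detection_method: str = "ecot"
    detection_direction: str = "DSG"
    detection_rule: str = "top_n"
    detection_value: float = 200
    heatmap_floor: float | None = None
    fpr_max: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "SuiteConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in data and isinstance(data["simulation"], dict):
            _check_keys(data["simulation"], SimplexSimConfig, "simulation")
            data["simulation"] = SimplexSimConfig(**data["simulation"])
        if "missingness" in data and isinstance(data["missingness"], dict):
            _check_keys(data["missingness"], MissingnessConfig, "missingness")
            data["missingness"] = MissingnessConfig(**data["missingness"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SuiteConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(data: dict, cls, name: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")


def run_pipeline(cfg: SuiteConfig, out_dir: str) -> dict:
    """Run simulate -> inject -> impute -> detect -> heatmap -> evaluate.

    Returns the manifest (also written to ``manifest.json``): every
    artifact with its producing stage and resolved parameters.  Any
    stage error aborts with the stage name; the partial manifest is
    still written.
    """
    os.makedirs(out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict = {"seed": cfg.seed, "config": cfg.to_dict(), "artifacts": []}

    def emit(stage: str, path: str, **params) -> None:
        manifest["artifacts"].append({"stage": stage,
                                      "path": os.path.basename(path),
                                      "params": params})

    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(cfg.simulation,
                                      seed=cfg.seed + STAGE_OFFSETS["simulate"])
        m, g, truth = simulate_dataset(sim_cfg)
        logger.info("simulated %d genes x %d samples (K=%d)",
                    m.n_genes, m.n_samples, sim_cfg.K)
        p = os.path.join(out_dir, "matrix.tsv")
        aio.write_matrix(m, p)
        emit(stage, p, K=sim_cfg.K, seed=sim_cfg.seed)
        p = os.path.join(out_dir, "labels.tsv")
        aio.write_labels(g, p)
        emit(stage, p)
        p = os.path.join(out_dir, "gene_truth.tsv")
        aio.write_table(truth, p)
        emit(stage, p)

        stage = "missingness"
        miss_cfg = dataclasses.replace(cfg.missingness,
                                       seed=cfg.seed + STAGE_OFFSETS["missingness"])
        m_log = to_log2(m, imp.LOG_PSEUDO)
        masked, omega = inject_missingness(m_log, miss_cfg)
        p = os.path.join(out_dir, "masked.tsv")
        aio.write_matrix(masked, p)
        emit(stage, p, rate=miss_cfg.overall_rate, mar=miss_cfg.mar_proportion,
             seed=miss_cfg.seed)
        p = os.path.join(out_dir, "omega.tsv")
        aio.write_table(omega, p)
        emit(stage, p)

        stage = "impute"
        kwargs = dict(cfg.imputation_params)
        if cfg.imputation_method == "ppca":
            kwargs.setdefault("seed", cfg.seed + STAGE_OFFSETS["impute"])
        result = imp.impute(masked, cfg.imputation_method, g=g, **kwargs)
        p = os.path.join(out_dir, "imputed.tsv")
        aio.write_matrix(result.matrix, p)
        emit(stage, p, method=result.method, **{k: v for k, v in
                                                result.params.items()})

        stage = "evaluate-imputation"
        report = {
            "rmse": ev.rmse(result, omega),
            "nrmse": ev.nrmse(result, omega),
            "n_omega": len(omega),
        }
        p = os.path.join(out_dir, "imputation_report.json")
        with open(p, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        emit(stage, p, method=cfg.imputation_method)

        if cfg.detection_enabled:
            stage = "detect"
            scores = sig.score_genes(result.matrix, g,
                                     direction=cfg.detection_direction,
                                     method=cfg.detection_method)
            p = os.path.join(out_dir, "scores.tsv")
            aio.write_table(scores, p)
            emit(stage, p, method=cfg.detection_method,
                 direction=cfg.detection_direction)
            selected = sig.detect(scores, cfg.detection_rule, cfg.detection_value)
            p = os.path.join(out_dir, "selected.tsv")
            aio.write_table(selected, p)
            emit(stage, p, rule=cfg.detection_rule, value=cfg.detection_value)

            stage = "heatmap"
            layout = unihm.build_layout(result.matrix, g, selected,
                                        floor=cfg.heatmap_floor)
            for p in unihm.export_layout(layout,
                                         os.path.join(out_dir, "heatmap")):
                emit(stage, p, floor=cfg.heatmap_floor)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out_dir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
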
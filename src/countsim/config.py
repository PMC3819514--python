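"""Run configuration, validation, logging and tabular file I/O.

A run is described by one YAML file with three optional blocks::

    seed: 1
    model:            # ModelConfig fields; omitted fields take the
      rho: 0.8        # reference defaults (D=20000, l=5, D_gm=10, ...)
    pipelines:
      - {name: MVN-GC, identity: true}
      - {name: 50K-100K, cov: 0.05, alpha: 2.0, beta: 3.75}
      - {name: 5M-5M+50K, cov: 0.05, total_range: [5.0e6, 5.05e6]}
    plan:
      sample_sizes: [60, 120, 180]
      n_t: 3000
      replicates: 10000
      d: 10
      rules: [LDA, 3NN, RBF_SVM]
      selection: TTEST

Unknown keys raise a descriptive error naming the key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import ClassifierSpec
from .experiment import ExperimentPlan
from .model import ModelConfig, ParameterError
from .sequencing import PipelineConfig

__all__ = ["RunConfig", "load_config", "dump_config", "setup_logging",
           "write_recovery_table", "write_results", "write_density",
           "write_manifest"]

log = logging.getLogger("countsim")


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("countsim")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class RunConfig:
    """Validated top-level configuration of one simulation run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    pipelines: list[PipelineConfig] = field(default_factory=lambda: [PipelineConfig.mvn_gc()])
    plan: ExperimentPlan = None  # filled in __post_init__
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.plan is None:
            self.plan = ExperimentPlan(model=self.model, pipelines=self.pipelines,
                                       seed=self.seed)


def _take(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_pipeline(entry: dict, idx: int) -> PipelineConfig:
    where = f"pipelines[{idx}]"
    _take(entry, {"name", "cov", "alpha", "beta", "total_range", "identity"}, where)
    if "name" not in entry:
        raise ParameterError(f"{where}: a pipeline needs a name")
    tr = entry.get("total_range")
    return PipelineConfig(
        name=entry["name"], cov=float(entry.get("cov", 0.05)),
        alpha=entry.get("alpha"), beta=entry.get("beta"),
        target_total_range=tuple(map(float, tr)) if tr else None,
        identity=bool(entry.get("identity", False)))


def _from_mapping(raw: dict) -> RunConfig:
    _take(raw, {"model", "pipelines", "plan", "seed", "out_dir", "log_level"}, "config")
    model_block = dict(raw.get("model") or {})
    model_fields = {f.name for f in dataclasses.fields(ModelConfig)}
    _take(model_block, model_fields, "model")
    model = ModelConfig(**model_block)

    entries = raw.get("pipelines")
    pipelines = ([_parse_pipeline(dict(e), i) for i, e in enumerate(entries)]
                 if entries else [PipelineConfig.mvn_gc()])

    plan_block = dict(raw.get("plan") or {})
    _take(plan_block, {"sample_sizes", "n_t", "replicates", "d", "rules",
                       "selection", "coupled", "subclass_mode",
                       "svm_C", "svm_gamma"}, "plan")
    d = int(plan_block.get("d", 10))
    selection = plan_block.get("selection", "TTEST")
    rules = plan_block.get("rules", [])
    specs = [ClassifierSpec(rule=r, d=d, selection=selection,
                            svm_C=float(plan_block.get("svm_C", 1.0)),
                            svm_gamma=plan_block.get("svm_gamma"))
             for r in rules] or [ClassifierSpec(rule=None, d=d, selection=selection)]
    seed = int(raw.get("seed", 0))
    plan = ExperimentPlan(
        model=model, pipelines=pipelines,
        sample_sizes=tuple(plan_block.get("sample_sizes", (60, 120, 180))),
        n_t=int(plan_block.get("n_t", 3000)),
        replicates=int(plan_block.get("replicates", 10000)),
        specs=tuple(specs), seed=seed,
        coupled=bool(plan_block.get("coupled", True)),
        subclass_mode=plan_block.get("subclass_mode", "balanced"))
    return RunConfig(model=model, pipelines=pipelines, plan=plan, seed=seed,
                     out_dir=str(raw.get("out_dir", "results")),
                     log_level=str(raw.get("log_level", "INFO")))


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if empty)."""
    if text is None:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    return _from_mapping(raw)


def dump_config(cfg: RunConfig) -> str:
    """YAML text whose reload reproduces ``cfg`` (round-trip identity)."""
    plan = cfg.plan
    rules = [s.rule for s in plan.specs if s.rule is not None]
    doc = {
        "seed": cfg.seed,
        "out_dir": cfg.out_dir,
        "log_level": cfg.log_level,
        "model": dataclasses.asdict(cfg.model),
        "pipelines": [
            {k: v for k, v in {
                "name": p.name, "identity": p.identity or None,
                "cov": None if p.identity else p.cov,
                "alpha": p.alpha, "beta": p.beta,
                "total_range": list(p.target_total_range) if p.target_total_range else None,
            }.items() if v is not None}
            for p in cfg.pipelines],
        "plan": {
            "sample_sizes": list(plan.sample_sizes), "n_t": plan.n_t,
            "replicates": plan.replicates, "d": plan.specs[0].d,
            "selection": plan.specs[0].selection, "rules": rules,
            "coupled": plan.coupled, "subclass_mode": plan.subclass_mode,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def write_recovery_table(table: pd.DataFrame, path: str | Path,
                         decimals: int = 4) -> None:
    """Recovery percentages as CSV with fixed decimal formatting."""
    if table.empty:
        raise ParameterError(f"refusing to write an empty table to {path}")
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    out.to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Per-replicate records as CSV."""
    if results.empty:
        raise ParameterError(f"refusing to write empty results to {path}")
    results.to_csv(path, index=False)


def write_density(density, path: str | Path) -> None:
    density.to_frame().to_csv(path, index=False)


def write_manifest(cfg: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """JSON manifest: resolved config, seed and a config hash."""
    text = dump_config(cfg)
    doc = {
        "config": yaml.safe_load(text),
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": cfg.seed,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
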
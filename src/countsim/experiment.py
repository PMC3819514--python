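"""Monte-Carlo harness: marker recovery tables and true-error densities.

Each replicate draws a fresh feature-label distribution realisation
(annotation), a training set of size ``n``, and -- when a classification
rule is evaluated -- a large balanced independent test set, pushes both
through the chosen measurement pipeline, performs t-test feature selection,
and records how many of the global markers appear among the top ``d``
features plus the true error of each trained rule on the test set.

Replicates are seeded independently from the root seed (one
``SeedSequence`` child per replicate), so they can be run in any order or
in parallel and merge into identical tables.  Within a replicate the
expression stream is independent of the pipeline stream: matched pipelines
at the same (n, replicate) see the same underlying expression draw
(coupled comparisons); pass ``coupled=False`` to break this.

Test sets are generated only at the selected features.  Counts are
conditionally independent across genes given the depth, so restricting the
test draw to the ``d`` selected columns is an exact marginal sample and
avoids materialising an ``n_t x 20,000`` matrix per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, t_scores, select_top_features, \
    train_classifier, true_error
from .model import ModelConfig, ParameterError, annotate_features, \
    sample_expression
from .sequencing import PipelineConfig, technical_noise_sd, transform_matrix

__all__ = [
    "ExperimentPlan",
    "ErrorDensity",
    "replicate_rng",
    "run_replicate",
    "run_recovery_replicate",
    "run_recovery_cell",
    "run_experiment",
    "tabulate_recovery",
    "recovery_table",
    "estimate_error_density",
    "rms_bound",
]

log = logging.getLogger(__name__)

RECOVERY_BINS = ("<8", "8", "9", "10")

# stream tags keeping the expression, pipeline and cell RNG streams disjoint
_STREAM_EXPR = 101
_STREAM_PIPE = 202
_STREAM_CELL = 303


@dataclass
class ExperimentPlan:
    """The full factorial design of one simulation run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    pipelines: list[PipelineConfig] = field(default_factory=lambda: [PipelineConfig.mvn_gc()])
    sample_sizes: tuple[int, ...] = (60, 120, 180)
    n_t: int = 3000
    replicates: int = 10000
    specs: tuple[ClassifierSpec, ...] = (ClassifierSpec(rule=None, d=10, selection="TTEST"),)
    seed: int = 0
    coupled: bool = True
    subclass_mode: str = "balanced"

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_t < 1:
            raise ParameterError("replicates and n_t must be >= 1")
        if not self.pipelines or not self.specs:
            raise ParameterError("need at least one pipeline and one classifier spec")
        names = [p.name for p in self.pipelines]
        if len(set(names)) != len(names):
            raise ParameterError(f"pipeline names must be unique, got {names}")


def replicate_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for one replicate/stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def run_replicate(model: ModelConfig, pipeline: PipelineConfig, n: int,
                  specs, n_t: int, rng_expr: np.random.Generator,
                  rng_pipe: np.random.Generator,
                  subclass_mode: str = "balanced") -> tuple[int, dict[str, float]]:
    """One full replicate: returns (recovery count, {rule: true error}).

    The recovery count is the number of global markers among the top-``d``
    t-ranked features (with ``d`` from the first TTEST spec); selection
    schemes that use all features or the global markers directly recover
    all of them by convention.
    """
    specs = list(specs)
    cfg = model
    ann = annotate_features(cfg, rng_expr)
    expr = sample_expression(cfg, n, rng_expr, annotation=ann,
                             subclass_mode=subclass_mode, dtype=np.float32)
    if pipeline.identity:
        train = expr.X.astype(np.float64)
    else:
        counts, _, _ = transform_matrix(expr.X, pipeline, rng_pipe, cfg,
                                        dtype=np.float32)
        train = counts.astype(np.float64)

    global_idx = ann.global_idx
    scores = None
    recovery = cfg.D_gm
    selections: dict[tuple[str, int], np.ndarray] = {}
    for spec in specs:
        key = (spec.selection, spec.d)
        if key in selections:
            continue
        if spec.selection == "NONE_GLOBAL":
            selections[key] = global_idx
        else:
            if scores is None:
                scores = t_scores(train, expr.y)
            sel = select_top_features(scores, spec.d)
            selections[key] = sel
            if spec.d == cfg.D_gm:
                recovery = int(np.isin(sel, global_idx).sum())
            elif spec.d == cfg.D:
                recovery = cfg.D_gm

    errors: dict[str, float] = {}
    rule_specs = [s for s in specs if s.rule is not None]
    if rule_specs:
        needed = np.unique(np.concatenate([selections[(s.selection, s.d)]
                                           for s in rule_specs]))
        test_expr = sample_expression(cfg, n_t, rng_expr, annotation=ann,
                                      stratified=True, subclass_mode=subclass_mode,
                                      feature_subset=needed, dtype=np.float32)
        if pipeline.identity:
            test = test_expr.X.astype(np.float64)
        else:
            tc, _, _ = transform_matrix(test_expr.X, pipeline, rng_pipe, cfg,
                                        dtype=np.float32)
            test = tc.astype(np.float64)
        pos = {j: i for i, j in enumerate(needed)}
        for spec in rule_specs:
            sel = selections[(spec.selection, spec.d)]
            clf = train_classifier(train, expr.y, spec, global_idx=global_idx)
            cols = np.array([pos[j] for j in sel])
            errors[spec.rule] = true_error(clf, test[:, cols], test_expr.y,
                                           columns=sel)
    return recovery, errors


def run_recovery_replicate(model: ModelConfig, pipeline: PipelineConfig, n: int,
                           d: int, rng: np.random.Generator,
                           subclass_mode: str = "balanced") -> int:
    """Marker recovery only (no test set, no classifier): the fast path.

    Works on bare arrays (technical noise folded into the Gaussian draw,
    counts never wrapped in a dataset) but is distributionally identical to
    the compositional route; see :func:`sample_counts_direct`.
    """
    if pipeline.identity:
        ds = sample_expression(model, n, rng, subclass_mode=subclass_mode,
                               dtype=np.float32)
        mat, y = ds.X, ds.y
    else:
        pipeline = pipeline.resolve(model)
        v = technical_noise_sd(pipeline.cov, model.m0, model.m1) ** 2
        ds = sample_expression(model, n, rng, subclass_mode=subclass_mode,
                               dtype=np.float32, extra_var=v)
        s = rng.uniform(pipeline.alpha, pipeline.beta, n)
        np.exp(ds.X, out=ds.X)
        mean = ds.X.astype(np.float64)
        mean *= s[:, None]
        mat, y = rng.poisson(mean), ds.y
    scores = t_scores(mat, y)
    sel = select_top_features(scores, d)
    return int((sel < model.D_gm).sum())  # global markers lead the ordering


def run_recovery_cell(model: ModelConfig, pipeline: PipelineConfig, n: int,
                      replicates: int, seed: int, d: int = 10,
                      pipe_index: int = 0,
                      subclass_mode: str = "balanced") -> np.ndarray:
    """Recovery counts for one (pipeline, n) cell over ``replicates`` runs."""
    pipeline = pipeline.resolve(model)
    out = np.empty(replicates, dtype=np.int64)
    for r in range(replicates):
        rng = replicate_rng(seed, _STREAM_CELL, pipe_index, n, r)
        out[r] = run_recovery_replicate(model, pipeline, n, d, rng,
                                        subclass_mode=subclass_mode)
    return out


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> pd.DataFrame:
    """Execute the full factorial design.

    Returns one row per (pipeline, n, replicate) with the recovery count
    and one error column per rule.  Matched pipelines share the expression
    stream within a replicate when ``plan.coupled``.
    """
    records = []
    rules = [s.rule for s in plan.specs if s.rule is not None]
    for n in plan.sample_sizes:
        for ip, pipe in enumerate(plan.pipelines):
            pipe = pipe.resolve(plan.model)
            for r in range(plan.replicates):
                expr_key = (_STREAM_EXPR, n, r) if plan.coupled else \
                    (_STREAM_EXPR, ip, n, r)
                rng_expr = replicate_rng(plan.seed, *expr_key)
                rng_pipe = replicate_rng(plan.seed, _STREAM_PIPE, ip, n, r)
                rec, errs = run_replicate(plan.model, pipe, n, plan.specs,
                                          plan.n_t, rng_expr, rng_pipe,
                                          subclass_mode=plan.subclass_mode)
                row = {"pipeline": pipe.name, "n": n, "replicate": r,
                       "recovery": rec}
                for rule in rules:
                    row[f"error_{rule}"] = errs.get(rule, np.nan)
                records.append(row)
            if progress:
                log.info("finished pipeline=%s n=%d (%d replicates)",
                         pipe.name, n, plan.replicates)
    return pd.DataFrame.from_records(records)


def tabulate_recovery(counts: np.ndarray, n_markers: int = 10) -> dict[str, float]:
    """Percentages of replicates recovering <8, 8, 9 and all markers."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ParameterError("no recovery counts to tabulate")
    if counts.min() < 0 or counts.max() > n_markers:
        raise ParameterError("recovery counts out of range")
    pct = 100.0 / counts.size
    return {
        "<8": float((counts < n_markers - 2).sum() * pct),
        str(n_markers - 2): float((counts == n_markers - 2).sum() * pct),
        str(n_markers - 1): float((counts == n_markers - 1).sum() * pct),
        str(n_markers): float((counts == n_markers).sum() * pct),
    }


def recovery_table(results: pd.DataFrame, n_markers: int = 10) -> pd.DataFrame:
    """Recovery-percentage table per (pipeline, n) from replicate records."""
    rows = []
    for (pipe, n), grp in results.groupby(["pipeline", "n"], sort=False):
        row = {"pipeline": pipe, "n": n}
        row.update(tabulate_recovery(grp["recovery"].to_numpy(), n_markers))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ErrorDensity:
    """Boundary-reflected Gaussian KDE of a true-error sample on [0, 1]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"error": self.grid, "density": self.density})


def estimate_error_density(errors, bandwidth: float | None = None,
                           grid_size: int = 513) -> ErrorDensity:
    """Kernel density estimate of the true-error distribution.

    A Gaussian kernel with a Silverman plug-in bandwidth, reflected at both
    boundaries of [0, 1] so the density integrates to one on the unit
    interval.
    """
    e = np.asarray(errors, dtype=np.float64)
    if e.size < 2:
        raise ParameterError("need at least two error values for a density")
    if bandwidth is None:
        sd = e.std(ddof=1)
        iqr = np.subtract(*np.percentile(e, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = max(0.9 * spread * e.size ** (-0.2), 1e-3)
    grid = np.linspace(0.0, 1.0, grid_size)
    pts = np.concatenate([e, -e, 2.0 - e])  # reflection at 0 and 1
    u = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (e.size * bandwidth * np.sqrt(2 * np.pi))
    return ErrorDensity(grid, dens, float(bandwidth), int(e.size))


def rms_bound(n_t: int) -> float:
    """Upper bound ``1/(2 sqrt(n_t))`` on the RMS between the hold-out
    error estimate and the true error."""
    if n_t < 1:
        raise ParameterError(f"n_t must be >= 1, got {n_t}")
    return 1.0 / (2.0 * np.sqrt(n_t))
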
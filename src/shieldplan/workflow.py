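"""End-to-end experiment runner on a synthetic cohort.

For every (phantom x shield window x planning model) cell: build the
per-scenario dose matrices on the planning grid, optimize dwell times,
rescale to the prescription on the fine nominal grid, evaluate dosimetric
indices under signed rotational/translational error scenarios, and emit
per-phantom index tables, cohort means, plan statistics, and paired
signed-rank comparisons between planning models.  Fully deterministic
for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dose import DoseMatrix, ScenarioSet, ScenarioSpec, SourceModel, build_dose_matrix
from .evaluate import (
    IndexReport,
    PlanStats,
    evaluate_plan,
    paired_signed_rank,
    plan_statistics,
    rescale_to_prescription,
)
from .optimize import (
    PenaltyConfig,
    RobustSolution,
    StructurePenalty,
    assemble_problem,
    default_penalties,
    solve,
    tune_target_weight,
    voxelwise_worstcase,
)
from .phantom import ApplicatorSpec, CohortSpec, CombinationSet, generate_phantom, rasterize_phantom, _draw_geometry

log = logging.getLogger("shieldplan.workflow")

KNOWN_MODELS = (
    "qpm",
    "qpm-r-rotation",
    "qpm-r-translation",
    "voxelwise-rotation",
    "voxelwise-translation",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, seedable description of one experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    shield_windows: Tuple[float, ...] = (180.0,)
    models: Tuple[str, ...] = ("qpm", "qpm-r-rotation", "qpm-r-translation")
    planning_rotation_offset: float = 5.0      # degrees, QPM-R rotation scenarios
    planning_translation_offset: float = 2.0   # mm, QPM-R translation scenarios
    eval_rotation_magnitudes: Tuple[float, ...] = (3.0, 5.0, 10.0)
    eval_translation_magnitudes: Tuple[float, ...] = (1.0, 2.0, 3.0)
    prescription: float = 10.0                 # Gy, CTV D90 target
    penalties: PenaltyConfig = field(default_factory=default_penalties)
    source: SourceModel = field(default_factory=SourceModel)
    lambda_worst: float = 1.0
    mean_weight: float = 1.0
    dwell_spacing: float = 5.0                 # mm
    angle_increment: float = 15.0              # degrees
    active_threshold: float = 0.5              # s
    tune_weights: bool = False
    significance_level: float = 0.05

    def __post_init__(self) -> None:
        if not self.shield_windows or not self.models:
            raise ValueError("need at least one shield window and one model")
        unknown = [m for m in self.models if m not in KNOWN_MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; known: {KNOWN_MODELS}")
        if any(m <= 0 for m in self.eval_rotation_magnitudes + self.eval_translation_magnitudes):
            raise ValueError("evaluation error magnitudes must be positive")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, float) and np.isinf(obj):
                return "inf"
            return obj
        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExperimentConfig":
        data = dict(data)
        if "cohort" in data:
            cohort = dict(data["cohort"])
            for key in ("tumor_angular_width_range", "tumor_length_range", "grid_extent"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            data["cohort"] = CohortSpec(**cohort)
        if "penalties" in data:
            structures = data["penalties"].get("structures", data["penalties"])
            data["penalties"] = PenaltyConfig({
                role: StructurePenalty(**{
                    k: (np.inf if v == "inf" else v) for k, v in pen.items()
                })
                for role, pen in structures.items()
            })
        if "source" in data:
            data["source"] = SourceModel(**data["source"])
        for key in ("shield_windows", "models", "eval_rotation_magnitudes",
                    "eval_translation_magnitudes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-cell planning
# ---------------------------------------------------------------------------

@dataclass
class PlanResult:
    phantom_index: int
    window: float
    model: str
    solution: RobustSolution
    dwell_times_rescaled: np.ndarray
    report: IndexReport
    stats: PlanStats
    failed: bool = False
    error: str = ""


def _scenario_set_for(model: str, config: ExperimentConfig) -> ScenarioSet:
    if model == "qpm":
        return ScenarioSet.nominal_only()
    if model in ("qpm-r-rotation", "voxelwise-rotation"):
        return ScenarioSet.rotation(config.planning_rotation_offset)
    if model in ("qpm-r-translation", "voxelwise-translation"):
        return ScenarioSet.translation(config.planning_translation_offset)
    raise ValueError(f"unknown model {model!r}")


def plan_cell(
    config: ExperimentConfig,
    phantom_index: int,
    window: float,
    model: str,
    planning_matrices: Optional[Dict[str, DoseMatrix]] = None,
) -> PlanResult:
    """Plan and evaluate one (phantom, shield window, model) cell."""
    applicator = ApplicatorSpec(window_width=window)
    combos = CombinationSet.build(applicator, config.dwell_spacing, config.angle_increment)
    geometry = _draw_geometry(config.cohort, phantom_index)
    plan_phantom = rasterize_phantom(geometry, config.cohort, applicator,
                                     config.cohort.planning_voxel)
    eval_phantom = rasterize_phantom(geometry, config.cohort, applicator,
                                     config.cohort.evaluation_voxel)

    scenarios = _scenario_set_for(model, config)
    cache = planning_matrices if planning_matrices is not None else {}
    mats = []
    for scen in scenarios:
        if scen.label not in cache:
            cache[scen.label] = build_dose_matrix(plan_phantom, combos, scen, config.source)
        mats.append(cache[scen.label])
    if model.startswith("voxelwise"):
        mats = [voxelwise_worstcase(mats)]

    problem = assemble_problem(mats, config.penalties,
                               config.lambda_worst, config.mean_weight)
    eval_key = "__eval_nominal__"
    if eval_key not in cache:
        cache[eval_key] = build_dose_matrix(eval_phantom, combos, ScenarioSpec(), config.source)
    eval_nominal = cache[eval_key]

    if config.tune_weights:
        tuned = tune_target_weight(problem, eval_nominal, config.prescription)
        problem = assemble_problem(mats, tuned.penalties,
                                   config.lambda_worst, config.mean_weight)
    solution = solve(problem)
    t_scaled = rescale_to_prescription(solution.dwell_times, eval_nominal,
                                       config.prescription)
    report = evaluate_plan(
        t_scaled, eval_phantom, combos, config.source,
        rotation_magnitudes=config.eval_rotation_magnitudes,
        translation_magnitudes=config.eval_translation_magnitudes,
    )
    stats = plan_statistics(t_scaled, config.active_threshold)
    return PlanResult(phantom_index, window, model, solution, t_scaled, report, stats)


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Report bundle: tidy tables plus the raw per-cell results."""

    config: ExperimentConfig
    results: List[PlanResult]
    indices: pd.DataFrame       # nominal index values per cell
    ratios: pd.DataFrame        # worst-case/nominal ratios per cell x magnitude
    stats: pd.DataFrame         # plan deliverability statistics
    comparisons: pd.DataFrame   # paired signed-rank model comparisons
    failed_cells: List[Tuple[int, float, str, str]] = field(default_factory=list)

    def write_csv(self, outdir: str | Path) -> List[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash: {self.config.config_hash()}\n"
        written = []
        for name, df in (("indices", self.indices), ("ratios", self.ratios),
                         ("plan_stats", self.stats), ("comparisons", self.comparisons)):
            path = outdir / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
            written.append(path)
        manifest = outdir / "manifest.json"
        manifest.write_text(json.dumps({
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "failed_cells": [list(c) for c in self.failed_cells],
        }, indent=2, sort_keys=True))
        written.append(manifest)
        return written


def _mean_rows(df: pd.DataFrame, group_cols: List[str], value_col: str,
               label_col: str = "phantom") -> pd.DataFrame:
    means = df.groupby(group_cols, as_index=False, sort=False)[value_col].mean()
    means[label_col] = "mean"
    return means


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full cohort study described by ``config``."""
    results: List[PlanResult] = []
    failed: List[Tuple[int, float, str, str]] = []
    for idx in range(config.cohort.n_phantoms):
        for window in config.shield_windows:
            cache: Dict[str, DoseMatrix] = {}
            for model in config.models:
                t0 = time.perf_counter()
                try:
                    res = plan_cell(config, idx, window, model, planning_matrices=cache)
                    results.append(res)
                    log.info(
                        "cell phantom=%d window=%g model=%s: objective=%.4g "
                        "status=%s clamped=%d elapsed=%.1fs",
                        idx, window, model, res.solution.objective,
                        res.solution.solver_status,
                        max((m.clamped_points for m in cache.values()), default=0),
                        time.perf_counter() - t0,
                    )
                except Exception as exc:  # cell isolation: keep the run going
                    log.error("cell phantom=%d window=%g model=%s failed: %s",
                              idx, window, model, exc)
                    failed.append((idx, window, model, str(exc)))

    idx_rows, ratio_rows, stat_rows = [], [], []
    for res in results:
        base = {"phantom": res.phantom_index, "window": res.window, "model": res.model}
        for (role, name), value in res.report.nominal.items():
            idx_rows.append({**base, "structure": role, "index": name,
                             "vol_cc": res.report.structure_volumes_cc[role],
                             "nominal_gy": value})
        for rec in res.report.to_records():
            ratio_rows.append({**base, **rec})
        stat_rows.append({**base, "n_active": res.stats.n_active,
                          "longest_dwell_s": res.stats.longest_dwell,
                          "total_time_s": res.stats.total_time})
    indices = pd.DataFrame(idx_rows)
    ratios = pd.DataFrame(ratio_rows)
    stats = pd.DataFrame(stat_rows)
    if not ratios.empty:
        means = _mean_rows(
            ratios, ["window", "model", "kind", "magnitude", "structure", "index"],
            "ratio")
        ratios = pd.concat([ratios, means], ignore_index=True)

    report = ExperimentReport(config, results, indices, ratios, stats,
                              comparisons=pd.DataFrame(), failed_cells=failed)
    comparisons = []
    robust_models = [m for m in config.models if m != "qpm"]
    if "qpm" in config.models and config.cohort.n_phantoms >= 5:
        for model in robust_models:
            try:
                comparisons.append(compare_models(report, "qpm", model))
            except ValueError as exc:
                log.warning("comparison qpm vs %s skipped: %s", model, exc)
    report.comparisons = (pd.concat(comparisons, ignore_index=True)
                          if comparisons else pd.DataFrame())
    return report


def compare_models(
    report: ExperimentReport,
    model_a: str,
    model_b: str,
    metrics: Optional[Sequence[Tuple[str, float, str, str]]] = None,
) -> pd.DataFrame:
    """Paired signed-rank comparison of worst-case ratios across phantoms.

    ``metrics`` is a list of (kind, magnitude, structure, index) rows; by
    default every metric present for both models is compared.
    """
    df = report.ratios
    df = df[df["phantom"] != "mean"]
    a = df[df["model"] == model_a]
    b = df[df["model"] == model_b]
    if a.empty or b.empty:
        raise ValueError(f"both models must be present ({model_a!r}, {model_b!r})")
    keys = ["window", "kind", "magnitude", "structure", "index"]
    if metrics is None:
        metrics_df = a[keys].drop_duplicates()
    else:
        metrics_df = pd.DataFrame(
            [{"window": w, "kind": k, "magnitude": m, "structure": s, "index": i}
             for w in a["window"].unique() for (k, m, s, i) in metrics])
    rows = []
    alpha = report.config.significance_level
    for _, met in metrics_df.iterrows():
        sel_a = a[(a[keys] == met[keys]).all(axis=1)].set_index("phantom")["ratio"]
        sel_b = b[(b[keys] == met[keys]).all(axis=1)].set_index("phantom")["ratio"]
        common = sel_a.index.intersection(sel_b.index)
        if len(common) != len(sel_a) or len(common) != len(sel_b):
            raise ValueError("unmatched phantom sets between models")
        va, vb = sel_a.loc[common].to_numpy(), sel_b.loc[common].to_numpy()
        try:
            res = paired_signed_rank(va, vb)
            p, nodiff = res.p_value, res.no_difference
        except ValueError as exc:
            p, nodiff = np.nan, False
        rows.append({
            **met.to_dict(),
            "mean_a": va.mean(), "mean_b": vb.mean(),
            "mean_diff": (va - vb).mean(),
            "p_value": p,
            "significant": bool(p <= alpha) if np.isfinite(p) else False,
            "no_difference": nodiff,
            "model_a": model_a, "model_b": model_b,
        })
    return pd.DataFrame(rows)
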
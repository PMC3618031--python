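"""Top-level orchestration: simulate -> estimate -> fit -> (bootstrap) -> classify.

A single YAML/JSON-able configuration drives the whole run; every stage
writes its outputs under the run directory and the final machine-readable
report records paths, seeds, EM trace summaries, confusion matrices and
misclassification rates so each number is recomputable from the emitted
intermediate files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import run_bootstrap
from .classify import LoocvConfig, run_loocv
from .effects import estimate_effects, pair_orthologs
from .fdr import gene_test_table
from .io import (
    read_expression,
    read_ortholog_map,
    write_dataset,
    write_categories,
    write_pairs,
)
from .mixture import fit_em
from .synthetic import SimulationConfig, simulate_expression

logger = logging.getLogger("orthomix")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "orthomix_run"
    seed: int = 0
    # simulate stage (set simulate=False and give paths to use existing data)
    simulate: bool = True
    n_genes: int = 2000
    n_samples_a: tuple[int, int] = (9, 5)
    n_samples_h: tuple[int, int] = (79, 77)
    residual_sd_a: float = 0.20
    residual_sd_h: float = 0.68
    expr_a: str | None = None
    meta_a: str | None = None
    expr_h: str | None = None
    meta_h: str | None = None
    orthologs: str | None = None
    # EM
    em_tol: float = 1e-8
    em_max_iter: int = 2000
    em_starts: int = 5
    # optional stages
    bootstrap: bool = False
    bootstrap_B: int = 200
    loocv: bool = False
    selection: str = "both-species"
    fdr_levels: tuple[float, ...] = (0.01, 0.00001)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for level in self.fdr_levels:
            if not 0 < level < 1:
                raise ConfigError(f"FDR level {level} outside (0, 1)")
        if not self.simulate:
            for name in ("expr_a", "meta_a", "expr_h", "meta_h", "orthologs"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"simulate=False requires existing file for {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    current_stage = "start"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        if config.simulate:
            t0 = stage("simulate")
            sim = SimulationConfig(
                n_genes=config.n_genes,
                n_samples_a=tuple(config.n_samples_a),
                n_samples_h=tuple(config.n_samples_h),
                residual_sd_a=config.residual_sd_a,
                residual_sd_h=config.residual_sd_h,
                seed=config.seed,
            )
            expr_a, expr_h, truth = simulate_expression(sim)
            paths = write_dataset(out / "data", expr_a, expr_h, truth)
            ortholog_map = read_ortholog_map(paths["orthologs"])
            report["stages"]["simulate"] = {"paths": paths, "seconds": time.perf_counter() - t0}
        else:
            t0 = stage("load")
            expr_a = read_expression(config.expr_a, config.meta_a)
            expr_h = read_expression(config.expr_h, config.meta_h)
            ortholog_map = read_ortholog_map(config.orthologs)
            report["stages"]["load"] = {"seconds": time.perf_counter() - t0}

        t0 = stage("estimate-effects")
        effects_a = estimate_effects(expr_a)
        effects_h = estimate_effects(expr_h)
        pairs, pair_report = pair_orthologs(effects_a, effects_h, ortholog_map)
        pairs_path = out / "effect_pairs.tsv"
        write_pairs(pairs, pairs_path)
        report["stages"]["estimate_effects"] = {
            "path": str(pairs_path),
            **pair_report,
            "seconds": time.perf_counter() - t0,
        }

        t0 = stage("fit-mixture")
        fit = fit_em(
            pairs,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
            starts=config.em_starts,
            seed=config.seed,
        )
        params_path = out / "mixture_params.json"
        fit.params.to_json(params_path)
        cats_path = out / "categories.tsv"
        write_categories(pairs, fit.categories, fit.responsibilities, cats_path)
        counts = {int(k): int((fit.categories == k).sum()) for k in range(9)}
        report["stages"]["fit_mixture"] = {
            "params": str(params_path),
            "categories": str(cats_path),
            "loglik": fit.loglik,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "category_counts": counts,
            "seconds": time.perf_counter() - t0,
        }

        if config.bootstrap:
            t0 = stage("bootstrap-se")
            boot = run_bootstrap(
                fit.params, len(pairs), B=config.bootstrap_B, seed=config.seed,
                tol=config.em_tol, max_iter=config.em_max_iter,
            )
            se_path = out / "bootstrap_se.json"
            with open(se_path, "w") as fh:
                json.dump(
                    {"B": boot.B, "n_failed": boot.n_failed, "se": boot.se.to_dict()},
                    fh, indent=2,
                )
            report["stages"]["bootstrap"] = {
                "path": str(se_path),
                "B": boot.B,
                "n_failed": boot.n_failed,
                "seconds": time.perf_counter() - t0,
            }

        t0 = stage("fdr-baseline")
        baseline = gene_test_table(expr_h, levels=config.fdr_levels)
        baseline_path = out / "fdr_baseline.tsv"
        baseline.to_csv(baseline_path, sep="\t", index_label="gene", float_format="%.6g")
        report["stages"]["fdr_baseline"] = {
            "path": str(baseline_path),
            "n_selected": {
                f"{lvl:g}": int(baseline[f"selected_{lvl:g}"].sum()) for lvl in config.fdr_levels
            },
            "seconds": time.perf_counter() - t0,
        }

        if config.loocv:
            t0 = stage("loocv")
            loocv_cfg = LoocvConfig(
                em_tol=config.em_tol,
                em_max_iter=config.em_max_iter,
                em_starts=config.em_starts,
                seed=config.seed,
            )
            result = run_loocv(expr_a, expr_h, ortholog_map, config.selection, loocv_cfg)
            pred_path = out / "loocv_predictions.tsv"
            result.folds.to_csv(pred_path, sep="\t", index=False)
            cm = result.confusion
            report["stages"]["loocv"] = {
                "path": str(pred_path),
                "selection": config.selection,
                "confusion": {"n11": cm.n11, "n12": cm.n12, "n21": cm.n21, "n22": cm.n22},
                "misclassification_rate": result.misclassification_rate,
                "n_unclassifiable": result.n_unclassifiable,
                "n_intersection_genes": len(result.intersection_genes),
                "n_union_genes": len(result.union_genes),
                "seconds": time.perf_counter() - t0,
            }
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    report["report_path"] = str(report_path)
    return report
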
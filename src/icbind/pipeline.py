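"""Pipeline orchestration: simulate → fit → predict → selectivity → sweep.

A :class:`PipelineConfig` (YAML) names the stages to run, the panel config,
input/output paths and the global seed. :func:`run_pipeline` executes enabled
stages in dependency order, writes delimited-text outputs, and returns a
manifest recording per-stage status and the SHA-256 of every written file —
identical inputs and seed give identical hashes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding_model import CrosslinkConstant, selectivity_ratio, solve_equilibrium, sweep_affinity
from .io import default_panel_path, read_panel_config
from .model_fit import SignalingDataset, fit_global_model
from .synthetic_data import GeneratorConfig, default_concentration_grid, gen_signaling_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("icbind.pipeline")

STAGES = ("simulate", "fit", "predict", "selectivity", "sweep")
#: stages that need fitted (or at least configured) model parameters
_NEEDS_FIT_INPUT = {"fit"}


@dataclass
class PipelineConfig:
    """Stage toggles, paths and the global seed for one pipeline run."""

    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    panel_config: Path | None = None  # default: shipped synthetic panel
    signaling_table: Path | None = None  # measured data for 'fit' (else simulated)
    cv: float = 0.10
    n_experiments: int = 3
    selectivity_conc_M: float = 1e-11  # 10 pM, the dose–bias comparison point
    sweep_kd_decades: tuple[float, float] = (-7.0, -4.0)
    sweep_points: int = 7

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: pipeline config must set a seed")
        kwargs = {}
        for key in (
            "outdir", "seed", "stages", "panel_config", "signaling_table",
            "cv", "n_experiments", "selectivity_conc_M", "sweep_points",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "sweep_kd_decades" in raw:
            kwargs["sweep_kd_decades"] = tuple(raw["sweep_kd_decades"])
        if "outdir" not in kwargs:
            raise ValueError(f"{path}: pipeline config must set outdir")
        for key in ("panel_config", "signaling_table"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    panel_path = cfg.panel_config or default_panel_path()
    ligands, cells, infer = read_panel_config(panel_path)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "panel_config": str(panel_path),
        "stages": {},
        "success": True,
    }
    outputs: dict[str, Path] = {}
    failed_upstream = False
    fit_result = None

    def record(stage: str, status: str, files: dict[str, Path] | None = None,
               error: str = "") -> None:
        entry: dict = {"status": status}
        if files:
            entry["outputs"] = {str(p): _sha256(p) for p in files.values()}
        if error:
            entry["error"] = error
        manifest["stages"][stage] = entry
        log.info("stage=%s seed=%d status=%s", stage, cfg.seed, status)

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if failed_upstream:
            record(stage, "skipped", error="upstream stage failed")
            continue
        try:
            if stage == "simulate":
                gen_cfg = GeneratorConfig(
                    seed=cfg.seed, cv=cfg.cv, n_experiments=cfg.n_experiments,
                    ligands=ligands, panel=cells,
                )
                data, truth = gen_signaling_dataset(gen_cfg)
                sig_path = cfg.outdir / "signaling.tsv"
                data.to_csv(sig_path)
                truth_path = cfg.outdir / "signaling_truth.yaml"
                with open(truth_path, "w") as fh:
                    yaml.safe_dump(
                        {
                            "kx_star": truth["kx_star"],
                            "kd_betagamma": {
                                k: ("none" if v is None else float(v))
                                for k, v in truth["kd_betagamma"].items()
                            },
                            "cv": truth["cv"],
                            "seed": truth["seed"],
                        },
                        fh,
                    )
                outputs["signaling"] = sig_path
                record(stage, "success", {"signaling": sig_path, "truth": truth_path})
            elif stage == "fit":
                src = cfg.signaling_table or outputs.get("signaling")
                if src is None:
                    raise FileNotFoundError(
                        "fit stage needs a signaling table (run simulate or set signaling_table)"
                    )
                try:
                    data = SignalingDataset.from_csv(src)
                except ValueError as exc:
                    raise ValueError(f"{src}: {exc}") from exc
                fit_result = fit_global_model(
                    data, ligands, infer, cells, seed=cfg.seed
                )
                if fit_result.degenerate or not np.isfinite(fit_result.rss):
                    raise RuntimeError(f"global fit failed: {fit_result.message}")
                report_path = cfg.outdir / "fit_report.yaml"
                with open(report_path, "w") as fh:
                    yaml.safe_dump(
                        {
                            "kx_star": float(fit_result.kx_star),
                            "kd_betagamma": {
                                k: float(v) for k, v in fit_result.kd_betagamma.items()
                            },
                            "scales": {
                                f"{e}/{c}": float(s)
                                for (e, c), s in sorted(fit_result.scales.items())
                            },
                            "rss": float(fit_result.rss),
                            "best_start": fit_result.best_start,
                            "start_rss": [float(r) for r in fit_result.start_rss],
                        },
                        fh, sort_keys=False,
                    )
                record(stage, "success", {"report": report_path})
            elif stage == "predict":
                kx, specs = _fitted_params(ligands, fit_result)
                grid = default_concentration_grid()
                rows = []
                for lig in specs.values():
                    for cell in cells.values():
                        for l0 in grid:
                            st = solve_equilibrium(lig, cell, l0, kx)
                            rows.append(
                                {
                                    "ligand": lig.name,
                                    "cell_type": cell.cell_type,
                                    "conc_M": l0,
                                    "bound_betagamma": st.bound_betagamma,
                                }
                            )
                pred_path = cfg.outdir / "predicted_curves.tsv"
                pd.DataFrame(rows).to_csv(pred_path, sep="\t", index=False)
                record(stage, "success", {"predicted": pred_path})
            elif stage == "selectivity":
                kx, specs = _fitted_params(ligands, fit_result)
                cell_list = list(cells.values())
                ref = cell_list[0]  # first panel entry = high-IL-2Rα target
                rows = []
                for lig in specs.values():
                    for other in cell_list[1:]:
                        rows.append(
                            {
                                "ligand": lig.name,
                                "numerator_cell": ref.cell_type,
                                "denominator_cell": other.cell_type,
                                "conc_M": cfg.selectivity_conc_M,
                                "pstat5_ratio": selectivity_ratio(
                                    lig, ref, other, cfg.selectivity_conc_M, kx
                                ),
                            }
                        )
                sel_path = cfg.outdir / "selectivity.tsv"
                pd.DataFrame(rows).to_csv(sel_path, sep="\t", index=False)
                record(stage, "success", {"selectivity": sel_path})
            elif stage == "sweep":
                kx, specs = _fitted_params(ligands, fit_result)
                template = next(
                    (s for s in specs.values() if s.valency > 1 and s.binds_betagamma),
                    next(iter(specs.values())),
                )
                lo, hi = cfg.sweep_kd_decades
                kd_grid = np.logspace(lo, hi, cfg.sweep_points)
                res = sweep_affinity(
                    template, kd_grid, cells.values(), default_concentration_grid(), kx
                )
                sweep_path = cfg.outdir / "affinity_sweep.tsv"
                res.summary.to_csv(sweep_path, sep="\t", index=False)
                curves_path = cfg.outdir / "affinity_sweep_curves.tsv"
                res.curves.to_csv(curves_path, sep="\t", index=False)
                record(stage, "success", {"summary": sweep_path, "curves": curves_path})
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
            manifest["success"] = False
            failed_upstream = True

    manifest_path = cfg.outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _fitted_params(ligands, fit_result):
    """Model parameters for downstream stages: fitted values when available,
    panel-config values otherwise."""
    if fit_result is not None:
        kx = CrosslinkConstant(fit_result.kx_star)
        specs = {
            name: (
                spec.with_kd_betagamma(fit_result.kd_betagamma[name])
                if name in fit_result.kd_betagamma
                else spec
            )
            for name, spec in ligands.items()
        }
        return kx, specs
    return CrosslinkConstant(1e-10), dict(ligands)
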
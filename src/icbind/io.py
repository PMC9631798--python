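"""Readers and writers for ligand/receptor panel configs and fit reports."""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .binding_model import LigandSpec, ReceptorProfile

__all__ = [
    "read_panel_config",
    "write_panel_config",
    "default_panel_path",
]

NONBINDING_SENTINELS = {"none", "non-binding", "nonbinding", None}


def default_panel_path() -> Path:
    """Path of the shipped SYNTHETIC default panel config."""
    return Path(__file__).with_name("data") / "synthetic_panel.yaml"


def _parse_kd(value: Any) -> float | None:
    if isinstance(value, str):
        value = value.strip().lower()
    if value in NONBINDING_SENTINELS:
        return None
    return float(value)


def read_panel_config(
    path: str | Path,
) -> tuple[dict[str, LigandSpec], dict[str, ReceptorProfile], list[str]]:
    """Read a YAML panel config.

    Expected keys::

        ligands:
          - {name: il2, valency: 1, kd_alpha_M: 1.0e-8, kd_betagamma_M: 5.0e-7}
          - {name: blocked_ic, valency: 2, kd_alpha_M: 1.0e-8, kd_betagamma_M: none}
        cells:
          - {cell_type: Treg, r_alpha: 3000, r_betagamma: 700}
        infer: [biased_ic]          # optional: ligands whose kd_betagamma is fitted

    Returns (ligands, cells, infer).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "ligands" not in cfg or "cells" not in cfg:
        raise ValueError(f"panel config {path} must define 'ligands' and 'cells'")
    ligands = {}
    for i, entry in enumerate(cfg["ligands"]):
        try:
            spec = LigandSpec(
                name=str(entry["name"]),
                valency=int(entry["valency"]),
                kd_alpha=float(entry["kd_alpha_M"]),
                kd_betagamma=_parse_kd(entry.get("kd_betagamma_M")),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad ligand entry {i}: {exc}") from exc
        ligands[spec.name] = spec
    cells = {}
    for i, entry in enumerate(cfg["cells"]):
        try:
            prof = ReceptorProfile(
                cell_type=str(entry["cell_type"]),
                r_alpha_total=float(entry["r_alpha"]),
                r_betagamma_total=float(entry["r_betagamma"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad cell entry {i}: {exc}") from exc
        cells[prof.cell_type] = prof
    infer = [str(n) for n in cfg.get("infer", [])]
    unknown = set(infer) - set(ligands)
    if unknown:
        raise ValueError(f"{path}: infer names unknown ligands {sorted(unknown)}")
    return ligands, cells, infer


def write_panel_config(
    path: str | Path,
    ligands: dict[str, LigandSpec],
    cells: dict[str, ReceptorProfile],
    infer: list[str] | None = None,
) -> None:
    cfg = {
        "ligands": [
            {
                "name": s.name,
                "valency": s.valency,
                "kd_alpha_M": s.kd_alpha,
                "kd_betagamma_M": "none" if s.kd_betagamma is None else s.kd_betagamma,
            }
            for s in ligands.values()
        ],
        "cells": [
            {
                "cell_type": p.cell_type,
                "r_alpha": p.r_alpha_total,
                "r_betagamma": p.r_betagamma_total,
            }
            for p in cells.values()
        ],
    }
    if infer:
        cfg["infer"] = list(infer)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
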
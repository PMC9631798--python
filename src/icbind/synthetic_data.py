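"""Seeded generators for every input the analysis pipeline consumes.

Raw inputs of this kind (flow-cytometry pSTAT5 dose–response panels, BLI
titrations, plasma PK series, splenocyte expansion counts) are usually not
publicly deposited, so this module emulates their statistical structure: responses follow the
relevant truth model (the multivalent binding model for signaling, a
hyperbola for titrations, a two-phase decay for PK, multiplicative treatment
effects for expansion counts) under multiplicative log-normal noise, the
scale-dependent noise characteristic of fluorescence readouts.

Every generator returns the dataset together with the ground truth that
produced it, and derives its random stream deterministically from one global
seed, so generator/fitter pairs form seeded closure tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_analytics import PKProfile, TitrationCurve
from .binding_model import (
    CrosslinkConstant,
    LigandSpec,
    ReceptorProfile,
    solve_equilibrium,
)
from .expansion_nnmf import ExpansionMatrix
from .model_fit import SignalingDataset

__all__ = [
    "GeneratorConfig",
    "default_receptor_panel",
    "default_ligands",
    "default_concentration_grid",
    "gen_signaling_dataset",
    "gen_bli_titration",
    "gen_pk_profile",
    "gen_expansion_counts",
]


def default_concentration_grid(n: int = 12, top: float = 1e-6, step: float = 4.0) -> np.ndarray:
    """Serial dilution grid: ``n`` ``step``-fold dilutions from ``top`` molar,
    strictly decreasing (mirrors the 12-point four-fold series of the
    signaling assays)."""
    return top / step ** np.arange(n)


def default_receptor_panel() -> dict[str, ReceptorProfile]:
    """SYNTHETIC receptor panel (receptors/cell) — plausible placeholders.

    IL-2Rα is high on Tregs and low on effectors; IL-2Rβ/γc is present on
    all. These are not measured abundances; real analyses should supply a
    quantitation-derived panel via config.
    """
    return {
        "Treg": ReceptorProfile("Treg", r_alpha_total=3000.0, r_betagamma_total=700.0),
        "CD8": ReceptorProfile("CD8", r_alpha_total=100.0, r_betagamma_total=1500.0),
        "Tconv": ReceptorProfile("Tconv", r_alpha_total=200.0, r_betagamma_total=800.0),
    }


def default_ligands() -> dict[str, LigandSpec]:
    """SYNTHETIC ligand panel: free IL-2, a bivalent control IC, and a
    Treg-biased IC whose IL-2Rβ/γc engagement is attenuated by the antibody.

    kd_alpha ≈ 10 nM matches the monomeric IL-2/IL-2Rα interaction scale;
    the control IC inherits free IL-2's site affinities (avidity arises from
    bivalency in the model, not from altered per-site K_D). The biased IC's
    kd_betagamma is the quantity the global fit infers.
    """
    return {
        "il2": LigandSpec("il2", valency=1, kd_alpha=1e-8, kd_betagamma=5e-7),
        "control_ic": LigandSpec("control_ic", valency=2, kd_alpha=1e-8, kd_betagamma=5e-7),
        "biased_ic": LigandSpec("biased_ic", valency=2, kd_alpha=1e-8, kd_betagamma=3e-5),
        "blocked_ic": LigandSpec("blocked_ic", valency=2, kd_alpha=1e-8, kd_betagamma=None),
    }


@dataclass
class GeneratorConfig:
    """Knobs of the signaling-data generator; defaults mirror the assays'
    design (12 four-fold dilutions from 1 µM, triplicate experiments, 10%
    multiplicative CV)."""

    seed: int = 0
    cv: float = 0.10
    concentrations: np.ndarray = field(default_factory=default_concentration_grid)
    n_experiments: int = 3
    kx_star: float = 1e-10
    ligands: dict[str, LigandSpec] = field(default_factory=default_ligands)
    panel: dict[str, ReceptorProfile] = field(default_factory=default_receptor_panel)
    scales: Mapping[tuple[str, str], float] | float = 1.0
    unstim_mfi: float = 50.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(c) >= 0):
            raise ValueError("concentration grid must be strictly decreasing")
        self.concentrations = c


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one substream per dataset, derived deterministically from the global seed
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def gen_signaling_dataset(cfg: GeneratorConfig) -> tuple[SignalingDataset, dict]:
    """Simulate a multi-cell-type pSTAT5 dose–response panel.

    MFI = unstim + scale × bound_βγ × noise, where bound_βγ comes from the
    multivalent equilibrium model at the configured true parameters. The
    returned truth record carries everything needed for recovery tests.
    """
    rng = _rng(cfg.seed, 1)
    kx = CrosslinkConstant(cfg.kx_star)
    rows = []
    for e in range(cfg.n_experiments):
        exp_id = f"exp{e + 1}"
        for cell_name, cell in cfg.panel.items():
            if isinstance(cfg.scales, Mapping):
                scale = cfg.scales.get((exp_id, cell_name), 1.0)
            else:
                scale = float(cfg.scales)
            for lig_name, ligand in cfg.ligands.items():
                noise = _lognormal_factor(rng, cfg.cv, cfg.concentrations.size)
                for l0, nz in zip(cfg.concentrations, noise):
                    state = solve_equilibrium(ligand, cell, l0, kx)
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "cell_type": cell_name,
                            "ligand": lig_name,
                            "conc_M": l0,
                            "mfi": cfg.unstim_mfi + scale * state.bound_betagamma * nz,
                            "unstim_mfi": cfg.unstim_mfi,
                        }
                    )
    truth = {
        "kx_star": cfg.kx_star,
        "kd_betagamma": {n: s.kd_betagamma for n, s in cfg.ligands.items()},
        "scales": cfg.scales,
        "cv": cfg.cv,
        "seed": cfg.seed,
    }
    return SignalingDataset(pd.DataFrame(rows)), truth


def gen_bli_titration(
    kd: float,
    rmax: float = 1.0,
    grid: Sequence[float] | None = None,
    cv: float = 0.05,
    seed: int = 0,
) -> tuple[TitrationCurve, dict]:
    """Simulate a first-order equilibrium titration R(c) = Rmax·c/(Kd + c)."""
    if grid is None:
        grid = kd * 2.0 ** np.arange(-4, 5)  # 9 points bracketing Kd
    c = np.sort(np.asarray(grid, dtype=float))
    rng = _rng(seed, 2)
    resp = rmax * c / (kd + c) * _lognormal_factor(rng, cv, c.size)
    return (
        TitrationCurve(concentrations=c, responses=resp),
        {"kd": kd, "rmax": rmax, "cv": cv, "seed": seed},
    )


def gen_pk_profile(
    a: float,
    b: float,
    t_half_fast: float,
    t_half_slow: float,
    times: Sequence[float] | None = None,
    cv: float = 0.05,
    seed: int = 0,
) -> tuple[PKProfile, dict]:
    """Simulate a two-phase plasma decay sampled on a tail-vein-style schedule
    (default 5 min – 120 h)."""
    if times is None:
        times = [5 / 60, 20 / 60, 40 / 60, 1, 2, 4, 8, 24, 48, 72, 96, 120]
    t = np.asarray(times, dtype=float)
    rng = _rng(seed, 3)
    conc = (
        a * 2.0 ** (-t / t_half_fast) + b * 2.0 ** (-t / t_half_slow)
    ) * _lognormal_factor(rng, cv, t.size)
    return (
        PKProfile(times=t, concentrations=conc),
        {
            "a": a, "b": b, "t_half_fast": t_half_fast,
            "t_half_slow": t_half_slow, "cv": cv, "seed": seed,
        },
    )


def gen_expansion_counts(
    base: Mapping[str, float],
    effects: Mapping[str, Mapping[str, float]],
    dispersion: float = 0.0,
    seed: int = 0,
    control: str = "PBS",
) -> tuple[ExpansionMatrix, dict]:
    """Simulate a treatments × cell-types count matrix.

    ``base`` gives control (vehicle) counts per cell type; each treatment
    multiplies them by its per-cell-type effect under log-normal dispersion.
    The control row is the base counts exactly (it is the reference the
    preprocessing subtracts).
    """
    cell_types = list(base)
    rng = _rng(seed, 4)
    rows = {control: [base[ct] for ct in cell_types]}
    for treatment, eff in effects.items():
        noise = _lognormal_factor(rng, dispersion, len(cell_types))
        rows[treatment] = [
            base[ct] * eff.get(ct, 1.0) * nz for ct, nz in zip(cell_types, noise)
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cell_types)
    return (
        ExpansionMatrix(counts=counts, control=control),
        {"base": dict(base), "effects": {k: dict(v) for k, v in effects.items()},
         "dispersion": dispersion, "seed": seed},
    )
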
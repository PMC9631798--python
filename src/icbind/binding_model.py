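"""Equilibrium model of multivalent immunocytokine binding to IL-2 receptors.

An immunocytokine (IC) carries ``v`` IL-2 modules (v = 1 for free IL-2, v = 2
for the bivalent fusions). Each module can engage one IL-2Rα and one composite
IL-2Rβ/γc site on the cell surface. The first ligand–cell bond forms with the
monomeric solution affinity; every subsequent bond by the tethered ligand forms
with a weight proportional to the free receptor abundance, the monomeric
association constant, and the crosslinking constant Kx*.

With χ_j = Kx* · R_j,eq / K_D,j for receptor class j, a single IL-2 module
contributes the factor m = (1 + χ_α)(1 + χ_βγ) to the partition sum, and

    bound-ligand weight      W      = (L0 / Kx*) · (m^v − 1)
    bound receptors, class j B_j    = (L0 / Kx*) · v · m^(v−1) · χ_j · (1 + χ_other)

The free receptor abundances R_j,eq are fixed by receptor conservation
R_j,tot = R_j,eq + B_j(R_eq); the ligand is assumed not depleted. pSTAT5 is
proportional to the amount of ligand-engaged IL-2Rβ/γc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LigandSpec",
    "ReceptorProfile",
    "CrosslinkConstant",
    "EquilibriumState",
    "SolverError",
    "solve_equilibrium",
    "predict_pstat5",
    "selectivity_ratio",
    "sweep_affinity",
    "SweepResult",
]

#: residual tolerance (relative, per receptor class) for accepted solutions
CONSERVATION_TOL = 1e-10
_MAX_ITER = 100_000


@dataclass(frozen=True)
class LigandSpec:
    """A ligand's valency and per-site dissociation constants.

    ``kd_betagamma=None`` is the non-binding sentinel (the IL-2Rβ/γc epitope is
    fully blocked, as for the intramolecularly assembled F5111 IC); it is
    treated as an exactly zero association weight, not as a huge K_D.
    """

    name: str
    valency: int
    kd_alpha: float  # molar
    kd_betagamma: float | None  # molar, or None for non-binding

    def __post_init__(self) -> None:
        if self.valency < 1:
            raise ValueError(f"valency must be >= 1, got {self.valency}")
        if not self.kd_alpha > 0:
            raise ValueError(f"kd_alpha must be > 0, got {self.kd_alpha}")
        if self.kd_betagamma is not None and not self.kd_betagamma > 0:
            raise ValueError(
                f"kd_betagamma must be > 0 or None, got {self.kd_betagamma}"
            )

    @property
    def binds_betagamma(self) -> bool:
        return self.kd_betagamma is not None and math.isfinite(self.kd_betagamma)

    def with_kd_betagamma(self, kd: float | None) -> "LigandSpec":
        return replace(self, kd_betagamma=kd)


@dataclass(frozen=True)
class ReceptorProfile:
    """Per-cell-type IL-2Rα and composite IL-2Rβ/γc surface abundances."""

    cell_type: str
    r_alpha_total: float  # receptors / cell
    r_betagamma_total: float  # receptors / cell

    def __post_init__(self) -> None:
        if self.r_alpha_total < 0 or self.r_betagamma_total < 0:
            raise ValueError("receptor abundances must be >= 0")


@dataclass(frozen=True)
class CrosslinkConstant:
    """Crosslinking scaling constant Kx*, molar·(receptors/cell)⁻¹.

    Chosen so that χ = kx_star · R_eq / K_D is dimensionless.
    """

    kx_star: float

    def __post_init__(self) -> None:
        if self.kx_star < 0:
            raise ValueError("kx_star must be >= 0")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved free/bound receptor quantities for one (ligand, cell, dose)."""

    ligand: str
    cell_type: str
    l0: float  # molar
    r_alpha_eq: float
    r_betagamma_eq: float
    bound_alpha: float
    bound_betagamma: float
    ligand_bound: float  # bound-ligand partition weight per cell


class SolverError(RuntimeError):
    """Equilibrium solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


def _chi(kx: float, r_eq: float, kd: float | None) -> float:
    if kd is None or not math.isfinite(kd):
        return 0.0
    return kx * r_eq / kd


def _bound_terms(
    ligand: LigandSpec, l0: float, kx: float, ra: float, rbg: float
) -> tuple[float, float, float]:
    """Bound α, bound βγ and bound-ligand weight at given free abundances."""
    v = ligand.valency
    ca = _chi(kx, ra, ligand.kd_alpha)
    cb = _chi(kx, rbg, ligand.kd_betagamma)
    m = (1.0 + ca) * (1.0 + cb)
    pref = l0 / kx * v * m ** (v - 1)
    bound_a = pref * ca * (1.0 + cb)
    bound_b = pref * cb * (1.0 + ca)
    w = l0 / kx * (m**v - 1.0)
    return bound_a, bound_b, w


def _solve_kx_zero(
    ligand: LigandSpec, cell: ReceptorProfile, l0: float
) -> EquilibriumState:
    # kx → 0 limit: classes decouple into independent single-bond Langmuir
    # binding; B_j = v·l0·R_j,eq/K_j and R_j,tot = R_j,eq·(1 + v·l0/K_j).
    v = ligand.valency
    ra = cell.r_alpha_total / (1.0 + v * l0 / ligand.kd_alpha)
    bound_a = v * l0 * ra / ligand.kd_alpha
    if ligand.binds_betagamma:
        rbg = cell.r_betagamma_total / (1.0 + v * l0 / ligand.kd_betagamma)
        bound_b = v * l0 * rbg / ligand.kd_betagamma
    else:
        rbg = cell.r_betagamma_total
        bound_b = 0.0
    return EquilibriumState(
        ligand=ligand.name,
        cell_type=cell.cell_type,
        l0=l0,
        r_alpha_eq=ra,
        r_betagamma_eq=rbg,
        bound_alpha=bound_a,
        bound_betagamma=bound_b,
        ligand_bound=bound_a + bound_b,
    )


def solve_equilibrium(
    ligand: LigandSpec,
    cell: ReceptorProfile,
    l0: float,
    kx: CrosslinkConstant | float,
) -> EquilibriumState:
    """Solve receptor conservation for the multivalent binding equilibrium.

    Parameters
    ----------
    ligand : LigandSpec
    cell : ReceptorProfile
    l0 : float
        Free ligand concentration in molar (held fixed; no depletion).
    kx : CrosslinkConstant or float
        Crosslinking constant Kx*; ``kx == 0`` is handled analytically as the
        single-bond limit.

    Returns
    -------
    EquilibriumState
        Conservation residual is at most ``CONSERVATION_TOL`` relative per
        receptor class.

    Raises
    ------
    SolverError
        If neither the damped fixed point nor the root-finding fallback reach
        the residual tolerance within the iteration cap.
    """
    kxv = kx.kx_star if isinstance(kx, CrosslinkConstant) else float(kx)
    if l0 < 0:
        raise ValueError("l0 must be >= 0")
    if kxv < 0:
        raise ValueError("kx must be >= 0")
    if l0 == 0.0:
        return EquilibriumState(
            ligand=ligand.name,
            cell_type=cell.cell_type,
            l0=0.0,
            r_alpha_eq=cell.r_alpha_total,
            r_betagamma_eq=cell.r_betagamma_total,
            bound_alpha=0.0,
            bound_betagamma=0.0,
            ligand_bound=0.0,
        )
    if kxv == 0.0:
        return _solve_kx_zero(ligand, cell, l0)

    ra_tot, rbg_tot = cell.r_alpha_total, cell.r_betagamma_total
    v = ligand.valency

    def step(ra: float, rbg: float) -> tuple[float, float]:
        # R_j,eq = R_j,tot / (1 + B_j / R_j,eq); B_j / R_j,eq is independent of
        # R_j,eq at fixed χ_other, making this a well-behaved Picard map.
        ca = _chi(kxv, ra, ligand.kd_alpha)
        cb = _chi(kxv, rbg, ligand.kd_betagamma)
        m = (1.0 + ca) * (1.0 + cb)
        pref = l0 * v * m ** (v - 1)
        ra_new = ra_tot / (1.0 + pref * (1.0 + cb) / ligand.kd_alpha)
        if ligand.binds_betagamma and rbg_tot > 0:
            rbg_new = rbg_tot / (1.0 + pref * (1.0 + ca) / ligand.kd_betagamma)
        else:
            rbg_new = rbg_tot
        return ra_new, rbg_new

    def residuals(ra: float, rbg: float) -> tuple[float, float]:
        ba, bb, _ = _bound_terms(ligand, l0, kxv, ra, rbg)
        res_a = abs(ra_tot - ra - ba) / max(ra_tot, 1.0)
        res_b = abs(rbg_tot - rbg - bb) / max(rbg_tot, 1.0)
        return res_a, res_b

    ra, rbg = max(ra_tot, 1e-30), max(rbg_tot, 1e-30)
    damping = 0.5
    res = math.inf
    for _ in range(_MAX_ITER):
        ra_new, rbg_new = step(ra, rbg)
        # damped update in log space keeps iterates strictly positive
        ra = math.exp((1 - damping) * math.log(ra) + damping * math.log(max(ra_new, 1e-300)))
        rbg = math.exp((1 - damping) * math.log(rbg) + damping * math.log(max(rbg_new, 1e-300)))
        res = max(residuals(ra, rbg))
        if res <= CONSERVATION_TOL:
            break
    else:
        ra, rbg, res = _root_fallback(ligand, cell, l0, kxv, ra, rbg)
        if res > CONSERVATION_TOL:
            raise SolverError(
                f"equilibrium solver did not converge for {ligand.name} on "
                f"{cell.cell_type} at l0={l0:g} M",
                res,
            )

    # a receptor class with zero abundance is exactly unengaged (the iteration
    # uses a tiny positive placeholder for it)
    if ra_tot == 0:
        ra = 0.0
    if rbg_tot == 0:
        rbg = 0.0
    ba, bb, w = _bound_terms(ligand, l0, kxv, ra, rbg)
    return EquilibriumState(
        ligand=ligand.name,
        cell_type=cell.cell_type,
        l0=l0,
        r_alpha_eq=ra,
        r_betagamma_eq=rbg,
        bound_alpha=ba,
        bound_betagamma=bb,
        ligand_bound=w,
    )


def _root_fallback(
    ligand: LigandSpec,
    cell: ReceptorProfile,
    l0: float,
    kx: float,
    ra0: float,
    rbg0: float,
) -> tuple[float, float, float]:
    ra_tot, rbg_tot = cell.r_alpha_total, cell.r_betagamma_total

    def fun(logr: np.ndarray) -> np.ndarray:
        ra, rbg = np.exp(logr)
        ba, bb, _ = _bound_terms(ligand, l0, kx, ra, rbg)
        return np.array(
            [
                (ra_tot - ra - ba) / max(ra_tot, 1.0),
                (rbg_tot - rbg - bb) / max(rbg_tot, 1.0),
            ]
        )

    x0 = np.log([max(ra0, 1e-30), max(rbg0, 1e-30)])
    sol = optimize.root(fun, x0, method="hybr", tol=1e-14)
    ra, rbg = np.exp(sol.x)
    res = float(np.max(np.abs(fun(sol.x))))
    return float(ra), float(rbg), res


def predict_pstat5(state: EquilibriumState, scale: float) -> float:
    """pSTAT5 prediction: ``scale × bound IL-2Rβ/γc`` (arbitrary MFI units).

    Complexes containing ligand-engaged IL-2Rβ/γc signal through JAK/STAT, so
    the readout is taken proportional to that species; ``scale`` is the
    per-(experiment, cell type) conversion factor.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    return scale * state.bound_betagamma


def selectivity_ratio(
    ligand: LigandSpec,
    cell_a: ReceptorProfile,
    cell_b: ReceptorProfile,
    l0: float,
    kx: CrosslinkConstant | float,
) -> float:
    """Ratio of predicted active species on cell_a vs cell_b at one dose.

    Uses unit scale factors for both cells (shared scales cancel). A zero
    denominator with a positive numerator returns ``math.inf``; 0/0 returns
    ``math.nan``. Neither raises.
    """
    num = predict_pstat5(solve_equilibrium(ligand, cell_a, l0, kx), 1.0)
    den = predict_pstat5(solve_equilibrium(ligand, cell_b, l0, kx), 1.0)
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


@dataclass(frozen=True)
class SweepResult:
    """Affinity-sweep output: per-point dose–response curves and summaries."""

    curves: pd.DataFrame  # kd_betagamma, cell_type, conc_M, response
    summary: pd.DataFrame  # kd_betagamma, cell_type, ec50_M, emax, hill, baseline, ok, reason


def sweep_affinity(
    template: LigandSpec,
    kd_betagamma_grid: Sequence[float],
    cells: Iterable[ReceptorProfile],
    l0_grid: Sequence[float],
    kx: CrosslinkConstant | float,
) -> SweepResult:
    """Sweep the IL-2Rβ/γc affinity of a ligand template over a K_D grid.

    For each grid K_D and cell type the full predicted dose–response (unit
    scale) is computed and summarized with a four-parameter logistic fit.
    Solver failures at individual grid points are recorded per point
    (``ok=False`` with a reason) rather than aborting the sweep.
    """
    from .model_fit import fit_4pl  # local import to avoid a cycle

    kd_grid = list(kd_betagamma_grid)
    l0s = np.asarray(list(l0_grid), dtype=float)
    cells = list(cells)
    if not kd_grid or l0s.size == 0 or not cells:
        raise ValueError("kd grid, l0 grid and cells must be non-empty")

    curve_rows: list[dict] = []
    summary_rows: list[dict] = []
    for kd in kd_grid:
        ligand = template.with_kd_betagamma(kd)
        for cell in cells:
            resp = np.full(l0s.shape, np.nan)
            failure = None
            for i, l0 in enumerate(l0s):
                try:
                    state = solve_equilibrium(ligand, cell, l0, kx)
                    resp[i] = state.bound_betagamma
                except SolverError as exc:
                    failure = str(exc)
            for l0, r in zip(l0s, resp):
                curve_rows.append(
                    {
                        "kd_betagamma": kd,
                        "cell_type": cell.cell_type,
                        "conc_M": l0,
                        "response": r,
                    }
                )
            row = {
                "kd_betagamma": kd,
                "cell_type": cell.cell_type,
                "ec50_M": np.nan,
                "emax": np.nan,
                "hill": np.nan,
                "baseline": np.nan,
                "ok": False,
                "reason": "",
            }
            if failure is not None:
                row["reason"] = failure
            else:
                mask = l0s > 0
                fit = fit_4pl(l0s[mask], resp[mask])
                if fit.ok:
                    row.update(
                        ec50_M=fit.ec50,
                        emax=fit.emax,
                        hill=fit.hill,
                        baseline=fit.baseline,
                        ok=True,
                    )
                else:
                    row["reason"] = fit.reason
            summary_rows.append(row)

    return SweepResult(
        curves=pd.DataFrame(curve_rows), summary=pd.DataFrame(summary_rows)
    )
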
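"""Dose–response summarization and global inference for the binding model.

Three layers of fitting live here:

* per-curve processing — background subtraction / normalization and
  four-parameter logistic (4PL) summaries yielding EC50 and Emax;
* global least squares — one shared crosslinking constant Kx*, one IL-2Rβ/γc
  dissociation constant per ligand flagged for inference, and one scale factor
  per (experiment, cell type), fitted jointly to all normalized curves;
* the Gaussian fit locating the cytokine/antibody affinity optimum from
  in vivo expansion-ratio vs EC50 data.

All nonlinear parameters are optimized in log10 space with bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .binding_model import (
    CrosslinkConstant,
    LigandSpec,
    ReceptorProfile,
    SolverError,
    solve_equilibrium,
)

__all__ = [
    "SignalingDataset",
    "FourPLFit",
    "GlobalFitResult",
    "GaussianOptimum",
    "DegenerateCurveError",
    "normalize_response",
    "fit_4pl",
    "fit_global_model",
    "fit_gaussian_optimum",
]

# log10 bounds for the global fit
KX_BOUNDS = (-18.0, -6.0)
KD_BOUNDS = (-12.0, -3.0)
SCALE_BOUNDS = (1e-6, 1e6)
HILL_BOUNDS = (0.1, 5.0)

CURVE_KEYS = ["experiment_id", "cell_type", "ligand"]
COLUMNS = CURVE_KEYS + ["conc_M", "mfi", "unstim_mfi"]


class DegenerateCurveError(ValueError):
    """Raised when a curve has no positive signal after background subtraction."""


@dataclass
class SignalingDataset:
    """Tidy pSTAT5 dose–response records.

    One row per measurement; columns ``experiment_id, cell_type, ligand,
    conc_M, mfi, unstim_mfi``. A curve is one (experiment, cell type, ligand)
    group and carries a single unstimulated reference MFI.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"signaling table missing columns: {missing}")
        bad = self.df.index[~(self.df["conc_M"] > 0)].tolist()
        if bad:
            raise ValueError(f"non-positive concentration at rows {bad[:5]}")
        for key, grp in self.df.groupby(CURVE_KEYS):
            if grp["conc_M"].nunique() < 4:
                raise ValueError(f"curve {key} has < 4 distinct concentrations")
            if grp["unstim_mfi"].nunique() != 1:
                raise ValueError(f"curve {key} has inconsistent unstim_mfi")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalingDataset":
        return cls(pd.read_csv(path, sep="\t"))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def curves(self):
        return self.df.groupby(CURVE_KEYS, sort=True)


def normalize_response(
    mfi: Sequence[float], unstim_mfi: float
) -> np.ndarray:
    """Background-subtract and scale a pSTAT5 curve to a maximum of 1.

    Output = (MFI − unstimulated MFI) / max(MFI − unstimulated MFI).
    Idempotent for already-normalized curves (unstim 0, max 1).

    Raises
    ------
    DegenerateCurveError
        If the post-subtraction maximum is not positive (flat or inverted
        curve) — the degenerate-curve flag.
    """
    y = np.asarray(mfi, dtype=float) - float(unstim_mfi)
    top = y.max()
    if not top > 0:
        raise DegenerateCurveError(
            f"no positive signal after subtracting unstimulated MFI ({unstim_mfi})"
        )
    return y / top


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic summary of one dose–response curve."""

    ec50: float  # molar
    emax: float
    hill: float
    baseline: float
    residuals: np.ndarray
    ok: bool = True
    reason: str = ""

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))


def four_pl(conc: np.ndarray, log_ec50: float, emax: float, hill: float, baseline: float) -> np.ndarray:
    """4PL in log10-concentration space; response rises with concentration."""
    logc = np.log10(conc)
    return baseline + (emax - baseline) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_4pl(concentrations: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Fit a four-parameter logistic to a dose–response curve.

    Requires >= 4 points spanning >= 2 decades of concentration. EC50 is
    bounded to the data range extended 100-fold on each side; the Hill slope
    to [0.1, 5]. Flat or non-converging data yield ``ok=False`` with a reason
    instead of raising.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 4:
        raise ValueError("need >= 4 points for a 4PL fit")
    if not np.all(c > 0):
        raise ValueError("concentrations must be > 0")
    if np.log10(c.max() / c.min()) < 2:
        raise ValueError("concentrations must span >= 2 log10 units")

    span = y.max() - y.min()
    if span <= 0 or (np.abs(y - y.mean()) < 1e-12 * max(1.0, abs(y.mean()))).all():
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, y - y.mean(),
                         ok=False, reason="flat response")

    lo, hi = np.log10(c.min()) - 2.0, np.log10(c.max()) + 2.0
    bounds = (
        [lo, y.min() - span, HILL_BOUNDS[0], y.min() - span],
        [hi, y.max() + span, HILL_BOUNDS[1], y.max() + span],
    )
    # midpoint-crossing start plus two bracketing alternatives
    order = np.argsort(c)
    mid = y.min() + span / 2.0
    idx = int(np.argmin(np.abs(y[order] - mid)))
    starts = [
        [np.log10(c[order][idx]), y.max(), 1.0, y.min()],
        [np.log10(np.median(c)), y.max(), 0.7, y.min()],
        [np.log10(np.sqrt(c.min() * c.max())), y.max(), 2.0, y.min()],
    ]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = optimize.curve_fit(
                four_pl, c, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        resid = four_pl(c, *popt) - y
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss, resid)
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, y,
                         ok=False, reason="did not converge")
    popt, _, resid = best
    return FourPLFit(
        ec50=10.0 ** popt[0], emax=popt[1], hill=popt[2], baseline=popt[3],
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# global binding-model fit


@dataclass
class GlobalFitResult:
    """Best global fit of Kx*, inferred K_D,βγ values and curve scales."""

    kx_star: float
    kd_betagamma: dict[str, float]  # per-ligand (inferred only)
    scales: dict[tuple[str, str], float]  # (experiment_id, cell_type) -> scale
    rss: float
    start_rss: list[float] = field(default_factory=list)
    best_start: int = 0
    n_evaluations: int = 0
    accepted_trace: list[float] = field(default_factory=list)
    degenerate: bool = False
    message: str = ""


def _normalized_curves(data: SignalingDataset) -> tuple[list[dict], int]:
    """Background-subtract and normalize curves per (experiment, cell type).

    The normalization unit is the (experiment, cell type) group, matching the
    granularity of the scale factors: every curve in a group is divided by the
    group's maximal background-subtracted signal, so relative amplitudes
    between ligands within a group are preserved (a per-curve normalization
    would erase them and make amplitude-carrying parameters unidentifiable).
    Degenerate groups (no positive signal) are dropped and counted.
    """
    curves = []
    n_degenerate = 0
    for (exp, cell), grp in data.df.groupby(["experiment_id", "cell_type"], sort=True):
        sub = grp["mfi"].to_numpy() - grp["unstim_mfi"].to_numpy()
        top = sub.max()
        if not top > 0:
            n_degenerate += grp.groupby("ligand").ngroups
            continue
        for ligand, cv in grp.groupby("ligand", sort=True):
            cv = cv.sort_values("conc_M")
            y = (cv["mfi"].to_numpy() - cv["unstim_mfi"].to_numpy()) / top
            curves.append(
                {
                    "experiment_id": exp,
                    "cell_type": cell,
                    "ligand": ligand,
                    "conc": cv["conc_M"].to_numpy(),
                    "y": y,
                }
            )
    return curves, n_degenerate


def fit_global_model(
    data: SignalingDataset,
    ligands: Mapping[str, LigandSpec],
    infer: Sequence[str],
    panel: Mapping[str, ReceptorProfile],
    n_starts: int = 8,
    seed: int = 0,
) -> GlobalFitResult:
    """Globally fit Kx*, flagged ligand IL-2Rβ/γc affinities and curve scales.

    The objective is the sum of squared differences between normalized
    measured curves and scaled model predictions, minimized over
    (log10 Kx*, log10 K_D,βγ per inferred ligand) with multi-start
    (Latin-hypercube start points, seeded). Scale factors per
    (experiment, cell type) are profiled in closed form at every objective
    evaluation — for fixed nonlinear parameters the optimal scale is the
    least-squares projection Σ(pred·y)/Σ(pred²) over that group's points —
    and reported alongside the nonlinear parameters.

    Parameters
    ----------
    ligands : mapping name -> LigandSpec
        Every ligand appearing in the data. Entries named in ``infer`` have
        their ``kd_betagamma`` re-estimated; all other specs are kept fixed.
    infer : sequence of ligand names to estimate kd_betagamma for.
    panel : mapping cell_type -> ReceptorProfile.
    """
    infer = list(infer)
    data_ligands = set(data.df["ligand"].unique())
    unknown = data_ligands - set(ligands)
    if unknown:
        raise ValueError(f"data contains ligands without specs: {sorted(unknown)}")
    fixed = [
        name for name in data_ligands
        if name not in infer and ligands[name].binds_betagamma
    ]
    if not fixed:
        raise ValueError(
            "need >= 1 ligand with fixed, finite kd_betagamma to anchor Kx* and scales"
        )
    missing_cells = set(data.df["cell_type"].unique()) - set(panel)
    if missing_cells:
        raise ValueError(f"receptor panel missing cell types: {sorted(missing_cells)}")

    curves, _ = _normalized_curves(data)
    if not curves:
        return GlobalFitResult(
            kx_star=math.nan, kd_betagamma={}, scales={}, rss=math.nan,
            degenerate=True, message="all curves degenerate (no positive signal)",
        )

    groups: dict[tuple[str, str], list[int]] = {}
    for i, cv in enumerate(curves):
        groups.setdefault((cv["experiment_id"], cv["cell_type"]), []).append(i)

    n_params = 1 + len(infer)
    lb = np.array([KX_BOUNDS[0]] + [KD_BOUNDS[0]] * len(infer))
    ub = np.array([KX_BOUNDS[1]] + [KD_BOUNDS[1]] * len(infer))

    eval_count = [0]
    accepted: list[float] = []

    def predictions(theta: np.ndarray) -> list[np.ndarray] | None:
        kx = CrosslinkConstant(10.0 ** theta[0])
        specs = dict(ligands)
        for j, name in enumerate(infer):
            specs[name] = specs[name].with_kd_betagamma(10.0 ** theta[1 + j])
        preds = []
        for cv in curves:
            ligand = specs[cv["ligand"]]
            cell = panel[cv["cell_type"]]
            p = np.empty_like(cv["conc"])
            for i, l0 in enumerate(cv["conc"]):
                try:
                    p[i] = solve_equilibrium(ligand, cell, l0, kx).bound_betagamma
                except SolverError:
                    return None
            preds.append(p)
        return preds

    def scales_for(preds: list[np.ndarray]) -> dict[tuple[str, str], float]:
        out = {}
        for key, idxs in groups.items():
            num = sum(float(preds[i] @ curves[i]["y"]) for i in idxs)
            den = sum(float(preds[i] @ preds[i]) for i in idxs)
            s = num / den if den > 0 else 0.0
            out[key] = float(np.clip(s, *SCALE_BOUNDS)) if s > 0 else 0.0
        return out

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        eval_count[0] += 1
        preds = predictions(theta)
        if preds is None:
            return np.full(sum(c["y"].size for c in curves), 1e3)
        sc = scales_for(preds)
        res = []
        for i, cv in enumerate(curves):
            s = sc[(cv["experiment_id"], cv["cell_type"])]
            res.append(s * preds[i] - cv["y"])
        r = np.concatenate(res)
        cost = float(r @ r)
        if not accepted or cost < accepted[-1]:
            accepted.append(cost)
        return r

    sampler = qmc.LatinHypercube(d=n_params, seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lb, ub)

    results = []
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual_vec, x0, bounds=(lb, ub), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            results.append(sol)
        except Exception:  # noqa: BLE001 - record failed starts, keep sweeping
            results.append(None)
    costs = [2 * s.cost if s is not None else math.inf for s in results]
    best_i = int(np.argmin(costs))
    if not math.isfinite(costs[best_i]):
        return GlobalFitResult(
            kx_star=math.nan, kd_betagamma={}, scales={}, rss=math.nan,
            start_rss=costs, degenerate=False, message="all starts failed",
        )
    best = results[best_i]
    theta = best.x
    preds = predictions(theta)
    scales = scales_for(preds)
    return GlobalFitResult(
        kx_star=10.0 ** theta[0],
        kd_betagamma={name: 10.0 ** theta[1 + j] for j, name in enumerate(infer)},
        scales=scales,
        rss=float(costs[best_i]),
        start_rss=costs,
        best_start=best_i,
        n_evaluations=eval_count[0],
        accepted_trace=accepted,
        message=best.message,
    )


def global_model_rss(
    data: SignalingDataset,
    ligands: Mapping[str, LigandSpec],
    panel: Mapping[str, ReceptorProfile],
    kx_star: float,
) -> float:
    """RSS of the global objective at fixed parameters (scales profiled).

    Used for profile-likelihood style checks around a fitted optimum.
    """
    curves, _ = _normalized_curves(data)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, cv in enumerate(curves):
        groups.setdefault((cv["experiment_id"], cv["cell_type"]), []).append(i)
    kx = CrosslinkConstant(kx_star)
    preds = []
    for cv in curves:
        ligand = ligands[cv["ligand"]]
        cell = panel[cv["cell_type"]]
        preds.append(
            np.array(
                [solve_equilibrium(ligand, cell, l0, kx).bound_betagamma
                 for l0 in cv["conc"]]
            )
        )
    rss = 0.0
    for key, idxs in groups.items():
        num = sum(float(preds[i] @ curves[i]["y"]) for i in idxs)
        den = sum(float(preds[i] @ preds[i]) for i in idxs)
        s = num / den if den > 0 else 0.0
        for i in idxs:
            r = s * preds[i] - curves[i]["y"]
            rss += float(r @ r)
    return rss


# ---------------------------------------------------------------------------
# Gaussian affinity optimum


@dataclass(frozen=True)
class GaussianOptimum:
    """Gaussian fit of expansion ratio vs log10 EC50: peak = affinity optimum."""

    mu: float  # log10 EC50 units
    sigma: float
    amplitude: float
    residuals: np.ndarray
    warning: str = ""


def _gaussian(x: np.ndarray, mu: float, sigma: float, a: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_optimum(x: Sequence[float], y: Sequence[float]) -> GaussianOptimum:
    """Least-squares zero-baseline Gaussian locating the optimum x (peak).

    Monotone data (no interior peak) produce a fit whose ``mu`` falls outside
    the observed x range; this is reported via a poor-fit warning rather than
    an exception, since the location is then only weakly constrained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points for a Gaussian fit")
    span = float(x.max() - x.min())
    p0 = [float(x[np.argmax(y)]), max(span / 4.0, 1e-3), float(y.max())]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=p0,
            bounds=([x.min() - 2 * span, 1e-6, 0.0],
                    [x.max() + 2 * span, 10 * span, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        popt = p0
    resid = _gaussian(x, *popt) - y
    warning = ""
    if not (x.min() <= popt[0] <= x.max()):
        warning = (
            "fitted peak lies outside the data range; location weakly "
            "constrained (monotone data?) — wide confidence on mu"
        )
    return GaussianOptimum(
        mu=float(popt[0]), sigma=float(popt[1]), amplitude=float(popt[2]),
        residuals=resid, warning=warning,
    )
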
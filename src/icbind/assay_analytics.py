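"""Non-model assay quantifications: equilibrium K_D, two-phase PK, suppression.

Covers the supporting analyses around the binding model: first-order
(hyperbolic) equilibrium fits of bio-layer interferometry and yeast-display
titrations, a two-phase (biexponential) plasma-decay fit parameterized by
half-lives, and the percent-suppression arithmetic of the in vitro Treg
suppression assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TitrationCurve",
    "PKProfile",
    "EquilibriumKdFit",
    "BiexponentialFit",
    "fit_equilibrium_kd",
    "fit_biexponential_pk",
    "percent_suppression",
    "read_titration_table",
    "read_pk_table",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Equilibrium titration: analyte concentrations vs equilibrium response.

    ``reference`` is an optional reference-sensor response used for background
    subtraction (non-specific binding). If absent and a zero-concentration row
    is present, that row's response is the background; zero-concentration rows
    are excluded from fitting either way.
    """

    concentrations: np.ndarray  # molar
    responses: np.ndarray
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        pos = c[c > 0]
        if np.unique(pos).size != pos.size:
            raise ValueError("duplicate concentrations")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != c.shape:
                raise ValueError("reference must align with concentrations")
            object.__setattr__(self, "reference", ref)


@dataclass(frozen=True)
class PKProfile:
    """Plasma concentration–time series (hours, µg/mL)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must align")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class EquilibriumKdFit:
    kd: float  # molar
    rmax: float
    residuals: np.ndarray
    warning: str = ""


def fit_equilibrium_kd(curve: TitrationCurve) -> EquilibriumKdFit:
    """First-order equilibrium fit R(c) = Rmax·c/(Kd + c).

    Background is subtracted (reference sensor if provided, else the
    zero-concentration row) and the curve normalized to its maximum before
    fitting; Rmax is reported on the normalized scale, so Kd is what carries
    the information. A titration that never approaches saturation
    (max concentration < fitted Kd) gets a wide-confidence warning.
    """
    c = curve.concentrations
    r = curve.responses.astype(float).copy()
    if curve.reference is not None:
        r = r - curve.reference
    elif np.any(c == 0):
        r = r - r[c == 0][0]
    mask = c > 0
    c, r = c[mask], r[mask]
    if c.size < 4:
        raise ValueError("need >= 4 positive concentrations")
    top = np.abs(r).max()
    if top <= 0:
        raise ValueError("no signal after background subtraction")
    r = r / top

    order = np.argsort(c)
    c, r = c[order], r[order]

    def hyperbola(cc, kd, rmax):
        return rmax * cc / (kd + cc)

    # half-maximal crossing as the Kd start
    half = r.max() / 2.0
    kd0 = c[int(np.argmin(np.abs(r - half)))]
    popt, _ = optimize.curve_fit(
        hyperbola, c, r, p0=[kd0, r.max()],
        bounds=([c.min() * 1e-6, 0.0], [c.max() * 1e6, np.inf]),
        maxfev=20000,
    )
    kd, rmax = float(popt[0]), float(popt[1])
    resid = hyperbola(c, kd, rmax) - r
    warning = ""
    if c.max() < kd:
        warning = "titration does not reach saturation; Kd weakly constrained"
    return EquilibriumKdFit(kd=kd, rmax=rmax, residuals=resid, warning=warning)


@dataclass(frozen=True)
class BiexponentialFit:
    """Two-phase decay C(t) = A·2^(−t/t_fast) + B·2^(−t/t_slow).

    Half-life parameterization; ``t_half_fast <= t_half_slow`` always. A
    profile that is effectively mono-exponential collapses to a single phase
    (``single_phase=True``, amplitude_slow = 0).
    """

    t_half_fast: float  # hours
    t_half_slow: float
    amplitude_fast: float
    amplitude_slow: float
    residuals: np.ndarray
    single_phase: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.amplitude_fast * 2.0 ** (-t / self.t_half_fast)
        if not self.single_phase:
            out = out + self.amplitude_slow * 2.0 ** (-t / self.t_half_slow)
        return out


def _biexp(t, a, b, th_fast, th_slow):
    return a * 2.0 ** (-t / th_fast) + b * 2.0 ** (-t / th_slow)


def fit_biexponential_pk(profile: PKProfile) -> BiexponentialFit:
    """Fit a two-phase decay to a plasma concentration–time profile.

    Requires >= 6 time points. Fits both a mono- and a bi-exponential decay;
    if the mono-exponential already explains the data to numerical precision,
    or the two recovered phases are indistinguishable, the result collapses to
    a flagged single phase.
    """
    t = profile.times
    c = profile.concentrations
    if t.size < 6:
        raise ValueError("need >= 6 time points covering both phases")
    cmax = c.max()
    if cmax <= 0:
        raise ValueError("all concentrations are zero")

    tspan = t.max() - t[t > 0].min() if np.any(t > 0) else t.max()

    def mono(t_, a, th):
        return a * 2.0 ** (-t_ / th)

    p_mono, _ = optimize.curve_fit(
        mono, t, c, p0=[cmax, max(t.max() / 4.0, 1e-3)],
        bounds=([0.0, 1e-6], [np.inf, 1e6]), maxfev=20000,
    )
    rss_mono = float(np.sum((mono(t, *p_mono) - c) ** 2))
    if rss_mono <= 1e-18 * cmax**2 * t.size:
        return BiexponentialFit(
            t_half_fast=float(p_mono[1]), t_half_slow=float(p_mono[1]),
            amplitude_fast=float(p_mono[0]), amplitude_slow=0.0,
            residuals=mono(t, *p_mono) - c, single_phase=True,
        )

    th0 = max(t[t > 0].min(), 1e-3)
    starts = [
        [cmax, cmax / 10.0, th0, max(t.max() / 2.0, 10 * th0)],
        [cmax / 2.0, cmax / 2.0, th0 / 2.0, t.max()],
        [cmax, p_mono[0] / 10.0, th0 / 5.0, p_mono[1]],
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _biexp, t, c, p0=p0,
                bounds=([0.0, 0.0, 1e-6, 1e-6], [np.inf, np.inf, 1e6, 1e6]),
                maxfev=40000,
            )
        except RuntimeError:
            continue
        resid = _biexp(t, *popt) - c
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss, resid)
    if best is None:
        return BiexponentialFit(
            t_half_fast=float(p_mono[1]), t_half_slow=float(p_mono[1]),
            amplitude_fast=float(p_mono[0]), amplitude_slow=0.0,
            residuals=mono(t, *p_mono) - c, single_phase=True,
        )
    (a, b, th1, th2), rss_bi, resid = best
    # order phases: fast first
    if th1 > th2:
        a, b, th1, th2 = b, a, th2, th1
    degenerate = (
        min(a, b) < 1e-9 * (a + b)
        or abs(math.log(th2 / th1)) < 1e-3
        or rss_bi > 0.999999 * rss_mono  # no real improvement over one phase
    )
    if degenerate:
        return BiexponentialFit(
            t_half_fast=float(p_mono[1]), t_half_slow=float(p_mono[1]),
            amplitude_fast=float(p_mono[0]), amplitude_slow=0.0,
            residuals=mono(t, *p_mono) - c, single_phase=True,
        )
    return BiexponentialFit(
        t_half_fast=float(th1), t_half_slow=float(th2),
        amplitude_fast=float(a), amplitude_slow=float(b),
        residuals=resid,
    )


def percent_suppression(
    pct_ctv_neg_alone: float, pct_ctv_neg_with_treg: float
) -> float:
    """Percent suppression of Tconv proliferation by co-cultured Tregs.

    ((%CTV⁻ alone − %CTV⁻ with Treg) / %CTV⁻ alone) × 100. A negative value
    (enhancement of proliferation) is passed through, not clipped.
    """
    for name, val in (
        ("pct_ctv_neg_alone", pct_ctv_neg_alone),
        ("pct_ctv_neg_with_treg", pct_ctv_neg_with_treg),
    ):
        if not 0.0 <= val <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {val}")
    if pct_ctv_neg_alone == 0.0:
        raise ValueError("percent suppression undefined when %CTV⁻ alone is 0")
    return (pct_ctv_neg_alone - pct_ctv_neg_with_treg) / pct_ctv_neg_alone * 100.0


def read_titration_table(path: str | Path) -> TitrationCurve:
    """Read a titration table (TSV: conc_M, response[, reference])."""
    df = pd.read_csv(path, sep="\t")
    ref = df["reference"].to_numpy() if "reference" in df.columns else None
    return TitrationCurve(
        concentrations=df["conc_M"].to_numpy(),
        responses=df["response"].to_numpy(),
        reference=ref,
    )


def read_pk_table(path: str | Path) -> PKProfile:
    """Read a PK table (TSV: time_h, conc_ug_per_ml)."""
    df = pd.read_csv(path, sep="\t")
    return PKProfile(
        times=df["time_h"].to_numpy(),
        concentrations=df["conc_ug_per_ml"].to_numpy(),
    )
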
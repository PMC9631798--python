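"""Log-fold-change preprocessing and 2-component NNMF of expansion matrices.

In vivo immune-cell expansion data arrive as a treatments × cell-types table
of replicate-averaged cell counts including a vehicle (PBS) control row. Each
entry is converted to a log10 fold change versus the control, and the
resulting matrix (negatives clipped to zero, since the factorization requires
non-negativity) is decomposed with multiplicative-update non-negative matrix
factorization into k = 2 components, separating a Treg-selective expansion
axis from a nonselective one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpansionMatrix",
    "NNMFResult",
    "preprocess_expansion_matrix",
    "nnmf_factorize",
    "read_expansion_table",
]


@dataclass(frozen=True)
class ExpansionMatrix:
    """Treatments × cell-types table of replicate-averaged cell counts."""

    counts: pd.DataFrame  # index = treatments, columns = cell types
    control: str  # control (vehicle) row label

    def __post_init__(self) -> None:
        if self.control not in self.counts.index:
            raise ValueError(f"control row {self.control!r} not in matrix")
        if not (self.counts.to_numpy() > 0).all():
            raise ValueError("all counts must be > 0")


def preprocess_expansion_matrix(m: ExpansionMatrix) -> pd.DataFrame:
    """log10 fold change of each treatment's counts versus the control row.

    Entry = log10(count) − log10(count_control), per cell type; the control
    row is removed from the output. Negative values (treatments that reduced
    a subset) are preserved here — clipping to zero happens only at the NNMF
    input stage.
    """
    logs = np.log10(m.counts)
    lfc = logs.subtract(logs.loc[m.control], axis="columns")
    return lfc.drop(index=m.control)


@dataclass(frozen=True)
class NNMFResult:
    """Non-negative factorization V ≈ W·H (scores × loadings)."""

    scores: pd.DataFrame  # treatments × k
    loadings: pd.DataFrame  # k × cell types
    reconstruction_error: float  # Frobenius norm of V − WH
    iterations: int
    seed: int
    error_trace: np.ndarray
    trivial: bool = False  # all-zero input


def nnmf_factorize(
    lfc: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NNMFResult:
    """Seeded alternating-NNLS NMF of a (clipped) log-fold-change matrix.

    Negative entries are clipped to 0 before factorization. Factors start from
    an NNDSVD decomposition (zero entries filled with small seeded random
    values) and are refined by alternating exact non-negative least-squares
    sweeps: each half-step solves its subproblem to optimality, so the
    reconstruction error never increases. Iteration stops when the error
    improves by less than a relative factor ``tol`` in one sweep, or after
    ``max_iter`` sweeps. The per-iteration error trace is returned for
    diagnostics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.clip(lfc.to_numpy(dtype=float), 0.0, None)
    comp_index = [f"component_{i + 1}" for i in range(k)]
    if not v.any():
        zero_w = pd.DataFrame(0.0, index=lfc.index, columns=comp_index)
        zero_h = pd.DataFrame(0.0, index=comp_index, columns=lfc.columns)
        return NNMFResult(
            scores=zero_w, loadings=zero_h, reconstruction_error=0.0,
            iterations=0, seed=seed, error_trace=np.array([0.0]), trivial=True,
        )

    rng = np.random.default_rng(seed)
    w, h = _nndsvd_init(v, k, rng)

    trace = [np.linalg.norm(v - w @ h)]
    it = 0
    for it in range(1, max_iter + 1):
        h = _nnls_solve(w, v)
        w = _nnls_solve(h.T, v.T).T
        err = np.linalg.norm(v - w @ h)
        prev = trace[-1]
        trace.append(err)
        # relative-improvement stop: plateaus (noise floor) terminate early,
        # geometric convergence on exact low-rank input runs to completion
        if prev - err < tol * prev:
            break

    return NNMFResult(
        scores=pd.DataFrame(w, index=lfc.index, columns=comp_index),
        loadings=pd.DataFrame(h, index=comp_index, columns=lfc.columns),
        reconstruction_error=float(trace[-1]),
        iterations=it,
        seed=seed,
        error_trace=np.asarray(trace),
    )


def _nnls_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise exact non-negative least squares: argmin_{X>=0} ||A X − B||_F."""
    from scipy.optimize import nnls

    x = np.empty((a.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        x[:, j], _ = nnls(a, b[:, j])
    return x


def _nndsvd_init(
    v: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD factor initialization: per singular pair, keep the dominant
    sign-consistent part. Zeros are filled with small seeded random values."""
    n, p = v.shape
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    k_eff = min(k, s.size)
    w = np.zeros((n, k))
    h = np.zeros((k, p))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k_eff):
        x, y = u[:, j], vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            sig, xu, yu = mp, xp / np.linalg.norm(xp), yp / np.linalg.norm(yp)
        elif mn > 0:
            sig, xu, yu = mn, xn / np.linalg.norm(xn), yn / np.linalg.norm(yn)
        else:
            continue
        w[:, j] = np.sqrt(s[j] * sig) * xu
        h[j] = np.sqrt(s[j] * sig) * yu
    fill = v.mean() * 1e-4
    w[w <= 0] = fill * (0.5 + rng.random(np.count_nonzero(w <= 0)))
    h[h <= 0] = fill * (0.5 + rng.random(np.count_nonzero(h <= 0)))
    return w, h


def read_expansion_table(path: str | Path, control: str) -> ExpansionMatrix:
    """Read a counts table (TSV; first column treatment labels, header = cell types)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpansionMatrix(counts=df, control=control)
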
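"""Independent brute-force oracles used to check the binding model.

The exhaustive enumeration lists every configuration of a v-module ligand's
binding sites (each IL-2 module free, α-bound, βγ-bound, or both), assigns
each configuration the weight (l0/kx)·∏_bonds kx·R_j,eq/K_D,j (the all-free
configuration is excluded), and sums bond counts. It shares no code with the
closed-form implementation.
"""

import itertools

import numpy as np
from scipy import optimize

#: module states: (n_alpha_bonds, n_betagamma_bonds)
_STATES = [(0, 0), (1, 0), (0, 1), (1, 1)]


def enumerate_bound(l0, kx, valency, kd_alpha, kd_betagamma, ra_eq, rbg_eq):
    """Bound α, bound βγ and total bound-ligand weight by explicit enumeration."""
    chi_a = kx * ra_eq / kd_alpha
    chi_b = 0.0 if kd_betagamma is None else kx * rbg_eq / kd_betagamma
    state_weight = [1.0, chi_a, chi_b, chi_a * chi_b]
    bound_a = bound_b = total = 0.0
    for config in itertools.product(range(4), repeat=valency):
        if all(s == 0 for s in config):
            continue
        w = l0 / kx
        for s in config:
            w *= state_weight[s]
        bound_a += w * sum(_STATES[s][0] for s in config)
        bound_b += w * sum(_STATES[s][1] for s in config)
        total += w
    return bound_a, bound_b, total


def enumerate_solve(l0, kx, valency, kd_alpha, kd_betagamma, ra_tot, rbg_tot):
    """Solve receptor conservation using only the enumeration oracle."""

    def residual(logr):
        ra, rb = np.exp(logr)
        ba, bb, _ = enumerate_bound(l0, kx, valency, kd_alpha, kd_betagamma, ra, rb)
        return [
            (ra_tot - ra - ba) / max(ra_tot, 1.0),
            (rbg_tot - rb - bb) / max(rbg_tot, 1.0),
        ]

    sol = optimize.root(
        residual, np.log([max(ra_tot, 1e-12), max(rbg_tot, 1e-12)]),
        method="hybr", tol=1e-14,
    )
    assert sol.success or max(abs(r) for r in residual(sol.x)) < 1e-10
    return tuple(np.exp(sol.x))


def random_parameter_grid(rng, n):
    """Random physically plausible parameter points for oracle comparisons."""
    points = []
    for _ in range(n):
        points.append(
            {
                "l0": 10.0 ** rng.uniform(-13, -7),
                "kx": 10.0 ** rng.uniform(-13, -9),
                "kd_alpha": 10.0 ** rng.uniform(-10, -7),
                "kd_betagamma": 10.0 ** rng.uniform(-9, -5),
                "ra_tot": 10.0 ** rng.uniform(1.5, 4),
                "rbg_tot": 10.0 ** rng.uniform(1.5, 4),
            }
        )
    return points
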
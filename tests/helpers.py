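"""Independent oracles shared by the test suite.

Everything here recomputes quantities from first principles (brute force,
enumeration, ray marching, dense grid search) without touching the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from shieldplan.dose import DoseMatrix, ScenarioSpec

CGY_PER_GY = 100.0


def make_dose_matrix(values_gy_per_s, roles, voxel_cc: float = 0.001,
                     label: str = "nominal") -> DoseMatrix:
    """Hand-built dose matrix; ``values_gy_per_s`` given in Gy/s for
    readability, stored in the engine's cGy/s convention."""
    values = np.asarray(values_gy_per_s, float) * CGY_PER_GY
    roles = np.asarray(roles, dtype=object)
    return DoseMatrix(
        values=values,
        row_role=roles,
        row_voxel=np.arange(values.shape[0]),
        voxel_volume_cc=voxel_cc,
        scenario=ScenarioSpec(label=label) if label == "nominal"
        else ScenarioSpec(rotation_offset=0.0, label=label),
    )


# ---------------------------------------------------------------------------
# penalty objective recomputed from raw ingredients
# ---------------------------------------------------------------------------

def penalty_terms(ts: np.ndarray, values_cgy: np.ndarray, lower, upper,
                  w_low, w_high, q_low, q_high) -> np.ndarray:
    """g(t) for a batch of dwell-time vectors ``ts`` (M, J): positive-part
    penalties summed over dose points, doses in Gy."""
    dose = ts @ (values_cgy / CGY_PER_GY).T          # (M, N)
    short = np.maximum(np.asarray(lower) - dose, 0.0)
    over = np.maximum(dose - np.asarray(upper), 0.0)
    over = np.where(np.isfinite(np.asarray(upper)), over, 0.0)
    return (short * w_low + short ** 2 * q_low
            + over * w_high + over ** 2 * q_high).sum(axis=1)


def robust_objective_batch(ts, matrices, lower, upper, w_low, w_high,
                           q_low, q_high, lam, mean_weight) -> np.ndarray:
    g = np.stack([
        penalty_terms(ts, m.values, lower, upper, w_low, w_high, q_low, q_high)
        for m in matrices
    ])
    return lam * g.max(axis=0) + mean_weight * g.mean(axis=0)


def grid_search_minimum(objective_batch, n_combos: int, upper: float = 50.0,
                        final_step: float = 0.01):
    """Coarse-to-fine dense grid search for the global minimum of a convex
    objective over [0, upper]^J, refined until the grid step is <= the
    requested final step.  Convexity guarantees the optimum stays inside
    the shrinking boxes."""
    lo = np.zeros(n_combos)
    hi = np.full(n_combos, float(upper))
    step = upper / 100.0
    best_t, best_f = None, np.inf
    while True:
        axes = [np.arange(l, h + step / 2, step) for l, h in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        ts = np.column_stack([m.ravel() for m in mesh])
        f = objective_batch(ts)
        k = int(np.argmin(f))
        best_t, best_f = ts[k], float(f[k])
        if step <= final_step:
            return best_t, best_f
        lo = np.maximum(best_t - 2.0 * step, 0.0)
        hi = np.minimum(best_t + 2.0 * step, upper)
        step = max(step / 25.0, final_step)


# ---------------------------------------------------------------------------
# shield chord by ray marching
# ---------------------------------------------------------------------------

def ray_march_tungsten_chord(r_inner: float, r_outer: float, r_max: float = 30.0,
                             ds: float = 0.01) -> float:
    """Length of the radial ray segment inside the tungsten annulus,
    marched in ``ds`` steps from the axis outward."""
    s = np.arange(0.0, r_max, ds) + ds / 2.0
    inside = (s >= r_inner) & (s <= r_outer)
    return float(inside.sum() * ds)


# ---------------------------------------------------------------------------
# DVH brute force
# ---------------------------------------------------------------------------

def dvh_index_brute(doses: Sequence[float], frac_volume: float) -> float:
    """Largest dose d such that the fraction of voxels receiving >= d is at
    least ``frac_volume`` — scanned over all candidate dose levels."""
    d = np.asarray(doses, float)
    best = -np.inf
    for level in np.unique(d):
        if np.mean(d >= level) >= frac_volume - 1e-12:
            best = max(best, level)
    return float(best)


# ---------------------------------------------------------------------------
# signed-rank brute force
# ---------------------------------------------------------------------------

def _avg_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_exact_brute(diffs: Sequence[float]) -> float:
    """Two-sided exact signed-rank p-value by full enumeration of every
    sign assignment (independent of any library)."""
    d = np.asarray([x for x in diffs if x != 0.0], float)
    n = len(d)
    ranks = _avg_ranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product((0, 1), repeat=n):
        w_all.append(sum(r for s, r in zip(signs, ranks) if s))
    w_all = np.asarray(w_all)
    eps = 1e-9
    p_low = np.mean(w_all <= w_obs + eps)
    p_high = np.mean(w_all >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))
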
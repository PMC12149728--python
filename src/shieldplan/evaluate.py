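"""Plan evaluation: DVHs, dosimetric indices, worst-case ratios, statistics.

Dosimetric indices follow the DX / DXcc convention: the minimum dose
received by the hottest X percent (or X cm^3) of a structure, read from
the step cumulative DVH as the dose of the ceil(fraction * n)-th hottest
voxel (no interpolation).

Plans are evaluated on a fine grid after rescaling the dwell times so the
nominal CTV D90 equals the prescription dose; error scenarios are then
scored with the plan held fixed, and each index's worst case is taken
over the two signed scenarios of a given error magnitude (the minimum for
target indices, the maximum for OAR indices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats as scistats

from .dose import DoseMatrix, ScenarioSpec, SourceModel, build_dose_matrix
from .phantom import CombinationSet, Phantom, TARGET_ROLES

CGY_PER_GY = 100.0

#: default per-structure index panel
DEFAULT_INDEX_SPEC: Dict[str, Tuple[str, ...]] = {
    "ctv": ("D90", "D98"),
    "sup": ("D0.1cc", "D2cc", "D50"),
    "inf": ("D0.1cc", "D2cc", "D50"),
    "contra": ("D0.1cc", "D2cc", "D50"),
}


# ---------------------------------------------------------------------------
# DVH and indices
# ---------------------------------------------------------------------------

@dataclass
class DVH:
    """Cumulative DVH of one structure: descending per-voxel doses."""

    doses: np.ndarray          # Gy, sorted descending
    voxel_volume: float        # cc
    structure_volume: float    # cc

    @property
    def n(self) -> int:
        return len(self.doses)


def cumulative_dvh(dose_per_voxel: np.ndarray, voxel_volume: float) -> DVH:
    """Build the cumulative DVH from per-voxel doses (Gy)."""
    d = np.asarray(dose_per_voxel, float)
    if d.size == 0:
        raise ValueError("cannot build a DVH for an empty structure")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    doses = np.sort(d)[::-1]
    return DVH(doses=doses, voxel_volume=float(voxel_volume),
               structure_volume=float(d.size * voxel_volume))


def _kth_hottest(dvh: DVH, k_real: float) -> float:
    """Dose of the ceil(k_real)-th hottest voxel, robust to float fuzz."""
    if abs(k_real - round(k_real)) < 1e-9:
        k = int(round(k_real))
    else:
        k = int(math.ceil(k_real))
    k = min(max(k, 1), dvh.n)
    return float(dvh.doses[k - 1])


def dose_at_volume_percent(dvh: DVH, percent: float) -> float:
    """DX: minimum dose to the hottest ``percent`` % of the structure."""
    if not (0.0 < percent <= 100.0):
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    return _kth_hottest(dvh, percent / 100.0 * dvh.n)


def dose_at_volume_cc(dvh: DVH, cc: float) -> float:
    """DXcc: minimum dose to the hottest ``cc`` cm^3; the minimum
    structure dose when ``cc`` exceeds the structure volume."""
    if cc <= 0:
        raise ValueError(f"volume must be positive, got {cc}")
    return _kth_hottest(dvh, cc / dvh.voxel_volume)


def dose_index(dvh: DVH, name: str) -> float:
    """Evaluate an index named 'D<number>' (percent) or 'D<number>cc'."""
    if not name.startswith("D"):
        raise ValueError(f"unknown index {name!r}")
    body = name[1:]
    if body.endswith("cc"):
        return dose_at_volume_cc(dvh, float(body[:-2]))
    return dose_at_volume_percent(dvh, float(body))


# ---------------------------------------------------------------------------
# rescaling and plan statistics
# ---------------------------------------------------------------------------

def rescale_to_prescription(
    t: np.ndarray,
    eval_matrix_nominal: DoseMatrix,
    prescription: float = 10.0,
    ctv_role: str = "ctv",
) -> np.ndarray:
    """Scale dwell times so the nominal CTV D90 equals the prescription.

    Dose is linear in the dwell times, so a single multiplicative factor
    suffices; the factor is derived on the nominal evaluation matrix only.
    """
    t = np.asarray(t, float)
    rows = eval_matrix_nominal.rows_for(ctv_role)
    if not rows.any():
        raise ValueError(f"evaluation matrix has no rows for {ctv_role!r}")
    dose = eval_matrix_nominal.values[rows] @ t / CGY_PER_GY
    d90 = dose_at_volume_percent(
        cumulative_dvh(dose, eval_matrix_nominal.voxel_volume_cc), 90.0)
    if d90 <= 0:
        raise ValueError("CTV receives no dose; cannot rescale")
    return t * (prescription / d90)


@dataclass(frozen=True)
class PlanStats:
    """Deliverability statistics of a plan."""

    n_active: int          # combinations with dwell time > threshold
    longest_dwell: float   # s
    total_time: float      # s
    active_threshold: float = 0.5


def plan_statistics(t: np.ndarray, active_threshold: float = 0.5) -> PlanStats:
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("dwell times must be nonnegative")
    return PlanStats(
        n_active=int(np.count_nonzero(t > active_threshold)),
        longest_dwell=float(t.max(initial=0.0)),
        total_time=float(t.sum()),
        active_threshold=float(active_threshold),
    )


# ---------------------------------------------------------------------------
# worst-case evaluation
# ---------------------------------------------------------------------------

@dataclass
class IndexReport:
    """Per-structure dosimetric indices and worst-case/nominal ratios.

    Keys are (role, index); scenario blocks are keyed by (error kind,
    magnitude) with kind in {"rotation", "translation"}.
    """

    nominal: Dict[Tuple[str, str], float]
    per_scenario: Dict[Tuple[str, float], Dict[Tuple[str, str], Dict[str, float]]]
    worst: Dict[Tuple[str, float], Dict[Tuple[str, str], float]]
    ratios: Dict[Tuple[str, float], Dict[Tuple[str, str], float]]
    structure_volumes_cc: Dict[str, float] = field(default_factory=dict)

    def ratio(self, kind: str, magnitude: float, role: str, index: str) -> float:
        return self.ratios[(kind, float(magnitude))][(role, index)]

    def to_records(self) -> List[Dict]:
        rows = []
        for (kind, mag), block in self.ratios.items():
            for (role, index), ratio in block.items():
                rows.append({
                    "kind": kind, "magnitude": mag, "structure": role, "index": index,
                    "nominal_gy": self.nominal[(role, index)],
                    "worst_gy": self.worst[(kind, mag)][(role, index)],
                    "ratio": ratio,
                })
        return rows


def _structure_indices(
    dose_by_role: Mapping[str, np.ndarray],
    voxel_volume: float,
    index_spec: Mapping[str, Sequence[str]],
) -> Dict[Tuple[str, str], float]:
    out = {}
    for role, names in index_spec.items():
        dvh = cumulative_dvh(dose_by_role[role], voxel_volume)
        for name in names:
            out[(role, name)] = dose_index(dvh, name)
    return out


def _scenario_doses(
    t: np.ndarray,
    phantom: Phantom,
    combos: CombinationSet,
    scenario: ScenarioSpec,
    model: SourceModel,
    roles: Sequence[str],
) -> Dict[str, np.ndarray]:
    m = build_dose_matrix(phantom, combos, scenario, model, roles=roles)
    dose = m.values @ np.asarray(t, float) / CGY_PER_GY
    return {role: dose[m.rows_for(role)] for role in roles}


def evaluate_plan(
    t: np.ndarray,
    phantom: Phantom,
    combos: CombinationSet,
    model: SourceModel,
    rotation_magnitudes: Sequence[float] = (3.0, 5.0, 10.0),
    translation_magnitudes: Sequence[float] = (1.0, 2.0, 3.0),
    index_spec: Mapping[str, Sequence[str]] | None = None,
) -> IndexReport:
    """Score a fixed plan under signed systematic error scenarios.

    ``phantom`` should be at evaluation resolution and ``t`` already
    rescaled on the nominal evaluation matrix.  For each error magnitude
    the indices are computed under the +delta and -delta scenarios; the
    worst case per index is the minimum over the signed pair for target
    structures and the maximum for OARs, and is reported as a ratio
    against the nominal value.
    """
    index_spec = dict(index_spec or
                      {r: DEFAULT_INDEX_SPEC[r] for r in phantom.roles()})
    roles = list(index_spec)
    vol = phantom.voxel_volume_cc

    nominal_dose = _scenario_doses(t, phantom, combos, ScenarioSpec(), model, roles)
    nominal = _structure_indices(nominal_dose, vol, index_spec)

    per_scenario: Dict = {}
    worst: Dict = {}
    ratios: Dict = {}
    blocks = [("rotation", m) for m in rotation_magnitudes]
    blocks += [("translation", m) for m in translation_magnitudes]
    for kind, mag in blocks:
        mag = float(mag)
        if kind == "rotation":
            pair = [ScenarioSpec(rotation_offset=s * mag, label=f"rot{s * mag:+g}")
                    for s in (+1, -1)]
        else:
            pair = [ScenarioSpec(translation_offset=s * mag, label=f"trans{s * mag:+g}")
                    for s in (+1, -1)]
        values: Dict[Tuple[str, str], Dict[str, float]] = {k: {} for k in nominal}
        for scen in pair:
            dose = _scenario_doses(t, phantom, combos, scen, model, roles)
            idx = _structure_indices(dose, vol, index_spec)
            for key, v in idx.items():
                values[key][scen.label] = v
        per_scenario[(kind, mag)] = values
        worst[(kind, mag)] = {}
        ratios[(kind, mag)] = {}
        for (role, name), by_label in values.items():
            agg = min if role in TARGET_ROLES else max
            w = agg(by_label.values())
            worst[(kind, mag)][(role, name)] = w
            ratios[(kind, mag)][(role, name)] = w / nominal[(role, name)]

    return IndexReport(
        nominal=nominal, per_scenario=per_scenario, worst=worst, ratios=ratios,
        structure_volumes_cc={r: phantom.structure_volume_cc(r) for r in roles},
    )


# ---------------------------------------------------------------------------
# paired signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedRankResult:
    statistic: float       # W+ = sum of ranks of positive differences
    p_value: float         # two-sided
    n: int                 # pairs remaining after dropping zero differences
    no_difference: bool = False
    method: str = "exact"


def paired_signed_rank(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_threshold: int = 15,
) -> SignedRankResult:
    """Two-sided paired signed-rank test on per-phantom metrics.

    Zero differences are dropped; tied magnitudes receive average ranks.
    The null distribution of W+ is enumerated exactly over all 2^n sign
    assignments for n <= ``exact_threshold`` and approximated by a
    tie-corrected normal beyond.  Identical samples yield a flagged
    no-difference result rather than an error.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return SignedRankResult(statistic=0.0, p_value=1.0, n=0,
                                no_difference=True, method="degenerate")
    n = int(d.size)
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks = scistats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_threshold:
        masks = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        w_all = masks @ ranks
        eps = 1e-9
        p_low = np.count_nonzero(w_all <= w_plus + eps) / w_all.size
        p_high = np.count_nonzero(w_all >= w_plus - eps) / w_all.size
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = float(((counts ** 3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        z = (w_plus - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * scistats.norm.sf(abs(z)))
        method = "normal"
    return SignedRankResult(statistic=w_plus, p_value=float(p), n=n, method=method)
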
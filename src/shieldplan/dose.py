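"""Analytic shielded-source dose engine and positional-error scenarios.

Dose-rate kernel per dwell position (point-source approximation):

    d(p) = R10 * (10 / r)^2 * exp(-mu_w * (r - 10)) * T(phi)

with ``r`` the distance (mm) from the source to the point, ``mu_w`` an
effective attenuation coefficient in water, and ``T(phi)`` the azimuthal
transmission of the rotating tungsten shield: 1 inside the emission
window, exp(-mu_s * chord) through the tungsten annulus outside, with a
linear penumbra ramp at the window edge.  ``R10`` is the unshielded
reference dose rate at 10 mm lateral distance (cGy/s).

Positional uncertainties are systematic: a scenario applies one signed
rotational offset (shield angle) or one signed translational offset
(source position along the applicator axis) to every combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .phantom import ApplicatorSpec, CombinationSet, Phantom, _wrap_deg

log = logging.getLogger("shieldplan.dose")


@dataclass(frozen=True)
class SourceModel:
    """Parameters of the analytic kernel.

    reference_dose_rate
        Unshielded dose rate at 10 mm lateral distance, cGy/s.  The
        default corresponds to a ~10 Ci HDR source.
    effective_attenuation_mu
        Effective attenuation+scatter coefficient in water, 1/mm.  Small,
        because scatter build-up nearly cancels primary attenuation for
        high-energy HDR sources within the first few cm.
    shield_attenuation_mu
        Linear attenuation in tungsten, 1/mm.  The default renders the
        shield effectively opaque (transmission < 1e-3 through the full
        annulus).
    min_distance
        Distance cutoff, mm.  Points closer to the source are evaluated
        at the clamped distance (and counted), never at infinity.
    penumbra_width
        Angular width (degrees) of the linear transmission ramp at the
        emission-window edge; 0 gives a hard edge.
    """

    reference_dose_rate: float = 7.5       # cGy/s at 10 mm
    effective_attenuation_mu: float = 0.003  # 1/mm in water
    shield_attenuation_mu: float = 1.0       # 1/mm in tungsten
    min_distance: float = 2.0                # mm
    penumbra_width: float = 5.0              # degrees

    def __post_init__(self) -> None:
        if min(self.reference_dose_rate, self.effective_attenuation_mu,
               self.shield_attenuation_mu, self.penumbra_width) < 0:
            raise ValueError("source-model parameters must be nonnegative")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """One systematic positional-error scenario.

    Exactly one of the offsets is nonzero, or both are zero (the nominal
    scenario).
    """

    rotation_offset: float = 0.0     # degrees, signed
    translation_offset: float = 0.0  # mm along applicator axis, signed
    label: str = "nominal"

    def __post_init__(self) -> None:
        if self.rotation_offset != 0.0 and self.translation_offset != 0.0:
            raise ValueError("a scenario carries a rotational or a translational offset, not both")
        if abs(self.rotation_offset) > 30:
            raise ValueError("|rotation_offset| must be <= 30 degrees")
        if abs(self.translation_offset) > 10:
            raise ValueError("|translation_offset| must be <= 10 mm")

    @property
    def is_nominal(self) -> bool:
        return self.rotation_offset == 0.0 and self.translation_offset == 0.0


NOMINAL = ScenarioSpec()


@dataclass(frozen=True)
class ScenarioSet:
    """Ordered scenario collection; the first entry is the nominal one."""

    scenarios: Tuple[ScenarioSpec, ...]

    def __post_init__(self) -> None:
        scen = tuple(self.scenarios)
        if not scen:
            raise ValueError("scenario set must be nonempty")
        labels = [s.label for s in scen]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        n_nominal = sum(s.is_nominal for s in scen)
        if n_nominal != 1 or not scen[0].is_nominal:
            raise ValueError("exactly one nominal scenario is required, listed first")
        object.__setattr__(self, "scenarios", scen)

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    @classmethod
    def nominal_only(cls) -> "ScenarioSet":
        return cls((NOMINAL,))

    @classmethod
    def rotation(cls, magnitude: float, include_nominal: bool = True) -> "ScenarioSet":
        """{nominal, +delta, -delta} rotational scenario set (degrees)."""
        pos = ScenarioSpec(rotation_offset=+magnitude, label=f"rot+{magnitude:g}")
        neg = ScenarioSpec(rotation_offset=-magnitude, label=f"rot-{magnitude:g}")
        if not include_nominal:
            raise ValueError("the scenario set must contain the nominal scenario first")
        return cls((NOMINAL, pos, neg))

    @classmethod
    def translation(cls, magnitude: float, include_nominal: bool = True) -> "ScenarioSet":
        """{nominal, +delta, -delta} translational scenario set (mm)."""
        pos = ScenarioSpec(translation_offset=+magnitude, label=f"trans+{magnitude:g}")
        neg = ScenarioSpec(translation_offset=-magnitude, label=f"trans-{magnitude:g}")
        if not include_nominal:
            raise ValueError("the scenario set must contain the nominal scenario first")
        return cls((NOMINAL, pos, neg))


def perturb_combination(
    dwell_axial: float, shield_angle: float, scenario: ScenarioSpec
) -> Tuple[float, float]:
    """Apply the systematic scenario offset to one combination."""
    return (
        dwell_axial + scenario.translation_offset,
        float(np.mod(shield_angle + scenario.rotation_offset, 360.0)),
    )


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def shield_transmission(
    azimuth_from_window_centre,
    applicator: ApplicatorSpec,
    model: SourceModel,
):
    """Azimuthal transmission factor in (0, 1].

    The ray from the on-axis source to any point is radial in
    cross-section, so the tungsten path length is the annulus chord
    ``shield_radius - channel_radius`` whenever the azimuth falls outside
    the emission window, independent of how far outside.  A linear ramp
    of width ``penumbra_width`` just inside the window edge softens the
    transition.
    """
    az = np.abs(_wrap_deg(np.asarray(azimuth_from_window_centre, float)))
    ww = applicator.window_width
    if ww >= 360.0:
        return np.ones_like(az) if az.ndim else 1.0
    pen = model.penumbra_width
    if pen > ww / 2.0:
        raise ValueError("penumbra_width must not exceed half the window width")
    half = ww / 2.0
    chord = applicator.shield_radius - applicator.channel_radius
    t_out = float(np.exp(-model.shield_attenuation_mu * chord))
    if pen == 0.0:
        out = np.where(az <= half, 1.0, t_out)
    else:
        ramp = 1.0 + (t_out - 1.0) * (az - (half - pen)) / pen
        out = np.where(az <= half - pen, 1.0, np.where(az >= half, t_out, ramp))
    return out if out.ndim else float(out)


def dose_rate(
    point,
    dwell_axial: float,
    shield_angle: float,
    applicator: ApplicatorSpec,
    model: SourceModel,
):
    """Dose rate (cGy/s) at ``point`` (mm, may be (..., 3)) from one
    combination.  Distances below ``model.min_distance`` are clamped."""
    p = np.asarray(point, float)
    src = np.asarray(applicator.axis_origin, float) + np.array([0.0, 0.0, dwell_axial])
    rel = p - src
    r = np.linalg.norm(rel, axis=-1)
    r = np.maximum(r, model.min_distance)
    az = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))
    trans = shield_transmission(az - shield_angle, applicator, model)
    val = (model.reference_dose_rate * (10.0 / r) ** 2
           * np.exp(-model.effective_attenuation_mu * (r - 10.0)) * trans)
    return val if np.ndim(val) else float(val)


# ---------------------------------------------------------------------------
# dose matrices
# ---------------------------------------------------------------------------

@dataclass
class DoseMatrix:
    """Dose-rate contributions for one scenario.

    ``values[i, j]`` is the dose rate (cGy/s) at dose point ``i`` from
    combination ``j``; rows are grouped by structure role in the order of
    ``role_order``.
    """

    values: np.ndarray               # (n_points, |J|), cGy/s
    row_role: np.ndarray             # (n_points,) structure role per row
    row_voxel: np.ndarray            # (n_points,) flat voxel index in the grid
    voxel_volume_cc: float
    scenario: ScenarioSpec
    clamped_points: int = 0          # dose points within min_distance of a dwell

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (dose points x combinations)")
        if len(self.row_role) != self.values.shape[0]:
            raise ValueError("row_role length must match the number of rows")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose-rate entries must be finite and nonnegative")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_combos(self) -> int:
        return self.values.shape[1]

    @property
    def role_order(self) -> List[str]:
        seen: List[str] = []
        for r in self.row_role:
            if r not in seen:
                seen.append(str(r))
        return seen

    def rows_for(self, role: str) -> np.ndarray:
        return np.asarray(self.row_role) == role

    def dose(self, t: np.ndarray) -> np.ndarray:
        """Total dose (same units as values * seconds) for dwell times t."""
        return self.values @ np.asarray(t, float)


def build_dose_matrix(
    phantom: Phantom,
    combos: CombinationSet,
    scenario: ScenarioSpec,
    model: SourceModel,
    roles: Sequence[str] | None = None,
) -> DoseMatrix:
    """Assemble d_ijr for one scenario.

    Dose points are the centres of all voxels inside each structure mask;
    rows are grouped by role.  The scenario's systematic offset is applied
    to every combination; the kernel is re-evaluated exactly (no
    interpolation from the unperturbed angular library).
    """
    roles = list(roles) if roles is not None else phantom.roles()
    pts_list, role_list, vox_list = [], [], []
    for role in roles:
        mask = phantom.structure_masks.get(role)
        if mask is None or not mask.any():
            raise ValueError(f"structure {role!r} is missing or empty in the phantom")
        pts = phantom.structure_points(role)
        pts_list.append(pts)
        role_list.append(np.full(len(pts), role, dtype=object))
        vox_list.append(np.flatnonzero(mask.ravel()))
    points = np.vstack(pts_list)
    row_role = np.concatenate(role_list)
    row_voxel = np.concatenate(vox_list)

    dwell_pert = combos.dwell_positions + scenario.translation_offset
    # distances depend only on the dwell position; transmissions only on the angle
    origin = np.asarray(phantom.applicator.axis_origin, float)
    dz = points[:, 2:3] - (origin[2] + dwell_pert[None, :])       # (N, nd)
    lat2 = (points[:, 0] - origin[0]) ** 2 + (points[:, 1] - origin[1]) ** 2
    r = np.sqrt(lat2[:, None] + dz ** 2)                           # (N, nd)
    clamped = int(np.count_nonzero(r < model.min_distance))
    r = np.maximum(r, model.min_distance)
    geom = (model.reference_dose_rate * (10.0 / r) ** 2
            * np.exp(-model.effective_attenuation_mu * (r - 10.0)))

    az_pts = np.degrees(np.arctan2(points[:, 1] - origin[1], points[:, 0] - origin[0]))
    ang_pert = np.mod(combos.shield_angles + scenario.rotation_offset, 360.0)
    trans = shield_transmission(
        az_pts[:, None] - ang_pert[None, :], phantom.applicator, model
    )                                                              # (N, na)

    values = (geom[:, :, None] * trans[:, None, :]).reshape(len(points), combos.size)
    if clamped:
        log.info("dose matrix %s: %d point-dwell pairs clamped to min_distance",
                 scenario.label, clamped)
    return DoseMatrix(
        values=values,
        row_role=row_role,
        row_voxel=row_voxel,
        voxel_volume_cc=phantom.voxel_volume_cc,
        scenario=scenario,
        clamped_points=clamped,
    )


def build_scenario_matrices(
    phantom: Phantom,
    combos: CombinationSet,
    scenarios: ScenarioSet,
    model: SourceModel,
    roles: Sequence[str] | None = None,
) -> List[DoseMatrix]:
    return [build_dose_matrix(phantom, combos, s, model, roles) for s in scenarios]
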
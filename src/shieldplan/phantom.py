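"""Synthetic voxel phantoms for endorectal rotating-shield brachytherapy.

A cylindrical intracavitary applicator sits on the +z axis of a
water-equivalent voxel grid.  The clinical target volume (CTV) is an
azimuthal sector of the rectal-wall annulus abutting the applicator
surface; the contralateral healthy wall (``contra``) is the wall sector
centred 180 degrees opposite; two dose-spill box structures (``sup``,
``inf``) sit 10 mm beyond the superior/inferior axial extent of the CTV.

Coordinate convention (fixed here, used everywhere downstream):
right-handed grid, applicator axis = +z (inferior to superior), azimuth
in degrees counterclockwise viewed from superior, 0 degrees at the CTV
sector centre.  Voxel coordinates are voxel centres with the grid centred
on the applicator axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

STRUCTURE_ROLES = ("ctv", "contra", "sup", "inf")

#: structures treated as planning targets; everything else is an OAR
TARGET_ROLES = frozenset({"ctv"})


# ---------------------------------------------------------------------------
# applicator and combination discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApplicatorSpec:
    """Cylindrical shielded applicator geometry.

    Defaults follow a silicone applicator of 20 mm outer diameter holding
    a 15 mm tungsten shield with a central 2 mm source channel and an
    8 cm long emission window (180 or 90 degrees wide).
    """

    outer_diameter: float = 20.0      # mm
    shield_diameter: float = 15.0     # mm
    channel_diameter: float = 2.0     # mm
    window_width: float = 180.0       # degrees
    window_length: float = 80.0       # mm
    axis_origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.channel_diameter < self.shield_diameter < self.outer_diameter):
            raise ValueError(
                "require channel_diameter < shield_diameter < outer_diameter, got "
                f"{self.channel_diameter}/{self.shield_diameter}/{self.outer_diameter}"
            )
        if not (0.0 < self.window_width <= 360.0):
            raise ValueError(f"window_width must lie in (0, 360], got {self.window_width}")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        d = np.asarray(self.axis_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("axis_direction must be a unit vector")
        # The analytic dose engine assumes the axis points along +z; the
        # field is stored for completeness but tilted applicators are not
        # modelled.
        if not np.allclose(d, (0.0, 0.0, 1.0), atol=1e-12):
            raise NotImplementedError("only axis_direction = +z is supported")

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def shield_radius(self) -> float:
        return self.shield_diameter / 2.0

    @property
    def channel_radius(self) -> float:
        return self.channel_diameter / 2.0


def enumerate_dwell_positions(applicator: ApplicatorSpec, spacing: float = 5.0) -> np.ndarray:
    """Axial dwell coordinates (mm) at uniform ``spacing`` along the channel.

    Positions span the emission-window length, inclusive of both ends and
    centred on the window (axial coordinate 0 = window centre).  A spacing
    larger than the window collapses to the single central position.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    length = applicator.window_length
    n = int(np.floor(length / spacing + 1e-9)) + 1
    span = (n - 1) * spacing
    return -span / 2.0 + spacing * np.arange(n)


def enumerate_shield_angles(increment: float = 15.0) -> np.ndarray:
    """Shield angles {0, inc, 2*inc, ...} covering [0, 360) degrees."""
    if increment <= 0:
        raise ValueError("increment must be positive")
    k = 360.0 / increment
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"increment must divide 360 exactly, got {increment}")
    return increment * np.arange(int(round(k)), dtype=float)


@dataclass(frozen=True)
class CombinationSet:
    """Enumerated (dwell position, shield angle) combinations.

    ``combos`` is dwell-major: combination j = (j // n_angles, j % n_angles).
    """

    dwell_positions: np.ndarray   # mm, strictly increasing, uniform spacing
    shield_angles: np.ndarray     # degrees in [0, 360), strictly increasing

    def __post_init__(self) -> None:
        dp = np.asarray(self.dwell_positions, float)
        sa = np.asarray(self.shield_angles, float)
        if dp.size == 0 or sa.size == 0:
            raise ValueError("dwell positions and shield angles must be nonempty")
        if dp.size > 1:
            d = np.diff(dp)
            if np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-9):
                raise ValueError("dwell positions must be strictly increasing with uniform spacing")
        if np.any(np.diff(sa) <= 0) or np.any(sa < 0) or np.any(sa >= 360):
            raise ValueError("shield angles must be strictly increasing in [0, 360)")
        object.__setattr__(self, "dwell_positions", dp)
        object.__setattr__(self, "shield_angles", sa)

    @classmethod
    def build(
        cls,
        applicator: ApplicatorSpec,
        dwell_spacing: float = 5.0,
        angle_increment: float = 15.0,
    ) -> "CombinationSet":
        return cls(
            dwell_positions=enumerate_dwell_positions(applicator, dwell_spacing),
            shield_angles=enumerate_shield_angles(angle_increment),
        )

    @property
    def n_dwell(self) -> int:
        return len(self.dwell_positions)

    @property
    def n_angles(self) -> int:
        return len(self.shield_angles)

    @property
    def size(self) -> int:
        """|J| = number of (dwell, angle) combinations."""
        return self.n_dwell * self.n_angles

    @property
    def combos(self) -> List[Tuple[int, int]]:
        return [(i, a) for i in range(self.n_dwell) for a in range(self.n_angles)]

    def combo_coordinates(self) -> Tuple[np.ndarray, np.ndarray]:
        """(axial mm, angle deg) arrays of length |J| in combination order."""
        ax = np.repeat(self.dwell_positions, self.n_angles)
        ang = np.tile(self.shield_angles, self.n_dwell)
        return ax, ang


# ---------------------------------------------------------------------------
# phantom container
# ---------------------------------------------------------------------------

def _axis_coords(n: int, h: float) -> np.ndarray:
    """Voxel-centre coordinates of ``n`` voxels of size ``h``, grid centred at 0."""
    return (np.arange(n) - (n - 1) / 2.0) * h


@dataclass
class Phantom:
    """Voxel phantom: structure masks on a regular grid plus the applicator.

    ``geometry`` carries the continuous (resolution-independent) structure
    parameters so the same anatomy can be re-rasterized at another voxel
    size (planning vs evaluation grids).
    """

    grid_shape: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float]      # mm per axis
    structure_masks: Dict[str, np.ndarray]      # role -> boolean mask
    applicator: ApplicatorSpec
    geometry: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, mask in self.structure_masks.items():
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {role!r} shape {mask.shape} != grid {self.grid_shape}")
        if "ctv" not in self.structure_masks or not self.structure_masks["ctv"].any():
            raise ValueError("phantom must contain a nonempty CTV mask")
        if (self.structure_masks.get("contra") is not None
                and np.any(self.structure_masks["ctv"] & self.structure_masks["contra"])):
            raise ValueError("CTV and contra masks must be disjoint")

    @property
    def voxel_volume_cc(self) -> float:
        hx, hy, hz = self.voxel_size
        return hx * hy * hz / 1000.0

    def axis_coords(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            _axis_coords(n, h) for n, h in zip(self.grid_shape, self.voxel_size)
        )

    def structure_points(self, role: str) -> np.ndarray:
        """(N, 3) voxel-centre coordinates (mm) of the voxels in ``role``."""
        mask = self.structure_masks[role]
        xs, ys, zs = self.axis_coords()
        ii, jj, kk = np.nonzero(mask)
        return np.column_stack([xs[ii], ys[jj], zs[kk]])

    def structure_volume_cc(self, role: str) -> float:
        return float(self.structure_masks[role].sum()) * self.voxel_volume_cc

    def roles(self) -> List[str]:
        return [r for r in STRUCTURE_ROLES if r in self.structure_masks]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic patient cohort.

    Tumor angular width, length and axial offset are drawn uniformly from
    the stated ranges under a splittable per-phantom seed, emulating
    patient-to-patient variability of noncircumferential rectal tumors.
    """

    n_phantoms: int = 10
    tumor_angular_width_range: Tuple[float, float] = (90.0, 150.0)   # degrees
    tumor_length_range: Tuple[float, float] = (30.0, 50.0)           # mm
    tumor_axial_offset_max: float = 8.0                              # mm, |offset|
    wall_thickness: float = 5.0                                      # mm
    contra_angular_width: float = 180.0                              # degrees
    spill_box_halfwidth: float = 15.0                                # mm lateral half-extent
    spill_box_length: float = 10.0                                   # mm axial extent
    spill_gap: float = 10.0                                          # mm beyond CTV extent
    grid_extent: Tuple[float, float, float] = (52.0, 52.0, 130.0)    # mm physical size
    planning_voxel: float = 3.0                                      # mm isotropic
    evaluation_voxel: float = 1.0                                    # mm isotropic
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")
        lo, hi = self.tumor_angular_width_range
        if not (0 < lo <= hi <= 360):
            raise ValueError("tumor angular width range must be nonempty within (0, 360]")
        lo, hi = self.tumor_length_range
        if not (0 < lo <= hi):
            raise ValueError("tumor length range must be nonempty and positive")
        if not (0 < self.contra_angular_width <= 180):
            raise ValueError("contra_angular_width must lie in (0, 180]")


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(a, float), 360.0)


def _draw_geometry(spec: CohortSpec, index: int) -> Dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.master_seed), int(index)]))
    width = rng.uniform(*spec.tumor_angular_width_range)
    length = rng.uniform(*spec.tumor_length_range)
    z_centre = rng.uniform(-spec.tumor_axial_offset_max, spec.tumor_axial_offset_max)
    return {
        "tumor_angular_width": float(width),
        "tumor_length": float(length),
        "tumor_z_centre": float(z_centre),
    }


def rasterize_phantom(
    geometry: Dict[str, float],
    spec: CohortSpec,
    applicator: ApplicatorSpec,
    voxel_size: float,
) -> Phantom:
    """Rasterize the continuous structure geometry onto a voxel grid.

    Membership is by voxel centre.  The grid is centred on the applicator
    axis, which keeps a CTV sector centred at azimuth 0 exactly mirror
    symmetric under y -> -y.
    """
    width = geometry["tumor_angular_width"]
    length = geometry["tumor_length"]
    zc = geometry["tumor_z_centre"]

    if width > 360.0:
        raise ValueError(f"tumor sector width {width} deg exceeds 360")
    if width + spec.contra_angular_width >= 360.0:
        raise ValueError(
            "tumor and contralateral sectors would overlap: "
            f"{width} + {spec.contra_angular_width} >= 360"
        )
    z_ctv_max = zc + length / 2.0
    z_ctv_min = zc - length / 2.0
    z_sup_far = z_ctv_max + spec.spill_gap + spec.spill_box_length
    z_inf_far = z_ctv_min - spec.spill_gap - spec.spill_box_length
    half_z = spec.grid_extent[2] / 2.0
    if z_sup_far > half_z or z_inf_far < -half_z:
        raise ValueError(
            f"grid z-extent {spec.grid_extent[2]} mm too small to contain the "
            f"sup/inf dose-spill boxes (need [{z_inf_far:.1f}, {z_sup_far:.1f}] mm)"
        )

    shape = tuple(int(round(e / voxel_size)) for e in spec.grid_extent)
    xs = _axis_coords(shape[0], voxel_size)
    ys = _axis_coords(shape[1], voxel_size)
    zs = _axis_coords(shape[2], voxel_size)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    R = np.hypot(X, Y)
    AZ = np.degrees(np.arctan2(Y, X))

    r_in = applicator.outer_radius
    r_out = r_in + spec.wall_thickness
    annulus = (R >= r_in) & (R <= r_out)
    in_z = (Z >= z_ctv_min) & (Z <= z_ctv_max)

    ctv = annulus & in_z & (np.abs(_wrap_deg(AZ)) <= width / 2.0)
    contra = annulus & in_z & (np.abs(_wrap_deg(AZ - 180.0)) <= spec.contra_angular_width / 2.0)

    hw = spec.spill_box_halfwidth
    box_xy = (np.abs(X) <= hw) & (np.abs(Y) <= hw) & (R >= r_in)
    sup = box_xy & (Z >= z_ctv_max + spec.spill_gap) & (Z <= z_sup_far)
    inf = box_xy & (Z <= z_ctv_min - spec.spill_gap) & (Z >= z_inf_far)

    for role, mask in (("ctv", ctv), ("contra", contra), ("sup", sup), ("inf", inf)):
        if not mask.any():
            raise ValueError(f"structure {role!r} rasterized to an empty mask at "
                             f"{voxel_size} mm resolution")

    geo = dict(geometry)
    geo.update({
        "ctv_z_min": z_ctv_min, "ctv_z_max": z_ctv_max,
        "sup_z_min": z_ctv_max + spec.spill_gap,
        "inf_z_max": z_ctv_min - spec.spill_gap,
    })
    return Phantom(
        grid_shape=shape,
        voxel_size=(voxel_size,) * 3,
        structure_masks={"ctv": ctv, "contra": contra, "sup": sup, "inf": inf},
        applicator=applicator,
        geometry=geo,
    )


def generate_phantom(
    spec: CohortSpec,
    index: int,
    applicator: ApplicatorSpec | None = None,
    voxel_size: float | None = None,
) -> Phantom:
    """Generate phantom ``index`` of the cohort — deterministic in
    (master_seed, index) and independent of the requested resolution."""
    if not (0 <= index < spec.n_phantoms):
        raise ValueError(f"index {index} out of range for cohort of {spec.n_phantoms}")
    applicator = applicator or ApplicatorSpec()
    voxel = spec.planning_voxel if voxel_size is None else float(voxel_size)
    geometry = _draw_geometry(spec, index)
    return rasterize_phantom(geometry, spec, applicator, voxel)


def generate_cohort(
    spec: CohortSpec,
    applicator: ApplicatorSpec | None = None,
    voxel_size: float | None = None,
) -> List[Phantom]:
    return [generate_phantom(spec, i, applicator, voxel_size) for i in range(spec.n_phantoms)]
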
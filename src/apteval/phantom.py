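"""Digital head-and-neck phantoms with weekly anatomy change and CBCT degradation.

The phantom is an axial-cylindrical stand-in for a head-and-neck patient:
an elliptical soft-tissue body, bony spine with a spinal-cord core, a
mandible arc with an optional dental-artifact region, an airway cavity,
larynx, pharyngeal constrictors, parotids, esophagus, and up to three
nested CTVs carrying prescription levels.  There is no attempt at
anatomical realism beyond tissue-class HUs and topology; the point is to
exercise every downstream algorithm (registration, sCT building, dose,
planning, evaluation) against known ground truth.

Weekly anatomy change is an *analytic* displacement field (radial body
shrink emulating weight loss plus a local tumor dilation/contraction), so
exact ground-truth deformations and deformed contours are available to the
test suite.  CBCT degradation is modelled as a radial low-frequency bias
field (cupping), additive Gaussian HU noise, and a limited axial
field of view.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .grids import Grid, StructureSet, VectorField, VoxelImage
from .registration import warp_image, warp_mask

# Tissue-class HU values (approximate clinical magnitudes)
DEFAULT_HU = {
    "air": -1000.0,
    "soft": 40.0,
    "parotid": 30.0,
    "larynx": 45.0,
    "cavity_air": -800.0,
    "bone": 700.0,
    "cord": 30.0,
    "mandible": 1200.0,
    "tumor": 55.0,
    "esophagus": 35.0,
}


@dataclass
class CbctModel:
    """Degradation model for the simulated cone-beam CT."""

    fov_axial_mm: float = 96.0      # axial (z) extent of the imaged volume
    bias_amplitude_hu: float = 60.0  # cupping amplitude at the body periphery
    noise_sigma_hu: float = 15.0


@dataclass
class PhantomSpec:
    """Parameter bundle fully determining one phantom and its trajectory.

    ``weekly_body_shrink`` is the fractional per-week reduction of the body
    radius (weight loss); ``weekly_tumor_change`` the fractional per-week
    change of the tumor radius (positive = growth).  Both must lie in
    (-0.5, 0.5).  A fixed ``seed`` makes every output bit-reproducible.
    """

    grid: Grid = field(
        default_factory=lambda: Grid(
            origin=(-95.0, -95.0, -63.0), spacing=(2.0, 2.0, 2.0), dims=(96, 96, 64)
        )
    )
    body_semiaxes_mm: Tuple[float, float] = (75.0, 62.0)
    spine_center_y_mm: float = 34.0
    spine_radius_mm: float = 12.0
    cord_radius_mm: float = 5.0
    mandible_center_y_mm: float = -38.0
    mandible_radius_mm: float = 24.0
    mandible_thickness_mm: float = 7.0
    cavity_center_y_mm: float = -14.0
    cavity_radius_mm: float = 7.0
    larynx_center_y_mm: float = -24.0
    larynx_radius_mm: float = 11.0
    constrictor_center_y_mm: float = -6.0
    parotid_center_x_mm: float = 52.0
    parotid_semiaxes_mm: Tuple[float, float, float] = (11.0, 14.0, 17.0)
    esophagus_center_y_mm: float = 12.0
    esophagus_radius_mm: float = 6.0
    tumor_center_mm: Tuple[float, float, float] = (24.0, -6.0, 4.0)
    tumor_radius_mm: float = 22.0
    ctv_expansion_mm: float = 7.0     # primary -> secondary -> tertiary shell width
    n_prescription_levels: int = 3
    prescriptions_gy: Tuple[float, ...] = (70.0, 63.0, 56.0)
    n_fractions: int = 35
    weekly_body_shrink: float = 0.0
    weekly_tumor_change: float = 0.0
    cbct: CbctModel = field(default_factory=CbctModel)
    artifact: bool = True
    hu: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    seed: int = 0
    max_displacement_mm: float = 25.0

    def __post_init__(self) -> None:
        if not (-0.5 < self.weekly_body_shrink < 0.5):
            raise ValueError("weekly_body_shrink must be in (-0.5, 0.5)")
        if not (-0.5 < self.weekly_tumor_change < 0.5):
            raise ValueError("weekly_tumor_change must be in (-0.5, 0.5)")
        if self.cbct.fov_axial_mm > self.grid.extent_mm[2] + 1e-9:
            raise ValueError("CBCT FOV exceeds the axial extent of the grid")
        if not (1 <= self.n_prescription_levels <= 3):
            raise ValueError("n_prescription_levels must be 1..3")
        for rx in self.prescriptions_gy[: self.n_prescription_levels]:
            if not (56.0 <= rx <= 70.0):
                raise ValueError(f"prescription {rx} Gy outside the 56-70 Gy range")
        if not (30 <= self.n_fractions <= 35):
            raise ValueError("fraction count must be 30-35")

    def scaled(self, factor: float, grid: Optional[Grid] = None,
               **overrides) -> "PhantomSpec":
        """A geometrically scaled copy (all mm organ parameters x factor).

        Used to build small, fast phantoms that keep the default's
        topology; ``grid`` replaces the voxel grid, ``overrides`` any
        other field.
        """
        kw = dict(
            body_semiaxes_mm=tuple(v * factor for v in self.body_semiaxes_mm),
            spine_center_y_mm=self.spine_center_y_mm * factor,
            spine_radius_mm=self.spine_radius_mm * factor,
            cord_radius_mm=self.cord_radius_mm * factor,
            mandible_center_y_mm=self.mandible_center_y_mm * factor,
            mandible_radius_mm=self.mandible_radius_mm * factor,
            mandible_thickness_mm=self.mandible_thickness_mm * factor,
            cavity_center_y_mm=self.cavity_center_y_mm * factor,
            cavity_radius_mm=self.cavity_radius_mm * factor,
            larynx_center_y_mm=self.larynx_center_y_mm * factor,
            larynx_radius_mm=self.larynx_radius_mm * factor,
            constrictor_center_y_mm=self.constrictor_center_y_mm * factor,
            parotid_center_x_mm=self.parotid_center_x_mm * factor,
            parotid_semiaxes_mm=tuple(v * factor for v in self.parotid_semiaxes_mm),
            esophagus_center_y_mm=self.esophagus_center_y_mm * factor,
            esophagus_radius_mm=self.esophagus_radius_mm * factor,
            tumor_center_mm=tuple(v * factor for v in self.tumor_center_mm),
            tumor_radius_mm=self.tumor_radius_mm * factor,
            ctv_expansion_mm=self.ctv_expansion_mm * factor,
            weekly_body_shrink=self.weekly_body_shrink,
            weekly_tumor_change=self.weekly_tumor_change,
            n_prescription_levels=self.n_prescription_levels,
            prescriptions_gy=self.prescriptions_gy,
            n_fractions=self.n_fractions,
            artifact=self.artifact,
            seed=self.seed,
        )
        if grid is None:
            kw["grid"] = self.grid
            kw["cbct"] = CbctModel(**dataclasses.asdict(self.cbct))
        else:
            kw["grid"] = grid
            fov = min(self.cbct.fov_axial_mm / self.grid.extent_mm[2], 1.0)
            kw["cbct"] = CbctModel(
                fov_axial_mm=fov * grid.extent_mm[2],
                bias_amplitude_hu=self.cbct.bias_amplitude_hu,
                noise_sigma_hu=self.cbct.noise_sigma_hu,
            )
        kw.update(overrides)
        return PhantomSpec(**kw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = {
            "origin": list(self.grid.origin),
            "spacing": list(self.grid.spacing),
            "dims": list(self.grid.dims),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grid"] = Grid(
            tuple(d["grid"]["origin"]),
            tuple(d["grid"]["spacing"]),
            tuple(d["grid"]["dims"]),
        )
        d["cbct"] = CbctModel(**d["cbct"])
        for k in ("body_semiaxes_mm", "parotid_semiaxes_mm", "tumor_center_mm",
                  "prescriptions_gy"):
            d[k] = tuple(d[k])
        return cls(**d)


def _ellipse_cyl(x, y, cx, cy, ax, ay):
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _cylinder(x, y, cx, cy, r):
    return (x - cx) ** 2 + (y - cy) ** 2 <= r * r


def _sphere(x, y, z, c, r):
    return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r * r


def _dilate_mm(mask: np.ndarray, grid: Grid, radius_mm: float) -> np.ndarray:
    """Isotropic dilation by a physical radius via a Euclidean distance map."""
    from scipy.ndimage import distance_transform_edt

    if radius_mm <= 0:
        return mask.copy()
    d = distance_transform_edt(~mask, sampling=grid.spacing)
    return d <= radius_mm


def build_planning_phantom(spec: PhantomSpec) -> Tuple[VoxelImage, StructureSet]:
    """Build the planning CT and its structure set from a phantom spec.

    Returns the pCT (HU) and a :class:`StructureSet` holding body, bones,
    OARs, nested CTVs (with prescriptions) and auxiliary masks
    (``artifact``, ``entry_avoidance``).  Deterministic for a fixed spec.
    """
    g = spec.grid
    ax_x, ax_y, ax_z = g.axes()
    x = ax_x[:, None, None]
    y = ax_y[None, :, None]
    z = ax_z[None, None, :]
    ex, ey = spec.body_semiaxes_mm
    half = [e / 2 for e in g.extent_mm]
    if ex >= half[0] or ey >= half[1]:
        raise ValueError(
            f"body semi-axes {spec.body_semiaxes_mm} exceed the grid half-extent {half[:2]}"
        )
    if spec.tumor_radius_mm <= 0:
        raise ValueError("tumor radius must be > 0 (CTV_primary would be empty)")

    hu = spec.hu
    vol = np.full(g.dims, hu["air"], dtype=np.float32)
    masks: Dict[str, np.ndarray] = {}

    body = np.broadcast_to(_ellipse_cyl(x, y, 0.0, 0.0, ex, ey), g.dims).copy()
    vol[body] = hu["soft"]
    masks["body"] = body

    zc = (ax_z[0] + ax_z[-1]) / 2.0
    z_extent = g.extent_mm[2]

    # parotids (bilateral ellipsoids, upper half)
    pz = zc + 0.22 * z_extent
    for side, name in ((1.0, "parotid_l"), (-1.0, "parotid_r")):
        pa = spec.parotid_semiaxes_mm
        m = (
            ((x - side * spec.parotid_center_x_mm) / pa[0]) ** 2
            + ((y + 4.0) / pa[1]) ** 2
            + ((z - pz) / pa[2]) ** 2
        ) <= 1.0
        m = np.broadcast_to(m, g.dims) & body
        vol[m] = hu["parotid"]
        masks[name] = m.copy()

    # larynx: soft cylinder with a small air core, mid slices
    lar_z = (z > zc - 0.18 * z_extent) & (z < zc + 0.10 * z_extent)
    lar = _cylinder(x, y, 0.0, spec.larynx_center_y_mm, spec.larynx_radius_mm) & lar_z
    lar = np.broadcast_to(lar, g.dims) & body
    vol[lar] = hu["larynx"]
    core = _cylinder(x, y, 0.0, spec.larynx_center_y_mm, spec.larynx_radius_mm * 0.35)
    core = np.broadcast_to(core & lar_z, g.dims) & body
    vol[core] = hu["cavity_air"]
    masks["larynx"] = lar.copy()

    # pharyngeal constrictors: thin posterior arc behind the larynx
    # (ring radii proportional to the body size so scaled phantoms keep shape)
    r_in, r_out = 0.16 * ex, 0.23 * ex
    rr = np.sqrt(x**2 + (y - spec.constrictor_center_y_mm) ** 2)
    con = (rr >= r_in) & (rr <= r_out) & (y > spec.constrictor_center_y_mm - r_out - 1.0)
    con_z = (z > zc - 0.22 * z_extent) & (z < zc + 0.22 * z_extent)
    con = np.broadcast_to(con & con_z & (y < spec.constrictor_center_y_mm + r_out + 0.5), g.dims) & body
    vol[con] = hu["soft"] + 5.0
    masks["constrictors"] = con.copy()

    # airway cavity (oropharynx), upper 2/3
    cav_z = z > zc - 0.10 * z_extent
    cav = _cylinder(x, y, 0.0, spec.cavity_center_y_mm, spec.cavity_radius_mm) & cav_z
    cav = np.broadcast_to(cav, g.dims) & body
    vol[cav] = hu["cavity_air"]

    # esophagus, inferior to the larynx
    eso_z = z <= zc - 0.18 * z_extent
    eso = _cylinder(x, y, 0.0, spec.esophagus_center_y_mm, spec.esophagus_radius_mm) & eso_z
    eso = np.broadcast_to(eso, g.dims) & body
    vol[eso] = hu["esophagus"]
    masks["esophagus"] = eso.copy()

    # spine + cord (full length)
    spine = _cylinder(x, y, 0.0, spec.spine_center_y_mm, spec.spine_radius_mm)
    spine = np.broadcast_to(spine, g.dims) & body
    vol[spine] = hu["bone"]
    cord = _cylinder(x, y, 0.0, spec.spine_center_y_mm, spec.cord_radius_mm)
    cord = np.broadcast_to(cord, g.dims) & body
    vol[cord] = hu["cord"]
    masks["spinal_cord"] = cord.copy()

    # mandible: anterior arc shell in the upper quarter
    mand_z = z > zc + 0.25 * z_extent
    rm = np.sqrt(x**2 + (y - spec.mandible_center_y_mm) ** 2)
    mand = (
        (rm >= spec.mandible_radius_mm - spec.mandible_thickness_mm)
        & (rm <= spec.mandible_radius_mm)
        & (y < spec.mandible_center_y_mm + spec.mandible_radius_mm * 0.4)
    )
    mand = np.broadcast_to(mand & mand_z, g.dims) & body
    vol[mand] = hu["mandible"]
    masks["mandible"] = mand.copy()

    # dental artifact: streaked box around the anterior mandible
    if spec.artifact:
        art = (
            (np.abs(x - 0.0) < 0.24 * ex)
            & (np.abs(y - (spec.mandible_center_y_mm - 0.08 * ey)) < 0.16 * ey)
            & mand_z
        )
        art = np.broadcast_to(art, g.dims) & body & ~mand
        ix = np.arange(g.dims[0])[:, None, None]
        streak = np.broadcast_to((ix % 2) == 0, g.dims)
        vol[art & streak] = 1500.0
        vol[art & ~streak] = -900.0
        masks["artifact"] = art.copy()
    else:
        masks["artifact"] = np.zeros(g.dims, dtype=bool)

    # entry-avoidance region: chin/teeth area (anterior wedge incl. mandible)
    avoid = np.broadcast_to(
        (y < spec.mandible_center_y_mm + 6.0) & mand_z, g.dims
    ) & body
    masks["entry_avoidance"] = avoid | masks["artifact"]

    # tumor and nested CTVs
    tc = spec.tumor_center_mm
    tumor = np.broadcast_to(_sphere(x, y, z, tc, spec.tumor_radius_mm), g.dims) & body
    if not tumor.any():
        raise ValueError("tumor lies outside the body; CTV_primary is empty")
    vol[tumor & ~spine & ~mand] = hu["tumor"]
    masks["ctv_primary"] = tumor.copy()
    prescriptions: Dict[str, Tuple[float, int]] = {
        "ctv_primary": (spec.prescriptions_gy[0], spec.n_fractions)
    }
    if spec.n_prescription_levels >= 2:
        sec = _dilate_mm(tumor, g, spec.ctv_expansion_mm) & body
        masks["ctv_secondary"] = sec
        prescriptions["ctv_secondary"] = (spec.prescriptions_gy[1], spec.n_fractions)
    if spec.n_prescription_levels >= 3:
        ter = _dilate_mm(masks["ctv_secondary"], g, spec.ctv_expansion_mm)
        # elective extension toward the inferior (shoulder) direction
        shift_vox = max(1, int(round(2 * spec.ctv_expansion_mm / g.spacing[2])))
        ter = ter | np.roll(ter, -shift_vox, axis=2)
        ter[..., -shift_vox:] = ter[..., -shift_vox - 1 : -shift_vox]
        ter &= body
        masks["ctv_tertiary"] = ter
        prescriptions["ctv_tertiary"] = (spec.prescriptions_gy[2], spec.n_fractions)

    np.clip(vol, -1024.0, 3071.0, out=vol)
    pct = VoxelImage(g, vol, kind="HU")
    structures = StructureSet(g, masks, prescriptions)
    _check_nesting(structures)
    return pct, structures


def _check_nesting(ss: StructureSet) -> None:
    order = [n for n in ("ctv_primary", "ctv_secondary", "ctv_tertiary") if n in ss]
    for inner, outer in zip(order, order[1:]):
        if not np.all(ss[outer][ss[inner]]):
            raise ValueError(f"CTV nesting violated: {inner} not within {outer}")


# ---------------------------------------------------------------------------
# weekly anatomy


def weekly_dvf(spec: PhantomSpec, week: int) -> VectorField:
    """Analytic ground-truth DVF for a given week (pull-back convention).

    Radial in-plane scaling about the body axis models weight loss; a
    Gaussian-windowed radial scaling about the tumor centre models tumor
    growth/shrinkage.  Week 0 is the identity.  The exact field (and hence
    its exact inverse by construction) is available to oracle tests.
    """
    if week < 0:
        raise ValueError("week must be >= 0")
    g = spec.grid
    u = np.zeros(g.dims + (3,), dtype=np.float64)
    if week == 0:
        return VectorField(g, u.astype(np.float32))

    x, y, z = g.coords()
    shrink = spec.weekly_body_shrink * week
    if abs(shrink) > 0:
        if shrink >= 1.0:
            raise ValueError("cumulative body shrink >= 100%")
        c = 1.0 / (1.0 - shrink) - 1.0  # sample outward -> body appears smaller
        ex, ey = spec.body_semiaxes_mm
        r2 = (x / (1.25 * ex)) ** 2 + (y / (1.25 * ey)) ** 2
        w = np.exp(-(r2**3))  # ~1 inside body, -> 0 at grid edge
        u[..., 0] += c * x * w
        u[..., 1] += c * y * w

    growth = spec.weekly_tumor_change * week
    if abs(growth) > 0:
        if growth <= -1.0:
            raise ValueError("cumulative tumor shrink >= 100%")
        ct = spec.tumor_center_mm
        cg = 1.0 / (1.0 + growth) - 1.0  # sample inward -> tumor appears larger
        # window localized enough that tumor change leaves the body contour alone
        sig = 1.5 * spec.tumor_radius_mm
        d2 = (x - ct[0]) ** 2 + (y - ct[1]) ** 2 + (z - ct[2]) ** 2
        w = np.exp(-d2 / (sig * sig))
        u[..., 0] += cg * (x - ct[0]) * w
        u[..., 1] += cg * (y - ct[1]) * w
        u[..., 2] += cg * (z - ct[2]) * w

    field_v = VectorField(g, u.astype(np.float32))
    if field_v.max_magnitude_mm > spec.max_displacement_mm:
        raise ValueError(
            f"week-{week} displacement {field_v.max_magnitude_mm:.1f} mm exceeds the "
            f"{spec.max_displacement_mm} mm bound"
        )
    _check_invertibility(field_v)
    return field_v


def _check_invertibility(dvf: VectorField) -> None:
    """Reject fields whose Jacobian is too large for fixed-point inversion.

    The iteration contracts when the displacement Jacobian has norm < 1;
    checked via the row-sum (infinity) norm per voxel.
    """
    g = dvf.grid
    row_sum = np.zeros(g.dims)
    for comp in range(3):
        grads = np.gradient(dvf.displacement[..., comp].astype(np.float64),
                            *g.spacing)
        row_sum = np.maximum(row_sum, np.abs(grads[0]) + np.abs(grads[1])
                             + np.abs(grads[2]))
    worst = float(row_sum.max())
    if worst >= 0.95:
        raise ValueError(
            f"DVF Jacobian bound {worst:.2f} >= 0.95: displacement gradient "
            "too large for invertibility"
        )


def sample_weekly_anatomy(
    spec: PhantomSpec, week: int
) -> Tuple[VectorField, VoxelImage, StructureSet]:
    """Ground-truth DVF, deformed CT and deformed ("physician-corrected") contours.

    The deformed CT plays the role of a same-day repeat CT; the deformed
    contours are the gold standard against which DIR-propagated contours
    are scored.
    """
    pct, structures = build_planning_phantom(spec)
    dvf = weekly_dvf(spec, week)
    if week == 0:
        return dvf, pct.copy(), structures.copy()
    deformed = warp_image(pct, dvf, interpolation="trilinear", fill_value=spec.hu["air"])
    masks = {name: warp_mask(structures[name], dvf) for name in structures.names()}
    gt = StructureSet(dvf.grid, masks, dict(structures.prescriptions))
    return dvf, deformed, gt


def simulate_cbct(
    deformed_ct: VoxelImage, spec: PhantomSpec, week: int = 0
) -> Tuple[VoxelImage, np.ndarray]:
    """Degrade a CT into a CBCT-like image: cupping bias, noise, limited FOV.

    Returns the CBCT and the boolean in-FOV mask.  Voxels outside the FOV
    are set to air and flagged invalid in the mask.  With zero bias, zero
    noise and a full FOV the CBCT equals the input exactly.
    """
    g = deformed_ct.grid
    m = spec.cbct
    vals = deformed_ct.values.astype(np.float64).copy()

    if m.bias_amplitude_hu != 0:
        x, y, _ = g.coords()
        ex, ey = spec.body_semiaxes_mm
        r2 = np.clip((x / ex) ** 2 + (y / ey) ** 2, 0.0, 1.0)
        cupping = -m.bias_amplitude_hu * (1.0 - r2)  # center depressed
        vals += np.broadcast_to(cupping, g.dims)

    if m.noise_sigma_hu > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919, week]))
        vals += rng.normal(0.0, m.noise_sigma_hu, size=g.dims)

    ax_z = g.axes()[2]
    zc = (ax_z[0] + ax_z[-1]) / 2.0
    in_fov_z = np.abs(ax_z - zc) <= m.fov_axial_mm / 2.0 + 1e-9
    fov = np.zeros(g.dims, dtype=bool)
    fov[:, :, in_fov_z] = True
    vals[~fov] = spec.hu["air"]
    np.clip(vals, -1024.0, 3071.0, out=vals)
    return VoxelImage(g, vals.astype(np.float32), kind="HU"), fov
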
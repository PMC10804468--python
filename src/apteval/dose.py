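"""Analytic spot-scanning proton dose engine.

A pencil-beam model indexed by water-equivalent thickness (WET): HU are
converted to relative stopping power (RSP) through a piecewise-linear
calibration curve, WET depth maps are ray-traced through the CT, each spot
deposits an analytic Bragg depth-dose along its ray with a depth-dependent
lateral Gaussian spread, and the total dose is linear in the spot weights
through sparse influence matrices.  Setup-shift and range-scaling
uncertainty scenarios re-evaluate the same spots with the dose pattern
rigidly shifted in the patient frame and the nominal ranges scaled.

This deliberately omits nuclear halo, beam divergence and Monte Carlo
transport: it preserves the properties the downstream analyses depend on
(range behaviour, scenario response, linearity, non-negativity) at desk
scale.  All doses are RBE-weighted with a constant factor (default 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import sparse
from scipy.ndimage import map_coordinates

from .grids import Grid, StructureSet, VoxelImage

DEFAULT_RSP_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (-200.0, 0.84),
    (-100.0, 0.93),
    (0.0, 1.0),
    (60.0, 1.04),
    (1000.0, 1.56),
    (3000.0, 2.40),
)


@dataclass(frozen=True)
class RSPCurve:
    """Piecewise-linear HU -> relative stopping power calibration.

    HU anchors must be strictly increasing, RSP non-negative, and the
    water anchor (0 HU, 1.0) must be present.  Evaluation clamps outside
    the anchor range.
    """

    anchors: Tuple[Tuple[float, float], ...] = DEFAULT_RSP_ANCHORS

    def __post_init__(self) -> None:
        hu = np.array([a[0] for a in self.anchors], dtype=float)
        rsp = np.array([a[1] for a in self.anchors], dtype=float)
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU anchors must be strictly increasing")
        if np.any(rsp < 0):
            raise ValueError("RSP must be >= 0")
        if not np.any((hu == 0.0) & (np.isclose(rsp, 1.0))):
            raise ValueError("curve must contain the water anchor (0 HU, 1.0 RSP)")

    def __call__(self, hu) -> np.ndarray:
        h = np.array([a[0] for a in self.anchors], dtype=float)
        r = np.array([a[1] for a in self.anchors], dtype=float)
        return np.interp(hu, h, r)  # np.interp clamps at the ends

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"anchors": [list(a) for a in self.anchors]}, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RSPCurve":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(tuple(tuple(a) for a in d["anchors"]))


def hu_to_rsp(hu, curve: Optional[RSPCurve] = None) -> np.ndarray:
    """Evaluate the HU -> RSP calibration (clamped piecewise-linear)."""
    return (curve or RSPCurve())(hu)


class Scenario(NamedTuple):
    """One robustness scenario: rigid dose-pattern shift (mm, patient frame)
    and a multiplicative scale on every spot's nominal range."""

    shift_mm: Tuple[float, float, float]
    range_scale: float


NOMINAL = Scenario((0.0, 0.0, 0.0), 1.0)


@dataclass
class Beam:
    """One treatment field: axial-plane direction and spot/layer grids."""

    direction: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    isocenter_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    lateral_spacing_mm: float = 6.0
    layer_spacing_mm: float = 6.0
    name: str = "beam"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or abs(d[2]) > 1e-9:
            raise ValueError("beam direction must be a nonzero axial-plane vector")
        self.direction = tuple(d / n)
        if self.lateral_spacing_mm <= 0 or self.layer_spacing_mm <= 0:
            raise ValueError("spot/layer spacings must be > 0")

    def frame(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit vectors (beam axis, in-plane lateral, axial lateral)."""
        d = np.asarray(self.direction)
        e1 = np.array([-d[1], d[0], 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        return d, e1, e2


@dataclass
class Spot:
    """A scanning spot: lateral beam-frame position and nominal range (WET mm)."""

    lateral_mm: Tuple[float, float]
    range_mm: float
    weight: float = 0.0
    beam_index: int = 0

    def __post_init__(self) -> None:
        if self.range_mm <= 0:
            raise ValueError("nominal range must be > 0")
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


# ---------------------------------------------------------------------------
# depth dose


def bragg_sigma_mm(range_mm) -> np.ndarray:
    """Distal falloff width: range straggling plus beamline energy spread (mm).

    The straggling term grows as ~R^0.935; the 2.5% energy-spread term
    dominates and keeps adjacent energy layers overlapping smoothly.
    """
    r = np.asarray(range_mm, dtype=float)
    return np.sqrt((0.012 * r**0.935) ** 2 + (0.025 * r) ** 2) + 0.8


def bragg_depth_dose(wet_depth_mm, range_mm) -> np.ndarray:
    """Analytic Bragg curve, peak-normalised to 1 at depth R.

    A narrow Gaussian peak at the nominal range R rides on a proximal
    plateau (entrance ~30% of peak, rising slowly with depth) that is
    switched off sigmoidally at the peak; the whole curve is tapered to
    exactly zero beyond R + 6 sigma.  Continuous in depth, single maximum
    at ~R, distal dose < 1% of peak beyond R + 5 sigma.
    """
    z = np.asarray(wet_depth_mm, dtype=float)
    R = np.asarray(range_mm, dtype=float)
    if np.any(R <= 0):
        raise ValueError("range must be > 0")
    sig = bragg_sigma_mm(R)
    c_p = 0.35
    peak = np.exp(-((z - R) ** 2) / (2.0 * sig**2))
    with np.errstate(over="ignore"):
        gate = 1.0 / (1.0 + np.exp(np.clip((z - R) / sig, -60.0, 60.0)))
    plateau = c_p * (1.0 + 0.6 * np.clip(z, 0.0, None) / R) * gate
    taper = np.clip((R + 6.0 * sig - z) / sig, 0.0, 1.0)
    d = (peak + plateau) * taper
    norm = 1.0 + c_p * 1.6 * 0.5  # value at z = R
    return d / norm


def lateral_sigma_mm(wet_depth_mm, sigma0_mm: float = 4.0,
                     growth_per_mm: float = 0.03) -> np.ndarray:
    """Lateral Gaussian spread vs depth (in-air spot size plus scattering)."""
    return sigma0_mm + growth_per_mm * np.clip(np.asarray(wet_depth_mm, float), 0, None)


# ---------------------------------------------------------------------------
# WET ray tracing


def wet_raytrace(
    ct: VoxelImage,
    entry_mm: Sequence[float],
    direction: Sequence[float],
    curve: Optional[RSPCurve] = None,
    step_mm: float = 1.0,
    length_mm: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative WET along a single ray.

    Returns ``(distances_mm, wet_mm)`` with ``wet[i]`` the integral of RSP
    from the entry point to ``distances[i]``.  The entry point must lie
    inside the grid; samples beyond the grid contribute nothing.
    """
    curve = curve or RSPCurve()
    g = ct.grid
    if step_mm > min(g.spacing) / 2.0 + 1e-9:
        raise ValueError("step must be <= half the smallest voxel spacing")
    entry = np.asarray(entry_mm, dtype=float)
    idx0 = g.world_to_index(entry)
    if np.any(idx0 < -0.5) or np.any(idx0 > np.asarray(g.dims) - 0.5):
        raise ValueError(f"entry point {entry} lies outside the grid")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if length_mm is None:
        length_mm = float(np.linalg.norm(g.extent_mm)) * 1.5
    s = np.arange(0.0, length_mm + step_mm / 2, step_mm)
    pts = entry[None, :] + s[:, None] * d[None, :]
    idx = g.world_to_index(pts)
    rsp_vol = curve(ct.values).astype(np.float64)
    rsp = map_coordinates(rsp_vol, [idx[:, 0], idx[:, 1], idx[:, 2]],
                          order=1, mode="constant", cval=0.0)
    wet = np.concatenate([[0.0], np.cumsum(0.5 * (rsp[1:] + rsp[:-1]) * step_mm)])
    return s, wet


def wet_depth_map(ct: VoxelImage, direction: Sequence[float],
                  curve: Optional[RSPCurve] = None) -> np.ndarray:
    """Per-voxel WET depth from the grid boundary along a parallel beam.

    Axis-aligned directions use an exact cumulative sum; oblique axial
    directions rotate the RSP volume (requires isotropic in-plane
    spacing), accumulate, and rotate back.
    """
    curve = curve or RSPCurve()
    g = ct.grid
    rsp = curve(ct.values).astype(np.float64)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if abs(d[2]) > 1e-9:
        raise ValueError("beam direction must lie in the axial plane")

    for axis in (0, 1):
        for sgn in (1.0, -1.0):
            ref = np.zeros(3)
            ref[axis] = sgn
            if np.allclose(d, ref, atol=1e-9):
                sp = g.spacing[axis]
                r = rsp if sgn > 0 else np.flip(rsp, axis=axis)
                cum = np.cumsum(r, axis=axis) * sp - 0.5 * r * sp
                return cum if sgn > 0 else np.flip(cum, axis=axis)

    if not np.isclose(g.spacing[0], g.spacing[1]):
        raise ValueError("oblique beams need isotropic in-plane spacing")
    from scipy.ndimage import rotate

    theta = np.degrees(np.arctan2(d[1], d[0]))
    # pad so no corner content is clipped, rotate the beam axis onto +x,
    # accumulate along x, rotate back, crop
    pad = int(0.3 * max(g.dims[0], g.dims[1])) + 2
    padded = np.pad(rsp, ((pad, pad), (pad, pad), (0, 0)))
    rot = rotate(padded, angle=-theta, axes=(1, 0), reshape=False, order=1,
                 mode="constant", cval=0.0)
    sp = g.spacing[0]
    cum = np.cumsum(rot, axis=0) * sp - 0.5 * rot * sp
    back = rotate(cum, angle=theta, axes=(1, 0), reshape=False, order=1,
                  mode="constant", cval=0.0)
    back = back[pad:-pad, pad:-pad, :]
    return np.clip(back, 0.0, None)


# ---------------------------------------------------------------------------
# spot placement


def _beam_maps(ct: VoxelImage, beam: Beam, curve: RSPCurve):
    """WET depth, geometric depth and lateral coordinate maps for a beam."""
    g = ct.grid
    dvec, e1, e2 = beam.frame()
    x, y, z = g.coords()
    iso = np.asarray(beam.isocenter_mm)
    px = x - iso[0]
    py = y - iso[1]
    pz = z - iso[2]
    lat1 = np.broadcast_to(px * e1[0] + py * e1[1], g.dims)
    lat2 = np.broadcast_to(pz * e2[2], g.dims)
    tgeom = np.broadcast_to(px * dvec[0] + py * dvec[1], g.dims)
    wet = wet_depth_map(ct, beam.direction, curve)
    return wet, tgeom, np.ascontiguousarray(lat1, dtype=np.float64), np.ascontiguousarray(lat2, dtype=np.float64)


def place_spots(
    targets: StructureSet,
    beam: Beam,
    ct: VoxelImage,
    curve: Optional[RSPCurve] = None,
    setup_margin_mm: float = 3.0,
    range_margin: float = 0.03,
    avoidance_mask: Optional[np.ndarray] = None,
    lateral_margin_mm: float = 3.0,
) -> Tuple[List[Spot], np.ndarray]:
    """Place spots over the field-specific target of one beam.

    The field-specific target is the union of the CTVs expanded
    isotropically by the setup margin; each lateral position's proximal
    and distal energy-layer extent is additionally expanded by the range
    margin in WET.  Spot positions additionally cover ``lateral_margin_mm``
    beyond the field target so the penumbra can be edge-enhanced under
    setup shifts (the returned mask is the field target itself).  Spots
    whose ray crosses the entry-avoidance region before reaching the
    target are removed.  Raises if no spot survives.
    """
    curve = curve or RSPCurve()
    g = ct.grid
    ctv_names = targets.ctv_names()
    if not ctv_names:
        raise ValueError("no CTVs with prescriptions in the structure set")
    union = np.zeros(g.dims, dtype=bool)
    for name in ctv_names:
        m = targets[name]
        if not m.any():
            raise ValueError(f"CTV '{name}' is empty")
        union |= m
    from .phantom import _dilate_mm

    field_target = _dilate_mm(union, g, setup_margin_mm)

    wet, tgeom, lat1, lat2 = _beam_maps(ct, beam, curve)
    tmask = field_target if lateral_margin_mm <= 0 else _dilate_mm(
        field_target, g, lateral_margin_mm)
    l1 = lat1[tmask]
    l2 = lat2[tmask]
    w = wet[tmask]
    tg = tgeom[tmask]

    half = beam.lateral_spacing_mm / 2.0
    a_grid = np.arange(l1.min(), l1.max() + half, beam.lateral_spacing_mm)
    b_grid = np.arange(l2.min(), l2.max() + half, beam.lateral_spacing_mm)

    if avoidance_mask is not None and avoidance_mask.any():
        av1 = lat1[avoidance_mask]
        av2 = lat2[avoidance_mask]
        avt = tgeom[avoidance_mask]
    else:
        av1 = av2 = avt = None

    spots: List[Spot] = []
    for a in a_grid:
        sel_a = np.abs(l1 - a) <= half
        if not sel_a.any():
            continue
        for b in b_grid:
            sel = sel_a & (np.abs(l2 - b) <= half)
            if not sel.any():
                continue
            if av1 is not None:
                blk = (np.abs(av1 - a) <= half) & (np.abs(av2 - b) <= half)
                if blk.any() and avt[blk].min() < tg[sel].min():
                    continue  # ray enters through the avoidance region
            wmin = w[sel].min() * (1.0 - range_margin)
            wmax = w[sel].max() * (1.0 + range_margin)
            wmin = max(wmin, beam.layer_spacing_mm)
            layers = np.arange(wmin, wmax + beam.layer_spacing_mm / 2,
                               beam.layer_spacing_mm)
            for r in layers:
                spots.append(Spot((float(a), float(b)), float(r)))
    if not spots:
        raise ValueError(
            f"no spots retained for beam '{beam.name}': target unreachable "
            "(avoidance region blocks every entrance or target empty)"
        )
    return spots, field_target


# ---------------------------------------------------------------------------
# influence computation


@dataclass
class InfluenceMatrix:
    """Sparse voxel x spot dose-per-unit-weight matrix for one scenario."""

    matrix: sparse.csr_matrix      # (n_voxels, n_spots), Gy per MU
    voxel_index: np.ndarray        # flat indices into the dose grid
    grid: Grid
    scenario: Scenario

    def dose_vector(self, weights: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ np.asarray(weights, dtype=np.float64))

    def dose_image(self, weights: np.ndarray) -> VoxelImage:
        flat = np.zeros(int(np.prod(self.grid.dims)), dtype=np.float64)
        flat[self.voxel_index] = self.dose_vector(weights)
        return VoxelImage(self.grid, flat.reshape(self.grid.dims), kind="Gy")

    def save(self, path: str) -> None:
        """Coordinate-triplet text format: one 'row col value' line per entry."""
        coo = self.matrix.tocoo()
        header = (
            f"# influence {self.matrix.shape[0]}x{self.matrix.shape[1]} "
            f"shift={self.scenario.shift_mm} scale={self.scenario.range_scale}"
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r} {c} {v:.6e}\n")


def compute_influence(
    ct: VoxelImage,
    beams: Sequence[Beam],
    spots_per_beam: Sequence[Sequence[Spot]],
    voxel_mask: np.ndarray,
    scenario: Scenario = NOMINAL,
    rbe: float = 1.1,
    curve: Optional[RSPCurve] = None,
    sparsity_cutoff: float = 1e-4,
) -> InfluenceMatrix:
    """Influence matrix of all spots of all beams over the masked voxels.

    Per spot, ``dose(v) = rbe * bragg(WET(v), R*scale) * G(lateral)`` with
    the lateral Gaussian normalised to conserve fluence with depth and the
    whole pattern shifted by the scenario's rigid shift in the patient
    frame.  Entries below ``sparsity_cutoff`` of the per-spot maximum are
    dropped.
    """
    curve = curve or RSPCurve()
    g = ct.grid
    flat_idx = np.flatnonzero(voxel_mask.ravel())
    n_vox = flat_idx.size
    shift = np.asarray(scenario.shift_mm, dtype=float)

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    col0 = 0
    sigma0 = 4.0
    for beam, spots in zip(beams, spots_per_beam):
        wet, _, lat1, lat2 = _beam_maps(ct, beam, curve)
        dvec, e1, e2 = beam.frame()
        s1 = float(shift @ e1)
        s2 = float(shift @ e2)
        wv = wet.ravel()[flat_idx]
        l1 = lat1.ravel()[flat_idx] - s1
        l2 = lat2.ravel()[flat_idx] - s2
        order = np.argsort(l1, kind="stable")
        l1s = l1[order]

        sig_max = float(lateral_sigma_mm(wv.max() if n_vox else 0.0, sigma0))
        reach = 3.5 * sig_max
        for j, spot in enumerate(spots):
            a, b = spot.lateral_mm
            lo = np.searchsorted(l1s, a - reach)
            hi = np.searchsorted(l1s, a + reach)
            cand = order[lo:hi]
            if cand.size == 0:
                continue
            sub = cand[np.abs(l2[cand] - b) <= reach]
            if sub.size == 0:
                continue
            r_eff = spot.range_mm * scenario.range_scale
            sig_d = float(bragg_sigma_mm(r_eff))
            depth_ok = wv[sub] <= r_eff + 7.0 * sig_d
            sub = sub[depth_ok]
            if sub.size == 0:
                continue
            depth = bragg_depth_dose(wv[sub], r_eff)
            sig = lateral_sigma_mm(wv[sub], sigma0)
            r2 = (l1[sub] - a) ** 2 + (l2[sub] - b) ** 2
            lat = (sigma0 / sig) ** 2 * np.exp(-r2 / (2.0 * sig**2))
            d = rbe * depth * lat
            keep = d > sparsity_cutoff * d.max()
            if not keep.any():
                continue
            rows.append(sub[keep].astype(np.int32))
            cols.append(np.full(int(keep.sum()), col0 + j, dtype=np.int32))
            vals.append(d[keep].astype(np.float32))
        col0 += len(spots)

    n_spots = col0
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_vox, n_spots),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((n_vox, n_spots))
    return InfluenceMatrix(mat, flat_idx, g, scenario)


def compute_dose(
    ct: VoxelImage,
    beams: Sequence[Beam],
    spots_per_beam: Sequence[Sequence[Spot]],
    weights: np.ndarray,
    voxel_mask: Optional[np.ndarray] = None,
    scenario: Scenario = NOMINAL,
    rbe: float = 1.1,
    curve: Optional[RSPCurve] = None,
) -> VoxelImage:
    """Total dose image for given spot weights (linear in the weights)."""
    if voxel_mask is None:
        voxel_mask = np.ones(ct.grid.dims, dtype=bool)
    infl = compute_influence(ct, beams, spots_per_beam, voxel_mask,
                             scenario=scenario, rbe=rbe, curve=curve)
    return infl.dose_image(weights)
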
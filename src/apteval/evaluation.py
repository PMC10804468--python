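"""Quantitative plan/dose comparison machinery.

DVH and dose-volume indices, 3D global gamma analysis restricted to the
region above a low-dose threshold, constraint auditing against the
clinical table, inverse-DVF dose accumulation on the planning CT,
generalized equivalent uniform dose (gEUD), Lyman-Kutcher-Burman NTCP and
paired statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats
from scipy.ndimage import map_coordinates

from .grids import Grid, VectorField, VoxelImage
from .registration import warp_image


# ---------------------------------------------------------------------------
# DVH and indices


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    bin_edges_gy: np.ndarray
    cum_volume_fraction: np.ndarray  # monotone non-increasing, starts at 1

    @classmethod
    def from_dose(cls, dose: np.ndarray, structure: str = "",
                  bin_width_gy: float = 0.1) -> "DVHCurve":
        d = np.asarray(dose, dtype=float)
        if d.size == 0:
            raise ValueError("empty structure")
        top = max(float(d.max()) + bin_width_gy, bin_width_gy)
        edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
        cum = np.array([(d >= e).mean() for e in edges])
        return cls(structure, edges, cum)


def dose_indices(
    dose: VoxelImage,
    mask: np.ndarray,
    rx_gy: Optional[float] = None,
    v_levels_gy: Sequence[float] = (20.0,),
) -> Dict[str, float]:
    """Dmean/Dmax plus VxGy levels and, when a prescription is given,
    V95/V100 relative to that structure's own prescription.

    Dmax is the single-voxel maximum (documented convention, no near-max
    percentile).  VxGy is the percentage of structure voxels at or above
    x Gy.
    """
    if not np.asarray(mask).any():
        raise ValueError("empty mask")
    d = dose.values[np.asarray(mask, dtype=bool)].astype(float)
    out = {
        "Dmean": float(d.mean()),
        "Dmax": float(d.max()),
        "Dmin": float(d.min()),
    }
    for lvl in v_levels_gy:
        out[f"V{lvl:g}Gy"] = 100.0 * float((d >= lvl).mean())
    if rx_gy is not None:
        out["V95"] = 100.0 * float((d >= 0.95 * rx_gy).mean())
        out["V100"] = 100.0 * float((d >= rx_gy).mean())
    return out


# ---------------------------------------------------------------------------
# gamma analysis


@dataclass
class GammaConfig:
    """3D global gamma settings (dose difference %, DTA mm)."""

    dose_pct: float = 3.0
    dta_mm: float = 3.0
    norm_dose_gy: Optional[float] = None  # None -> global max of the reference
    threshold_fraction: float = 0.10      # analyse only voxels above this x norm
    search_radius_dta: float = 2.0
    step_fraction_dta: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("gamma criteria must be > 0")
        if not (0.0 <= self.threshold_fraction < 1.0):
            raise ValueError("threshold fraction must be in [0, 1)")


def gamma_3d(
    ref: VoxelImage,
    evl: VoxelImage,
    cfg: Optional[GammaConfig] = None,
) -> Tuple[float, np.ndarray]:
    """Global gamma map and pass rate over the above-threshold region.

    For each analysed reference voxel, gamma is the minimum over candidate
    offsets within the search radius of
    ``sqrt(|dr|^2/DTA^2 + dD^2/(dd*Dnorm)^2)`` with the evaluated dose
    interpolated trilinearly at sub-voxel offsets.  ``gamma <= 1`` counts
    as a pass (inclusive).  Returns ``(pass_rate_%, gamma_map)`` with NaN
    outside the analysed region.
    """
    cfg = cfg or GammaConfig()
    if not ref.grid.same_geometry(evl.grid):
        raise ValueError("gamma analysis requires conforming grids")
    norm = cfg.norm_dose_gy
    if norm is None:
        norm = float(ref.values.max())
    if norm <= 0:
        raise ValueError("zero normalization dose")
    dd_abs = cfg.dose_pct / 100.0 * norm

    g = ref.grid
    analysed = ref.values >= cfg.threshold_fraction * norm
    if not analysed.any():
        raise ValueError("no voxels above the low-dose threshold")
    ii, jj, kk = np.nonzero(analysed)
    ref_d = ref.values[analysed].astype(np.float64)

    step = cfg.step_fraction_dta * cfg.dta_mm
    radius = cfg.search_radius_dta * cfg.dta_mm
    n = int(math.floor(radius / step + 1e-9))
    offs = np.arange(-n, n + 1) * step
    eval_vol = evl.values.astype(np.float64)
    spacing = np.asarray(g.spacing)

    best = np.full(ref_d.shape, np.inf)
    # offsets sorted by distance so the spatial term prunes later shifts
    cand = [
        (ox, oy, oz, ox * ox + oy * oy + oz * oz)
        for ox in offs for oy in offs for oz in offs
        if ox * ox + oy * oy + oz * oz <= radius * radius + 1e-9
    ]
    cand.sort(key=lambda t: t[3])
    for ox, oy, oz, r2 in cand:
        space_term = r2 / cfg.dta_mm**2
        if space_term >= best.max():
            break
        ci = ii + ox / spacing[0]
        cj = jj + oy / spacing[1]
        ck = kk + oz / spacing[2]
        ev = map_coordinates(eval_vol, [ci, cj, ck], order=1,
                             mode="nearest")
        gam2 = space_term + ((ev - ref_d) / dd_abs) ** 2
        np.minimum(best, gam2, out=best)

    gmap = np.full(g.dims, np.nan, dtype=np.float32)
    gvals = np.sqrt(best)
    gmap[analysed] = gvals
    pass_rate = 100.0 * float((gvals <= 1.0).mean())
    return pass_rate, gmap


# ---------------------------------------------------------------------------
# constraint auditing


def check_constraints(
    indices: Dict[str, Dict[str, float]],
    table: Sequence[Dict],
    rx_primary_gy: Optional[float] = None,
) -> List[Dict]:
    """Audit per-structure indices against the clinical constraint table.

    All limits are strict inequalities (a value exactly at the limit
    fails).  Returns one record per applicable (structure, constraint).
    """
    from .planning import _match_constraints

    records: List[Dict] = []
    for name, idx in indices.items():
        for c in _match_constraints(name, table):
            metric = c["metric"]
            if metric in ("Dmax", "Dmean"):
                limit = c.get("limit_gy")
                if limit is None:
                    if rx_primary_gy is None:
                        continue
                    limit = c["limit_pct"] / 100.0 * rx_primary_gy
                value = idx.get(metric)
            elif metric.startswith("V") and metric.endswith("Gy"):
                limit = c["limit_pct_volume"]
                value = idx.get(f"V{float(metric[1:-2]):g}Gy")
            else:  # pragma: no cover
                continue
            if value is None:
                continue
            records.append({
                "structure": name,
                "metric": metric,
                "limit": float(limit),
                "value": float(value),
                "pass": bool(value < limit),
            })
    return records


# ---------------------------------------------------------------------------
# dose accumulation


def accumulate_dose(
    weekly_doses: Sequence[VoxelImage],
    inverse_dvfs: Sequence[VectorField],
    fractions_per_week: Sequence[int],
) -> VoxelImage:
    """Fraction-weighted accumulation of weekly doses on the planning CT.

    ``accumulated = sum_w (f_w / F) * warp(D_w, invDVF_w)`` — each weekly
    dose is the full-course dose recalculated on that week's sCT, warped
    back to the planning CT through the inverse of the DVF that created
    the sCT, and averaged with fraction weights (a convex combination
    commensurate with the planned full-course dose).
    """
    if not (len(weekly_doses) == len(inverse_dvfs) == len(fractions_per_week)):
        raise ValueError("need one dose, inverse DVF and fraction count per week")
    if len(weekly_doses) == 0:
        raise ValueError("no weeks to accumulate")
    total_fx = float(sum(fractions_per_week))
    grid = inverse_dvfs[0].grid
    acc = np.zeros(grid.dims, dtype=np.float64)
    for dose_w, inv_w, fx in zip(weekly_doses, inverse_dvfs, fractions_per_week):
        warped = warp_image(dose_w, inv_w, interpolation="trilinear", fill_value=0.0)
        acc += (fx / total_fx) * warped.values.astype(np.float64)
    return VoxelImage(grid, acc, kind="Gy")


def weekly_fraction_schedule(total_fractions: int, n_weeks: int) -> List[int]:
    """Fractions represented by each weekly sample (fractions 1, 6, 11, ...).

    Each weekly image stands for the block of fractions until the next
    sample; the last block absorbs the remainder.
    """
    if n_weeks < 1 or total_fractions < n_weeks:
        raise ValueError("need at least one fraction per sampled week")
    base = total_fractions // n_weeks
    out = [base] * n_weeks
    out[-1] += total_fractions - base * n_weeks
    return out


# ---------------------------------------------------------------------------
# radiobiology


@dataclass
class NTCPParams:
    """LKB model parameters for one endpoint.

    The parameter values shipped with the package are editable,
    clearly-labelled literature stand-ins (see data/ntcp_params.yaml);
    the model form is NTCP = Phi((gEUD - TD50) / (m * TD50)).
    """

    endpoint: str
    structure: str
    n: float
    m: float
    td50_gy: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0 or self.td50_gy <= 0:
            raise ValueError("n, m and TD50 must all be > 0")


def load_ntcp_params(path: Optional[str] = None) -> Dict[str, NTCPParams]:
    """Load the NTCP parameter table (package default or a user YAML)."""
    if path is None:
        text = resources.files("apteval").joinpath("data/ntcp_params.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        k: NTCPParams(endpoint=k, **v) for k, v in raw["endpoints"].items()
    }


def geud(dose: np.ndarray, n: float,
         volumes: Optional[np.ndarray] = None) -> float:
    """Generalized equivalent uniform dose ``(sum v_i d_i^(1/n))^n``.

    Equal voxel volumes by default.  Reduces to the mean dose at n = 1 and
    approaches Dmax as n -> 0.
    """
    if n <= 0:
        raise ValueError("volume parameter n must be > 0")
    d = np.asarray(dose, dtype=float)
    if d.size == 0:
        raise ValueError("empty dose sample")
    if volumes is None:
        v = np.full(d.size, 1.0 / d.size)
    else:
        v = np.asarray(volumes, dtype=float)
        if not np.isclose(v.sum(), 1.0):
            raise ValueError("volumes must sum to 1")
    a = 1.0 / n
    return float((v * np.power(np.clip(d, 0.0, None), a)).sum() ** n)


def lkb_ntcp(geud_gy: float, params: NTCPParams) -> float:
    """LKB complication probability Phi((gEUD - TD50)/(m TD50))."""
    t = (geud_gy - params.td50_gy) / (params.m * params.td50_gy)
    return float(stats.norm.cdf(t))


def ntcp_from_dose(dose: VoxelImage, mask: np.ndarray,
                   params: NTCPParams) -> float:
    d = dose.values[np.asarray(mask, dtype=bool)]
    return lkb_ntcp(geud(d, params.n), params)


# ---------------------------------------------------------------------------
# statistics


class PairedTestResult(NamedTuple):
    mean_difference: float
    t_statistic: float
    p_value: float
    zero_variance: bool


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on matched samples.

    Degenerate difference variance is flagged rather than raised: the p
    value is reported as 1.0 and ``zero_variance`` set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = x - y
    md = float(diff.mean())
    if float(diff.std(ddof=1)) == 0.0:
        return PairedTestResult(md, 0.0 if md == 0 else math.inf, 1.0, True)
    t, p = stats.ttest_rel(x, y)
    return PairedTestResult(md, float(t), float(p), False)
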
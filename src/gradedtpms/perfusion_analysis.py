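"""Perfusion quantification from contrast-enhanced CT volumes.

A bolus of iodine contrast agent (CA) is injected into a steady water flow
upstream of the specimen while a CT scanner records Hounsfield-unit (HU)
volumes every 0.5 s. Each voxel mixes solid membrane material with fluid
(water + CA), and HU mixes linearly, so two static scans calibrate the
unmixing:

* porosity from the water-filled scan,
      ε = (HU_t0 − HU_air) / (HU_water − HU_air),
* CA volume fraction of the fluid phase in each transient frame,
      Φ = [ (HU_t − (1 − ε)·HU_material) / ε  −  HU_water ]
          / (HU_CA − HU_water).

The linear-mixing assumption needs voxels that average over several lattice
cells, so volumes are first block-averaged to a 2 mm analysis resolution.

Perfusion is then summarized by region-averaged concentration curves and
shares (bottom / left / center / right / top corner regions of the
cross-section), and by the Homogeneity Index

    HI = 1 − (1/SD_max) · (1/n) · Σ_planes sample-SD(Φ on plane),

the mean of per-plane standard deviations of Φ on the n planes
perpendicular to the main flow direction, normalized by the maximum
expected standard deviation SD_max. HI = 1 means perfectly uniform
perfusion; HI is deliberately not clamped below 0 (values below 0 flag
SD beyond SD_max and remain meaningful for relative comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: porosity floor keeping the concentration unmixing well-posed
EPS_FLOOR = 0.05

#: default maximum expected standard deviation, in concentration percent,
#: for a 20% maximum inlet concentration
DEFAULT_SD_MAX = 10.0


@dataclass
class HUConstants:
    """Reference Hounsfield values of the pure substances."""

    material: float = 120.0
    water: float = 0.0
    ca: float = 2000.0
    air: float = -1000.0

    def __post_init__(self):
        if self.ca == self.water:
            raise ValueError("HU_CA must differ from HU_water")
        if self.water == self.air:
            raise ValueError("HU_water must differ from HU_air")


@dataclass
class HUStack:
    """Co-registered HU volumes: air scan, water scan, transient frames."""

    air: np.ndarray
    water: np.ndarray
    frames: np.ndarray          # (nt, nx, ny, nz)
    times: np.ndarray
    constants: HUConstants = field(default_factory=HUConstants)

    def __post_init__(self):
        if self.air.shape != self.water.shape or self.frames.shape[1:] != self.water.shape:
            raise ValueError("HU volumes must share one grid")


def porosity_from_hu(
    hu_water_scan: np.ndarray,
    hu_air: float,
    hu_water: float,
    *,
    air_scan: np.ndarray | None = None,
    eps_floor: float = EPS_FLOOR,
    max_out_of_range: float = 0.05,
) -> np.ndarray:
    """Voxel porosity from the water-filled static scan.

        ε = (HU_t0 − HU_air) / (HU_water − HU_air)

    The reference subtracted in the numerator should be the co-registered
    *air-filled scan field* (``air_scan``): both static scans mix the same
    material fraction, (1−ε)·HU_material, so the subtraction cancels the
    solid contribution voxelwise and the quotient is exactly ε. When no air
    scan is available the scalar air HU constant is used instead, which is
    exact only where the voxel contains no solid. Values are clipped to
    [eps_floor, 1]; if more than ``max_out_of_range`` of voxels fall
    outside [−0.1, 1.1] before clipping, the scans are presumed
    mis-registered and an error is raised.
    """
    denom = hu_water - hu_air
    if denom == 0:
        raise ValueError("HU_water must differ from HU_air")
    ref = np.asarray(air_scan, float) if air_scan is not None else hu_air
    eps = (np.asarray(hu_water_scan, float) - ref) / denom
    frac_bad = np.mean((eps < -0.1) | (eps > 1.1))
    if frac_bad > max_out_of_range:
        raise ValueError(
            f"{frac_bad:.1%} of voxels outside [-0.1, 1.1]; "
            "scans appear mis-registered or constants are wrong"
        )
    return np.clip(eps, eps_floor, 1.0)


def concentration_from_hu(
    hu_t: np.ndarray,
    eps: np.ndarray,
    constants: HUConstants,
    *,
    clip: bool = True,
) -> tuple[np.ndarray, float]:
    """CA volume fraction of the fluid phase from one transient frame.

    Two-step unmixing: subtract the material contribution and divide by ε
    to get the fluid-phase HU, then invert the linear water↔CA mixing.
    Returns ``(Φ, out_of_range_fraction)``; Φ is clipped to [0, 1].
    """
    eps = np.asarray(eps, float)
    if np.any(eps < EPS_FLOOR - 1e-12):
        raise ValueError(f"porosity below floor {EPS_FLOOR}; clip it first")
    c = constants
    hu_fluid = (np.asarray(hu_t, float) - (1.0 - eps) * c.material) / eps
    phi = (hu_fluid - c.water) / (c.ca - c.water)
    frac_out = float(np.mean((phi < 0) | (phi > 1)))
    if clip:
        phi = np.clip(phi, 0.0, 1.0)
    return phi, frac_out


def downsample(fld: np.ndarray, spacing: float, target_edge: float = 2.0) -> np.ndarray:
    """Block arithmetic mean to ``target_edge`` (same units as spacing).

    Partial trailing blocks are averaged over the voxels available.
    """
    if target_edge < spacing:
        raise ValueError("target edge must be >= source spacing")
    b = max(1, int(round(target_edge / spacing)))
    if b == 1:
        return np.asarray(fld, float).copy()
    fld = np.asarray(fld, float)
    from skimage.measure import block_reduce

    return block_reduce(fld, (b,) * fld.ndim, np.mean)


@dataclass
class RegionMask:
    """Disjoint voxel regions B, L, C, R, T partitioning the domain."""

    labels: dict[str, np.ndarray]

    def __post_init__(self):
        masks = list(self.labels.values())
        total = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("regions overlap")
        if total.min() < 1:
            raise ValueError("regions do not cover the domain")


def default_regions(
    shape: tuple[int, int, int],
    *,
    up_axis: int = 1,
    depth_axis: int = 2,
    corner_frac: float = 0.35,
) -> RegionMask:
    """Corner/center partition of the cross-section, swept through depth.

    In the plane spanned by the in-plane axis and the flow (up) axis, four
    corner blocks each covering ``corner_frac`` of both extents are labelled
    B (inlet-side bottom corner), R (opposite bottom corner), L (inlet-side
    top corner) and T (top corner farthest from the inlet); the complement
    is the center region C.
    """
    axes = [0, 1, 2]
    axes.remove(up_axis)
    axes.remove(depth_axis)
    a = axes[0]  # in-plane axis
    na, nb = shape[a], shape[up_axis]
    ia = (np.arange(na) + 0.5) / na
    ib = (np.arange(nb) + 0.5) / nb
    lo_a = ia < corner_frac
    hi_a = ia >= 1.0 - corner_frac
    lo_b = ib < corner_frac
    hi_b = ib >= 1.0 - corner_frac

    def plane(mask_a, mask_b):
        m2 = mask_a[:, None] & mask_b[None, :]  # indexed (a, up_axis)
        shape3 = [1, 1, 1]
        shape3[a] = na
        shape3[up_axis] = nb
        m2 = m2 if a < up_axis else m2.T
        return np.broadcast_to(m2.reshape(shape3), shape).copy()

    B = plane(lo_a, lo_b)
    R = plane(hi_a, lo_b)
    L = plane(lo_a, hi_b)
    T = plane(hi_a, hi_b)
    C = ~(B | R | L | T)
    return RegionMask({"B": B, "L": L, "C": C, "R": R, "T": T})


def region_curves(frames: np.ndarray, masks: RegionMask) -> dict[str, np.ndarray]:
    """Mean Φ over each region per frame."""
    out = {}
    for name, m in masks.labels.items():
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"region {name!r} is empty")
        out[name] = frames[:, m].mean(axis=1)
    return out


def region_shares(
    curves: dict[str, np.ndarray],
    masks: RegionMask | None = None,
    dt: float = 1.0,
) -> dict[str, float]:
    """Fraction of CA that passed through each region.

    Trapezoidal time integral of each curve, weighted by region voxel count
    when masks are given, normalized to sum to 1.
    """
    totals = {}
    for name, c in curves.items():
        c = np.asarray(c, float)
        if np.any(c < 0):
            raise ValueError("curves must be non-negative")
        w = float(masks.labels[name].sum()) if masks is not None else 1.0
        totals[name] = w * float(np.trapezoid(c, dx=dt))
    s = sum(totals.values())
    if s == 0:
        raise ValueError("all curves are zero; no CA passed through")
    return {k: v / s for k, v in totals.items()}


def max_expected_sd(phi_max_percent: float = 20.0) -> float:
    """Maximum expected standard deviation of a bounded concentration.

    For values confined to [0, Φ_max] the population SD is maximized by
    placing equal mass at the two extremes, giving SD = Φ_max/2 (10% for a
    20% maximum inlet concentration under homogeneous mixing).
    """
    if not phi_max_percent > 0:
        raise ValueError("phi_max must be > 0")
    return phi_max_percent / 2.0


def homogeneity_index(
    frame: np.ndarray,
    axis: int = 1,
    sd_max: float = DEFAULT_SD_MAX,
    *,
    phi_in_percent: bool = False,
) -> float:
    """Homogeneity Index of one concentration frame.

    Sample standard deviations (m − 1 denominator) of Φ, in percent, on
    each voxel plane perpendicular to ``axis``, averaged over planes and
    normalized by ``sd_max`` (percent). Set ``phi_in_percent`` when the
    frame is already expressed in percent rather than as a 0–1 fraction.
    """
    frame = np.asarray(frame, float)
    if not phi_in_percent:
        frame = frame * 100.0
    frame = np.moveaxis(frame, axis, 0)
    n = frame.shape[0]
    planes = frame.reshape(n, -1)
    if planes.shape[1] < 2:
        raise ValueError("each plane needs at least 2 evaluation points")
    sds = planes.std(axis=1, ddof=1)
    return float(1.0 - sds.mean() / sd_max)


def homogeneity_curve(
    frames: np.ndarray, axis: int = 1, sd_max: float = DEFAULT_SD_MAX
) -> np.ndarray:
    """HI per frame of a concentration series (fractional Φ)."""
    return np.array([homogeneity_index(f, axis=axis, sd_max=sd_max) for f in frames])


def spearman_validation(
    sim: np.ndarray, meas: np.ndarray, *, tie_warn_frac: float = 0.01
) -> tuple[float, float, float]:
    """Spearman rank correlation of paired (region, time) concentrations.

    Returns ``(r, p, tie_fraction)`` with a two-sided p-value. The tie
    fraction (share of samples involved in tied ranks, pooled over both
    series) is reported so callers can check it stays below ~1%.
    """
    sim = np.asarray(sim, float).ravel()
    meas = np.asarray(meas, float).ravel()
    if sim.shape != meas.shape:
        raise ValueError("paired samples must have equal length")
    if np.ptp(sim) == 0 or np.ptp(meas) == 0:
        raise ValueError("constant input: rank correlation undefined")
    ties = 0
    for arr in (sim, meas):
        _, counts = np.unique(arr, return_counts=True)
        ties += int(counts[counts > 1].sum())
    tie_frac = ties / (2.0 * sim.size)
    r, p = stats.spearmanr(sim, meas)
    return float(r), float(p), float(tie_frac)
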
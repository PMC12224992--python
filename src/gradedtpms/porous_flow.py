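"""Steady Darcy–Forchheimer flow and passive-tracer transport.

The graded lattice is far too fine to resolve directly at device scale, so
flow through it is modelled as a porous medium. The local pressure loss
follows the Darcy–Forchheimer law

    ∇p = (η D + ½ ρ F |u⃗|) u⃗

with viscous (Darcy) coefficient D (1/m²), inertial (Forchheimer)
coefficient F (1/m), fluid viscosity η and density ρ, and superficial
velocity u⃗ (volumetric flux per total cross-section). The steady solver
enforces continuity ∇·u⃗ = 0 on a collocated structured grid with a
fixed-flux inlet and fixed-pressure outlet; the |u⃗| nonlinearity is
handled by Picard iteration with under-relaxation. In the Darcy limit
(F = 0) the discretization is exactly a linear resistor network.

A first-order upwind finite-volume scheme transports a passive tracer
(contrast-agent volume fraction Φ of the fluid phase) through the
converged flow field at the interstitial velocity u⃗/ε, emulating the
bolus-injection CT experiment used to assess perfusion homogeneity. Upwind
differencing is monotone, so Φ stays within [0, Φ_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import PchipInterpolator
from scipy.sparse.linalg import spsolve

from .grids import RegularGrid

_FACES = {"xmin": (0, 0), "xmax": (0, 1), "ymin": (1, 0), "ymax": (1, 1),
          "zmin": (2, 0), "zmax": (2, 1)}


class ConvergenceError(RuntimeError):
    """Steady solver failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------------------
# porous coefficients
# ---------------------------------------------------------------------------

@dataclass
class ParametricCoefficients:
    """Pore-size scaling model for the lattice hydraulic coefficients.

    For granular/lattice porous media the permeability scales with the pore
    size squared and the inertial coefficient with the inverse pore size, so
    with reference values (d0, f0) at unit cell size cs0:

        D(cs) = d0 · (cs0/cs)²        F(cs) = f0 · (cs0/cs)

    d0 and f0 are calibration inputs (defaults are placeholders on the
    scale typical of mm-pore lattices); a measured table can replace this
    model via :class:`TableCoefficients`.
    """

    d0: float = 1.0e9   # 1/m² at cs0
    f0: float = 1.0e4   # 1/m  at cs0
    cs0: float = 1.2    # mm

    def __call__(self, cs):
        cs = np.asarray(cs, dtype=float)
        if np.any(cs <= 0):
            raise ValueError("cs must be > 0")
        r = self.cs0 / cs
        return self.d0 * r**2, self.f0 * r


class TableCoefficients:
    """Monotone (PCHIP) interpolation of a user-supplied (cs, D, F) table."""

    def __init__(self, cs: np.ndarray, D: np.ndarray, F: np.ndarray):
        cs = np.asarray(cs, float)
        order = np.argsort(cs)
        self.cs = cs[order]
        self._d = PchipInterpolator(self.cs, np.asarray(D, float)[order])
        self._f = PchipInterpolator(self.cs, np.asarray(F, float)[order])

    def __call__(self, cs):
        cs = np.asarray(cs, dtype=float)
        if np.any(cs < self.cs[0]) or np.any(cs > self.cs[-1]):
            raise ValueError(
                f"cs outside table range [{self.cs[0]}, {self.cs[-1]}]"
            )
        return self._d(cs), self._f(cs)


def coefficients(cs, model=None):
    """Darcy and Forchheimer coefficients for unit cell size ``cs`` (mm)."""
    if model is None:
        model = ParametricCoefficients()
    return model(cs)


# ---------------------------------------------------------------------------
# problem definition
# ---------------------------------------------------------------------------

@dataclass
class PorousProps:
    """Cellwise porous-medium properties plus fluid constants (SI).

    Default fluid: water at 20 °C.
    """

    D: np.ndarray          # 1/m², broadcastable to the grid
    F: np.ndarray          # 1/m
    eps: np.ndarray        # porosity, 0 < ε ≤ 1
    eta: float = 1.0e-3    # Pa·s
    rho: float = 998.0     # kg/m³

    def validate(self, shape) -> "PorousProps":
        D = np.broadcast_to(np.asarray(self.D, float), shape).copy()
        F = np.broadcast_to(np.asarray(self.F, float), shape).copy()
        eps = np.broadcast_to(np.asarray(self.eps, float), shape).copy()
        if np.any(D <= 0):
            raise ValueError("Darcy coefficient D must be > 0")
        if np.any(F < 0):
            raise ValueError("Forchheimer coefficient F must be >= 0")
        if np.any(eps <= 0) or np.any(eps > 1):
            raise ValueError("porosity must be in (0, 1]")
        return PorousProps(D, F, eps, self.eta, self.rho)


@dataclass(frozen=True)
class Patch:
    """Rectangular boundary patch on one box face.

    ``span`` gives fractional bounds over the two in-face axes (in axis
    order, e.g. for a ymin/ymax face: (x-bounds, z-bounds)).
    """

    face: str
    span: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0))

    def __post_init__(self):
        if self.face not in _FACES:
            raise ValueError(f"unknown face {self.face!r}")


@dataclass
class FlowGeometry:
    """Structured box with inlet/outlet boundary patches (SI units)."""

    grid: RegularGrid  # centered=True, spacing in m
    inlet: list[Patch] = field(default_factory=list)
    outlet: list[Patch] = field(default_factory=list)

    def __post_init__(self):
        if not self.grid.centered:
            raise ValueError("flow grid must use the voxel (cell-centered) convention")
        if not self.inlet or not self.outlet:
            raise ValueError("inlet and outlet patches must be non-empty")
        ink = {(p.face, tuple(map(tuple, p.span))) for p in self.inlet}
        outk = {(p.face, tuple(map(tuple, p.span))) for p in self.outlet}
        if ink & outk:
            raise ValueError("inlet and outlet patches must be disjoint")

    def patch_cells(self, patches: list[Patch]):
        """Boundary cells touched by ``patches``: (axis, side, flat cell idx)."""
        shape = self.grid.shape
        idx = np.arange(int(np.prod(shape))).reshape(shape)
        out = []
        for p in patches:
            axis, side = _FACES[p.face]
            a, b = [ax for ax in range(3) if ax != axis]
            sel = [slice(None)] * 3
            sel[axis] = -1 if side else 0
            face_idx = idx[tuple(sel)]  # shape (shape[a], shape[b])
            (la, ha), (lb, hb) = p.span
            ia = np.arange(shape[a])
            ib = np.arange(shape[b])
            # a cell belongs to the patch if its center lies inside the span
            ca = (ia + 0.5) / shape[a]
            cb = (ib + 0.5) / shape[b]
            mask = (ca[:, None] >= la) & (ca[:, None] < ha) & \
                   (cb[None, :] >= lb) & (cb[None, :] < hb)
            out.append((axis, side, face_idx[mask].ravel()))
        return out


@dataclass
class FlowField:
    """Converged steady solution.

    ``u`` is the cell-centered superficial velocity; ``face_flux`` holds the
    signed volumetric flows (m³/s, positive along +axis) on the staggered
    face arrays, which the tracer scheme uses for exact conservation.
    """

    grid: RegularGrid
    p: np.ndarray
    u: np.ndarray                       # (*, 3) superficial, m/s
    face_flux: tuple[np.ndarray, np.ndarray, np.ndarray]
    residual: float
    iterations: int
    history: list[float]

    def speed(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=-1))


@dataclass
class BolusInjection:
    """Inlet tracer schedule: Φ = phi_max during [start, start+duration)."""

    start: float = 0.0
    duration: float = 2.0
    phi_max: float = 0.20


@dataclass
class ConcentrationSeries:
    """Time-resolved tracer volume-fraction fields Φ(t)."""

    times: np.ndarray
    fields: np.ndarray  # (nt, nx, ny, nz)
    injection: BolusInjection


# ---------------------------------------------------------------------------
# steady solver
# ---------------------------------------------------------------------------

def pressure_loss(u, props: PorousProps):
    """Darcy–Forchheimer pressure gradient (Pa/m) for velocity ``u`` (m/s)."""
    u = np.asarray(u, dtype=float)
    mag = np.sqrt((u**2).sum(axis=-1)) if u.ndim else np.abs(u)
    resist = props.eta * props.D + 0.5 * props.rho * props.F * mag
    return (np.asarray(resist)[..., None] * u) if u.ndim else resist * u


def reference_velocity(Q: float, A: float, eps_mean: float) -> float:
    """Target interstitial velocity: total flow / (cross-section · porosity)."""
    if not A > 0:
        raise ValueError("area must be > 0")
    if not 0 < eps_mean <= 1:
        raise ValueError("porosity must be in (0, 1]")
    return Q / (A * eps_mean)


def _face_conductances(k: np.ndarray, grid: RegularGrid):
    """Harmonic-mean conductance g = k̄·A/h on internal faces, per axis."""
    hx, hy, hz = grid.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    out = []
    for a in range(3):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[a] = slice(None, -1)
        sl2[a] = slice(1, None)
        k1, k2 = k[tuple(sl1)], k[tuple(sl2)]
        kf = 2.0 * k1 * k2 / (k1 + k2)
        out.append(kf * areas[a] / grid.spacing[a])
    return out


def solve_steady(
    props: PorousProps,
    geom: FlowGeometry,
    Q: float,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    relax: float = 0.7,
) -> FlowField:
    """Solve ∇·u = 0, u = −[ηD + ½ρF|u|]⁻¹ ∇p by Picard iteration.

    Fixed total flux ``Q`` (m³/s) distributed uniformly over the inlet patch
    area; fixed pressure 0 on the outlet patch. Convergence is measured as
    the max face-flux change between Picard iterates relative to ``Q``; in
    the Darcy limit the loop converges on the second iterate.
    """
    grid = geom.grid
    shape = grid.shape
    props = props.validate(shape)
    N = int(np.prod(shape))
    hx, hy, hz = grid.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    idx = np.arange(N).reshape(shape)

    inlet_faces = geom.patch_cells(geom.inlet)
    outlet_faces = geom.patch_cells(geom.outlet)
    total_in_area = sum(areas[ax] * cells.size for ax, _, cells in inlet_faces)
    if total_in_area == 0:
        raise ValueError("inlet patch covers no boundary faces")
    if sum(c.size for _, _, c in outlet_faces) == 0:
        raise ValueError("outlet patch covers no boundary faces")

    # fixed inlet source per cell (m³/s)
    b_in = np.zeros(N)
    for ax, _, cells in inlet_faces:
        np.add.at(b_in, cells, Q * areas[ax] / total_in_area)

    speed = np.zeros(shape)            # cell superficial |u| for Forchheimer
    fluxes = [np.zeros((shape[0] + 1, shape[1], shape[2])),
              np.zeros((shape[0], shape[1] + 1, shape[2])),
              np.zeros((shape[0], shape[1], shape[2] + 1))]
    history: list[float] = []

    for it in range(1, max_iter + 1):
        resist = props.eta * props.D + 0.5 * props.rho * props.F * speed
        k = 1.0 / resist
        g_int = _face_conductances(k, grid)

        rows, cols, vals = [], [], []
        for a in range(3):
            sl1 = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl1[a] = slice(None, -1)
            sl2[a] = slice(1, None)
            i1 = idx[tuple(sl1)].ravel()
            i2 = idx[tuple(sl2)].ravel()
            g = g_int[a].ravel()
            rows += [i1, i2, i1, i2]
            cols += [i1, i2, i2, i1]
            vals += [g, g, -g, -g]

        b = b_in.copy()
        out_g = []  # (cells, conductances) for outlet flux recovery
        for ax, side, cells in outlet_faces:
            g_b = k.ravel()[cells] * areas[ax] / (grid.spacing[ax] / 2.0)
            rows.append(cells)
            cols.append(cells)
            vals.append(g_b)
            out_g.append((ax, side, cells, g_b))

        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        )
        p = spsolve(A, b)

        new_fluxes = [np.zeros_like(f) for f in fluxes]
        p3 = p.reshape(shape)
        for a in range(3):
            sl1 = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl1[a] = slice(None, -1)
            sl2[a] = slice(1, None)
            inner = [slice(None)] * 3
            inner[a] = slice(1, -1)
            new_fluxes[a][tuple(inner)] = g_int[a] * (p3[tuple(sl1)] - p3[tuple(sl2)])
        # boundary faces: inlet prescribed, outlet from the half-cell conductance
        for ax, side, cells in inlet_faces:
            q_face = Q * areas[ax] / total_in_area
            _add_boundary_flux(new_fluxes[ax], shape, ax, side, cells,
                               np.full(cells.size, q_face))
        for ax, side, cells, g_b in out_g:
            q_out = g_b * p.ravel()[cells]  # volumetric outflow
            _add_boundary_flux(new_fluxes[ax], shape, ax, side, cells, q_out,
                               outflow=True)

        delta = max(np.abs(nf - f).max() for nf, f in zip(new_fluxes, fluxes)) / abs(Q)
        history.append(float(delta))
        fluxes = new_fluxes

        u = np.stack(
            [0.5 * (_lo_faces(fluxes[a], a) + _hi_faces(fluxes[a], a)) / areas[a]
             for a in range(3)],
            axis=-1,
        )
        new_speed = np.sqrt((u**2).sum(axis=-1))
        speed = relax * new_speed + (1.0 - relax) * speed

        if delta < tol and it >= 2:
            div = _divergence(fluxes, b_in, out_g, shape)
            residual = float(np.abs(div).max() / abs(Q))
            return FlowField(grid, p3, u, tuple(fluxes), residual, it, history)

    raise ConvergenceError(
        f"Picard iteration did not converge in {max_iter} iterations "
        f"(last Δ={history[-1]:.3e})",
        history,
    )


def _lo_faces(fa: np.ndarray, axis: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = slice(None, -1)
    return fa[tuple(sl)]


def _hi_faces(fa: np.ndarray, axis: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = slice(1, None)
    return fa[tuple(sl)]


def _add_boundary_flux(fa, shape, axis, side, cells, q, *, outflow=False):
    """Write signed boundary fluxes into the staggered face array."""
    multi = np.array(np.unravel_index(cells, shape)).T
    for (ci, cj, ck), qi in zip(multi, q):
        pos = [ci, cj, ck]
        if side:  # max face: boundary face index = n along axis
            pos[axis] += 1
            fa[tuple(pos)] = qi if outflow else -qi
        else:     # min face at index 0: +axis direction points inward
            fa[tuple(pos)] = -qi if outflow else qi


def _divergence(fluxes, b_in, out_g, shape):
    """Net volumetric imbalance per cell (should vanish at convergence)."""
    div = np.zeros(shape)
    for a in range(3):
        div += _lo_faces(fluxes[a], a) - _hi_faces(fluxes[a], a)
    return div


def flow_balance(flow: FlowField, geom: FlowGeometry) -> tuple[float, float]:
    """(total inflow, total outflow) across the inlet/outlet patches, m³/s."""
    totals = []
    for patches in (geom.inlet, geom.outlet):
        tot = 0.0
        for ax, side, cells in geom.patch_cells(patches):
            fa = flow.face_flux[ax]
            multi = np.array(np.unravel_index(cells, geom.grid.shape)).T
            for ci, cj, ck in multi:
                pos = [ci, cj, ck]
                if side:
                    pos[ax] += 1
                    tot += -fa[tuple(pos)] if patches is geom.inlet else fa[tuple(pos)]
                else:
                    tot += fa[tuple(pos)] if patches is geom.inlet else -fa[tuple(pos)]
        totals.append(tot)
    return totals[0], totals[1]


# ---------------------------------------------------------------------------
# transient tracer
# ---------------------------------------------------------------------------

def advect_tracer(
    flow: FlowField,
    props: PorousProps,
    geom: FlowGeometry,
    injection: BolusInjection,
    t_end: float,
    frame_dt: float = 0.5,
    *,
    cfl: float = 0.9,
) -> ConcentrationSeries:
    """First-order upwind transport of the tracer fraction Φ.

    Internally sub-steps to keep the interstitial CFL number below ``cfl``
    (≤ 1 guarantees monotonicity and boundedness); frames are recorded every
    ``frame_dt`` seconds starting at t = 0. The scheme is conservative: the
    tracer volume Σ Φ·ε·V changes only through the inlet and outlet faces.
    """
    grid = flow.grid
    shape = grid.shape
    props = props.validate(shape)
    eps = props.eps
    V = grid.cell_volume
    fx, fy, fz = flow.face_flux
    fluxes = (fx, fy, fz)

    # stable step: eps*V / (sum of out-directed face flows) per cell
    outflux = np.zeros(shape)
    for a in range(3):
        outflux += np.maximum(_hi_faces(fluxes[a], a), 0.0)
        outflux += np.maximum(-_lo_faces(fluxes[a], a), 0.0)
    with np.errstate(divide="ignore"):
        dt_stable = np.min(np.where(outflux > 0, eps * V / np.maximum(outflux, 1e-300), np.inf))
    if not np.isfinite(dt_stable):
        dt_stable = frame_dt
    n_sub = max(1, int(np.ceil(frame_dt / (cfl * dt_stable))))
    dt = frame_dt / n_sub

    inlet_faces = geom.patch_cells(geom.inlet)
    outlet_faces = geom.patch_cells(geom.outlet)

    n_frames = int(round(t_end / frame_dt)) + 1
    times = np.arange(n_frames) * frame_dt
    out = np.zeros((n_frames, *shape))

    phi = np.zeros(shape)
    mass = phi * eps * V
    out[0] = phi
    for fr in range(1, n_frames):
        for sub in range(n_sub):
            # exact overlap of [t, t+dt] with the bolus window, so the
            # injected tracer volume is Q·Φ_max·duration to round-off
            t = (fr - 1) * frame_dt + sub * dt
            overlap = max(0.0, min(t + dt, injection.start + injection.duration)
                          - max(t, injection.start))
            phi_in = injection.phi_max * overlap / dt
            dm = np.zeros(shape)
            for a in range(3):
                q = fluxes[a]
                inner = [slice(None)] * 3
                inner[a] = slice(1, -1)
                qi = q[tuple(inner)]  # internal faces
                sl1 = [slice(None)] * 3
                sl2 = [slice(None)] * 3
                sl1[a] = slice(None, -1)
                sl2[a] = slice(1, None)
                phi_up = np.where(qi > 0, phi[tuple(sl1)], phi[tuple(sl2)])
                adv = qi * phi_up  # tracer volume flow in +a
                dm[tuple(sl1)] -= adv
                dm[tuple(sl2)] += adv
            # boundary faces
            for ax, side, cells in inlet_faces:
                q_face = _boundary_flux_values(fluxes[ax], shape, ax, side, cells)
                inflow = np.where(side, -q_face, q_face)  # into the domain
                np.add.at(dm.reshape(-1), cells, inflow * phi_in)
            for ax, side, cells in outlet_faces:
                q_face = _boundary_flux_values(fluxes[ax], shape, ax, side, cells)
                outflow = np.where(side, q_face, -q_face)
                np.add.at(dm.reshape(-1), cells, -outflow * phi.reshape(-1)[cells])
            mass = mass + dt * dm
            phi = mass / (eps * V)
            if phi.min() < -1e-9 or phi.max() > injection.phi_max + 1e-9:
                raise RuntimeError(
                    f"unstable tracer step: Φ ∈ [{phi.min():.3g}, {phi.max():.3g}]"
                )
        out[fr] = phi
    return ConcentrationSeries(times, out, injection)


def _boundary_flux_values(fa, shape, axis, side, cells):
    multi = np.array(np.unravel_index(cells, shape)).T
    vals = np.empty(cells.size)
    for i, (ci, cj, ck) in enumerate(multi):
        pos = [ci, cj, ck]
        if side:
            pos[axis] += 1
        vals[i] = fa[tuple(pos)]
    return vals
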
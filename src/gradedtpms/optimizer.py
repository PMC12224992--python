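"""CFD-in-the-loop unit-cell-size optimization for homogeneous perfusion.

The loop seeks a cell-size field cs(X) such that the local interstitial
flow velocity u inside the porous lattice equals a single reference value

    u_ref = Q / (A · ε̄)

everywhere (Q: total volume flow, A: structure cross-section, ε̄: mean
porosity). Each iteration:

1. simulate steady Darcy–Forchheimer flow for the current cs field,
2. evaluate the objective |u − u_ref| at every control point,
3. update the control values by the gradient-free rule

       cs_{i+1} = max(cs_min, cs_i − α (u − u_ref))

   — where flow is too fast the cell size shrinks (raising resistance),
   where it is too slow the cell grows (lowering resistance), never below
   the manufacturable minimum cs_min,
4. smooth the control values into a new cs field by Gaussian RBF
   interpolation and feed it back to the flow model.

The loop runs for at least ``min_iterations`` and stops once the largest
relative cell-size change between consecutive iterations drops below
``change_tol`` (default 5%), or at the iteration cap.

``u`` in the update rule is the interstitial velocity magnitude
|u_superficial|/ε sampled at the control point, consistent with the
porosity-corrected definition of u_ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import porous_flow
from .field_model import CellSizeField, ControlGrid, smooth_field
from .grids import RegularGrid
from .porous_flow import FlowField, FlowGeometry, PorousProps


def objective(u_local: np.ndarray, u_ref: float) -> tuple[np.ndarray, float]:
    """Per-point |u − u_ref| and its mean (the scalar summary)."""
    if not u_ref > 0:
        raise ValueError("u_ref must be > 0")
    err = np.abs(np.asarray(u_local, float) - u_ref)
    return err, float(err.mean())


def update_cellsizes(
    cs_values: np.ndarray,
    u_local: np.ndarray,
    u_ref: float,
    alpha: float,
    cs_min: float,
    cs_max: float | None = None,
) -> np.ndarray:
    """One optimization step: cs ← max(cs_min, cs − α(u − u_ref))."""
    if not alpha > 0:
        raise ValueError("optimization rate alpha must be > 0")
    new = np.asarray(cs_values, float) - alpha * (np.asarray(u_local, float) - u_ref)
    new = np.maximum(new, cs_min)
    if cs_max is not None:
        new = np.minimum(new, cs_max)
    return new


@dataclass
class OptimizationState:
    """Snapshot of one optimization iteration."""

    iteration: int
    cs_control: np.ndarray
    cs_field: CellSizeField
    flow: FlowField
    objective: np.ndarray        # |u − u_ref| per control point
    mean_objective: float
    max_rel_change: float
    relative_area: float         # ∫ dV/cs — surface area up to the SWD shape constant


@dataclass
class OptimizationProblem:
    """Everything the loop needs to simulate one cs field.

    ``coefficient_model`` maps cs (mm) to (D, F); ``porosity`` is the
    lattice porosity (≈ 0.5 for the Schwarz Diamond at zero offset);
    ``props_hook`` may override properties cellwise (e.g. fixture plenums).
    """

    control: ControlGrid
    sample_grid: RegularGrid          # node grid (mm) for the smoothed cs field
    geometry: FlowGeometry            # flow grid in m
    Q: float                          # m³/s
    coefficient_model: Callable = None
    porosity: float = 0.5
    eta: float = 1.0e-3
    rho: float = 998.0
    u_ref: float | None = None        # computed from Q/(A·ε) if None
    cs_max: float | None = None
    props_hook: Callable[[PorousProps, np.ndarray], PorousProps] | None = None
    flow_axis: int = 1                # main flow direction (for A)

    def reference_velocity(self) -> float:
        if self.u_ref is not None:
            return self.u_ref
        ext = self.geometry.grid.extent
        A = np.prod([e for i, e in enumerate(ext) if i != self.flow_axis])
        return porous_flow.reference_velocity(self.Q, float(A), self.porosity)


def _cs_on_flow_grid(cs_field: CellSizeField, flow_grid: RegularGrid) -> np.ndarray:
    """Sample the cs field (mm, node grid) at flow cell centers (m)."""
    interp = RegularGridInterpolator(
        cs_field.grid.axes(), cs_field.cs, bounds_error=False, fill_value=None
    )
    pts_mm = flow_grid.points() * 1e3
    return interp(pts_mm).reshape(flow_grid.shape)


def _interstitial_speed_at(points_mm: np.ndarray, flow: FlowField, eps) -> np.ndarray:
    speed = flow.speed() / eps
    interp = RegularGridInterpolator(
        flow.grid.axes(), speed, bounds_error=False, fill_value=None
    )
    return interp(points_mm * 1e-3)


def simulate(problem: OptimizationProblem, cs_field: CellSizeField) -> tuple[FlowField, PorousProps]:
    """Steady flow solve for one cell-size field."""
    model = problem.coefficient_model or porous_flow.ParametricCoefficients()
    cs_cells = np.clip(
        _cs_on_flow_grid(cs_field, problem.geometry.grid), cs_field.bounds[0], None
    )
    D, F = model(cs_cells)
    props = PorousProps(D, F, problem.porosity, problem.eta, problem.rho)
    props = props.validate(problem.geometry.grid.shape)
    if problem.props_hook is not None:
        props = problem.props_hook(props, cs_cells)
    flow = porous_flow.solve_steady(props, problem.geometry, problem.Q)
    return flow, props


def run_optimization(
    problem: OptimizationProblem,
    *,
    alpha: float | None = None,
    min_iterations: int = 50,
    change_tol: float = 0.05,
    max_iterations: int = 300,
    keep_history: bool = True,
) -> list[OptimizationState]:
    """Run the simulate → evaluate → update → smooth loop.

    Default optimization rate: α = 0.5 · cs_init / u_ref, i.e. a velocity
    error of one u_ref moves the cell size by half the initial value. The
    loop is deterministic. If the flow solver fails mid-run, the surviving
    history is attached to the raised error.
    """
    control = problem.control
    u_ref = problem.reference_velocity()
    if alpha is None:
        alpha = 0.5 * float(control.values.mean()) / u_ref

    history: list[OptimizationState] = []
    cs_vals = control.values.copy()
    dV = problem.sample_grid.cell_volume

    for it in range(max_iterations + 1):
        ctrl = control.with_values(cs_vals)
        cs_field = smooth_field(ctrl, problem.sample_grid,
                                cs_max=problem.cs_max, max_gradient=None)
        try:
            flow, props = simulate(problem, cs_field)
        except porous_flow.ConvergenceError as err:
            err.optimization_history = history  # surviving iterations
            raise
        u_ctrl = _interstitial_speed_at(control.points, flow, problem.porosity)
        err, mean_err = objective(u_ctrl, u_ref)

        new_vals = update_cellsizes(cs_vals, u_ctrl, u_ref, alpha,
                                    control.cs_min, problem.cs_max)
        max_rel_change = float(np.max(np.abs(new_vals - cs_vals) / cs_vals))
        state = OptimizationState(
            iteration=it,
            cs_control=cs_vals.copy(),
            cs_field=cs_field,
            flow=flow,
            objective=err,
            mean_objective=mean_err,
            max_rel_change=max_rel_change,
            relative_area=float((1.0 / cs_field.cs).sum() * dV),
        )
        if keep_history or len(history) < 2:
            history.append(state)
        else:
            history[-1] = state  # keep first and latest only
        if it >= min_iterations and max_rel_change < change_tol:
            break
        cs_vals = new_vals
    return history


def matched_constant_cs(cs_field: CellSizeField) -> float:
    """Constant cell size with the same total surface area as ``cs_field``.

    Lattice surface area density scales as 1/cs, so the area-matched
    constant is the harmonic mean of the graded field.
    """
    return float(1.0 / np.mean(1.0 / cs_field.cs))
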
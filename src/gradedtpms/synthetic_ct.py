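"""Synthetic CT phantoms and small flow fixtures.

The phantom generator forward-models the voxel HU mixing that the
perfusion analytics invert: each voxel blends solid membrane material with
fluid (air, water, or a water/contrast-agent mix), and HU mixes linearly,

    air scan    = (1 − ε)·HU_material + ε·HU_air
    water scan  = (1 − ε)·HU_material + ε·HU_water
    frame(t)    = (1 − ε)·HU_material + ε·[Φ·HU_CA + (1 − Φ)·HU_water]

plus optional additive i.i.d. Gaussian noise, seeded for reproducibility.
The default HU constants (air −1000, water 0, material 120, CA 2000) are
synthetic, on the scale typical of polymer prints and iodine contrast.

``make_flow_fixture`` builds small (≤ 40³ cells) flow configurations with
oracle-known behavior for end-to-end testing of the solver/optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RegularGrid
from .perfusion_analysis import HUConstants, HUStack
from .porous_flow import FlowGeometry, Patch, PorousProps


@dataclass
class PhantomSpec:
    """Ground truth for a synthetic HU stack.

    ``eps``: porosity per voxel; ``phi``: (nt, *shape) tracer fraction of
    the fluid phase; ``noise_sd`` in HU.
    """

    eps: np.ndarray
    phi: np.ndarray
    times: np.ndarray
    constants: HUConstants = field(default_factory=HUConstants)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.eps = np.asarray(self.eps, float)
        self.phi = np.asarray(self.phi, float)
        if self.phi.shape[1:] != self.eps.shape:
            raise ValueError(
                f"phi grid {self.phi.shape[1:]} does not match eps grid {self.eps.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_phantom(spec: PhantomSpec) -> HUStack:
    """Forward-model the HU stack (air scan, water scan, transient frames)."""
    c = spec.constants
    solid = (1.0 - spec.eps) * c.material
    air = solid + spec.eps * c.air
    water = solid + spec.eps * c.water
    fluid_hu = spec.phi * c.ca + (1.0 - spec.phi) * c.water
    frames = solid[None] + spec.eps[None] * fluid_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        air = air + rng.normal(0.0, spec.noise_sd, air.shape)
        water = water + rng.normal(0.0, spec.noise_sd, water.shape)
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    return HUStack(air, water, frames, np.asarray(spec.times, float), c)


@dataclass
class FlowFixture:
    """A small flow configuration with oracle-known expectations."""

    name: str
    geometry: FlowGeometry
    props: PorousProps
    Q: float
    expected: dict


def make_flow_fixture(preset: str, *, d0: float = 1.0e9) -> FlowFixture:
    """Named small flow configurations for end-to-end tests.

    Presets
    -------
    ``uniform_column``
        1D Darcy column; expected uniform superficial u = Q/A, linear p.
    ``two_channel``
        Two parallel channels (D₂ = D₁/4, i.e. channel 2 four times more
        permeable) joined by high-permeability plenums; expected flow split
        80/20 by the resistor analogy.
    ``corner_inlet_box``
        Box with inlet and outlet patches at opposite ends of the bottom
        face; expected tracer arrival order: bottom region before top.
    """
    eta, rho = 1.0e-3, 998.0
    if preset == "uniform_column":
        grid = RegularGrid((1, 20, 1), (0.01, 0.005, 0.01), centered=True)
        geom = FlowGeometry(grid, [Patch("ymin")], [Patch("ymax")])
        Q = 1.0e-6
        A = 0.01 * 0.01
        props = PorousProps(d0, 0.0, 0.5, eta, rho)
        L = 20 * 0.005
        expected = {
            "u": Q / A,
            "dp": eta * d0 * (Q / A) * L,
            "interstitial_u": Q / A / 0.5,
        }
        return FlowFixture(preset, geom, props, Q, expected)

    if preset == "two_channel":
        # columns: 0 = channel 1, 1 = wall, 2 = channel 2; plenum rows top+bottom
        nx, ny, nz = 3, 10, 1
        grid = RegularGrid((nx, ny, nz), (0.01, 0.01, 0.01), centered=True)
        geom = FlowGeometry(grid, [Patch("ymin")], [Patch("ymax")])
        D = np.full((nx, ny, nz), d0)
        D[2, :, :] = d0 / 4.0          # more permeable channel
        D[1, 1:-1, :] = d0 * 1.0e9     # impermeable wall between channels
        D[:, 0, :] = d0 * 1.0e-4       # distribution plenums
        D[:, -1, :] = d0 * 1.0e-4
        props = PorousProps(D, 0.0, 0.5, eta, rho)
        Q = 2.0e-6
        expected = {"split": (0.2, 0.8), "channel_columns": (0, 2)}
        return FlowFixture(preset, geom, props, Q, expected)

    if preset == "corner_inlet_box":
        nx, ny, nz = 12, 12, 6
        grid = RegularGrid((nx, ny, nz), (0.004, 0.004, 0.004), centered=True)
        geom = FlowGeometry(
            grid,
            [Patch("ymin", ((0.0, 0.25), (0.0, 1.0)))],
            [Patch("ymin", ((0.75, 1.0), (0.0, 1.0)))],
        )
        props = PorousProps(d0, 1.0e4, 0.5, eta, rho)
        Q = 8.333e-6  # 0.5 l/min
        expected = {"arrival_order": ("B", "T")}
        return FlowFixture(preset, geom, props, Q, expected)

    raise ValueError(f"unknown preset {preset!r}")


def two_channel_problem(*, cs_fast: float = 2.0, cs_slow: float = 1.2,
                        d0: float = 1.0e9):
    """Optimizer toy problem: two parallel channels with unequal start.

    Channel 1 (column 0) starts at ``cs_slow``, channel 2 (column 2) at
    ``cs_fast``; larger cells mean lower resistance, so channel 2 initially
    takes more flow. The unique Darcy fixed point is the equal split with
    interstitial velocity u_ref in both channels. The wall and plenum cells
    are not part of the design domain; a props hook re-imposes them after
    the coefficient model.
    """
    from . import optimizer as opt
    from .field_model import make_control_grid
    from .grids import grid_from_box
    from .porous_flow import ParametricCoefficients

    fx = make_flow_fixture("two_channel", d0=d0)
    eps = 0.5
    # control lattice with points at the channel centers (x = 5 and 25 mm)
    control = make_control_grid((20.0, 60.0, 0.0), 20.0, cs_slow,
                                cs_min=1.2, origin=(5.0, 20.0, 5.0))
    vals = control.values.copy()
    pts = control.points
    vals[pts[:, 0] > 15.0] = cs_fast
    control = control.with_values(vals)
    sample_grid = grid_from_box((20.0, 60.0, 0.0), 10.0, origin=(5.0, 20.0, 5.0))

    model = ParametricCoefficients(d0=d0, f0=0.0, cs0=cs_slow)

    def props_hook(props, cs_cells):
        props.D[1, 1:-1, :] = d0 * 1.0e9     # wall
        props.D[:, 0, :] = d0 * 1.0e-4       # plenums
        props.D[:, -1, :] = d0 * 1.0e-4
        props.F[:] = 0.0
        return props

    A_channels = 2 * 0.01 * 0.01  # wall column is not structure cross-section
    u_ref = fx.Q / (A_channels * eps)
    problem = opt.OptimizationProblem(
        control=control, sample_grid=sample_grid, geometry=fx.geometry,
        Q=fx.Q, coefficient_model=model, porosity=eps,
        u_ref=u_ref, props_hook=props_hook)
    return problem


def corner_box_problem(*, cs_init: float = 1.2, cs_min: float = 1.2,
                       d0: float = 1.0e9, f0: float = 1.0e4):
    """Optimizer problem on the corner-inlet box.

    Inlet and outlet sit at opposite ends of the bottom face, so the upper
    half of the box is initially starved; the optimizer should grow cell
    sizes with distance from the inlet to pull flow upward. The main (bulk)
    flow direction runs inlet→outlet along x, so perfusion-homogeneity
    planes for this problem are perpendicular to axis 0.
    """
    from . import optimizer as opt
    from .field_model import make_control_grid
    from .grids import grid_from_box
    from .porous_flow import ParametricCoefficients

    fx = make_flow_fixture("corner_inlet_box", d0=d0)
    domain_mm = (48.0, 48.0, 24.0)
    control = make_control_grid(domain_mm, 12.0, cs_init, cs_min=cs_min)
    sample_grid = grid_from_box(domain_mm, 6.0)
    model = ParametricCoefficients(d0=d0, f0=f0, cs0=cs_min)
    problem = opt.OptimizationProblem(
        control=control, sample_grid=sample_grid, geometry=fx.geometry,
        Q=fx.Q, coefficient_model=model, porosity=0.5, flow_axis=0)
    return problem
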
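"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def resistor_network_solve(D, grid, inlet_cells, outlet_cells, Q, eta=1.0e-3):
    """Independent dense resistor-network oracle for the Darcy limit.

    Nodes are cell centers; edge conductance between neighbors is the
    harmonic mean of k = 1/(ηD) times face area over distance. Inlet cells
    receive equal shares of Q; outlet cells connect to ground (p = 0)
    through their boundary half-cell. Solved densely with numpy, entirely
    separate from the package's sparse Picard solver.
    """
    shape = grid.shape
    hx, hy, hz = grid.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    N = int(np.prod(shape))
    idx = np.arange(N).reshape(shape)
    k = 1.0 / (eta * np.broadcast_to(np.asarray(D, float), shape))
    A = np.zeros((N, N))
    for ax in range(3):
        for pos in np.ndindex(*shape):
            nb = list(pos)
            nb[ax] += 1
            if nb[ax] >= shape[ax]:
                continue
            ki, kj = k[pos], k[tuple(nb)]
            g = 2 * ki * kj / (ki + kj) * areas[ax] / grid.spacing[ax]
            i, j = idx[pos], idx[tuple(nb)]
            A[i, i] += g
            A[j, j] += g
            A[i, j] -= g
            A[j, i] -= g
    b = np.zeros(N)
    for c, ax in inlet_cells:
        b[c] += Q / len(inlet_cells)
    for c, ax in outlet_cells:
        g = k.ravel()[c] * areas[ax] / (grid.spacing[ax] / 2)
        A[c, c] += g
    p = np.linalg.solve(A, b)
    return p.reshape(shape)
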
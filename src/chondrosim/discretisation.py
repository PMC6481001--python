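"""Spatial grid, state container and method-of-lines right-hand side.

The dimensionless domain is [0, 2]: the cell-seeded scaffold occupies
[0, 1] and the cell-free culture medium (1, 2].  Seven fields live on the
grid: MSC density ``m``, chondrocyte density ``n``, unbound latent TGF-beta
``c``, matrix-bound latent TGF-beta ``b``, unbound active TGF-beta ``a``,
and the receptor-bound TGF-beta mass densities ``p = f*m`` (on MSCs) and
``q = g*n`` (on chondrocytes).  The occupancy fractions ``f`` and ``g`` are
recovered from the bound masses by a guarded division, because the bound
masses — not the fractions — satisfy conservative evolution equations.

Spatial derivatives use second-order central differences with ghost-node
reflection for the no-flux boundaries; the resulting ODE system is stiff
(active TGF-beta decays 43x faster than cells differentiate) and is
integrated by the :mod:`chondrosim.integrator` module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .params import DimensionlessParameters

__all__ = [
    "Grid1D",
    "SystemState",
    "FIELD_NAMES",
    "heaviside",
    "recover_fraction",
    "diffusion_operator",
    "rhs",
    "rhs_flat",
    "jacobian_sparsity",
    "RhsError",
    "DENSITY_GUARD",
]

FIELD_NAMES = ("m", "n", "c", "b", "a", "p", "q")

#: Dimensionless cell density below which a node is treated as empty when
#: recovering receptor-occupancy fractions.
DENSITY_GUARD = 1e-9

# Undershoot handling: stiff integrators produce small negative excursions of
# order the absolute tolerance; these are clipped before fraction recovery.
# Negatives beyond max(_NEG_ABS, _NEG_REL * max|field|) indicate genuine
# instability and abort the integration.
_NEG_ABS = 1e-7
_NEG_REL = 1e-6


class RhsError(RuntimeError):
    """Raised when the right-hand side encounters an invalid state."""


class Grid1D:
    """Uniform vertex-centred grid of ``N`` nodes covering [0, 2].

    Nodes sit at ``x_i = i*h`` with ``h = 2/(N-1)``; both endpoints are
    included.  The scaffold/medium interface at x = 1 generally falls
    between nodes and is effectively snapped to within half a grid cell.
    """

    def __init__(self, N: int = 200):
        if N < 3:
            raise ValueError(f"grid needs at least 3 nodes, got {N}")
        self.N = int(N)
        self.h = 2.0 / (self.N - 1)
        self.x = np.linspace(0.0, 2.0, self.N)

    @property
    def scaffold_mask(self) -> np.ndarray:
        return self.x <= 1.0 + 1e-12

    @property
    def medium_mask(self) -> np.ndarray:
        return ~self.scaffold_mask

    def __repr__(self):
        return f"Grid1D(N={self.N})"


@dataclass
class SystemState:
    """Nodal field values; see the module docstring for field meanings."""

    m: np.ndarray
    n: np.ndarray
    c: np.ndarray
    b: np.ndarray
    a: np.ndarray
    p: np.ndarray
    q: np.ndarray

    @classmethod
    def zeros(cls, N: int) -> "SystemState":
        return cls(*(np.zeros(N) for _ in FIELD_NAMES))

    @classmethod
    def from_flat(cls, y: np.ndarray, N: int) -> "SystemState":
        return cls(*(y[i * N : (i + 1) * N].copy() for i in range(7)))

    def to_flat(self) -> np.ndarray:
        return np.concatenate([getattr(self, name) for name in FIELD_NAMES])

    @property
    def f(self) -> np.ndarray:
        """Receptor-occupancy fraction on MSCs, recovered from p = f*m."""
        return recover_fraction(self.p, self.m)

    @property
    def g(self) -> np.ndarray:
        """Receptor-occupancy fraction on chondrocytes, recovered from q = g*n."""
        return recover_fraction(self.q, self.n)


def heaviside(z):
    """Step function with the convention H(0) = 0.

    Differentiation is active only for strictly positive excess receptor
    occupancy f - fd.  Accepts scalars or arrays.
    """
    if np.isscalar(z):
        return 1.0 if z > 0 else 0.0
    return (np.asarray(z) > 0).astype(float)


def recover_fraction(
    bound_mass: np.ndarray, cell_density: np.ndarray, guard: float = DENSITY_GUARD
) -> np.ndarray:
    """Recover an occupancy fraction from bound mass and cell density.

    Returns ``bound_mass / cell_density`` clipped to [0, 1] where the cell
    density exceeds ``guard``, and 0 at (effectively) empty nodes.  The
    division by a vanishing cell density is the model's only singularity;
    empty nodes carry no receptors, so their fraction is defined as 0.
    """
    if guard <= 0:
        raise ValueError("guard must be positive")
    bound_mass = np.asarray(bound_mass, dtype=float)
    cell_density = np.asarray(cell_density, dtype=float)
    occupied = cell_density > guard
    frac = np.zeros_like(bound_mass)
    np.divide(bound_mass, cell_density, out=frac, where=occupied)
    return np.clip(frac, 0.0, 1.0)


def diffusion_operator(field: np.ndarray, D: float, grid: Grid1D) -> np.ndarray:
    """Second-order diffusion stencil with no-flux (reflecting) boundaries.

    Interior: D*(u_{i-1} - 2 u_i + u_{i+1})/h^2.  At the boundaries a ghost
    node mirrors the first interior neighbour (u_{-1} = u_1), which enforces
    zero flux to second order.
    """
    u = np.asarray(field, dtype=float)
    if u.shape != (grid.N,):
        raise ValueError(f"field has shape {u.shape}, expected ({grid.N},)")
    h2 = grid.h * grid.h
    out = np.empty_like(u)
    out[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h2
    out[0] = 2.0 * (u[1] - u[0]) / h2
    out[-1] = 2.0 * (u[-2] - u[-1]) / h2
    return D * out


def _switch(f: np.ndarray, fd: float, eps_H: float) -> np.ndarray:
    """Differentiation switch H(f - fd), optionally smoothed to a linear ramp
    of half-width ``eps_H`` for solver-robustness studies (default off)."""
    if eps_H > 0.0:
        return np.clip((f - fd + eps_H) / (2.0 * eps_H), 0.0, 1.0)
    return heaviside(f - fd)


def rhs_flat(
    t: float,
    y: np.ndarray,
    params: DimensionlessParameters,
    grid: Grid1D,
    guard: float = DENSITY_GUARD,
    eps_H: float = 0.0,
) -> np.ndarray:
    """Time derivative of the flat state vector [m, n, c, b, a, p, q].

    Per node the model reads:

    * dm/dt = -H(f - fd) m            (MSC differentiation)
    * dn/dt = +H(f - fd) m
    * dc/dt = Dtc Lap(c) + lt3 n - (lt4 + lt5) c
    * db/dt = lt4 c - (lt6 + lt7) b
    * da/dt = Dta Lap(a) + lt6 b - lt8 a - ltm9 a m (1-f) - ltn9 a n (1-g)
    * dp/dt = lhm9 a m (1-f) - ltm10 p - H(f - fd) f m
    * dq/dt = lhn9 a n (1-g) - ltn10 q + H(f - fd) f m

    Receptor-bound TGF-beta travels with a differentiating cell, so the sink
    in dp/dt equals the source in dq/dt exactly.  Reaction terms apply over
    the whole domain; cell-dependent terms vanish automatically where no
    cells are present.
    """
    N = grid.N
    if not np.all(np.isfinite(y)):
        bad = int(np.argmin(np.isfinite(y)))
        raise RhsError(
            f"non-finite value in field '{FIELD_NAMES[bad // N]}' "
            f"at node {bad % N} (t={t:.6g})"
        )
    floor = -max(_NEG_ABS, _NEG_REL * float(np.max(np.abs(y), initial=0.0)))
    ymin = float(y.min(initial=0.0))
    if ymin < floor:
        bad = int(np.argmin(y))
        raise RhsError(
            f"field '{FIELD_NAMES[bad // N]}' at node {bad % N} went negative "
            f"({ymin:.3e} < {floor:.3e}) at t={t:.6g}"
        )

    m, n, c, b, a, p, q = (y[i * N : (i + 1) * N] for i in range(7))
    m = np.maximum(m, 0.0)
    n = np.maximum(n, 0.0)
    pr = params

    f = recover_fraction(p, m, guard)
    g = recover_fraction(q, n, guard)
    sw = _switch(f, pr.fd, eps_H)

    diff_flux = sw * m  # MSCs differentiating per unit time
    bound_transfer = sw * f * m  # their receptor-bound TGF-beta travels along

    bind_m = pr.lhm9 * a * m * (1.0 - f)
    bind_n = pr.lhn9 * a * n * (1.0 - g)

    out = np.empty_like(y)
    out[0:N] = -diff_flux
    out[N : 2 * N] = diff_flux
    out[2 * N : 3 * N] = (
        diffusion_operator(c, pr.Dtc, grid) + pr.lt3 * n - (pr.lt4 + pr.lt5) * c
    )
    out[3 * N : 4 * N] = pr.lt4 * c - (pr.lt6 + pr.lt7) * b
    out[4 * N : 5 * N] = (
        diffusion_operator(a, pr.Dta, grid)
        + pr.lt6 * b
        - pr.lt8 * a
        - pr.ltm9 * a * m * (1.0 - f)
        - pr.ltn9 * a * n * (1.0 - g)
    )
    out[5 * N : 6 * N] = bind_m - pr.ltm10 * p - bound_transfer
    out[6 * N : 7 * N] = bind_n - pr.ltn10 * q + bound_transfer
    return out


def rhs(
    t: float,
    state: SystemState,
    params: DimensionlessParameters,
    grid: Grid1D,
    guard: float = DENSITY_GUARD,
    eps_H: float = 0.0,
) -> SystemState:
    """Structured wrapper around :func:`rhs_flat`."""
    dy = rhs_flat(t, state.to_flat(), params, grid, guard=guard, eps_H=eps_H)
    return SystemState.from_flat(dy, grid.N)


def jacobian_sparsity(grid: Grid1D) -> sparse.csr_matrix:
    """Sparsity pattern of the RHS Jacobian for the stiff integrator.

    All seven fields couple within a node; only the two diffusing species
    (c and a) couple to neighbouring nodes.
    """
    N = grid.N
    S = sparse.lil_matrix((7 * N, 7 * N), dtype=np.int8)
    idx = np.arange(N)
    for fi in range(7):
        for fj in range(7):
            S[fi * N + idx, fj * N + idx] = 1
    for fi in (2, 4):  # c, a diffusion stencils
        S[fi * N + idx[1:], fi * N + idx[:-1]] = 1
        S[fi * N + idx[:-1], fi * N + idx[1:]] = 1
    return S.tocsr()
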
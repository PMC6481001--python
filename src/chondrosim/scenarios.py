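"""Culture-strategy scenarios: initial states for the three case studies.

Case 1: a layer of MSCs (density 1, depth 1-d) below a layer of seeded
chondrocytes (density n0, depth d); no exogenous TGF-beta — differentiation
must be driven by chondrocyte secretion alone.

Case 2: MSCs fill the whole scaffold; the culture medium carries a single
initial dose of active TGF-beta at concentration a0.

Case 3: both — layered seeding plus an exogenous dose.  Internally case 2
is the d = 0, n0 = 0 limit of case 3, and one code path builds all three.

Layer indicators are evaluated per node from products of step functions
with H(0) = 0, so a layer boundary that falls between nodes is effectively
snapped to within half a grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .discretisation import Grid1D, SystemState, heaviside

__all__ = ["ScenarioConfig", "ScenarioError", "initial_state", "msc_support"]


class ScenarioError(ValueError):
    """Raised for an inconsistent scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of a single culture simulation.

    Parameters
    ----------
    case_id : {1, 2, 3}
        Culture strategy (see module docstring).
    n0 : float
        Initial chondrocyte density in the upper layer (dimensionless,
        i.e. in units of M0 = 1 Mio/mL).
    a0 : float
        Initial active TGF-beta concentration in the culture medium
        (dimensionless, units of A0 = 1 ng/mL).
    d : float
        Depth fraction of the upper chondrocyte layer, in [0, 1].
    N : int
        Grid nodes over the full domain [0, 2].
    t_end : float
        Latest dimensionless time; simulations stop earlier if 90% of the
        initial MSC population has differentiated.
    rtol, atol : float
        Integrator tolerances.
    snapshot_dt : float
        Cadence of stored state snapshots.
    eps_H : float
        Optional half-width of a linear ramp replacing the differentiation
        step function (0 disables smoothing; the reference model uses the
        exact step).
    max_step : float
        Integrator step cap, guarding against stepping over ignition of the
        differentiation switch.
    stop_at_t90 : bool
        Stop the run once 90% of the initial MSC population has
        differentiated (the reference stopping rule).  Disable to follow
        the dynamics beyond t90, e.g. when inspecting late-time states.
    seed : int
        Reserved; the model core is deterministic.
    """

    case_id: int
    n0: float = 0.0
    a0: float = 0.0
    d: float = 0.0
    N: int = 200
    t_end: float = 20.0
    rtol: float = 1e-6
    atol: float = 1e-9
    snapshot_dt: float = 0.1
    eps_H: float = 0.0
    max_step: float = 0.05
    stop_at_t90: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.case_id not in (1, 2, 3):
            raise ScenarioError(f"case_id must be 1, 2 or 3, got {self.case_id!r}")
        if self.n0 < 0 or self.a0 < 0:
            raise ScenarioError("n0 and a0 must be non-negative")
        if not (0.0 <= self.d <= 1.0):
            raise ScenarioError(f"d must lie in [0, 1], got {self.d!r}")
        if self.case_id == 1 and self.a0 != 0:
            raise ScenarioError("case 1 has no exogenous TGF-beta (a0 must be 0)")
        if self.case_id == 2 and (self.n0 != 0 or self.d != 0):
            raise ScenarioError("case 2 seeds no chondrocytes (n0 = d = 0)")
        if self.case_id == 3 and self.n0 == 0 and self.a0 == 0:
            raise ScenarioError("case 3 needs n0 > 0 or a0 > 0")
        if self.t_end <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ScenarioError("t_end, rtol and atol must be positive")

    def replace(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


def initial_state(config: ScenarioConfig, grid: Grid1D) -> SystemState:
    """Build the nodal initial condition for a scenario.

    MSCs occupy 0 < x < 1-d at density 1, seeded chondrocytes 1-d < x < 1 at
    density n0, and the exogenous dose fills the medium 1 < x < 2 at
    concentration a0.  All other TGF-beta pools and the receptor-bound
    masses start at zero.
    """
    x = grid.x
    d = config.d if config.case_id != 2 else 0.0
    state = SystemState.zeros(grid.N)
    state.m = heaviside(1.0 - d - x) * heaviside(x)
    if config.case_id in (1, 3):
        state.n = config.n0 * heaviside(x - 1.0 + d) * heaviside(1.0 - x)
    if config.case_id in (2, 3):
        state.a = config.a0 * heaviside(x - 1.0) * heaviside(2.0 - x)
    return state


def msc_support(config: ScenarioConfig) -> tuple[float, float]:
    """Interval initially occupied by MSCs, over which the chondrocyte yield
    N(t) is integrated: [0, 1-d] for layered seedings, [0, 1] for case 2."""
    if config.case_id == 2:
        return (0.0, 1.0)
    return (0.0, 1.0 - config.d)
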
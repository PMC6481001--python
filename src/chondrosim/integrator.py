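"""Stiff time integration of the semi-discrete model.

The method-of-lines ODE system is advanced with scipy's adaptive BDF
integrator (L-stable, sparse Jacobian) at tolerance-controlled accuracy.
A terminal event tracks the chondrocyte yield N(t) — the trapezoidal
integral of chondrocyte density over the initial MSC region — and stops
the run at t90, the first time N(t) reaches 90% of the initial MSC number;
otherwise the run ends at ``t_end``.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .discretisation import (
    Grid1D,
    RhsError,
    SystemState,
    jacobian_sparsity,
    rhs_flat,
)
from .params import (
    DimensionalParameters,
    DimensionlessParameters,
    default_parameters,
    nondimensionalise,
)
from .scenarios import ScenarioConfig, initial_state, msc_support

__all__ = ["SimulationResult", "simulate", "detect_t90"]


@dataclass
class SimulationResult:
    """Outcome of one culture simulation.

    ``states`` has shape (T, 7, N) with field order m, n, c, b, a, p, q;
    ``N_series`` is the chondrocyte yield per cross-sectional area in the
    initial MSC region at each sampled time.  ``t90`` is present only if
    90% of the initial MSC population differentiated before ``t_end``.
    ``steady_state_residual`` reports max |dy/dt| at the terminal state as
    a proximity-to-steady-state diagnostic (reported, not enforced).
    """

    config: ScenarioConfig
    params: DimensionlessParameters
    times: np.ndarray
    states: np.ndarray
    N_series: np.ndarray
    t90: float | None
    terminal_state: SystemState
    termination_reason: str  # t90_reached | t_end_reached | aborted
    initial_msc_number: float
    steady_state_residual: float = float("nan")
    diagnostic: str = ""
    wall_time: float = 0.0

    @property
    def grid(self) -> Grid1D:
        return Grid1D(self.config.N)

    @property
    def N_final(self) -> float:
        return float(self.N_series[-1]) if len(self.N_series) else 0.0

    def state_at(self, index: int) -> SystemState:
        return SystemState(*(self.states[index, i].copy() for i in range(7)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (t, x, m, n, c, b, a, f, g) of all snapshots."""
        grid = self.grid
        rows = []
        for k, t in enumerate(self.times):
            st = self.state_at(k)
            rows.append(
                pd.DataFrame(
                    {
                        "t": t,
                        "x": grid.x,
                        "m": st.m,
                        "n": st.n,
                        "c": st.c,
                        "b": st.b,
                        "a": st.a,
                        "f": st.f,
                        "g": st.g,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        return {
            "case_id": self.config.case_id,
            "n0": self.config.n0,
            "a0": self.config.a0,
            "d": self.config.d,
            "t90": self.t90,
            "N_final": self.N_final,
            "initial_msc_number": self.initial_msc_number,
            "termination_reason": self.termination_reason,
            "steady_state_residual": self.steady_state_residual,
            "diagnostic": self.diagnostic,
            "wall_time_s": self.wall_time,
        }


def detect_t90(
    times: np.ndarray, N_series: np.ndarray, threshold: float
) -> float | None:
    """First time a non-decreasing yield series reaches ``threshold``.

    Linear interpolation between samples; returns None if the threshold is
    never reached.  The event detection inside :func:`simulate` locates the
    crossing on the integrator's dense output and is more accurate; this
    helper serves stored series.
    """
    times = np.asarray(times, dtype=float)
    N_series = np.asarray(N_series, dtype=float)
    above = N_series >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    y0, y1 = N_series[k - 1], N_series[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) * (t1 - t0) / (y1 - y0))


def _support_slice(grid: Grid1D, support: tuple[float, float]) -> slice:
    lo, hi = support
    idx = np.nonzero((grid.x >= lo - 1e-12) & (grid.x <= hi + 1e-12))[0]
    return slice(int(idx[0]), int(idx[-1]) + 1)


def simulate(
    config: ScenarioConfig,
    params: DimensionlessParameters | None = None,
    dim: DimensionalParameters | None = None,
) -> SimulationResult:
    """Run one culture simulation.

    Parameters default to the non-dimensionalised reference set.  The run
    terminates at t90 (90% of the initial MSC population differentiated) or
    at ``config.t_end``, whichever is earlier.  Integrator failure or an
    invalid state yields a result with ``termination_reason='aborted'``
    carrying the last valid snapshots and a diagnostic message.
    """
    if params is None:
        params = nondimensionalise(dim if dim is not None else default_parameters())
    grid = Grid1D(config.N)
    state0 = initial_state(config, grid)
    y0 = state0.to_flat()

    sup = _support_slice(grid, msc_support(config))
    xs = grid.x[sup]
    N_nodes = grid.N
    initial_msc = float(np.trapezoid(state0.m[sup], xs))
    threshold = 0.9 * initial_msc

    def fun(t, y):
        return rhs_flat(t, y, params, grid, eps_H=config.eps_H)

    def yield_event(t, y):
        return float(np.trapezoid(y[N_nodes : 2 * N_nodes][sup], xs)) - threshold

    yield_event.terminal = bool(initial_msc > 0 and config.stop_at_t90)
    yield_event.direction = 1

    t_eval = np.arange(0.0, config.t_end + 0.5 * config.snapshot_dt, config.snapshot_dt)
    t_eval = t_eval[t_eval <= config.t_end]

    start = _time.perf_counter()
    diagnostic = ""
    try:
        sol = solve_ivp(
            fun,
            (0.0, config.t_end),
            y0,
            method="BDF",
            rtol=config.rtol,
            atol=config.atol,
            jac_sparsity=jacobian_sparsity(grid),
            events=yield_event,
            t_eval=t_eval,
            max_step=config.max_step,
        )
    except RhsError as err:
        sol = None
        diagnostic = str(err)
    wall = _time.perf_counter() - start

    if sol is None or sol.status == -1:
        if sol is not None:
            diagnostic = sol.message
            times = sol.t
            states = sol.y.T.reshape(-1, 7, N_nodes)
        else:
            times = np.array([0.0])
            states = y0.reshape(1, 7, N_nodes)
        if len(times) == 0:
            times = np.array([0.0])
            states = y0.reshape(1, 7, N_nodes)
        N_series = np.trapezoid(states[:, 1, sup], xs, axis=1)
        terminal = SystemState(*(states[-1, i].copy() for i in range(7)))
        return SimulationResult(
            config=config,
            params=params,
            times=times,
            states=states,
            N_series=N_series,
            t90=None,
            terminal_state=terminal,
            termination_reason="aborted",
            initial_msc_number=initial_msc,
            diagnostic=diagnostic,
            wall_time=wall,
        )

    times = sol.t
    states = sol.y.T.reshape(-1, 7, N_nodes)

    t90 = float(sol.t_events[0][0]) if sol.t_events[0].size else None
    if t90 is not None and config.stop_at_t90:
        y_term = sol.y_events[0][0]
        reason = "t90_reached"
        # store the terminal (event) state exactly
        if len(times) == 0 or times[-1] < t90:
            times = np.append(times, t90)
            states = np.concatenate([states, y_term.reshape(1, 7, N_nodes)])
    else:
        reason = "t_end_reached"
        y_term = sol.y[:, -1]

    N_series = np.trapezoid(states[:, 1, sup], xs, axis=1)
    terminal = SystemState(*(y_term.reshape(7, N_nodes)[i].copy() for i in range(7)))
    residual = float(
        np.max(np.abs(rhs_flat(times[-1], y_term, params, grid, eps_H=config.eps_H)))
    )
    return SimulationResult(
        config=config,
        params=params,
        times=times,
        states=states,
        N_series=N_series,
        t90=t90,
        terminal_state=terminal,
        termination_reason=reason,
        initial_msc_number=initial_msc,
        steady_state_residual=residual,
        wall_time=wall,
    )
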
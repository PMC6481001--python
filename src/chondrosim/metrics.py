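"""Summary statistics, outcome classification and threshold searches.

Three long-term outcomes are distinguished.  *Full* differentiation: the
entire initial MSC population is committed — either 90% have differentiated
within the simulated window (t90 reached) or, at the terminal time, the
receptor occupancy exceeds the differentiation threshold everywhere MSCs
remain, so the stragglers are guaranteed to follow.  *None*: the final
chondrocyte yield in the MSC region is below a small floor.  *Partial*:
anything in between, typically a thin chondrocyte layer at the top of the
scaffold whose density stays below the self-sustaining level.

:func:`find_critical` brackets the none/partial-to-full boundary in either
the seeded chondrocyte density n0 (linear bisection) or the exogenous dose
a0 (bisection in log10, since the boundary spans orders of magnitude), and
:func:`phase_sweep` maps the outcome over an (a0, n0) grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretisation import DENSITY_GUARD, Grid1D
from .integrator import SimulationResult, simulate
from .params import DimensionlessParameters
from .scenarios import ScenarioConfig, msc_support

__all__ = [
    "OutcomeClassification",
    "CriticalSearchResult",
    "ClassificationError",
    "BracketError",
    "yield_N",
    "classify_outcome",
    "find_critical",
    "phase_sweep",
    "YIELD_FLOOR_FRACTION",
    "CLASSIFY_GUARD",
]

#: "None" outcome: final yield below this fraction of the initial MSC number.
YIELD_FLOOR_FRACTION = 1e-4

#: MSC density above which a node counts as still occupied when testing the
#: terminal receptor-occupancy criterion.  Larger than the fraction-recovery
#: guard so that fully differentiated regions (m ~ e^-20) are not counted.
CLASSIFY_GUARD = 1e-6


class ClassificationError(RuntimeError):
    """Raised when an aborted simulation is classified."""


class BracketError(ValueError):
    """Raised when a critical search bracket does not straddle the boundary."""


@dataclass(frozen=True)
class OutcomeClassification:
    label: str  # none | partial | full
    N_final: float
    t90: float | None


@dataclass
class CriticalSearchResult:
    """Result of a bisection for a critical parameter value.

    ``evaluations`` logs every simulation as a dict with the parameter
    value, outcome label, N_final and t90, in evaluation order; the
    monotonicity of outcomes along the parameter axis is validated from it.
    """

    param_name: str
    bracket: tuple[float, float]
    critical_value: float
    tolerance: float
    achieved_tolerance: float
    log_scale: bool
    evaluations: list = field(default_factory=list)
    monotone: bool = True

    def evaluation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.evaluations)


def yield_N(state, support: tuple[float, float], grid: Grid1D) -> float:
    """Chondrocyte number per cross-sectional area: trapezoidal integral of
    the chondrocyte density over ``support`` (a sub-interval of the
    scaffold, normally the initial MSC region)."""
    lo, hi = support
    if lo < -1e-12 or hi > 1.0 + 1e-12 or hi < lo:
        raise ValueError(f"support {support} must be an interval within [0, 1]")
    mask = (grid.x >= lo - 1e-12) & (grid.x <= hi + 1e-12)
    return float(np.trapezoid(state.n[mask], grid.x[mask]))


def classify_outcome(
    result: SimulationResult,
    config: ScenarioConfig | None = None,
    yield_floor_fraction: float = YIELD_FLOOR_FRACTION,
    guard: float = CLASSIFY_GUARD,
) -> OutcomeClassification:
    """Classify a finished run as none / partial / full (see module docstring)."""
    if result.termination_reason == "aborted":
        raise ClassificationError(f"cannot classify aborted run: {result.diagnostic}")
    if config is None:
        config = result.config

    N_final = result.N_final
    if result.t90 is not None:
        return OutcomeClassification("full", N_final, result.t90)

    term = result.terminal_state
    remaining = term.m > guard
    if remaining.any() and np.all(term.f[remaining] >= result.params.fd):
        # every remaining MSC is past the commitment threshold
        return OutcomeClassification("full", N_final, None)

    floor = yield_floor_fraction * result.initial_msc_number
    if N_final < floor:
        return OutcomeClassification("none", N_final, None)
    return OutcomeClassification("partial", N_final, None)


_ORDER = {"none": 0, "partial": 1, "full": 2}


def _is_full(label: str) -> bool:
    return label == "full"


def find_critical(
    param_name: str,
    base_config: ScenarioConfig,
    bracket: tuple[float, float],
    tol: float,
    params: DimensionlessParameters | None = None,
) -> CriticalSearchResult:
    """Bisect for the critical value of ``n0`` or ``a0``.

    The lower bracket endpoint must classify non-full and the upper full.
    ``n0`` is bisected linearly to absolute tolerance ``tol``; ``a0`` is
    bisected in log10 until the bracket ratio is below ``1 + tol``
    (relative tolerance).  The returned critical value is the bracket
    midpoint (geometric mean for a0).  A non-monotone outcome sequence
    along the parameter axis attaches a warning and sets ``monotone=False``.
    """
    if param_name not in ("n0", "a0"):
        raise ValueError(f"param_name must be 'n0' or 'a0', got {param_name!r}")
    log_scale = param_name == "a0"
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 <= lo < hi):
        raise BracketError(f"invalid bracket {bracket}")
    if log_scale and lo <= 0:
        raise BracketError("a0 bracket must be strictly positive for log bisection")

    evaluations = []

    def classify_at(value):
        cfg = base_config.replace(**{param_name: value})
        outcome = classify_outcome(simulate(cfg, params=params))
        evaluations.append(
            {
                "value": value,
                "label": outcome.label,
                "N_final": outcome.N_final,
                "t90": outcome.t90,
            }
        )
        return outcome

    lo_out = classify_at(lo)
    hi_out = classify_at(hi)
    if _is_full(lo_out.label) or not _is_full(hi_out.label):
        raise BracketError(
            f"bracket endpoints must classify (non-full, full); got "
            f"({lo_out.label}, {hi_out.label}) at {param_name}=({lo}, {hi})"
        )

    def width(a, b):
        return b / a - 1.0 if log_scale else b - a

    while width(lo, hi) > tol:
        mid = math.sqrt(lo * hi) if log_scale else 0.5 * (lo + hi)
        if _is_full(classify_at(mid).label):
            hi = mid
        else:
            lo = mid

    critical = math.sqrt(lo * hi) if log_scale else 0.5 * (lo + hi)

    by_value = sorted(evaluations, key=lambda e: e["value"])
    ranks = [_ORDER[e["label"]] for e in by_value]
    monotone = all(a <= b for a, b in zip(ranks, ranks[1:]))
    if not monotone:
        warnings.warn(
            f"outcome not monotone in {param_name}; critical value unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    return CriticalSearchResult(
        param_name=param_name,
        bracket=(lo, hi),
        critical_value=critical,
        tolerance=tol,
        achieved_tolerance=width(lo, hi),
        log_scale=log_scale,
        evaluations=evaluations,
        monotone=monotone,
    )


def phase_sweep(
    a0_values,
    n0_values,
    base_config: ScenarioConfig,
    params: DimensionlessParameters | None = None,
) -> pd.DataFrame:
    """Classify one simulation per (a0, n0) pair.

    Returns a tidy frame with columns (a0, n0, d, label, N_final, t90);
    aborted runs are recorded with label 'aborted' and the sweep continues.
    """
    a0_values = list(a0_values)
    n0_values = list(n0_values)
    if not a0_values or not n0_values:
        raise ValueError("value lists must be non-empty")
    if min(a0_values) < 0 or min(n0_values) < 0:
        raise ValueError("a0 and n0 values must be non-negative")

    rows = []
    for n0 in n0_values:
        for a0 in a0_values:
            cfg = base_config.replace(n0=n0, a0=a0)
            res = simulate(cfg, params=params)
            if res.termination_reason == "aborted":
                rows.append(
                    {
                        "a0": a0,
                        "n0": n0,
                        "d": cfg.d,
                        "label": "aborted",
                        "N_final": np.nan,
                        "t90": np.nan,
                    }
                )
                continue
            out = classify_outcome(res)
            rows.append(
                {
                    "a0": a0,
                    "n0": n0,
                    "d": cfg.d,
                    "label": out.label,
                    "N_final": out.N_final,
                    "t90": out.t90 if out.t90 is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
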
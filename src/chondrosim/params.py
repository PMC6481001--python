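"""Model parameters and non-dimensionalisation.

The model is formulated dimensionally (rates per minute, concentrations in
ng/mL, cell densities in millions of cells per mL, lengths in metres) and
solved in dimensionless form.  Concentrations are scaled by ``A0``, cell
densities by ``M0``, lengths by the scaffold height ``L`` and time by the
MSC-to-chondrocyte differentiation rate ``Lambda1`` (so one dimensionless
time unit is ``1/Lambda1`` minutes).

:class:`DimensionalParameters` holds the laboratory-unit rate constants,
:class:`Scales` the scaling constants, and :func:`nondimensionalise` maps the
two onto the :class:`DimensionlessParameters` consumed by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = [
    "DimensionalParameters",
    "Scales",
    "DimensionlessParameters",
    "default_parameters",
    "default_scales",
    "nondimensionalise",
    "dimensional_time",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter value violates its physical constraints."""


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0):
            raise ParameterError(
                f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}"
            )


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional rate constants, capacities and diffusivities.

    Attributes
    ----------
    Lambda1 : float
        MSC-to-chondrocyte differentiation rate once the receptor-occupancy
        threshold is exceeded (per minute).
    fd : float
        Receptor-occupancy fraction above which an MSC commits to
        differentiation (dimensionless, in (0, 1)).
    lambda3 : float
        Constitutive secretion rate of latent TGF-beta by chondrocytes
        (ng per minute per Mio cells).
    lambda4 : float
        Binding rate of unbound latent TGF-beta to the hydrogel/ECM
        (per minute; matrix density is absorbed into this constant).
    lambda5 : float
        Natural decay rate of unbound latent TGF-beta (per minute).
    lambda6 : float
        Chemical activation rate of matrix-bound TGF-beta (per minute).
    lambda7 : float
        Natural decay rate of matrix-bound latent TGF-beta (per minute).
    lambda8 : float
        Decay rate of unbound active TGF-beta (per minute); the fast
        timescale of the model.
    lambda_m9, lambda_n9 : float
        Binding rates of active TGF-beta to MSC and chondrocyte surface
        receptors (per minute per (ng/mL)).
    lambda_m10, lambda_n10 : float
        Internalisation rates of receptor-bound TGF-beta (per minute).
    Ftot, Gtot : float
        Maximum mass of TGF-beta that can be receptor-bound per MSC /
        chondrocyte (ng per Mio cells).
    Dc, Da : float
        Diffusivities of unbound latent and active TGF-beta (m^2 per minute).
    """

    Lambda1: float
    fd: float
    lambda3: float
    lambda4: float
    lambda5: float
    lambda6: float
    lambda7: float
    lambda8: float
    lambda_m9: float
    lambda_n9: float
    lambda_m10: float
    lambda_n10: float
    Ftot: float
    Gtot: float
    Dc: float
    Da: float

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self) if f.name != "fd"])
        if not (0.0 < self.fd < 1.0):
            raise ParameterError(f"fd must lie in (0, 1), got {self.fd!r}")

    def replace(self, **changes) -> "DimensionalParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class Scales:
    """Scaling constants used to non-dimensionalise the model.

    ``A0`` scales TGF-beta concentrations (ng/mL), ``M0`` cell densities
    (Mio/mL) and ``L`` lengths (m); the time scale is ``1/Lambda1`` and is
    carried by :class:`DimensionalParameters`.
    """

    A0: float = 1.0
    M0: float = 1.0
    L: float = 2.4e-3

    def __post_init__(self):
        _require_positive(self, ("A0", "M0", "L"))


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless parameters of the solved system.

    ``lt*`` are tilde parameters (rates scaled by the differentiation rate),
    ``lh*`` hat parameters (receptor-binding rates scaled for the occupancy
    equations), ``Dtc``/``Dta`` dimensionless diffusivities and ``fd`` the
    differentiation threshold carried through unchanged.
    """

    lt3: float
    lt4: float
    lt5: float
    lt6: float
    lt7: float
    lt8: float
    ltm9: float
    ltn9: float
    lhm9: float
    lhn9: float
    ltm10: float
    ltn10: float
    Dtc: float
    Dta: float
    fd: float

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self) if f.name != "fd"])
        if not (0.0 < self.fd < 1.0):
            raise ParameterError(f"fd must lie in (0, 1), got {self.fd!r}")


def default_parameters() -> DimensionalParameters:
    """Return the reference dimensional parameter set.

    Values are representative estimates for TGF-beta mediated chondrogenesis
    of human MSCs in a hydrogel construct, drawn from in vitro measurements
    and earlier modelling of related systems.
    """
    return DimensionalParameters(
        Lambda1=6e-3,       # /min
        fd=0.01,
        lambda3=1.094e-1,   # ng/(min Mio)
        lambda4=1e-1,       # /min
        lambda5=6e-3,       # /min
        lambda6=6e-2,       # /min
        lambda7=6e-3,       # /min
        lambda8=0.258,      # /min
        lambda_m9=6e-2,     # /(min ng/mL)
        lambda_n9=6e-2,     # /(min ng/mL)
        lambda_m10=0.25,    # /min
        lambda_n10=0.25,    # /min
        Ftot=6.23e-1,       # ng/Mio
        Gtot=6.23e-1,       # ng/Mio
        Dc=1.278e-9,        # m^2/min
        Da=1.278e-9,        # m^2/min
    )


def default_scales() -> Scales:
    """Return the reference scaling constants (A0=1 ng/mL, M0=1 Mio/mL, L=2.4 mm)."""
    return Scales()


def nondimensionalise(
    dim: DimensionalParameters, scales: Scales | None = None
) -> DimensionlessParameters:
    """Map dimensional parameters onto the dimensionless set used by the solver.

    Rates are scaled by the differentiation rate ``Lambda1``, the secretion
    rate additionally by ``M0/A0``, the receptor-binding rates by ``A0``
    (hat form, driving receptor occupancy) and by ``M0*Ftot`` resp.
    ``M0*Gtot`` (tilde form, depleting free active TGF-beta), and the
    diffusivities by ``Lambda1*L^2``.
    """
    s = scales if scales is not None else Scales()
    L1 = dim.Lambda1
    return DimensionlessParameters(
        lt3=s.M0 * dim.lambda3 / (s.A0 * L1),
        lt4=dim.lambda4 / L1,
        lt5=dim.lambda5 / L1,
        lt6=dim.lambda6 / L1,
        lt7=dim.lambda7 / L1,
        lt8=dim.lambda8 / L1,
        ltm9=s.M0 * dim.Ftot * dim.lambda_m9 / L1,
        ltn9=s.M0 * dim.Gtot * dim.lambda_n9 / L1,
        lhm9=s.A0 * dim.lambda_m9 / L1,
        lhn9=s.A0 * dim.lambda_n9 / L1,
        ltm10=dim.lambda_m10 / L1,
        ltn10=dim.lambda_n10 / L1,
        Dtc=dim.Dc / (L1 * s.L**2),
        Dta=dim.Da / (L1 * s.L**2),
        fd=dim.fd,
    )


def dimensional_time(t_star: float, dim: DimensionalParameters) -> float:
    """Convert dimensionless time to hours.

    One dimensionless time unit equals ``1/Lambda1`` minutes (about 2.78 h
    at the default differentiation rate).
    """
    import numpy as np

    if np.any(np.asarray(t_star) < 0):
        raise ParameterError(f"t_star must be non-negative, got {t_star!r}")
    return t_star / dim.Lambda1 / 60.0
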
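"""Thermal state and conversions between free energy and redox potential.

Internal energy unit is kJ/mol (the convention of the MD toolchain that
produces the upstream energies); redox potentials are reported in mV.
The reduction free energy and the midpoint potential are related by
``ΔG = −n F E`` for an n-electron reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InvalidParameterError

#: Boltzmann (= molar gas) constant, kJ mol^-1 K^-1.
BOLTZMANN_KJ_PER_MOL_K = 0.008314462618

#: Faraday constant, 96485.3 C mol^-1, expressed as kJ mol^-1 V^-1.
FARADAY_KJ_PER_MOL_V = 96.4853

#: Faraday constant per millivolt, kJ mol^-1 mV^-1.
FARADAY_KJ_PER_MOL_MV = FARADAY_KJ_PER_MOL_V / 1000.0


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature defining Boltzmann factors.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin; must be positive.

    Attributes
    ----------
    beta
        Inverse temperature 1/(k_B T) in mol/kJ.
    """

    temperature: float
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature!r}"
            )
        object.__setattr__(
            self, "beta", 1.0 / (BOLTZMANN_KJ_PER_MOL_K * self.temperature)
        )

    @property
    def kbt(self) -> float:
        """Thermal energy k_B T in kJ/mol."""
        return 1.0 / self.beta


def make_thermo(temperature: float = 298.0) -> ThermoState:
    """Build a :class:`ThermoState` for ``temperature`` (kelvin, default 298)."""
    return ThermoState(temperature=float(temperature))


@dataclass(frozen=True)
class RedoxEstimate:
    """A redox potential in mV with its standard error and provenance.

    ``method`` records which free-energy estimator produced it; the
    forward/backward counts are the work-sample sizes it was built from.
    """

    potential: float
    std_error: float | None
    method: str
    n_forward: int = 0
    n_backward: int = 0

    def __post_init__(self) -> None:
        if self.std_error is not None and self.std_error < 0:
            raise InvalidParameterError("std_error must be >= 0")


def delta_g_to_potential(
    delta_g: float,
    std_error: float | None = 0.0,
    n_electrons: int = 1,
    method: str = "",
    n_forward: int = 0,
    n_backward: int = 0,
) -> RedoxEstimate:
    """Convert a reduction free energy (kJ/mol) to a redox potential (mV).

    Uses ``E = −ΔG / (n F)`` with F = 96.4853 kJ mol^-1 V^-1.  The standard
    error is scaled by the same positive factor 1/(n F).

    Raises
    ------
    InvalidParameterError
        If ``n_electrons < 1`` or ``std_error < 0``.
    """
    if n_electrons < 1:
        raise InvalidParameterError(f"n_electrons must be >= 1, got {n_electrons}")
    if std_error is not None and std_error < 0:
        raise InvalidParameterError("std_error must be >= 0")
    scale = 1.0 / (n_electrons * FARADAY_KJ_PER_MOL_MV)
    err = None if std_error is None else std_error * scale
    return RedoxEstimate(
        potential=-delta_g * scale,
        std_error=err,
        method=method,
        n_forward=n_forward,
        n_backward=n_backward,
    )


def potential_to_delta_g(potential_mv: float, n_electrons: int = 1) -> float:
    """Inverse of :func:`delta_g_to_potential`: mV back to kJ/mol."""
    if n_electrons < 1:
        raise InvalidParameterError(f"n_electrons must be >= 1, got {n_electrons}")
    return -potential_mv * n_electrons * FARADAY_KJ_PER_MOL_MV
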
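"""Hydrogel-equivalent elastic modulus of the suspended carbon film.

A vertical point load on an elastic half-space of modulus ``E`` and
Poisson ratio ``ν``, applied over an adhesion radius ``α``, behaves as a
linear spring of stiffness

    k = π α E / ((1 − ν)(1 + ν))

The film spring constant measured by AFM can therefore be expressed as
the modulus of a homogeneous gel that would feel the same to a cell
pulling vertically on it.  ``E`` is linear in ``k``, so the standard
deviation propagates by exact scaling, not by linearization error.

Internally everything is SI (Pa, m, N/m); the ``*_kpa_um`` helpers take
and return the kPa/µm units practitioners quote, preventing the unit
slips this formula invites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HalfSpaceModel",
    "spring_from_modulus",
    "modulus_from_spring",
    "propagate_sd",
    "modulus_interval",
    "spring_from_modulus_kpa_um",
    "modulus_from_spring_kpa_um",
    "propagate_sd_kpa_um",
]


def _check_params(nu: float, alpha: float) -> None:
    if abs(nu) >= 1.0:
        raise ValueError("Poisson ratio with |nu| >= 1 makes the half-space relation singular")
    if alpha <= 0:
        raise ValueError("adhesion radius alpha must be positive")


def spring_from_modulus(E_gel: float, nu: float, alpha: float) -> float:
    """Spring constant (N/m) of a half-space gel: k = π α E / ((1−ν)(1+ν)).

    Parameters: ``E_gel`` in Pa, ``nu`` dimensionless, ``alpha`` in m.
    """
    _check_params(nu, alpha)
    if E_gel < 0:
        raise ValueError("elastic modulus must be non-negative")
    return float(np.pi * alpha * E_gel / ((1.0 - nu) * (1.0 + nu)))


def modulus_from_spring(k: float, nu: float, alpha: float) -> float:
    """Exact inverse of :func:`spring_from_modulus`: E = k(1−ν)(1+ν)/(πα), in Pa."""
    _check_params(nu, alpha)
    if k < 0:
        raise ValueError("spring constant must be non-negative")
    return float(k * (1.0 - nu) * (1.0 + nu) / (np.pi * alpha))


def propagate_sd(sd_k: float, nu: float, alpha: float) -> float:
    """Standard deviation of E from the sd of k (Pa from N/m).

    E is linear in k, so sd_E = sd_k (1−ν)(1+ν)/(πα) exactly.
    """
    if sd_k < 0:
        raise ValueError("sd_k must be non-negative")
    return modulus_from_spring(sd_k, nu, alpha)


def modulus_interval(mean_E: float, sd_E: float) -> tuple[float, float]:
    """Mean ± 1 sd interval (same units in as out)."""
    if sd_E < 0:
        raise ValueError("sd_E must be non-negative")
    return (mean_E - sd_E, mean_E + sd_E)


# ---------------------------------------------------------------- unit layer

_KPA = 1e3  # Pa per kPa
_UM = 1e-6  # m per µm


def spring_from_modulus_kpa_um(E_kpa: float, nu: float, alpha_um: float) -> float:
    """As :func:`spring_from_modulus` with E in kPa and α in µm; returns N/m."""
    return spring_from_modulus(E_kpa * _KPA, nu, alpha_um * _UM)


def modulus_from_spring_kpa_um(k: float, nu: float, alpha_um: float) -> float:
    """As :func:`modulus_from_spring` with α in µm; returns kPa."""
    return modulus_from_spring(k, nu, alpha_um * _UM) / _KPA


def propagate_sd_kpa_um(sd_k: float, nu: float, alpha_um: float) -> float:
    """As :func:`propagate_sd` with α in µm; returns kPa."""
    return propagate_sd(sd_k, nu, alpha_um * _UM) / _KPA


@dataclass
class HalfSpaceModel:
    """Measured spring constant mapped onto the half-space gel model.

    ``nu`` and ``alpha_um`` are literature-derived assumptions, held as
    configuration (defaults 0.48 and 1 µm), never baked into the math.
    """

    k: float  # N/m
    sd_k: float = 0.0  # N/m
    nu: float = 0.48
    alpha_um: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.sd_k < 0:
            raise ValueError("k and sd_k must be non-negative")
        _check_params(self.nu, self.alpha_um * _UM)
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio outside [0, 0.5] is unphysical for a gel")

    @property
    def E_kpa(self) -> float:
        return modulus_from_spring_kpa_um(self.k, self.nu, self.alpha_um)

    @property
    def sd_E_kpa(self) -> float:
        return propagate_sd_kpa_um(self.sd_k, self.nu, self.alpha_um)

    @property
    def interval_kpa(self) -> tuple[float, float]:
        return modulus_interval(self.E_kpa, self.sd_E_kpa)

    def to_dict(self) -> dict:
        lo, hi = self.interval_kpa
        return {
            "k_Nm": self.k,
            "sd_k_Nm": self.sd_k,
            "nu": self.nu,
            "alpha_um": self.alpha_um,
            "E_kPa": self.E_kpa,
            "sd_E_kPa": self.sd_E_kpa,
            "interval_kPa": [lo, hi],
        }
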
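"""Synthetic AFM approach curves from a two-spring contact model.

Past contact the cantilever (stiffness ``k_c``) and the suspended carbon
film (stiffness ``k_f``) deform as elastic springs in series: for a piezo
extension ``z`` beyond the contact point,

    d_c  = z * k_f / (k_c + k_f)      (cantilever deflection)
    δ_f  = z * k_c / (k_c + k_f)      (film deformation)

so that ``d_c + δ_f = z`` and ``k_c·d_c = k_f·δ_f`` hold sample-wise.
Measurement noise (Gaussian plus mains-harmonic sinusoids) is added on
the deflection channel only, which is where the photodiode noise lives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..types import ForceCurve

__all__ = ["GeneratorConfig", "gen_force_curve", "gen_calibration_curve"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic force-curve generator.

    Defaults reflect the acquisition conditions the package targets:
    a 0.251 N/m cantilever with 25.97 nm/V optical lever sensitivity,
    100 nm approach ramps at 100 or 1000 nm/s, and ambient periodic
    noise at ~60 and ~300 Hz.

    Attributes
    ----------
    seed : int
        RNG seed; identical configs produce byte-identical records.
    sampling_rate : float
        Samples per second.  2 kHz default resolves the 300 Hz harmonic
        with Nyquist margin.
    loading_rate : float
        Piezo speed in nm/s.
    ramp_length : float
        Total piezo travel of the approach in nm.
    cantilever_k : float
        Cantilever spring constant ``k_c`` in N/m.
    film_k : float
        Film spring constant ``k_f`` in N/m; ``math.inf`` simulates a
        rigid substrate (glass).
    sensitivity : float
        Optical lever sensitivity ``S`` in nm/V, used when emitting a
        photodiode-volt channel.
    noise_sd : float
        Gaussian noise standard deviation on the deflection, nm.
    periodic_noise : list of (frequency Hz, amplitude nm)
        Sinusoidal interference components, random phase per component.
    baseline_fraction : float
        Fraction of the ramp spent out of contact before the surface is
        reached (pre-contact baseline).
    """

    seed: int = 0
    sampling_rate: float = 2000.0
    loading_rate: float = 100.0
    ramp_length: float = 100.0
    cantilever_k: float = 0.251
    film_k: float = 0.85
    sensitivity: float = 25.97
    noise_sd: float = 0.0
    periodic_noise: list[tuple[float, float]] = field(
        default_factory=lambda: [(60.0, 0.2), (300.0, 0.1)]
    )
    baseline_fraction: float = 0.2

    def validate(self) -> None:
        if self.cantilever_k <= 0:
            raise ValueError("cantilever_k must be positive")
        if not (self.film_k > 0):  # inf allowed
            raise ValueError("film_k must be positive (inf = rigid substrate)")
        if self.sampling_rate <= 0 or self.loading_rate <= 0 or self.ramp_length <= 0:
            raise ValueError("sampling_rate, loading_rate and ramp_length must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.baseline_fraction < 1.0:
            raise ValueError("baseline_fraction must lie in (0, 1)")
        for f, a in self.periodic_noise:
            if f <= 0 or a < 0:
                raise ValueError("periodic noise needs positive frequency, non-negative amplitude")
            if self.sampling_rate <= 2.0 * f:
                raise ValueError(
                    f"aliased periodic noise: component at {f} Hz requires a "
                    f"sampling rate above {2 * f} Hz (configured {self.sampling_rate} Hz)"
                )


def _simulate(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Return (time, piezo, noisy deflection, true contact index)."""
    cfg.validate()
    n = max(int(round(cfg.ramp_length / cfg.loading_rate * cfg.sampling_rate)), 10)
    time = np.arange(n) / cfg.sampling_rate
    piezo = cfg.loading_rate * time
    z_contact = cfg.baseline_fraction * cfg.ramp_length

    indent = np.clip(piezo - z_contact, 0.0, None)
    if math.isinf(cfg.film_k):
        deflection = indent.copy()
    else:
        deflection = indent * cfg.film_k / (cfg.cantilever_k + cfg.film_k)

    rng = np.random.default_rng(cfg.seed)
    noise = np.zeros(n)
    for f, a in cfg.periodic_noise:
        if a > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            noise += a * np.sin(2.0 * np.pi * f * time + phase)
    if cfg.noise_sd > 0:
        noise += rng.normal(0.0, cfg.noise_sd, size=n)

    contact_index = int(np.searchsorted(piezo, z_contact, side="right"))
    return time, piezo, deflection + noise, contact_index


def gen_force_curve(cfg: GeneratorConfig, square_id: str | None = None) -> ForceCurve:
    """Simulate one approach curve on a compliant film, deflection in nm.

    The returned curve's ``meta`` carries the ground truth
    (``contact_index``, ``film_k``, ``cantilever_k``, ``z_contact``).
    """
    time, piezo, deflection, contact_index = _simulate(cfg)
    return ForceCurve(
        time=time,
        piezo=piezo,
        deflection=deflection,
        loading_rate=cfg.loading_rate,
        square_id=square_id,
        meta={
            "contact_index": contact_index,
            "z_contact": cfg.baseline_fraction * cfg.ramp_length,
            "film_k": cfg.film_k,
            "cantilever_k": cfg.cantilever_k,
            "synthetic": True,
        },
    )


def gen_calibration_curve(cfg: GeneratorConfig, square_id: str | None = None) -> ForceCurve:
    """Simulate a force scan against glass, reported in photodiode volts.

    The substrate is rigid regardless of ``cfg.film_k``, so past contact
    the cantilever deflects one-for-one with the piezo and
    ``signal_V = deflection_nm / S``.
    """
    rigid = GeneratorConfig(**{**cfg.__dict__, "film_k": math.inf})
    time, piezo, deflection, contact_index = _simulate(rigid)
    return ForceCurve(
        time=time,
        piezo=piezo,
        signal=deflection / cfg.sensitivity,
        loading_rate=cfg.loading_rate,
        square_id=square_id,
        meta={
            "contact_index": contact_index,
            "z_contact": cfg.baseline_fraction * cfg.ramp_length,
            "sensitivity": cfg.sensitivity,
            "cantilever_k": cfg.cantilever_k,
            "synthetic": True,
            "rigid_substrate": True,
        },
    )
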
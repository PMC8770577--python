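"""Standing-surface-acoustic-wave (SSAW) sorting physics.

Cells in the sorting region are deflected by the acoustic radiation force of
a standing wave excited on a piezoelectric substrate by interdigital
transducers.  The force on a small compressible sphere in a 1-D standing
pressure wave is

    F(x) = -(pi * p0^2 * V_c * beta_w / (2 * lambda)) * phi * sin(2 k x)

with acoustic contrast factor

    phi = (5 rho_c - 2 rho_w) / (2 rho_c + rho_w) - beta_c / beta_w.

phi > 0 (denser, less compressible than the medium) means the particle is
node-seeking; the maximum translocation achievable by a single standing wave
is a quarter wavelength.

``x`` is measured from a pressure node (documented convention; the origin is
otherwise arbitrary up to a half-wavelength shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SSAWParams",
    "AcousticMedium",
    "wavelength_um",
    "max_translocation_um",
    "contrast_factor",
    "radiation_force",
    "force_profile",
]

#: Surface sound speed of 128deg Y-cut lithium niobate, m/s.
DEFAULT_SOUND_SPEED = 3978.2
#: IDT excitation frequency, Hz (70 um electrode-finger pitch).
DEFAULT_FREQUENCY = 55.23e6


def wavelength_um(sound_speed: float = DEFAULT_SOUND_SPEED,
                  frequency: float = DEFAULT_FREQUENCY) -> float:
    """Standing-wave wavelength lambda = v / f, returned in micrometres.

    Parameters are in SI units (m/s, Hz).  For the default substrate and
    excitation this is 72.03 um.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    return sound_speed / frequency * 1e6


def max_translocation_um(wavelength: float) -> float:
    """Maximum lateral displacement of an object by one SSAW: lambda/4 (um)."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    return wavelength / 4.0


@dataclass(frozen=True)
class SSAWParams:
    """Substrate/excitation parameters of the standing wave.

    ``wavelength_m`` and ``wavenumber`` are derived (lambda = v/f, k = 2 pi/lambda).
    ``acoustic_pressure`` p0 is setup-dependent and has no canonical value;
    force magnitudes are therefore demonstrative unless p0 is calibrated.
    """

    sound_speed: float = DEFAULT_SOUND_SPEED    # m/s
    frequency: float = DEFAULT_FREQUENCY        # Hz
    acoustic_pressure: float = 1e5              # Pa

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.sound_speed <= 0:
            raise ValueError("sound speed and frequency must be positive")
        if self.acoustic_pressure < 0:
            raise ValueError("acoustic pressure must be non-negative")

    @property
    def wavelength_m(self) -> float:
        return self.sound_speed / self.frequency

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_m * 1e6

    @property
    def wavenumber(self) -> float:
        """k = 2 pi / lambda, in 1/m."""
        return 2.0 * math.pi / self.wavelength_m


@dataclass(frozen=True)
class AcousticMedium:
    """Fluid and cell material properties entering the contrast factor.

    Compressibilities in 1/Pa, densities in kg/m^3, cell volume in m^3.
    Defaults: water-like medium (beta_w ~ 4.5 GPa^-1, rho_w = 1000) and a
    typical cell (beta_c ~ 4 GPa^-1, rho_c = 1050, 10 um diameter).
    """

    fluid_compressibility: float = 4.5e-10
    cell_compressibility: float = 4.0e-10
    fluid_density: float = 1000.0
    cell_density: float = 1050.0
    cell_volume: float = field(default=4.0 / 3.0 * math.pi * (5e-6) ** 3)

    def __post_init__(self) -> None:
        for name in ("fluid_compressibility", "cell_compressibility",
                     "fluid_density", "cell_density", "cell_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def contrast_factor(medium: AcousticMedium) -> float:
    """Acoustic contrast factor phi(beta, rho).

    phi = (5 rho_c - 2 rho_w)/(2 rho_c + rho_w) - beta_c/beta_w.
    Positive phi -> node-seeking particle (pushed toward pressure nodes),
    negative phi -> antinode-seeking.  Matched media give exactly 0.
    """
    rho_c, rho_w = medium.cell_density, medium.fluid_density
    density_term = (5.0 * rho_c - 2.0 * rho_w) / (2.0 * rho_c + rho_w)
    return density_term - medium.cell_compressibility / medium.fluid_compressibility


def radiation_force(params: SSAWParams, medium: AcousticMedium,
                    x: float | np.ndarray) -> float | np.ndarray:
    """Acoustic radiation force (N) on a cell at position x (m) from a node.

    F = -(pi p0^2 V_c beta_w / (2 lambda)) phi sin(2 k x).  The sign makes a
    node-seeking cell (phi > 0) experience a restoring force toward x = 0:
    lambda/2-periodic, odd around each node, zero at nodes and antinodes.
    """
    lam = params.wavelength_m
    amplitude = (math.pi * params.acoustic_pressure ** 2 * medium.cell_volume
                 * medium.fluid_compressibility) / (2.0 * lam)
    return -amplitude * contrast_factor(medium) * np.sin(2.0 * params.wavenumber * np.asarray(x))


def force_profile(params: SSAWParams, medium: AcousticMedium,
                  n_points: int = 101) -> pd.DataFrame:
    """Tabulate the radiation force over one wavelength from a pressure node.

    Returns a DataFrame with columns ``x_um`` and ``force_N``.
    """
    lam = params.wavelength_m
    x = np.linspace(0.0, lam, n_points)
    return pd.DataFrame({
        "x_um": x * 1e6,
        "force_N": radiation_force(params, medium, x),
    })
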
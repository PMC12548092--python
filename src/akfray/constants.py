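"""Physical constants for amide 15N relaxation.

Gyromagnetic ratios are CODATA values; the 15N ratio is negative, which is
what makes the heteronuclear NOE of mobile amides go negative. The N-H bond
length and 15N CSA defaults are the values conventionally used for backbone
amides (1.02 A, -160 ppm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MU0 = 1.25663706212e-6  # T^2 m^3 J^-1 (vacuum permeability)
HBAR = 1.054571817e-34  # J s
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1 (1H)
GAMMA_N = -2.7126189e7  # rad s^-1 T^-1 (15N; negative)


@dataclass(frozen=True)
class PhysicalConstants:
    """Spin-interaction constants for one field strength.

    Parameters
    ----------
    field_mhz : 1H Larmor frequency in MHz.
    r_nh : N-H internuclear distance in Angstrom.
    csa_ppm : 15N chemical-shift anisotropy (Delta sigma) in ppm.
    """

    field_mhz: float
    r_nh: float = 1.02
    csa_ppm: float = -160.0

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")
        if self.r_nh <= 0:
            raise ValueError("r_nh must be positive")

    @property
    def omega_h(self) -> float:
        """1H angular frequency, rad/s (magnitude)."""
        return 2.0 * math.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency, rad/s (magnitude)."""
        return self.omega_h * abs(GAMMA_N) / GAMMA_H

    @property
    def d2(self) -> float:
        """Squared dipolar coupling constant (mu0 hbar gH gN / 4 pi r^3)^2, rad^2/s^2."""
        r_m = self.r_nh * 1e-10
        d = MU0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4.0 * math.pi * r_m**3)
        return d * d

    @property
    def c2(self) -> float:
        """Squared CSA coupling constant (omega_N * Delta_sigma)^2 / 3, rad^2/s^2."""
        return (self.omega_n * self.csa_ppm * 1e-6) ** 2 / 3.0
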
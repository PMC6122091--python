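"""Physical constants and the molar-CD conversion prefactor.

The central quantity is the prefactor ``a`` that converts a sum of
energy-weighted rotatory strengths into molar circular dichroism,

    Delta_eps(E) = 4a * sum_n R_n * E_n * sigma_n(E),

with Delta_eps in M^-1 cm^-1, R_n the length-gauge rotatory strength in
cgs units (erg esu cm / Gauss), E_n the excitation energy in eV and
sigma_n a Gaussian normalized in energy (eV^-1).  In cgs,

    a = 8 pi^3 N_A / (3 * 10^3 * ln(10) * h * c),

so that 4a = 1 / (2.2965e-39), the conversion constant familiar from the
chiroptical post-processing literature.  ``a`` is derived here from the
CODATA-2018 constants rather than hard-coded, so the unit chain is
auditable in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: CODATA-2018 exact defining values.
AVOGADRO = 6.02214076e23  # mol^-1
PLANCK_J_S = 6.62607015e-34  # J s
LIGHTSPEED_CM_S = 2.99792458e10  # cm s^-1

#: Energy <-> wavelength conversion, hc in eV nm (CODATA).
HC_EV_NM = 1239.841984

_ERG_PER_JOULE = 1.0e7


def _derive_prefactor(avogadro: float, planck: float, lightspeed: float) -> float:
    """a = 8 pi^3 N_A / (3e3 ln10 h c) with h converted J s -> erg s."""
    h_erg = planck * _ERG_PER_JOULE
    return 8.0 * math.pi**3 * avogadro / (3.0e3 * math.log(10.0) * h_erg * lightspeed)


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the stick-to-spectrum conversion.

    ``prefactor_a`` is always computed from the other three fields in
    ``__post_init__``; passing it explicitly is not supported.  The
    ``derivation`` string records the closed form actually evaluated.
    """

    avogadro: float = AVOGADRO  # mol^-1
    planck: float = PLANCK_J_S  # J s
    lightspeed: float = LIGHTSPEED_CM_S  # cm s^-1
    prefactor_a: float = field(init=False)
    derivation: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = _derive_prefactor(self.avogadro, self.planck, self.lightspeed)
        object.__setattr__(self, "prefactor_a", a)
        object.__setattr__(
            self,
            "derivation",
            "a = 8*pi^3*N_A / (3e3*ln(10)*h*c) [cgs: h in erg s, c in cm/s]; "
            f"N_A={self.avogadro!r} mol^-1, h={self.planck!r} J s, "
            f"c={self.lightspeed!r} cm/s -> a={a!r}; "
            "equivalently 1/(4a) = 2.2965e-39, the standard cgs "
            "rotatory-strength -> molar-CD conversion constant",
        )


#: Module-level default constants object.
CODATA2018 = PhysicalConstants()


def prefactor(constants: PhysicalConstants = CODATA2018) -> float:
    """Return the molar-CD prefactor ``a`` (cgs) for the given constants."""
    return constants.prefactor_a


def ev_to_nm(energy_ev):
    """Convert photon energy in eV to vacuum wavelength in nm."""
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm):
    """Convert vacuum wavelength in nm to photon energy in eV."""
    return HC_EV_NM / wavelength_nm
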
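"""Broaden a three-state stick spectrum into a molar-CD curve.

A TDDFT calculation reports excitation energies (eV) and length-gauge
rotatory strengths (1e-40 cgs).  Gaussian broadening with half-width
sigma (eV) turns these sticks into the continuous Delta_eps curve that
is compared with a measured ECD spectrum.
"""

import numpy as np

import ecdkit as ek

stick = ek.StickSpectrum(
    [
        ek.ExcitedState(1, energy=4.5, rotatory_strength=+8.0),
        ek.ExcitedState(2, energy=5.2, rotatory_strength=-15.0),
        ek.ExcitedState(3, energy=6.0, rotatory_strength=-10.0),
    ],
    label="demo",
)
spec = ek.convolve(stick, ek.BroadeningConfig(sigma=0.3))

i_min, i_max = np.argmin(spec.values), np.argmax(spec.values)
print(f"grid: {spec.grid[0]:.0f}-{spec.grid[-1]:.0f} nm, {len(spec)} points")
print(f"most negative: {spec.values[i_min]:+.3f} M^-1 cm^-1 at {spec.grid[i_min]:.1f} nm")
print(f"most positive: {spec.values[i_max]:+.3f} M^-1 cm^-1 at {spec.grid[i_max]:.1f} nm")
print("The negative extremum sits between the two negative sticks (238/207 nm);")
print("the positive lobe comes from the +8 stick near 276 nm.")
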
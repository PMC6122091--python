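"""Stick spectra, Gaussian broadening and the molar-CD convolution.

A TDDFT excited-state calculation yields a *stick spectrum*: one
(excitation energy, rotatory strength) pair per state.  Broadening each
stick with a normalized Gaussian of half-width ``sigma`` (in eV) and
weighting by the excitation energy produces the continuous molar
circular dichroism curve

    Delta_eps(E) = 4a * sum_n R_n * E_n * sigma_n(E),

evaluated here on a wavelength grid (nm) via E = hc/lambda.  All
arithmetic is done in energy space; wavelengths appear only on the
output axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import CODATA2018, HC_EV_NM, PhysicalConstants


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its domain."""


class InvalidStateError(ValueError):
    """Raised when an excited state carries unusable data."""


@dataclass(frozen=True)
class ExcitedState:
    """A single electronic transition.

    Parameters
    ----------
    index : int
        1-based state number from the upstream calculation.
    energy : float
        Excitation energy E_n in eV; must be positive.
    rotatory_strength : float
        Length-gauge R_n in units of 1e-40 cgs (erg esu cm / Gauss).
    oscillator_strength : float, optional
        Dimensionless f; carried through but not used for CD.
    """

    index: int
    energy: float
    rotatory_strength: float
    oscillator_strength: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidStateError(f"state index must be >= 1, got {self.index}")
        if not (self.energy > 0):
            raise InvalidStateError(
                f"state {self.index}: excitation energy must be > 0 eV, "
                f"got {self.energy}"
            )
        if not math.isfinite(self.rotatory_strength):
            raise InvalidStateError(
                f"state {self.index}: rotatory strength is not finite "
                f"({self.rotatory_strength})"
            )

    @property
    def wavelength(self) -> float:
        """Transition wavelength in nm, derived from the energy."""
        return HC_EV_NM / self.energy


@dataclass
class StickSpectrum:
    """An ordered collection of excited states from one calculation.

    States are normalized to ascending energy order on construction;
    duplicate state indices are rejected.
    """

    states: list[ExcitedState]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = sorted(self.states, key=lambda s: s.energy)
        indices = [s.index for s in self.states]
        if len(set(indices)) != len(indices):
            seen, dupes = set(), set()
            for i in indices:
                (dupes if i in seen else seen).add(i)
            raise InvalidStateError(f"duplicate state indices: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states], dtype=float)

    @property
    def rotatory_strengths(self) -> np.ndarray:
        return np.array([s.rotatory_strength for s in self.states], dtype=float)

    def scaled(self, factor: float) -> "StickSpectrum":
        """Return a copy with every rotatory strength multiplied by *factor*."""
        return StickSpectrum(
            states=[
                ExcitedState(s.index, s.energy, s.rotatory_strength * factor,
                             s.oscillator_strength)
                for s in self.states
            ],
            label=self.label,
            metadata=dict(self.metadata),
        )


EnergyWeighting = Literal["per_state_energy", "incident_energy"]


@dataclass(frozen=True)
class BroadeningConfig:
    """Lineshape width and output grid for the convolution.

    sigma : Gaussian half-width in eV (0.3 eV for the Ag+-mediated
        tetramer, 0.2 eV for B-DNA and plain guanine tetramers).
    grid_min, grid_max, grid_step : output wavelength window in nm.
    energy_weighting : which energy multiplies R_n in the sum — the
        per-state excitation energy E_n (default, the standard
        Delta_eps ∝ E·R relation applied stickwise) or the incident
        photon energy E; both conventions occur in post-processing
        codes and differ only within a linewidth.
    """

    sigma: float
    grid_min: float = 170.0
    grid_max: float = 400.0
    grid_step: float = 0.5
    energy_weighting: EnergyWeighting = "per_state_energy"

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidParameterError(f"sigma must be > 0 eV, got {self.sigma}")
        if not (self.grid_min < self.grid_max):
            raise InvalidParameterError(
                f"grid_min < grid_max required, got [{self.grid_min}, {self.grid_max}]"
            )
        if not (self.grid_step > 0):
            raise InvalidParameterError(f"grid_step must be > 0, got {self.grid_step}")
        if self.energy_weighting not in ("per_state_energy", "incident_energy"):
            raise InvalidParameterError(
                f"unknown energy_weighting {self.energy_weighting!r}"
            )

    def wavelength_grid(self) -> np.ndarray:
        """Ascending nm grid covering [grid_min, grid_max]."""
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        grid = self.grid_min + self.grid_step * np.arange(n + 1)
        return grid[grid <= self.grid_max + 1e-9]


@dataclass
class Spectrum:
    """A Delta_eps curve on a strictly monotone grid.

    ``axis`` tags the grid as wavelength (nm, ascending) or energy (eV).
    Values are molar circular dichroism in M^-1 cm^-1.
    """

    grid: np.ndarray
    values: np.ndarray
    axis: Literal["wavelength_nm", "energy_eV"] = "wavelength_nm"
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise InvalidParameterError("grid and values must be matching 1-D arrays")
        d = np.diff(self.grid)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("spectrum grid must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("spectrum values must be finite")

    def __len__(self) -> int:
        return len(self.grid)


def lineshape(energy, center: float, sigma: float):
    """Normalized Gaussian lineshape in energy, sigma_n(E), in eV^-1.

    sigma_n(E) = 1/(sqrt(2 pi) sigma) * exp(-(E - E_n)^2 / (2 sigma^2));
    symmetric about the center and of unit integral over all E.
    Accepts scalar or array ``energy``.
    """
    if not (sigma > 0):
        raise InvalidParameterError(f"sigma must be > 0 eV, got {sigma}")
    e = np.asarray(energy, dtype=float)
    out = np.exp(-0.5 * ((e - center) / sigma) ** 2) / (math.sqrt(2.0 * math.pi) * sigma)
    return out if out.ndim else float(out)


def convolve(
    stick: StickSpectrum,
    config: BroadeningConfig,
    constants: PhysicalConstants = CODATA2018,
) -> Spectrum:
    """Broaden a stick spectrum into a molar-CD curve on the nm grid.

    Delta_eps(E) = 4a * sum_n R_n * w_n(E) * sigma_n(E) with
    w_n = E_n (default) or w_n = E, R_n in 1e-40 cgs, E in eV; the
    result is reported against wavelength.  An empty stick gives the
    zero spectrum.
    """
    grid_nm = config.wavelength_grid()
    energies_ev = HC_EV_NM / grid_nm  # descending as wavelength ascends

    if len(stick) == 0:
        return Spectrum(grid_nm, np.zeros_like(grid_nm), label=stick.label,
                        metadata={"sigma_eV": config.sigma, **stick.metadata})

    en = stick.energies  # validated > 0 by ExcitedState
    rn = stick.rotatory_strengths  # validated finite

    # (n_states, n_grid) Gaussian matrix; sum over states.
    diff = energies_ev[None, :] - en[:, None]
    gauss = np.exp(-0.5 * (diff / config.sigma) ** 2) / (
        math.sqrt(2.0 * math.pi) * config.sigma
    )
    if config.energy_weighting == "per_state_energy":
        weighted = (rn * en)[:, None] * gauss
    else:
        weighted = rn[:, None] * gauss * energies_ev[None, :]
    values = 4.0 * constants.prefactor_a * 1.0e-40 * weighted.sum(axis=0)

    return Spectrum(
        grid_nm,
        values,
        label=stick.label,
        metadata={
            "sigma_eV": config.sigma,
            "energy_weighting": config.energy_weighting,
            **stick.metadata,
        },
    )


def merge_sticks(sticks: Iterable[StickSpectrum], label: str = "") -> StickSpectrum:
    """Concatenate stick spectra, reindexing states to keep indices unique."""
    states: list[ExcitedState] = []
    for stick in sticks:
        for s in stick.states:
            states.append(
                ExcitedState(len(states) + 1, s.energy, s.rotatory_strength,
                             s.oscillator_strength)
            )
    return StickSpectrum(states=states, label=label)
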
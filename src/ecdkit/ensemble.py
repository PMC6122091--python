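"""Snapshot-ensemble averaging with pointwise confidence bands.

Solution-phase ECD is compared with theory by averaging the spectra of
structures sampled from a molecular-dynamics trajectory (ten snapshots
are typically adequate for the Ag+-mediated guanine tetramer).  This
module resamples member spectra onto a common wavelength grid, forms
the pointwise mean, and attaches a 95% confidence band — by default a
Student-t interval on the mean (appropriate at n ~ 10), with a seeded
bootstrap-percentile alternative for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import InvalidParameterError, Spectrum


class RangeError(ValueError):
    """Target grid extends beyond the source span."""


class EnsembleError(ValueError):
    """Invalid ensemble input."""


@dataclass
class EnsembleSpectrum:
    """Mean spectrum of a snapshot ensemble with a confidence band."""

    grid: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    members: list[Spectrum]
    confidence_level: float = 0.95
    ci_method: str = "t"
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("grid", "mean", "ci_lower", "ci_upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            np.all(self.ci_lower <= self.mean + 1e-12)
            and np.all(self.mean <= self.ci_upper + 1e-12)
        ):
            raise EnsembleError("confidence band must bracket the mean pointwise")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as wavelength, mean, band and per-member columns."""
        data = {
            "wavelength_nm": self.grid,
            "mean": self.mean,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }
        for i, m in enumerate(self.members, start=1):
            data[f"member_{i}"] = resample(m, self.grid).values
        return pd.DataFrame(data)


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto *grid* (same axis, nm).

    Raises :class:`RangeError` if any target point lies outside the
    source span — extrapolating a CD curve is never meaningful.
    """
    grid = np.asarray(grid, dtype=float)
    src_grid, src_vals = spectrum.grid, spectrum.values
    if src_grid[0] > src_grid[-1]:  # tolerate descending storage
        src_grid, src_vals = src_grid[::-1], src_vals[::-1]
    lo, hi = src_grid[0], src_grid[-1]
    eps = 1e-9
    if grid.min() < lo - eps or grid.max() > hi + eps:
        raise RangeError(
            f"target grid [{grid.min():g}, {grid.max():g}] nm exceeds source span "
            f"[{lo:g}, {hi:g}] nm"
        )
    vals = np.interp(np.clip(grid, lo, hi), src_grid, src_vals)
    return Spectrum(grid, vals, axis=spectrum.axis, label=spectrum.label,
                    metadata=dict(spectrum.metadata))


def common_grid(members: Sequence[Spectrum]) -> np.ndarray:
    """Intersection of member spans, sampled at the finest member step."""
    lo = max(min(m.grid[0], m.grid[-1]) for m in members)
    hi = min(max(m.grid[0], m.grid[-1]) for m in members)
    if lo >= hi:
        raise EnsembleError("member spectra have no overlapping wavelength range")
    step = min(np.min(np.abs(np.diff(m.grid))) for m in members if len(m) > 1)
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


CiMethod = Literal["t", "bootstrap"]


def average(
    members: Sequence[Spectrum],
    confidence_level: float = 0.95,
    ci_method: CiMethod = "t",
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    grid: np.ndarray | None = None,
    label: str = "",
) -> EnsembleSpectrum:
    """Average snapshot spectra and attach a pointwise confidence band.

    Members are resampled to a shared grid (intersection of spans at
    the finest step, unless *grid* is given).  With ``ci_method="t"``
    the band is mean +/- t_{(1+cl)/2, n-1} * s / sqrt(n); with
    ``"bootstrap"`` it is the percentile interval of *n_bootstrap*
    seeded resamples of the member set.  A single member yields a
    degenerate band equal to the mean, with a warning.
    """
    members = list(members)
    if not members:
        raise EnsembleError("cannot average an empty collection of spectra")
    if not (0 < confidence_level < 1):
        raise InvalidParameterError(
            f"confidence_level must be in (0, 1), got {confidence_level}"
        )
    target = common_grid(members) if grid is None else np.asarray(grid, dtype=float)
    matrix = np.vstack([resample(m, target).values for m in members])
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)

    if n == 1:
        warnings.warn(
            "ensemble of a single spectrum: confidence band degenerates to the mean",
            stacklevel=2,
        )
        lower = upper = mean.copy()
    elif ci_method == "t":
        s = matrix.std(axis=0, ddof=1)
        half = stats.t.ppf(0.5 + confidence_level / 2.0, df=n - 1) * s / np.sqrt(n)
        lower, upper = mean - half, mean + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boot_means = matrix[idx].mean(axis=1)  # (n_bootstrap, n_grid)
        q = (1.0 - confidence_level) / 2.0
        lower = np.quantile(boot_means, q, axis=0)
        upper = np.quantile(boot_means, 1.0 - q, axis=0)
        # percentile interval need not bracket the mean exactly at tiny n
        lower = np.minimum(lower, mean)
        upper = np.maximum(upper, mean)
    else:
        raise InvalidParameterError(f"unknown ci_method {ci_method!r}")

    return EnsembleSpectrum(
        grid=target, mean=mean, ci_lower=lower, ci_upper=upper,
        members=members, confidence_level=confidence_level,
        ci_method=ci_method, label=label,
    )


def write_ensemble_csv(ensemble: EnsembleSpectrum, path) -> None:
    """Write the ensemble table (mean, band, members) as CSV."""
    ensemble.to_frame().to_csv(path, index=False)


def read_ensemble_csv(path) -> pd.DataFrame:
    """Read back an ensemble CSV as a DataFrame."""
    return pd.read_csv(path)
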
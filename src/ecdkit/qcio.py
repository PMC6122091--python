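"""Readers and writers for excited-state data and spectra.

Three surfaces:

* ``parse_qc_log`` — the mainstream Gaussian-type TDDFT output dialect:
  an ``Excited State N: ... eV ... nm`` block plus the length-gauge
  rotatory-strength table headed ``R(length)``.  Other codes enter via
  the plain stick table.
* stick exchange table — TSV with header
  ``state  energy_eV  wavelength_nm  R_length_1e-40cgs  f``.
* experimental spectra — two-column CSV ``wavelength_nm,delta_epsilon``.
"""

from __future__ import annotations

import io
import re
import warnings
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .constants import HC_EV_NM
from .spectra import ExcitedState, Spectrum, StickSpectrum


class QCFormatError(ValueError):
    """A required section or field is missing or malformed."""


class StateCountMismatchError(QCFormatError):
    """Energy and rotatory-strength blocks disagree on the state count."""


class InsufficientDataError(ValueError):
    """Fewer valid data rows than the operation requires."""


_EXCITED_STATE_RE = re.compile(
    r"Excited State\s+(?P<index>\d+):\s+(?P<label>\S+)\s+"
    r"(?P<energy>-?\d+\.?\d*)\s*eV\s+(?P<nm>-?\d+\.?\d*)\s*nm"
    r"(?:\s+f=\s*(?P<f>-?\d+\.?\d*))?"
)
_R_HEADER_RE = re.compile(r"R\(length\)")
_R_ROW_RE = re.compile(
    r"^\s*(?P<index>\d+)\s+(?P<cols>(?:-?\d+\.?\d*(?:[eEdD][+-]?\d+)?\s+)*"
    r"-?\d+\.?\d*(?:[eEdD][+-]?\d+)?)\s*$"
)


def _coerce(text: str) -> float:
    return float(text.replace("D", "E").replace("d", "e"))


def parse_qc_log(source: str | Path | TextIO) -> StickSpectrum:
    """Parse a Gaussian-type TDDFT log into a stick spectrum.

    Energies are taken from the eV field (not re-derived from nm; a
    discrepancy beyond 0.1 nm is warned about), rotatory strengths from
    the last column of the ``R(length)`` table, in 1e-40 cgs.  States
    present in the energy block but absent from the rotatory block are
    an error, never a silent zero.  Only singlet states are retained
    when multiplicity labels are present.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
        label = Path(source).name
    elif isinstance(source, str):
        text, label = source, ""
    else:
        text, label = source.read(), getattr(source, "name", "")

    states_raw = []
    for m in _EXCITED_STATE_RE.finditer(text):
        states_raw.append(
            {
                "index": int(m.group("index")),
                "label": m.group("label"),
                "energy": float(m.group("energy")),
                "nm": float(m.group("nm")),
                "f": float(m.group("f")) if m.group("f") is not None else None,
            }
        )
    if not states_raw:
        raise QCFormatError(
            "no 'Excited State' block found: not a TDDFT excited-state log?"
        )

    header = _R_HEADER_RE.search(text)
    if header is None:
        raise QCFormatError(
            "no length-gauge rotatory-strength table (header 'R(length)') found"
        )
    r_values: dict[int, float] = {}
    for line in text[header.end():].splitlines():
        row = _R_ROW_RE.match(line)
        if row is None:
            if r_values and line.strip() and not line.strip()[0].isdigit():
                break  # table ended
            continue
        cols = row.group("cols").split()
        r_values[int(row.group("index"))] = _coerce(cols[-1])

    n_e, n_r = len(states_raw), len(r_values)
    missing = [s["index"] for s in states_raw if s["index"] not in r_values]
    if missing or n_e != n_r:
        raise StateCountMismatchError(
            f"energy block has {n_e} states but R(length) table has {n_r}"
            + (f"; states missing from R table: {missing}" if missing else "")
        )

    states = []
    for s in states_raw:
        if "triplet" in s["label"].lower():
            continue
        derived_nm = HC_EV_NM / s["energy"] if s["energy"] > 0 else float("nan")
        if s["nm"] > 0 and abs(derived_nm - s["nm"]) > 0.1:
            warnings.warn(
                f"state {s['index']}: printed wavelength {s['nm']} nm differs from "
                f"hc/E = {derived_nm:.2f} nm by more than 0.1 nm; using the eV field",
                stacklevel=2,
            )
        states.append(
            ExcitedState(
                index=s["index"],
                energy=s["energy"],
                rotatory_strength=r_values[s["index"]],
                oscillator_strength=s["f"],
            )
        )
    return StickSpectrum(states=states, label=label,
                         metadata={"source": label or "<stream>", "format": "qc_log"})


STICK_COLUMNS = ["state", "energy_eV", "wavelength_nm", "R_length_1e-40cgs", "f"]


def write_stick_table(stick: StickSpectrum, path: str | Path) -> None:
    """Write the TSV stick exchange table (header + one row per state)."""
    rows = []
    for s in stick.states:
        rows.append(
            {
                "state": s.index,
                "energy_eV": repr(s.energy),
                "wavelength_nm": repr(s.wavelength),
                "R_length_1e-40cgs": repr(s.rotatory_strength),
                "f": "" if s.oscillator_strength is None else repr(s.oscillator_strength),
            }
        )
    pd.DataFrame(rows, columns=STICK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_stick_table(path: str | Path) -> StickSpectrum:
    """Read the stick exchange table (tab- or comma-separated)."""
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, skip_blank_lines=True)
    except Exception as exc:  # malformed table structure
        raise QCFormatError(f"{path}: cannot parse stick table: {exc}") from exc
    missing = [c for c in STICK_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise QCFormatError(f"{path}: stick table lacks columns {missing}")
    states = []
    for pos, row in df.iterrows():
        line_no = pos + 2  # header is line 1
        try:
            f_val = row.get("f")
            f_val = None if f_val is None or pd.isna(f_val) else float(f_val)
            state = ExcitedState(
                index=int(row["state"]),
                energy=float(row["energy_eV"]),
                rotatory_strength=float(row["R_length_1e-40cgs"]),
                oscillator_strength=f_val,
            )
        except (ValueError, TypeError) as exc:
            raise QCFormatError(f"{path}:{line_no}: bad stick-table row: {exc}") from exc
        if not pd.isna(row["wavelength_nm"]):
            derived = state.wavelength
            if abs(derived - float(row["wavelength_nm"])) > 0.1:
                warnings.warn(
                    f"{path}:{line_no}: wavelength column disagrees with energy by "
                    f"more than 0.1 nm; energy field wins",
                    stacklevel=2,
                )
        states.append(state)
    return StickSpectrum(states=states, label=path.stem,
                         metadata={"source": str(path), "format": "stick_table"})


def read_experimental_csv(path: str | Path) -> Spectrum:
    """Read a measured spectrum: CSV ``wavelength_nm,delta_epsilon``.

    An optional single header line is tolerated; rows are sorted by
    wavelength and duplicate wavelengths averaged.  Fewer than 3 valid
    rows is an error.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        parts = [p for p in re.split(r"[,\t;]|\s+", line.strip()) if p]
        if len(parts) < 2:
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if ln == 1 or not line.strip():
                continue  # header / blank
            raise QCFormatError(f"{path}:{ln}: non-numeric spectrum row: {line!r}")
    if len(rows) < 3:
        raise InsufficientDataError(
            f"{path}: experimental spectrum needs >= 3 valid rows, found {len(rows)}"
        )
    df = pd.DataFrame(rows, columns=["wl", "de"]).groupby("wl", as_index=False).mean()
    df = df.sort_values("wl")
    return Spectrum(
        df["wl"].to_numpy(), df["de"].to_numpy(),
        label=path.stem, metadata={"source": str(path), "kind": "experimental"},
    )


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV with a header."""
    pd.DataFrame(
        {"wavelength_nm": spectrum.grid, "delta_epsilon": spectrum.values}
    ).to_csv(path, index=False)
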
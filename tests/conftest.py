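"""Shared fixtures: QC-log text builders and small molecular fixtures.

All fixtures are generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from ecdkit.spectra import BroadeningConfig, ExcitedState, StickSpectrum, convolve


def make_qc_log(states, multiplicity="Singlet-A", r_values=None):
    """Render a Gaussian-type excited-state log for (index, eV, R, f) rows.

    *r_values* overrides the rotatory-strength table rows (to build
    mismatch fixtures); by default one row per state.
    """
    hc = 1239.841984
    lines = [
        " Excitation energies and oscillator strengths:",
        "",
    ]
    for idx, ev, r, f in states:
        lines.append(
            f" Excited State  {idx:3d}:      {multiplicity}    {ev:8.4f} eV "
            f"{hc / ev:8.2f} nm  f={f:7.4f}  <S**2>=0.000"
        )
        lines.append("      90 ->  91        0.70000")
        lines.append("")
    lines += [
        " 1/2[<0|r|b>*<b|rxdel|0> + (<0|rxdel|b>*<b|r|0>)*]",
        " Rotatory Strengths (R) in cgs (10**-40 erg-esu-cm/gauss)",
        "       state          XX          YY          ZZ     R(length)",
    ]
    rows = r_values if r_values is not None else [(idx, r) for idx, ev, r, f in states]
    for idx, r in rows:
        lines.append(f"      {idx:5d}     {0.1:11.4f} {0.2:11.4f} {0.3:11.4f} {r:12.4f}")
    lines.append(" SavETr:  write IOETJK to disk")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_state_log():
    return make_qc_log(
        [(1, 4.50, 8.0, 0.010), (2, 5.20, -15.0, 0.020), (3, 6.00, -10.0, 0.005)]
    )


@pytest.fixture
def three_state_stick():
    return StickSpectrum(
        [
            ExcitedState(1, 4.5, 8.0, 0.010),
            ExcitedState(2, 5.2, -15.0, 0.020),
            ExcitedState(3, 6.0, -10.0, 0.005),
        ],
        label="three_states",
    )


# -- guanine nucleotide PDB fixture ----------------------------------------
#
# Idealized (not crystallographic) coordinates: a ribose-phosphate arm and
# a planar guanine; only topology and the C1'-N9 direction matter here.
_GUANINE_NUCLEOTIDE = [
    # (name, element, x, y, z)
    ("P", "P", -4.000, 2.000, 0.500),
    ("OP1", "O", -4.800, 3.100, 0.900),
    ("OP2", "O", -4.500, 0.700, 0.100),
    ("O5'", "O", -2.900, 2.400, -0.500),
    ("C5'", "C", -2.000, 3.400, -0.200),
    ("C4'", "C", -1.000, 3.300, -1.300),
    ("O4'", "O", -0.300, 2.100, -1.200),
    ("C3'", "C", -1.600, 3.200, -2.700),
    ("O3'", "O", -1.200, 4.300, -3.500),
    ("C2'", "C", -1.000, 1.900, -3.200),
    ("C1'", "C", 0.100, 1.600, -2.300),
    ("N9", "N", 1.300, 1.200, -2.900),
    ("C8", "C", 1.500, 0.400, -3.980),
    ("N7", "N", 2.750, 0.200, -4.300),
    ("C5", "C", 3.480, 0.900, -3.390),
    ("C6", "C", 4.870, 1.050, -3.250),
    ("O6", "O", 5.750, 0.520, -3.950),
    ("N1", "N", 5.230, 1.880, -2.220),
    ("C2", "C", 4.340, 2.510, -1.400),
    ("N2", "N", 4.810, 3.300, -0.430),
    ("N3", "N", 3.020, 2.390, -1.520),
    ("C4", "C", 2.640, 1.580, -2.520),
]


def pdb_atom_line(serial, name, res_name, chain, res_seq, x, y, z, element):
    pdb_name = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {pdb_name}{'':1s}{res_name:>3s} {chain}{res_seq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def guanine_pdb_text(n_residues=1, with_silver=0, res_name="DG"):
    """A PDB with *n_residues* guanine nucleotides (+ optional Ag ions)."""
    lines = []
    serial = 0
    for ri in range(1, n_residues + 1):
        dz = 3.4 * (ri - 1)
        for name, el, x, y, z in _GUANINE_NUCLEOTIDE:
            serial += 1
            lines.append(
                pdb_atom_line(serial, name, res_name, "A", ri, x, y, z + dz, el)
            )
    for ai in range(1, with_silver + 1):
        serial += 1
        lines.append(
            pdb_atom_line(serial, "AG", "AG", "B", ai, 3.2, -0.8, -4.9 - 3.4 * ai, "AG")
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def guanine_pdb(tmp_path):
    p = tmp_path / "guanine.pdb"
    p.write_text(guanine_pdb_text())
    return p


@pytest.fixture
def tetramer_pdb(tmp_path):
    """Four guanine nucleotides plus two silver ions, G2-Ag2-G2-like."""
    p = tmp_path / "tetramer.pdb"
    p.write_text(guanine_pdb_text(n_residues=4, with_silver=2))
    return p
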
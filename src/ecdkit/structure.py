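"""Backbone truncation of nucleic-acid models for excited-state QM.

Full nucleotides are too expensive for high-level excited-state
calculations, and the sugar-phosphate backbone neither hosts the metal
binding sites nor contributes transitions in the spectral window of
interest.  The truncation implemented here removes the phosphate and
sugar atoms of each nucleotide, cuts the glycosidic bond (C1'-N9 for
purines, C1'-N1 for pyrimidines) and caps the freed nitrogen with a
hydrogen placed along the former bond direction at 1.01 A — the
geometric starting point that a subsequent DFT relaxation of the cap
hydrogens would refine.  Non-nucleotide species (Ag+ ions, waters) are
passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException


class StructureError(ValueError):
    """Malformed structure file or inconsistent atom records."""


class GeometryError(ValueError):
    """Degenerate geometry (e.g. zero-length bond vector)."""


@dataclass(frozen=True)
class Atom:
    """One atom with PDB-style naming and coordinates in Angstrom."""

    element: str
    name: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.coords, dtype=float)


@dataclass
class MolecularStructure:
    """An ordered atom list with provenance metadata.

    (chain, residue number, atom name) triples must be unique.
    """

    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise StructureError(
                    f"duplicate atom record: chain {a.chain_id!r} residue "
                    f"{a.res_seq} atom {a.name!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Group atoms by (chain, residue number, residue name), file order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.res_seq, a.res_name), []).append(a)
        return out


@dataclass(frozen=True)
class CutBond:
    """A severed glycosidic bond: the kept base nitrogen and the removed C1'."""

    base_atom: Atom  # glycosidic N, kept
    removed_position: tuple[float, float, float]  # former C1' coordinates
    site: str  # "N9" (purine) or "N1" (pyrimidine)


#: Standard nucleotide residue names (DNA/RNA, one-letter and D-prefixed).
NUCLEOTIDE_RESNAMES = {
    "DA", "DG", "DC", "DT", "DU", "A", "G", "C", "T", "U",
    "ADE", "GUA", "CYT", "THY", "URA",
}
PURINE_RESNAMES = {"DA", "DG", "A", "G", "ADE", "GUA"}

#: Sugar + phosphate heavy-atom names (primed PDB v3 convention; the
#: asterisked v2 spelling is normalized on read).
BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}
#: Hydrogens riding on those atoms.
BACKBONE_HYDROGENS = {
    "H5'", "H5''", "H5'1", "H5'2", "H4'", "H3'", "H2'", "H2''",
    "H2'1", "H2'2", "H1'", "HO5'", "HO3'", "HO2'", "H5T", "H3T",
    "HO'2",
}
_BACKBONE_ALL = BACKBONE_ATOMS | BACKBONE_HYDROGENS


def _normalize_name(name: str) -> str:
    """Map asterisked sugar names (O5*) onto the primed convention (O5')."""
    return name.replace("*", "'")


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789'")
    if len(stripped) >= 2 and stripped[:2].capitalize() in {"Ag", "Cl", "Br", "Na", "Mg", "Zn", "Fe", "Cu"}:
        return stripped[:2].capitalize()
    return stripped[0].upper() if stripped else "X"


def read_structure(path: str | Path, fmt: str | None = None) -> MolecularStructure:
    """Read a PDB or XYZ file into a :class:`MolecularStructure`.

    ``fmt`` is inferred from the suffix when omitted.  PDB coordinates
    are taken verbatim at the file's 3-decimal precision.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.upper()
    if fmt == "PDB":
        return _read_pdb(path)
    if fmt == "XYZ":
        return _read_xyz(path)
    raise StructureError(f"unsupported structure format {fmt!r} (use PDB or XYZ)")


def _read_pdb(path: Path) -> MolecularStructure:
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        model = parser.get_structure(path.stem, str(path))[0]
    except PDBConstructionException as exc:
        raise StructureError(f"{path}: malformed PDB record: {exc}") from exc
    except ValueError as exc:
        raise StructureError(f"{path}: unparseable PDB field: {exc}") from exc
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                x, y, z = (float(v) for v in atom.coord)
                name = _normalize_name(atom.get_name())
                element = atom.element.capitalize() if atom.element else _element_from_name(name)
                atoms.append(
                    Atom(
                        element=element,
                        name=name,
                        res_name=residue.get_resname().strip(),
                        res_seq=residue.get_id()[1],
                        chain_id=chain.get_id(),
                        coords=(round(x, 3), round(y, 3), round(z, 3)),
                    )
                )
    return MolecularStructure(atoms, metadata={"source": str(path), "format": "PDB"})


def _read_xyz(path: Path) -> MolecularStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"{path}:1: XYZ header must start with the atom count") from exc
    if len(lines) < n + 2:
        raise StructureError(f"{path}: XYZ promises {n} atoms but file is shorter")
    atoms: list[Atom] = []
    for i, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureError(f"{path}:{i}: XYZ atom line needs 'El x y z'")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError as exc:
            raise StructureError(f"{path}:{i}: non-numeric coordinate") from exc
        el = parts[0].capitalize()
        atoms.append(
            Atom(element=el, name=f"{el}{i - 2}", res_name="MOL", res_seq=1,
                 chain_id="A", coords=(x, y, z))
        )
    return MolecularStructure(atoms, metadata={"source": str(path), "format": "XYZ",
                                               "comment": lines[1]})


def write_xyz(structure: MolecularStructure, path: str | Path, comment: str = "") -> None:
    """Write element symbols and coordinates in plain XYZ."""
    lines = [str(len(structure)), comment or structure.metadata.get("comment", "")]
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def strip_backbone(
    structure: MolecularStructure,
) -> tuple[MolecularStructure, list[CutBond]]:
    """Remove sugar-phosphate atoms from nucleotide residues.

    Returns the base-only structure and one :class:`CutBond` per
    residue whose C1' was removed, recording the glycosidic nitrogen
    and the lost C1' position.  Residues of non-nucleotide species pass
    through untouched; a nucleotide lacking its glycosidic nitrogen is
    an error.  The operation is idempotent.
    """
    kept: list[Atom] = []
    cut_bonds: list[CutBond] = []
    for (chain, seq, res_name), res_atoms in structure.residues().items():
        if res_name not in NUCLEOTIDE_RESNAMES:
            kept.extend(res_atoms)
            continue
        site = "N9" if res_name in PURINE_RESNAMES else "N1"
        names = {a.name for a in res_atoms}
        base_atoms = [a for a in res_atoms if a.name not in _BACKBONE_ALL]
        if site not in names:
            raise StructureError(
                f"residue {res_name} {chain}:{seq} lacks glycosidic nitrogen {site}"
            )
        kept.extend(base_atoms)
        c1 = next((a for a in res_atoms if a.name == "C1'"), None)
        if c1 is not None:
            n_atom = next(a for a in res_atoms if a.name == site)
            cut_bonds.append(
                CutBond(base_atom=n_atom, removed_position=c1.coords, site=site)
            )
    out = MolecularStructure(
        kept, metadata={**structure.metadata, "backbone_stripped": True}
    )
    return out, cut_bonds


def cap_with_hydrogens(
    base_only: MolecularStructure,
    cut_bonds: list[CutBond],
    nh_distance: float = 1.01,
) -> MolecularStructure:
    """Cap each severed glycosidic bond with a hydrogen.

    The cap H sits along the unit vector from the glycosidic nitrogen
    toward the removed C1' position, at *nh_distance* Angstrom
    (default 1.01 A, a standard amine N-H length).  Cap atoms are named
    H9 (purine site) or H1 (pyrimidine site).  Pre-existing atoms are
    never moved.
    """
    atoms = list(base_only.atoms)
    present = {(a.chain_id, a.res_seq, a.name) for a in atoms}
    for bond in cut_bonds:
        n = bond.base_atom
        if (n.chain_id, n.res_seq, n.name) not in present:
            raise StructureError(
                f"cut-bond nitrogen {n.name} of residue {n.chain_id}:{n.res_seq} "
                "is absent from the base-only structure"
            )
        vec = np.asarray(bond.removed_position) - n.xyz
        norm = float(np.linalg.norm(vec))
        if norm < 1e-9:
            raise GeometryError(
                f"zero-length glycosidic bond vector at {n.chain_id}:{n.res_seq}"
            )
        pos = n.xyz + nh_distance * vec / norm
        atoms.append(
            Atom(
                element="H",
                name="H9" if bond.site == "N9" else "H1",
                res_name=n.res_name,
                res_seq=n.res_seq,
                chain_id=n.chain_id,
                coords=(float(pos[0]), float(pos[1]), float(pos[2])),
            )
        )
    return MolecularStructure(
        atoms, metadata={**base_only.metadata, "capped": True,
                         "nh_distance_A": nh_distance}
    )


def truncate_to_bases(
    structure: MolecularStructure, nh_distance: float = 1.01
) -> MolecularStructure:
    """Convenience: strip the backbone and cap in one step."""
    base_only, bonds = strip_backbone(structure)
    return cap_with_hydrogens(base_only, bonds, nh_distance=nh_distance)
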
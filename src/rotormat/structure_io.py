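"""PDB reading/writing and extraction of the four dihedral rotors.

Each residue of a polypeptide chain carries up to four rotatable dihedral
angles ("rotors"): the backbone torsions phi (C(i-1)-N-CA-C) and psi
(N-CA-C-N(i+1)) and the first two side-chain torsions chi1 (N-CA-CB-G)
and chi2 (CA-CB-G-D), where G and D are the gamma and delta heavy atoms
of the residue type.  Rotors that do not exist for a residue type (GLY
has no side chain, ALA stops at CB, SER/CYS/THR/VAL have no delta atom)
or that cannot be computed from the available coordinates are explicitly
undefined (``None``), never zero.

Only the PDB format is supported.  Parsing keeps the first MODEL of
multi-model files, keeps only alternate location indicators ' ' or 'A',
and skips HETATM records and waters.  Coordinates are written at the
standard three decimal places by default; a higher ``decimals`` widens
the coordinate fields (a documented extension used when downstream
analysis needs torsions reproduced to well below a hundredth of a
degree, which three-decimal coordinates cannot carry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import RotormatError
from .geometry import dihedral_angle

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueGroup",
    "RotorRecord",
    "ROTOR_NAMES",
    "CHI1_GAMMA_ATOM",
    "CHI2_DELTA_ATOM",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "parse_pdb",
    "write_pdb",
    "group_atoms",
    "extract_rotor_table",
    "rotor_table_from_pdb",
    "write_rotor_table",
    "read_rotor_table",
]

ROTOR_NAMES = ("phi", "psi", "chi1", "chi2")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Fixed chi atom quadruples (rotamer-library convention).  Branch
# ambiguities are resolved once here: ILE chi1 via CG1 and chi2 via CD1,
# THR chi1 via OG1, VAL chi1 via CG1, ASP/ASN chi2 via OD1, HIS chi2 via
# ND1, PHE/TYR/TRP/LEU chi2 via CD1.
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}
CHI2_DELTA_ATOM = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "ILE": "CD1", "LEU": "CD1", "LYS": "CD", "MET": "SD",
    "PHE": "CD1", "PRO": "CD", "TRP": "CD1", "TYR": "CD1",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_BACKBONE = ("N", "CA", "C")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, parent residue identity and Cartesian coordinates (A)."""

    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: tuple[float, float, float]
    insertion_code: str = ""

    def __post_init__(self):
        if not self.name:
            raise RotormatError("atom name must be non-empty")
        if not all(x == x and abs(x) != float("inf") for x in self.coordinates):
            raise RotormatError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueGroup:
    """All retained atoms of one residue, keyed by atom name."""

    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    is_standard: bool = True
    incomplete: bool = False

    def coord(self, atom_name: str):
        rec = self.atoms.get(atom_name)
        return None if rec is None else rec.coordinates


@dataclass(frozen=True)
class RotorRecord:
    """One residue's identity, chain position and four rotor values.

    Angles are degrees in (-180, +180]; ``None`` marks an undefined rotor.
    """

    residue_name: str  # 1-letter code; "X" for non-standard residues
    chain_id: str
    sequence_index: int
    phi: float | None = None
    psi: float | None = None
    chi1: float | None = None
    chi2: float | None = None

    def rotor(self, name: str) -> float | None:
        if name not in ROTOR_NAMES:
            raise RotormatError(f"unknown rotor {name!r}; expected one of {ROTOR_NAMES}")
        return getattr(self, name)


def _parse_atom_line(line: str, line_number: int) -> AtomRecord | None:
    name = line[12:16].strip()
    altloc = line[16]
    resname = line[17:20].strip()
    chain_id = line[21].strip() or "A"
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise RotormatError(f"line {line_number}: unreadable residue number") from exc
    icode = line[26].strip()
    if altloc not in (" ", "A"):
        return None
    # Standard files carry x, y, z in columns 31-54 (three 8.3 fields);
    # files written at higher precision widen those fields, in which case
    # the 31-54 slice no longer holds three complete numbers and the
    # whole tail is tokenized instead.
    xyz = None
    std = line[30:54].split()
    if len(std) == 3:
        try:
            xyz = (float(std[0]), float(std[1]), float(std[2]))
        except ValueError:
            xyz = None
    if xyz is None:
        toks = line[30:].split()
        try:
            xyz = (float(toks[0]), float(toks[1]), float(toks[2]))
        except (IndexError, ValueError) as exc:
            raise RotormatError(f"line {line_number}: unreadable coordinates") from exc
    return AtomRecord(
        name=name,
        residue_name=resname,
        chain_id=chain_id,
        residue_number=resnum,
        coordinates=xyz,
        insertion_code=icode,
    )


def parse_pdb(path: str | Path) -> list[list[ResidueGroup]]:
    """Parse a PDB file into chains of residue atom groups.

    Keeps the first MODEL only; skips HETATM records and waters; keeps
    the first alternate location (' ' or 'A') per atom.  Residues missing
    a backbone atom are flagged ``incomplete`` (a warning, not an error);
    non-standard residues are retained with ``is_standard=False``.

    Raises :class:`RotormatError` if the file is unreadable or contains
    no usable ATOM records.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise RotormatError(f"cannot read PDB file {path}: {exc}") from exc

    chains: dict[str, dict[tuple, ResidueGroup]] = {}
    in_first_model = True
    model_seen = False
    n_atoms = 0
    for i, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            if model_seen:
                in_first_model = False
            model_seen = True
            continue
        if record.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if record == "HETATM":
            continue
        if record != "ATOM  ":
            continue
        if line[17:20].strip() in _WATER_NAMES:
            continue
        atom = _parse_atom_line(line, i)
        if atom is None:
            continue
        n_atoms += 1
        key = (atom.residue_number, atom.insertion_code)
        residues = chains.setdefault(atom.chain_id, {})
        group = residues.get(key)
        if group is None:
            group = ResidueGroup(
                residue_name=atom.residue_name,
                chain_id=atom.chain_id,
                residue_number=atom.residue_number,
                insertion_code=atom.insertion_code,
                is_standard=atom.residue_name in THREE_TO_ONE,
            )
            residues[key] = group
        if atom.name not in group.atoms:  # first altloc wins
            group.atoms[atom.name] = atom

    if n_atoms == 0:
        raise RotormatError(f"{path}: no ATOM records found")

    result: list[list[ResidueGroup]] = []
    for chain_id in chains:
        groups = [chains[chain_id][k] for k in sorted(chains[chain_id])]
        for g in groups:
            if any(a not in g.atoms for a in _BACKBONE):
                g.incomplete = True
                logger.warning(
                    "residue %s %s%s%s missing backbone atom(s); flagged incomplete",
                    g.residue_name, g.chain_id, g.residue_number, g.insertion_code,
                )
            if not g.is_standard:
                logger.warning(
                    "non-standard residue %s %s%s retained",
                    g.residue_name, g.chain_id, g.residue_number,
                )
        result.append(groups)
    return result


def write_pdb(chains: Sequence[Sequence[ResidueGroup]] | Sequence[AtomRecord],
              path: str | Path, decimals: int = 3) -> None:
    """Write residue groups (or a flat atom list) as PDB ATOM records.

    ``decimals=3`` produces standard fixed-column PDB.  Larger values
    widen the three coordinate fields, preserving geometry beyond the
    format's native milli-angstrom resolution; :func:`parse_pdb` reads
    both layouts.
    """
    atoms: list[AtomRecord] = []
    for item in chains:
        if isinstance(item, AtomRecord):
            atoms.append(item)
        else:
            for group in item:
                atoms.extend(group.atoms.values())
    width = max(8, decimals + 5)
    lines = []
    serial = 0
    prev_chain = None
    for a in atoms:
        serial += 1
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.coordinates
        coords = "".join(f"{v:{width}.{decimals}f}" for v in (x, y, z))
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{coords}{1.0:6.2f}{0.0:6.2f}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def group_atoms(atoms: Sequence[AtomRecord]) -> list[list[ResidueGroup]]:
    """Group a flat atom list into chains of residue groups (no file I/O).

    Atoms are grouped by (chain_id, residue_number, insertion_code) in
    order of first appearance; backbone completeness is flagged exactly
    as in :func:`parse_pdb`.
    """
    chains: dict[str, dict[tuple, ResidueGroup]] = {}
    for atom in atoms:
        key = (atom.residue_number, atom.insertion_code)
        residues = chains.setdefault(atom.chain_id, {})
        group = residues.get(key)
        if group is None:
            group = ResidueGroup(
                residue_name=atom.residue_name,
                chain_id=atom.chain_id,
                residue_number=atom.residue_number,
                insertion_code=atom.insertion_code,
                is_standard=atom.residue_name in THREE_TO_ONE,
            )
            residues[key] = group
        if atom.name not in group.atoms:
            group.atoms[atom.name] = atom
    result = []
    for chain_id in chains:
        groups = [chains[chain_id][k] for k in sorted(chains[chain_id])]
        for g in groups:
            if any(a not in g.atoms for a in _BACKBONE):
                g.incomplete = True
        result.append(groups)
    return result


def _residue_dihedral(atoms: Sequence[tuple | None]) -> float | None:
    if any(p is None for p in atoms):
        return None
    return dihedral_angle(*atoms)


def extract_rotor_table(chain: Sequence[ResidueGroup]) -> list[RotorRecord]:
    """Compute phi, psi, chi1 and chi2 for every residue of one chain.

    The first residue has no phi and the last no psi; rotors whose atoms
    are absent (by residue type or because the residue is incomplete) are
    undefined.
    """
    records: list[RotorRecord] = []
    n = len(chain)
    for i, res in enumerate(chain):
        name3 = res.residue_name
        one = THREE_TO_ONE.get(name3, "X")
        prev_c = chain[i - 1].coord("C") if i > 0 else None
        next_n = chain[i + 1].coord("N") if i < n - 1 else None
        phi = _residue_dihedral([prev_c, res.coord("N"), res.coord("CA"), res.coord("C")])
        psi = _residue_dihedral([res.coord("N"), res.coord("CA"), res.coord("C"), next_n])
        chi1 = chi2 = None
        gamma = CHI1_GAMMA_ATOM.get(name3)
        if gamma is not None:
            chi1 = _residue_dihedral(
                [res.coord("N"), res.coord("CA"), res.coord("CB"), res.coord(gamma)]
            )
            delta = CHI2_DELTA_ATOM.get(name3)
            if delta is not None:
                chi2 = _residue_dihedral(
                    [res.coord("CA"), res.coord("CB"), res.coord(gamma), res.coord(delta)]
                )
        if res.incomplete:
            logger.debug(
                "residue %s%d incomplete; rotors computed from available atoms only",
                one, i,
            )
        records.append(
            RotorRecord(
                residue_name=one,
                chain_id=res.chain_id if chain else "A",
                sequence_index=i,
                phi=phi, psi=psi, chi1=chi1, chi2=chi2,
            )
        )
    return records


def rotor_table_from_pdb(path: str | Path) -> list[RotorRecord]:
    """All chains of a PDB file as a single rotor-record list."""
    records: list[RotorRecord] = []
    for chain in parse_pdb(path):
        records.extend(extract_rotor_table(chain))
    return records


def _fmt(angle: float | None) -> str:
    return "NA" if angle is None else f"{angle:.6f}"


def write_rotor_table(records: Iterable[RotorRecord], path: str | Path) -> None:
    """Write a dihedral table as TSV with 'NA' marking undefined rotors."""
    rows = [
        {
            "chain": r.chain_id,
            "index": r.sequence_index,
            "aa": r.residue_name,
            "phi": _fmt(r.phi),
            "psi": _fmt(r.psi),
            "chi1": _fmt(r.chi1),
            "chi2": _fmt(r.chi2),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["chain", "index", "aa", "phi", "psi", "chi1", "chi2"]).to_csv(
        path, sep="\t", index=False
    )


def read_rotor_table(path: str | Path) -> list[RotorRecord]:
    """Read a dihedral TSV written by :func:`write_rotor_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "aa": str}, na_values=["NA"])
    cols = ["chain", "index", "aa", "phi", "psi", "chi1", "chi2"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RotormatError(f"{path}: dihedral table missing columns {missing}")

    def val(x):
        return None if pd.isna(x) else float(x)

    records = []
    for chain, idx, aa, phi, psi, chi1, chi2 in df[cols].itertuples(index=False, name=None):
        records.append(
            RotorRecord(
                residue_name=str(aa),
                chain_id=str(chain),
                sequence_index=int(idx),
                phi=val(phi), psi=val(psi), chi1=val(chi1), chi2=val(chi2),
            )
        )
    return records
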
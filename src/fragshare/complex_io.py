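"""Reading, selecting and writing molecular structures in PDB and PDBQT.

The partitioning method scores every fragment *in place*, in the fixed
Cartesian frame of the ligand-receptor complex. Coordinates are therefore
kept exactly as printed in the source file — no centering, no rotation,
ever. PDBQT is handled as a PDB dialect carrying Gasteiger-style partial
charges, AutoDock atom types and a TORSDOF (torsion count) record; the
torsion-tree records (ROOT/BRANCH) are tolerated and ignored, since all
scoring here is single-point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "SFType",
    "Molecule",
    "ComplexGeometry",
    "ParseError",
    "SelectionError",
    "UnknownElementError",
    "read_structure",
    "write_structure",
    "read_models",
    "select_component",
    "assign_interaction_types",
    "perceive_bonds",
    "load_type_table",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})

# Approximate single-bond covalent radii (A) for distance-based bond
# perception on ligands lacking CONECT records.
_COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "FE": 1.32, "ZN": 1.22, "MG": 1.41, "MN": 1.39, "CA": 1.76,
}
_BOND_TOL = 0.45  # A added to the covalent-radius sum
_MIN_BOND = 0.40  # below this two records are treated as a clash, not a bond

_KNOWN_ELEMENTS = frozenset(_COVALENT_RADII)


class ParseError(ValueError):
    """A structure file record could not be parsed (carries the line number)."""


class UnknownElementError(ValueError):
    """An atom's element could not be established or is not in the tables."""


class SelectionError(ValueError):
    """A selection matched no atoms; lists what is available."""


@dataclass(frozen=True)
class SFType:
    """Interaction-type record consumed by the pairwise scoring function."""

    is_heavy: bool
    hydrophobic: bool
    donor: bool
    acceptor: bool
    radius: float  # vdW radius, A (0 for hydrogens — they form no pairs)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), A
    record: str = "ATOM"
    res_name: str = "UNK"
    res_seq: int = 1
    chain_id: str = "A"
    icode: str = ""
    altloc: str = ""
    segment: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    formal_charge: int = 0
    partial_charge: float | None = None
    ad_type: str | None = None  # AutoDock atom-type column, verbatim
    sf_type: SFType | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.serial <= 0:
            raise ValueError("atom serial must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Molecule:
    """An ordered list of atoms plus an explicit bond list.

    Bonds are stored once as (i, j, order) with i < j referring to atom
    *indices* (0-based); user-facing fragment schemes use 1-based serials
    exactly as printed in the source file.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    provenance: str = ""
    n_rotatable: int | None = None  # from TORSDOF when read from PDBQT

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        canon = []
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            canon.append((key[0], key[1], order))
        self.bonds = canon

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial}")

    def index_by_serial(self, serial: int) -> int:
        for i, a in enumerate(self.atoms):
            if a.serial == serial:
                return i
        raise KeyError(f"no atom with serial {serial}")

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            provenance=self.provenance,
            n_rotatable=self.n_rotatable,
        )


@dataclass
class ComplexGeometry:
    """Receptor and ligand sharing one Cartesian frame."""

    receptor: Molecule
    ligand: Molecule
    frame_note: str = ""


# ---------------------------------------------------------------------------
# parsing


def _parse_element(line: str, lineno: int) -> tuple[str, int]:
    """Element symbol and formal charge from PDB columns 77-80, with a
    name-based fallback for minimal files."""
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        name = line[12:16].strip()
        stripped = name.lstrip("0123456789")
        if stripped[:2].upper() in _KNOWN_ELEMENTS and not stripped[:1].upper() == "H":
            element = stripped[:2].upper()
        elif stripped[:1].upper() in _KNOWN_ELEMENTS or stripped[:1].upper() == "H":
            element = stripped[:1].upper()
    if element in {"D", "T"}:
        element = "H"
    if not element or (element not in _KNOWN_ELEMENTS and element != "H"):
        raise UnknownElementError(
            f"line {lineno}: cannot establish element for atom record "
            f"{line[6:16].strip()!r} (got {element!r})"
        )
    charge = 0
    if len(line) >= 80:
        tok = line[78:80].strip()
        if tok:
            try:
                charge = int(tok[::-1]) if tok[-1] in "+-" else int(tok)
            except ValueError:
                charge = 0
    return element, charge


def _parse_atom_line(line: str, lineno: int, fmt: str) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip() if len(line) > 16 else ""
        res_name = line[17:20].strip()
        chain_id = line[21].strip() if len(line) > 21 else ""
        res_seq = int(line[22:26]) if line[22:26].strip() else 1
        icode = line[26].strip() if len(line) > 26 else ""
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed {line[:6].strip()} record: {exc}") from exc

    partial_charge: float | None = None
    ad_type: str | None = None
    if fmt == "pdbqt":
        try:
            partial_charge = float(line[70:76])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed PDBQT charge column") from exc
        ad_type = line[77:79].strip() or None
        # element from the AutoDock type (PDBQT drops the element column)
        base = (ad_type or "").rstrip("ADHP") or (ad_type or "")
        cand = base.upper()
        if cand in _KNOWN_ELEMENTS or cand == "H":
            element = cand
        elif (ad_type or "").upper() in {"A", "G"}:  # aromatic / glue carbons
            element = "C"
        elif (ad_type or "").upper() in {"HD", "HS"}:
            element = "H"
        elif (ad_type or "").upper() in {"NA", "NS"}:
            element = "N"
        elif (ad_type or "").upper() in {"OA", "OS"}:
            element = "O"
        elif (ad_type or "").upper() == "SA":
            element = "S"
        else:
            element, _ = _parse_element(line, lineno)
        charge = 0
    else:
        element, charge = _parse_element(line, lineno)
    segment = line[72:76].strip() if fmt == "pdb" and len(line) >= 76 else ""

    return Atom(
        serial=serial, name=name, element=element,
        coords=np.array([x, y, z]), record=line[:6].strip(),
        res_name=res_name, res_seq=res_seq, chain_id=chain_id, icode=icode,
        altloc=altloc, segment=segment, occupancy=occ, b_factor=bfac,
        formal_charge=charge, partial_charge=partial_charge, ad_type=ad_type,
    )


def _parse_lines(lines: list[str], fmt: str, provenance: str) -> Molecule:
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    bonds: list[tuple[int, int, int]] = []
    n_rotatable: int | None = None
    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6].strip()
        if rec in {"ATOM", "HETATM"}:
            atom = _parse_atom_line(raw.rstrip("\n"), lineno, fmt)
            serial_to_index[atom.serial] = len(atoms)
            atoms.append(atom)
        elif rec == "CONECT":
            fields = raw.split()[1:]
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CONECT record") from exc
            if serials and serials[0] in serial_to_index:
                i = serial_to_index[serials[0]]
                for s in serials[1:]:
                    if s in serial_to_index:
                        bonds.append((i, serial_to_index[s], 1))
        elif raw.startswith("TORSDOF"):
            try:
                n_rotatable = int(raw.split()[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"line {lineno}: malformed TORSDOF record") from exc
        # MODEL/ENDMDL handled by read_models; ROOT/BRANCH/TER/REMARK ignored
    return Molecule(atoms=atoms, bonds=bonds, provenance=provenance,
                    n_rotatable=n_rotatable)


def read_structure(path: str | Path, format: str | None = None) -> Molecule:
    """Read a PDB or PDBQT file into a Molecule (first model only).

    Coordinates are returned exactly as printed, in A. ``format`` defaults
    to the file extension.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "pdbqt"}:
        raise ValueError(f"unsupported format {fmt!r} (expected pdb or pdbqt)")
    lines = path.read_text().splitlines()
    # keep only the first MODEL block if the file is multi-model
    if any(l.startswith("MODEL") for l in lines):
        block: list[str] = []
        inside = False
        for l in lines:
            if l.startswith("MODEL"):
                inside = True
                continue
            if l.startswith("ENDMDL"):
                break
            if inside:
                block.append(l)
        lines = block
    return _parse_lines(lines, fmt, provenance=f"{path} [{fmt}]")


def read_models(path: str | Path, format: str | None = None) -> list[tuple[Molecule, dict]]:
    """Read every MODEL block of a multi-model PDB / multi-pose PDBQT.

    Returns ``(molecule, meta)`` pairs; ``meta`` carries the model number and,
    for AutoDock Vina output, the score parsed from ``REMARK VINA RESULT``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    lines = path.read_text().splitlines()
    if not any(l.startswith("MODEL") for l in lines):
        return [(read_structure(path, fmt), {"model": 1, "vina_score": None})]
    out: list[tuple[Molecule, dict]] = []
    block: list[str] = []
    meta: dict = {}
    inside = False
    for l in lines:
        if l.startswith("MODEL"):
            inside = True
            block = []
            toks = l.split()
            meta = {"model": int(toks[1]) if len(toks) > 1 else len(out) + 1,
                    "vina_score": None}
        elif l.startswith("ENDMDL"):
            out.append((_parse_lines(block, fmt, f"{path} model {meta['model']}"), meta))
            inside = False
        elif inside:
            if l.startswith("REMARK VINA RESULT:"):
                try:
                    meta["vina_score"] = float(l.split(":")[1].split()[0])
                except (IndexError, ValueError):
                    pass
            block.append(l)
    return out


# ---------------------------------------------------------------------------
# writing


def _format_atom_line(a: Atom, fmt: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    base = (
        f"{a.record:<6s}{a.serial:>5d} {name:<4s}{a.altloc or ' ':1s}"
        f"{a.res_name:>3s} {a.chain_id or ' ':1s}{a.res_seq:>4d}{a.icode or ' ':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}"
    )
    if fmt == "pdbqt":
        ad = a.ad_type or (a.element.capitalize() if a.element != "H" else "H")
        q = a.partial_charge if a.partial_charge is not None else 0.0
        return f"{base}    {q:6.3f} {ad:<2s}"
    seg = f"{a.segment:<4s}" if a.segment else "    "
    chg = ""
    if a.formal_charge:
        chg = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
    return f"{base}      {seg}{a.element.capitalize():>2s}{chg:<2s}".rstrip()


def write_structure(mol: Molecule, path: str | Path, format: str | None = None) -> Path:
    """Write a Molecule as PDB (with CONECT) or PDBQT (charges, AD types,
    TORSDOF). Round-trips with :func:`read_structure` to 3 decimals."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "pdbqt"}:
        raise ValueError(f"unsupported format {fmt!r}")
    lines = [_format_atom_line(a, fmt) for a in mol.atoms]
    if fmt == "pdb":
        by_index: dict[int, list[int]] = {}
        for i, j, _ in mol.bonds:
            by_index.setdefault(i, []).append(j)
            by_index.setdefault(j, []).append(i)
        for i in sorted(by_index):
            partners = "".join(f"{mol.atoms[j].serial:>5d}" for j in sorted(by_index[i]))
            lines.append(f"CONECT{mol.atoms[i].serial:>5d}{partners}")
    else:
        if mol.n_rotatable is not None:
            lines.append(f"TORSDOF {mol.n_rotatable}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# selection


def select_component(
    mol: Molecule,
    chains: set[str] | None = None,
    segments: set[str] | None = None,
    residue_names: set[str] | None = None,
    strip_solvent: bool = False,
    altloc_policy: str = "first",
) -> Molecule:
    """Subset a structure by chain / segment / residue name.

    Waters (HOH/WAT/...) are dropped when ``strip_solvent`` is on. The
    default altloc policy keeps the first-listed alternative of each
    (chain, residue, atom name) group and warns about the rest. Selection
    is idempotent and never reorders atoms.
    """
    if altloc_policy not in {"first", "all"}:
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    keep: list[int] = []
    seen_alt: set[tuple] = set()
    dropped_alt: list[str] = []
    for i, a in enumerate(mol.atoms):
        if chains is not None and a.chain_id not in chains:
            continue
        if segments is not None and a.segment not in segments:
            continue
        if residue_names is not None and a.res_name not in residue_names:
            continue
        if strip_solvent and a.res_name in WATER_RESNAMES:
            continue
        if altloc_policy == "first" and a.altloc:
            key = (a.chain_id, a.res_seq, a.icode, a.name)
            if key in seen_alt:
                dropped_alt.append(f"{a.res_name}{a.res_seq}/{a.name}:{a.altloc}")
                continue
            seen_alt.add(key)
        keep.append(i)
    if dropped_alt:
        warnings.warn(
            "dropped alternative locations: " + ", ".join(dropped_alt),
            stacklevel=2,
        )
    if not keep:
        avail_chains = sorted({a.chain_id for a in mol.atoms})
        avail_segs = sorted({a.segment for a in mol.atoms if a.segment})
        raise SelectionError(
            f"selection matched no atoms; available chains={avail_chains}, "
            f"segments={avail_segs}"
        )
    index_map = {old: new for new, old in enumerate(keep)}
    atoms = [replace(mol.atoms[i], coords=mol.atoms[i].coords.copy()) for i in keep]
    bonds = [
        (index_map[i], index_map[j], o)
        for i, j, o in mol.bonds
        if i in index_map and j in index_map
    ]
    return Molecule(atoms=atoms, bonds=bonds,
                    provenance=mol.provenance + " | selected",
                    n_rotatable=mol.n_rotatable)


# ---------------------------------------------------------------------------
# bond perception & interaction typing


def perceive_bonds(mol: Molecule, tol: float = _BOND_TOL) -> Molecule:
    """Distance-based bond perception (covalent-radius sum + tolerance).

    Used for PDB ligands lacking CONECT records; existing bonds win — a
    molecule that already has a bond list is returned unchanged.
    """
    if mol.bonds:
        return mol
    out = mol.copy()
    coords = out.coords
    radii = np.array([_COVALENT_RADII.get(a.element, 0.77) for a in out.atoms])
    bonds: list[tuple[int, int, int]] = []
    for i in range(len(out.atoms)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        limit = radii[i] + radii[i + 1:] + tol
        for off in np.nonzero((d < limit) & (d > _MIN_BOND))[0]:
            j = i + 1 + int(off)
            if out.atoms[i].is_hydrogen and out.atoms[j].is_hydrogen:
                continue
            bonds.append((i, j, 1))
    out.bonds = bonds
    return out


def load_type_table(path: str | Path | None = None) -> dict:
    """Load the versioned interaction-type parameter table (JSON)."""
    if path is None:
        ref = resources.files("fragshare.params") / "interaction_types.json"
        return json.loads(ref.read_text())
    return json.loads(Path(path).read_text())


def assign_interaction_types(mol: Molecule, table: dict | None = None) -> Molecule:
    """Assign hydrophobic/donor/acceptor flags and vdW radii to every atom.

    Rules (from the versioned table): a carbon is hydrophobic iff all its
    heavy neighbours are carbons; N/O are acceptors; N/O/S with a bonded
    hydrogen are donors; halogens are hydrophobic; hydrogens are flagged
    non-interacting (they contribute no pairs to the score).

    Bonds are perceived first if the molecule has none — the donor rule
    needs the connectivity.
    """
    table = table or load_type_table()
    elements = table["elements"]
    out = perceive_bonds(mol) if not mol.bonds and len(mol) > 1 else mol.copy()
    for idx, atom in enumerate(out.atoms):
        el = atom.element.upper()
        if el not in elements:
            raise UnknownElementError(
                f"element {el!r} of atom {atom.serial} ({atom.name}) is not in "
                f"type table {table.get('table_id', '?')}"
            )
        row = elements[el]
        if atom.is_hydrogen:
            atom.sf_type = SFType(False, False, False, False, 0.0)
            continue
        nbr_elements = [out.atoms[j].element for j in out.neighbors(idx)]
        hydrophobic = bool(row["hydrophobic_candidate"])
        if el == "C":
            hydrophobic = all(e in {"C", "H"} for e in nbr_elements)
        donor = bool(row["donor_candidate"]) and "H" in nbr_elements
        acceptor = bool(row["acceptor"])
        atom.sf_type = SFType(True, hydrophobic, donor, acceptor, float(row["radius"]))
    return out
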
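"""User-defined ligand fragmentation with hydrogen (or methyl) capping.

A fragment scheme is a partition of the ligand's heavy atoms plus the list
of inter-fragment bonds to cut. Each fragment is extracted as a regular
molecule: its original atoms keep their coordinates bit-for-bit (the whole
point of in-place scoring), and every cut bond is healed by a cap placed
along the direction of the departed neighbour. Caps complete the valence
without perturbing geometry; they are artifacts of the method, so the
heavy-atom count NH of a fragment never includes cap atoms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .complex_io import Atom, Molecule, perceive_bonds

__all__ = [
    "FragmentScheme",
    "FragmentDef",
    "CappedFragment",
    "SchemeValidation",
    "CapPlacementError",
    "validate_scheme",
    "cut_and_cap",
    "place_cap",
    "CAP_BOND_LENGTHS",
    "METHYL_BOND_LENGTHS",
]

# Cap bond lengths, A, per stub element: standard X-H distances for the
# hydrogen cap and X-C single-bond distances for the methyl cap. Fixed
# table by design — the method is single-point, nothing is ever minimised.
CAP_BOND_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34, "P": 1.42, "B": 1.19}
METHYL_BOND_LENGTHS = {"C": 1.54, "N": 1.47, "O": 1.43, "S": 1.81, "P": 1.85, "B": 1.55}
_METHYL_CH = 1.09
_TETRAHEDRAL = math.radians(109.471)
_CAP_CLASH = 0.5  # A; a cap landing this close to an existing atom is an error


class CapPlacementError(ValueError):
    """A cap could not be placed (degenerate direction or steric clash)."""


@dataclass
class FragmentDef:
    fragment_id: str
    atom_serials: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        self.atom_serials = frozenset(int(s) for s in self.atom_serials)
        if not self.label:
            self.label = self.fragment_id


@dataclass
class FragmentScheme:
    """Named partition of ligand heavy atoms + bonds to cut (1-based serials)."""

    fragments: list[FragmentDef]
    cut_bonds: list[tuple[int, int]] = field(default_factory=list)
    cap_kind: str = "hydrogen"

    def __post_init__(self) -> None:
        if self.cap_kind not in {"hydrogen", "methyl"}:
            raise ValueError(f"unknown cap kind {self.cap_kind!r}")
        self.cut_bonds = [(int(a), int(b)) for a, b in self.cut_bonds]
        ids = [f.fragment_id for f in self.fragments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate fragment ids")

    def fragment_of(self, serial: int) -> str | None:
        for f in self.fragments:
            if serial in f.atom_serials:
                return f.fragment_id
        return None

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "cap_kind": self.cap_kind,
            "fragments": [
                {"fragment_id": f.fragment_id, "label": f.label,
                 "atom_serials": sorted(f.atom_serials)}
                for f in self.fragments
            ],
            "cut_bonds": [list(b) for b in self.cut_bonds],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FragmentScheme":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith(".json")
        ) else str(source)
        doc = json.loads(text)
        return cls(
            fragments=[
                FragmentDef(f["fragment_id"], frozenset(f["atom_serials"]),
                            f.get("label", ""))
                for f in doc["fragments"]
            ],
            cut_bonds=[tuple(b) for b in doc.get("cut_bonds", [])],
            cap_kind=doc.get("cap_kind", "hydrogen"),
        )

    @classmethod
    def from_atom_map(cls, source: str | Path, cut_bonds=(), cap_kind="hydrogen"):
        """Build a scheme from a 2-column ``serial fragment_id`` map file."""
        groups: dict[str, set[int]] = {}
        for line in Path(source).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            serial, fid = line.split()[:2]
            groups.setdefault(fid, set()).add(int(serial))
        return cls(
            fragments=[FragmentDef(fid, frozenset(s)) for fid, s in groups.items()],
            cut_bonds=list(cut_bonds), cap_kind=cap_kind,
        )


@dataclass
class CappedFragment:
    """One fragment extracted as a molecule, with caps on every cut bond."""

    fragment_id: str
    label: str
    molecule: Molecule
    original_atom_serials: list[int]  # parent-ligand serials, in output order
    cap_atom_indices: list[int]       # indices (into molecule.atoms) of added caps
    nh: int                           # heavy atoms of the *original* fragment

    @property
    def n_caps(self) -> int:
        return len(self.cap_atom_indices)


@dataclass
class SchemeValidation:
    ok: bool
    missing_atoms: list[int]
    overlapping_atoms: list[int]
    extra_atoms: list[int]
    missing_cut_bonds: list[tuple[int, int]]
    bogus_cut_bonds: list[tuple[int, int]]
    intra_fragment_cuts: list[tuple[int, int]]
    ring_bond_cuts: list[tuple[int, int]]
    messages: list[str]


def _ligand_with_bonds(ligand: Molecule) -> Molecule:
    return ligand if ligand.bonds else perceive_bonds(ligand)


def validate_scheme(ligand: Molecule, scheme: FragmentScheme) -> SchemeValidation:
    """Check a scheme against a ligand: full heavy-atom coverage, no
    overlaps, and a cut bond for every inter-fragment ligand bond.

    Report-style — never raises; ``ok`` is True iff the scheme invariants
    hold. Ring-bond cuts are allowed but flagged (capping a ring bond with
    hydrogen cannot preserve the ring).
    """
    ligand = _ligand_with_bonds(ligand)
    heavy_serials = {ligand.atoms[i].serial for i in ligand.heavy_indices}
    all_serials = {a.serial for a in ligand.atoms}

    counts: dict[int, int] = {}
    for f in scheme.fragments:
        for s in f.atom_serials:
            counts[s] = counts.get(s, 0) + 1
    claimed = set(counts)
    overlapping = sorted(s for s, c in counts.items() if c > 1)
    missing = sorted(heavy_serials - claimed)
    extra = sorted(claimed - heavy_serials)

    ligand_bonds = set()
    for i, j, _ in ligand.bonds:
        a, b = ligand.atoms[i].serial, ligand.atoms[j].serial
        if a in heavy_serials and b in heavy_serials:
            ligand_bonds.add((min(a, b), max(a, b)))

    declared = {(min(a, b), max(a, b)) for a, b in scheme.cut_bonds}
    inter = {
        (a, b) for (a, b) in ligand_bonds
        if scheme.fragment_of(a) is not None and scheme.fragment_of(b) is not None
        and scheme.fragment_of(a) != scheme.fragment_of(b)
    }
    missing_cuts = sorted(inter - declared)
    bogus = sorted(b for b in declared if b not in ligand_bonds)
    intra = sorted(
        b for b in declared & ligand_bonds
        if scheme.fragment_of(b[0]) == scheme.fragment_of(b[1])
        and scheme.fragment_of(b[0]) is not None
    )
    ring_cuts = sorted(b for b in declared & ligand_bonds if _in_ring(ligand, b))

    msgs: list[str] = []
    if missing:
        msgs.append(f"heavy atoms not covered by any fragment: {missing}")
    if overlapping:
        msgs.append(f"heavy atoms claimed by more than one fragment: {overlapping}")
    if extra:
        bad = [s for s in extra if s not in all_serials]
        h = [s for s in extra if s in all_serials]
        if bad:
            msgs.append(f"fragment atoms not present in the ligand: {bad}")
        if h:
            msgs.append(f"fragment atom lists include hydrogens: {h}")
    if missing_cuts:
        msgs.append(f"inter-fragment ligand bonds missing from cut_bonds: {missing_cuts}")
    if bogus:
        msgs.append(f"cut_bonds that are not ligand bonds: {bogus}")
    if intra:
        msgs.append(f"cut_bonds internal to one fragment: {intra}")
    if ring_cuts:
        msgs.append(f"warning: cut_bonds inside rings: {ring_cuts}")

    ok = not (missing or overlapping or extra or missing_cuts or bogus or intra)
    return SchemeValidation(ok, missing, overlapping, extra, missing_cuts,
                            bogus, intra, ring_cuts, msgs)


def _in_ring(ligand: Molecule, bond: tuple[int, int]) -> bool:
    """A bond is in a ring iff its endpoints stay connected after removal."""
    ia, ib = ligand.index_by_serial(bond[0]), ligand.index_by_serial(bond[1])
    adj: dict[int, set[int]] = {}
    for i, j, _ in ligand.bonds:
        if {i, j} == {ia, ib}:
            continue
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    stack, seen = [ia], {ia}
    while stack:
        node = stack.pop()
        if node == ib:
            return True
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _orthonormal_pair(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, probe)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def place_cap(stub_atom: Atom, departed_coords: np.ndarray, cap_kind: str = "hydrogen",
              serial_start: int = 1) -> list[Atom]:
    """Build cap atom(s) replacing a departed bonded neighbour.

    Hydrogen cap: one H on the stub→departed unit vector at the tabulated
    X-H distance. Methyl cap: a C on that vector at the X-C single-bond
    distance plus three tetrahedral hydrogens in a fixed (staggered,
    deterministic) azimuthal orientation.
    """
    direction = np.asarray(departed_coords, float) - stub_atom.coords
    norm = float(np.linalg.norm(direction))
    if norm < 1e-8:
        raise CapPlacementError(
            f"zero-length cap direction at atom serial {stub_atom.serial}"
        )
    u = direction / norm
    el = stub_atom.element.upper()
    if cap_kind == "hydrogen":
        length = CAP_BOND_LENGTHS.get(el, 1.09)
        return [Atom(serial=serial_start, name="HCP", element="H",
                     coords=stub_atom.coords + length * u, record="HETATM",
                     res_name=stub_atom.res_name, res_seq=stub_atom.res_seq,
                     chain_id=stub_atom.chain_id)]
    if cap_kind == "methyl":
        length = METHYL_BOND_LENGTHS.get(el, 1.54)
        c_pos = stub_atom.coords + length * u
        atoms = [Atom(serial=serial_start, name="CCP", element="C", coords=c_pos,
                      record="HETATM", res_name=stub_atom.res_name,
                      res_seq=stub_atom.res_seq, chain_id=stub_atom.chain_id)]
        e1, e2 = _orthonormal_pair(u)
        for k in range(3):
            phi = 2.0 * math.pi * k / 3.0 + math.pi / 3.0  # staggered vs stub
            # H-C-stub angle is tetrahedral; the stub sits at -u from the cap C
            h_dir = (-math.cos(_TETRAHEDRAL) * u
                     + math.sin(_TETRAHEDRAL) * (math.cos(phi) * e1 + math.sin(phi) * e2))
            atoms.append(Atom(serial=serial_start + 1 + k, name=f"HC{k+1}",
                              element="H", coords=c_pos + _METHYL_CH * h_dir,
                              record="HETATM", res_name=stub_atom.res_name,
                              res_seq=stub_atom.res_seq, chain_id=stub_atom.chain_id))
        return atoms
    raise ValueError(f"unknown cap kind {cap_kind!r}")


def cut_and_cap(ligand: Molecule, scheme: FragmentScheme) -> list[CappedFragment]:
    """Extract every fragment of the scheme as a capped molecule.

    Each fragment keeps its heavy atoms *and their original hydrogens* at
    the parent-ligand coordinates (bit-identical), plus one cap per cut
    bond incident on the fragment. Deterministic: identical inputs give
    identical outputs, atoms ordered as in the parent ligand with caps
    appended.
    """
    report = validate_scheme(ligand, scheme)
    if not report.ok:
        raise ValueError("invalid fragment scheme: " + "; ".join(report.messages))
    ligand = _ligand_with_bonds(ligand)
    serial_to_index = {a.serial: i for i, a in enumerate(ligand.atoms)}
    cut_set = {(min(a, b), max(a, b)) for a, b in scheme.cut_bonds}

    out: list[CappedFragment] = []
    for frag in scheme.fragments:
        member_idx: set[int] = {serial_to_index[s] for s in frag.atom_serials}
        # original hydrogens ride along with their heavy atom
        for i, j, _ in ligand.bonds:
            if i in member_idx and ligand.atoms[j].is_hydrogen:
                member_idx.add(j)
            elif j in member_idx and ligand.atoms[i].is_hydrogen:
                member_idx.add(i)
        ordered = sorted(member_idx)
        index_map = {old: new for new, old in enumerate(ordered)}
        atoms = [replace(ligand.atoms[i], coords=ligand.atoms[i].coords.copy())
                 for i in ordered]
        bonds = [(index_map[i], index_map[j], o) for i, j, o in ligand.bonds
                 if i in index_map and j in index_map]

        next_serial = max((a.serial for a in atoms), default=0) + 1
        cap_indices: list[int] = []
        for (sa, sb) in sorted(cut_set):
            for stub_serial, departed_serial in ((sa, sb), (sb, sa)):
                if stub_serial not in frag.atom_serials:
                    continue
                if departed_serial in frag.atom_serials:
                    continue
                stub = ligand.atoms[serial_to_index[stub_serial]]
                departed = ligand.atoms[serial_to_index[departed_serial]]
                caps = place_cap(stub, departed.coords, scheme.cap_kind,
                                 serial_start=next_serial)
                for c in caps:
                    d = np.linalg.norm(
                        np.array([a.coords for a in atoms]) - c.coords, axis=1
                    )
                    too_close = d < _CAP_CLASH
                    # the stub itself is legitimately within bond distance
                    stub_pos = index_map[serial_to_index[stub_serial]]
                    if c is caps[0]:
                        too_close[stub_pos] = False
                    if np.any(too_close):
                        raise CapPlacementError(
                            f"cap for cut bond ({sa},{sb}) clashes with an atom of "
                            f"fragment {frag.fragment_id!r}"
                        )
                stub_new = index_map[serial_to_index[stub_serial]]
                base = len(atoms)
                atoms.extend(caps)
                bonds.append((stub_new, base, 1))
                for extra in range(1, len(caps)):  # methyl C-H bonds
                    bonds.append((base, base + extra, 1))
                cap_indices.extend(range(base, base + len(caps)))
                next_serial += len(caps)

        mol = Molecule(atoms=atoms, bonds=bonds,
                       provenance=f"{ligand.provenance} | fragment {frag.fragment_id}")
        nh = len(frag.atom_serials)
        out.append(CappedFragment(
            fragment_id=frag.fragment_id, label=frag.label, molecule=mol,
            original_atom_serials=[ligand.atoms[i].serial for i in ordered],
            cap_atom_indices=cap_indices, nh=nh,
        ))
    return out
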
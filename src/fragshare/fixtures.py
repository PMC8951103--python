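"""Synthetic receptor-ligand fixtures with analytically known scores.

The generator builds chemically minimal systems — an alkane-like ligand
chain plus isolated receptor "probe" atoms placed at controlled surface
distances — so that every pairwise term of the built-in scoring function is
exercised in a known regime and every stage of the partition chain can be
tested without any external structure. Expected per-fragment scores are
computed by :func:`closed_form_pair_sum`, a deliberately naive double loop
with the term formulas written out inline, independent of the production
scoring path.

Realism is not the goal; coverage and determinism are. Fixtures are exactly
reproducible for a fixed seed and round-trip through the PDB/PDBQT I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complex_io import (Atom, ComplexGeometry, Molecule, SFType,
                         assign_interaction_types, write_structure)
from .fragmentation import FragmentDef, FragmentScheme, cut_and_cap
from .scoring import SFParameters, get_builtin_params

__all__ = [
    "FixtureSpec",
    "make_toy_complex",
    "make_random_typed_pair",
    "closed_form_pair_sum",
    "write_fixture",
]

_CC_BOND = 1.54  # A, alkane C-C


@dataclass
class FixtureSpec:
    """Deterministic recipe for a toy complex.

    ``probe_plan`` lists (ligand_atom_index, surface_distance_A) pairs; by
    default three quarters of the probes sit over the first fragment and the
    rest over the last, at the Gaussian-optimum surface distance 0, so the
    first fragment dominates the partition roughly 3:1.
    """

    n_ligand_atoms: int = 8
    n_fragments: int = 2
    n_receptor_probes: int = 4
    ligand_topology: str = "linear"  # or "branched"
    bond_length: float = _CC_BOND
    probe_surface_distance: float = 0.0
    probe_plan: list[tuple[int, float]] | None = None
    probe_elements: tuple[str, ...] = ("C",)
    beyond_cutoff: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1 or self.n_fragments > self.n_ligand_atoms:
            raise ValueError("n_fragments must be in [1, n_ligand_atoms]")
        if self.ligand_topology not in {"linear", "branched"}:
            raise ValueError(f"unknown topology {self.ligand_topology!r}")
        if self.ligand_topology == "branched" and self.n_ligand_atoms < 4:
            raise ValueError("branched topology needs >= 4 atoms")


def _build_ligand(spec: FixtureSpec) -> Molecule:
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, int]] = []
    n = spec.n_ligand_atoms
    n_chain = n - 1 if spec.ligand_topology == "branched" else n
    for i in range(n_chain):
        atoms.append(Atom(serial=i + 1, name=f"C{i+1}", element="C",
                          coords=np.array([i * spec.bond_length, 0.0, 0.0]),
                          record="HETATM", res_name="LIG", res_seq=1, chain_id="L"))
        if i > 0:
            bonds.append((i - 1, i, 1))
    if spec.ligand_topology == "branched":
        mid = n_chain // 2
        atoms.append(Atom(serial=n_chain + 1, name=f"C{n_chain+1}", element="C",
                          coords=atoms[mid].coords + np.array([0.0, spec.bond_length, 0.0]),
                          record="HETATM", res_name="LIG", res_seq=1, chain_id="L"))
        bonds.append((mid, n_chain, 1))
    return Molecule(atoms=atoms, bonds=bonds, provenance=f"toy ligand seed={spec.seed}")


def _default_scheme(ligand: Molecule, n_fragments: int) -> FragmentScheme:
    serials = [a.serial for a in ligand.atoms]
    blocks = np.array_split(np.array(serials), n_fragments)
    frags = [FragmentDef(f"F{k+1}", frozenset(int(s) for s in blk))
             for k, blk in enumerate(blocks)]
    scheme = FragmentScheme(fragments=frags, cut_bonds=[], cap_kind="hydrogen")
    cut = []
    for i, j, _ in ligand.bonds:
        sa, sb = ligand.atoms[i].serial, ligand.atoms[j].serial
        if scheme.fragment_of(sa) != scheme.fragment_of(sb):
            cut.append((sa, sb))
    return FragmentScheme(fragments=frags, cut_bonds=cut, cap_kind="hydrogen")


def _probe_positions(spec: FixtureSpec, ligand: Molecule,
                     params: SFParameters) -> list[tuple[np.ndarray, str]]:
    plan = spec.probe_plan
    n = len(ligand.atoms)
    if plan is None:
        n_first = max(1, round(0.75 * spec.n_receptor_probes))
        first_block = list(range(min(n, max(1, n // spec.n_fragments))))
        plan = []
        for k in range(spec.n_receptor_probes):
            if k < n_first:
                target = first_block[k % len(first_block)]
            else:
                target = n - 1 - ((k - n_first) % max(1, n // spec.n_fragments))
            plan.append((target, spec.probe_surface_distance))
    offsets = [np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0]),
               np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    out = []
    table_radius = {"C": 1.9, "N": 1.8, "O": 1.7}
    for k, (atom_idx, d_surf) in enumerate(plan):
        el = spec.probe_elements[k % len(spec.probe_elements)]
        r_lig = 1.9  # all toy ligand atoms are carbon
        r = table_radius[el] + r_lig + d_surf
        if spec.beyond_cutoff:
            r = params.cutoff + 50.0
        pos = ligand.atoms[atom_idx].coords + r * offsets[k % len(offsets)]
        out.append((pos, el))
    return out


def make_toy_complex(spec: FixtureSpec, params: SFParameters | None = None
                     ) -> tuple[ComplexGeometry, FragmentScheme, dict[str, float]]:
    """Build a toy complex, its fragment scheme, and oracle fragment scores.

    The expected scores are computed with :func:`closed_form_pair_sum` on the
    hydrogen-capped fragments, exactly as the production chain will score
    them. Raises if two probes collide (< 1 A apart).
    """
    params = params or get_builtin_params("builtin_vina")
    ligand = _build_ligand(spec)
    scheme = _default_scheme(ligand, spec.n_fragments)

    probes = _probe_positions(spec, ligand, params)
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            if np.linalg.norm(probes[i][0] - probes[j][0]) < 1.0:
                raise ValueError(f"infeasible geometry: probes {i} and {j} collide")
    rec_atoms = [Atom(serial=k + 1, name=f"P{k+1}", element=el, coords=pos,
                      record="ATOM", res_name="PRB", res_seq=k + 1, chain_id="R")
                 for k, (pos, el) in enumerate(probes)]
    receptor = Molecule(atoms=rec_atoms, bonds=[],
                        provenance=f"toy receptor seed={spec.seed}")

    typed_receptor = assign_interaction_types(receptor)
    expected: dict[str, float] = {}
    for frag in cut_and_cap(ligand, scheme):
        typed_frag = assign_interaction_types(frag.molecule)
        expected[frag.fragment_id] = closed_form_pair_sum(typed_receptor, typed_frag, params)

    geometry = ComplexGeometry(receptor=receptor, ligand=ligand,
                               frame_note=f"synthetic toy fixture, seed={spec.seed}")
    return geometry, scheme, expected


def closed_form_pair_sum(receptor: Molecule, mol: Molecule,
                         params: SFParameters) -> float:
    """Independent scoring oracle: direct O(N*M) double loop, inline formulas.

    Kept free of any call into the production scoring path so the two can
    check each other.
    """
    w = params.weights
    s = params.shape
    total = 0.0
    for ra in receptor.atoms:
        if ra.is_hydrogen:
            continue
        for la in mol.atoms:
            if la.is_hydrogen:
                continue
            r = math.dist(tuple(ra.coords), tuple(la.coords))
            if r > params.cutoff:
                continue
            d = r - ra.sf_type.radius - la.sf_type.radius
            e = w["gauss1"] * math.exp(-(((d - s["gauss1_offset"]) / s["gauss1_width"]) ** 2))
            e += w["gauss2"] * math.exp(-(((d - s["gauss2_offset"]) / s["gauss2_width"]) ** 2))
            if d < 0:
                e += w["repulsion"] * d * d
            if ra.sf_type.hydrophobic and la.sf_type.hydrophobic:
                if d <= s["hydrophobic_good"]:
                    e += w["hydrophobic"]
                elif d < s["hydrophobic_bad"]:
                    e += w["hydrophobic"] * (s["hydrophobic_bad"] - d) / (
                        s["hydrophobic_bad"] - s["hydrophobic_good"])
            if (ra.sf_type.donor and la.sf_type.acceptor) or (
                    la.sf_type.donor and ra.sf_type.acceptor):
                if d <= s["hbond_good"]:
                    e += w["hbond"]
                elif d < s["hbond_bad"]:
                    e += w["hbond"] * (s["hbond_bad"] - d) / (
                        s["hbond_bad"] - s["hbond_good"])
            total += e
    return total


def make_random_typed_pair(rng: np.random.Generator, n_receptor: int = 30,
                           n_ligand: int = 10, box: float = 12.0
                           ) -> tuple[Molecule, Molecule]:
    """Random typed receptor/ligand pair for scoring property tests.

    Atoms get random positions in a box and random interaction types
    (radius, hydrophobic/donor/acceptor flags) drawn to cover every term
    regime, including close contacts in the repulsive region.
    """

    def random_atoms(n: int, chain: str, offset: np.ndarray) -> list[Atom]:
        atoms = []
        for k in range(n):
            el = rng.choice(["C", "N", "O", "S"])
            pos = offset + rng.uniform(-box / 2, box / 2, size=3)
            a = Atom(serial=k + 1, name=f"{el}{k+1}", element=str(el), coords=pos,
                     record="ATOM", res_name="RND", res_seq=k + 1, chain_id=chain)
            hydrophobic = bool(el == "C" and rng.random() < 0.7)
            donor = bool(el in {"N", "O"} and rng.random() < 0.5)
            acceptor = bool(el in {"N", "O"})
            radius = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0}[str(el)]
            a.sf_type = SFType(True, hydrophobic, donor, acceptor, radius)
            atoms.append(a)
        return atoms

    receptor = Molecule(atoms=random_atoms(n_receptor, "R", np.zeros(3)),
                        provenance="random receptor")
    ligand = Molecule(atoms=random_atoms(n_ligand, "L", np.array([2.0, 0.0, 0.0])),
                      provenance="random ligand")
    return receptor, ligand


def write_fixture(directory: str | Path, geometry: ComplexGeometry,
                  scheme: FragmentScheme) -> dict[str, Path]:
    """Emit receptor.pdb, ligand.pdb, ligand.pdbqt and scheme.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "receptor_pdb": write_structure(geometry.receptor, directory / "receptor.pdb"),
        "ligand_pdb": write_structure(geometry.ligand, directory / "ligand.pdb"),
        "ligand_pdbqt": write_structure(geometry.ligand, directory / "ligand.pdbqt"),
    }
    scheme.to_json(directory / "scheme.json")
    paths["scheme_json"] = directory / "scheme.json"
    return paths
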
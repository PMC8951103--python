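"""Single-point protein-ligand scoring.

Two built-in backends implement the empirical pairwise functional form used
by AutoDock Vina: a sum over intermolecular heavy-atom pairs of five terms
of the surface distance d = r - R_i - R_j — two Gaussians, a quadratic
repulsion for d < 0, and piecewise-linear hydrophobic and hydrogen-bond
ramps — with weights read from versioned parameter files (``vina_default``
and the Vinardo re-parameterisation ``vinardo_default``). Everything is
score-only: a fixed conformation, no intramolecular terms, no search.

External score-only programs plug in through :class:`BackendAdapter`, a
contract describing how to invoke the executable and parse one scalar back;
the package ships no external binary and never needs one.
"""

from __future__ import annotations

import json
import re
import subprocess
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .complex_io import Molecule

__all__ = [
    "ScoreValue",
    "SFParameters",
    "BackendAdapter",
    "ScoringError",
    "ExternalBackendError",
    "TERM_NAMES",
    "pair_terms",
    "score_pose",
    "external_score",
    "get_builtin_params",
    "BUILTIN_BACKENDS",
]

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")

KCAL_PER_MOL = "kcal_per_mol"
PKD = "pKd"
KNOWLEDGE_BASED = "knowledge_based_units"
UNITLESS = "unitless"

NEGATIVE_IS_BETTER = "negative_is_better"
POSITIVE_IS_BETTER = "positive_is_better"


class ScoringError(ValueError):
    """Molecules not typed / empty, or parameters unusable."""


class ExternalBackendError(RuntimeError):
    """External scorer failed; carries the captured output."""

    def __init__(self, message: str, output: str = ""):
        super().__init__(message)
        self.output = output


@dataclass(frozen=True)
class ScoreValue:
    value: float
    units: str
    backend_id: str
    favorable_direction: str = NEGATIVE_IS_BETTER
    provenance: dict = field(default_factory=dict)

    @property
    def favorable_magnitude(self) -> float:
        """Score mapped so that favorable is positive, unfavorable negative."""
        return -self.value if self.favorable_direction == NEGATIVE_IS_BETTER else self.value


@dataclass(frozen=True)
class SFParameters:
    """Weights and shape constants of the built-in empirical form."""

    weights: dict[str, float]
    shape: dict[str, float]
    cutoff: float = 8.0
    rotor_weight: float = 0.05846
    parameter_set_id: str = "custom"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        missing = set(TERM_NAMES) - set(self.weights)
        if missing:
            raise ValueError(f"missing term weights: {sorted(missing)}")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[t] for t in TERM_NAMES], dtype=float)

    @classmethod
    def from_file(cls, path: str | Path) -> "SFParameters":
        doc = json.loads(Path(path).read_text())
        return cls(weights=doc["weights"], shape=doc["shape"],
                   cutoff=doc.get("cutoff", 8.0),
                   rotor_weight=doc.get("rotor_weight", 0.05846),
                   parameter_set_id=doc.get("parameter_set_id", "custom"))


def _load_builtin(name: str) -> SFParameters:
    ref = resources.files("fragshare.params") / f"{name}.json"
    doc = json.loads(ref.read_text())
    return SFParameters(weights=doc["weights"], shape=doc["shape"],
                        cutoff=doc["cutoff"], rotor_weight=doc["rotor_weight"],
                        parameter_set_id=doc["parameter_set_id"])


BUILTIN_BACKENDS = ("builtin_vina", "builtin_vinardo")


def get_builtin_params(backend_id: str) -> SFParameters:
    if backend_id in {"builtin_vina", "vina_default"}:
        return _load_builtin("vina")
    if backend_id in {"builtin_vinardo", "vinardo_default"}:
        return _load_builtin("vinardo")
    raise KeyError(f"unknown built-in backend {backend_id!r}; "
                   f"available: {list(BUILTIN_BACKENDS)}")


def pair_terms(surface_distance: float, types_i, types_j,
               params: SFParameters) -> np.ndarray:
    """Unweighted term vector (gauss1, gauss2, repulsion, hydrophobic, hbond)
    for one heavy-atom pair at the given surface distance (A).

    The hydrophobic term is nonzero only when both atoms are hydrophobic;
    the H-bond term only for donor-acceptor pairs.
    """
    d = float(surface_distance)
    s = params.shape
    g1 = np.exp(-(((d - s["gauss1_offset"]) / s["gauss1_width"]) ** 2))
    g2 = np.exp(-(((d - s["gauss2_offset"]) / s["gauss2_width"]) ** 2))
    rep = d * d if d < 0.0 else 0.0

    phob = 0.0
    if types_i.hydrophobic and types_j.hydrophobic:
        good, bad = s["hydrophobic_good"], s["hydrophobic_bad"]
        if d <= good:
            phob = 1.0
        elif d < bad:
            phob = (bad - d) / (bad - good)

    hb = 0.0
    if (types_i.donor and types_j.acceptor) or (types_j.donor and types_i.acceptor):
        good, bad = s["hbond_good"], s["hbond_bad"]
        if d <= good:
            hb = 1.0
        elif d < bad:
            hb = (bad - d) / (bad - good)

    return np.array([g1, g2, rep, phob, hb])


def _typed_heavy(mol: Molecule, role: str):
    idx, coords, radii, types = [], [], [], []
    for i, a in enumerate(mol.atoms):
        if a.is_hydrogen:
            continue
        if a.sf_type is None:
            raise ScoringError(
                f"{role} atom {a.serial} ({a.name}) has no interaction type; "
                "run assign_interaction_types first"
            )
        idx.append(i)
        coords.append(a.coords)
        radii.append(a.sf_type.radius)
        types.append(a.sf_type)
    return idx, np.array(coords, float), np.array(radii, float), types


def score_pose(receptor: Molecule, mol: Molecule, params: SFParameters,
               apply_nrot_scaling: bool = False) -> ScoreValue:
    """Single-point score of ``mol`` against ``receptor`` in their shared frame.

    Sum over intermolecular heavy-atom pairs within the interatomic cutoff
    of the weighted pair terms; kcal/mol, negative favorable. With
    ``apply_nrot_scaling`` the sum is divided by (1 + w_rot * N_rot) using
    the molecule's recorded rotatable-bond count — whole-ligand,
    LE-style scoring; fragment shares are computed without it.
    """
    if len(mol.atoms) == 0:
        raise ScoringError("cannot score an empty molecule")
    _, rec_xyz, rec_r, rec_t = _typed_heavy(receptor, "receptor")
    _, lig_xyz, lig_r, lig_t = _typed_heavy(mol, "ligand")
    if len(lig_xyz) == 0:
        raise ScoringError("molecule has no heavy atoms to score")

    total = 0.0
    w = params.weight_vector()
    if len(rec_xyz):
        tree = cKDTree(rec_xyz)
        for j, lx in enumerate(lig_xyz):
            for i in tree.query_ball_point(lx, params.cutoff):
                r = float(np.linalg.norm(rec_xyz[i] - lx))
                if r > params.cutoff:
                    continue
                d = r - rec_r[i] - lig_r[j]
                total += float(w @ pair_terms(d, rec_t[i], lig_t[j], params))

    n_rot = mol.n_rotatable or 0
    if apply_nrot_scaling:
        total /= 1.0 + params.rotor_weight * n_rot
    return ScoreValue(
        value=total, units=KCAL_PER_MOL, backend_id=params.parameter_set_id,
        favorable_direction=NEGATIVE_IS_BETTER,
        provenance={"parameter_set_id": params.parameter_set_id,
                    "nrot_scaling": bool(apply_nrot_scaling),
                    "n_rotatable": n_rot},
    )


@dataclass(frozen=True)
class BackendAdapter:
    """Contract for an external score-only program.

    ``command_template`` is a list of argv tokens; ``{receptor}`` and
    ``{ligand}`` are substituted with file paths. ``parse_pattern`` is a
    regex whose first group captures the scalar score in the program's
    stdout/stderr.
    """

    backend_id: str
    command_template: list[str]
    parse_pattern: str
    units: str = KCAL_PER_MOL
    favorable_direction: str = NEGATIVE_IS_BETTER

    @classmethod
    def from_config(cls, doc: dict) -> "BackendAdapter":
        return cls(backend_id=doc["id"], command_template=list(doc["command"]),
                   parse_pattern=doc["pattern"],
                   units=doc.get("units", KCAL_PER_MOL),
                   favorable_direction=doc.get("direction", NEGATIVE_IS_BETTER))


def external_score(adapter: BackendAdapter, receptor_file: str | Path,
                   mol_file: str | Path) -> ScoreValue:
    """Run an external scorer in score-only mode and parse one scalar."""
    argv = [tok.format(receptor=str(receptor_file), ligand=str(mol_file))
            for tok in adapter.command_template]
    proc = subprocess.run(argv, capture_output=True, text=True)
    output = proc.stdout + proc.stderr
    if proc.returncode != 0:
        raise ExternalBackendError(
            f"backend {adapter.backend_id!r} exited with {proc.returncode}", output)
    m = re.search(adapter.parse_pattern, output)
    if not m:
        raise ExternalBackendError(
            f"backend {adapter.backend_id!r}: pattern {adapter.parse_pattern!r} "
            "matched nothing", output)
    try:
        value = float(m.group(1))
    except (IndexError, ValueError) as exc:
        raise ExternalBackendError(
            f"backend {adapter.backend_id!r}: captured group is not a number",
            output) from exc
    return ScoreValue(value=value, units=adapter.units,
                      backend_id=adapter.backend_id,
                      favorable_direction=adapter.favorable_direction,
                      provenance={"argv": argv, "raw_output": output})
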
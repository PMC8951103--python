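"""Docking-pose selection against a crystal reference of the anchor fragment.

Docking ranks poses by score, but scores rank binding modes poorly; when the
crystal position of a core ("anchor") fragment is known from a smaller
complex, the pose to analyse is the one whose anchor atoms lie closest — by
plain RMSD, *without* superposition, since poses and reference already share
the receptor frame — to that experimental position. Fitting before the RMSD
would defeat the positional criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complex_io import Molecule, read_models
from .scoring import ScoreValue

__all__ = [
    "PoseSet",
    "Pose",
    "AnchorReference",
    "CorrespondenceError",
    "anchor_rmsd",
    "select_pose",
    "read_pose_set",
]

RMSD_TIE_TOL = 0.01  # A; poses closer than this are tied, broken by score


class CorrespondenceError(ValueError):
    """Reference atoms could not be matched to pose atoms."""


@dataclass
class Pose:
    rank: int
    ligand: Molecule
    score: ScoreValue | None = None


@dataclass
class PoseSet:
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = [p.rank for p in self.poses]
        if len(ranks) != len(set(ranks)):
            raise ValueError("pose ranks must be unique")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class AnchorReference:
    """Crystal-coordinate reference for the anchor fragment.

    ``correspondence`` names how reference heavy atoms map onto pose atoms:
    ``"by_atom_name"`` (default), or an explicit ``{ref_serial: pose_serial}``
    map. At least 3 corresponded heavy atoms are required for a meaningful
    positional RMSD.
    """

    molecule: Molecule
    correspondence: str | dict[int, int] = "by_atom_name"

    def resolve(self, pose: Molecule, anchor_atom_serials: set[int] | None) -> list[tuple[int, int]]:
        """Return (ref_index, pose_index) pairs over reference heavy atoms."""
        ref_heavy = [i for i in self.molecule.heavy_indices]
        pairs: list[tuple[int, int]] = []
        unmatched: list[str] = []
        allowed = None
        if anchor_atom_serials is not None:
            allowed = {int(s) for s in anchor_atom_serials}
        if isinstance(self.correspondence, dict):
            serial_to_pose = {a.serial: k for k, a in enumerate(pose.atoms)}
            for i in ref_heavy:
                rs = self.molecule.atoms[i].serial
                ps = self.correspondence.get(rs)
                if ps is None or ps not in serial_to_pose:
                    unmatched.append(f"serial {rs}")
                    continue
                if allowed is not None and ps not in allowed:
                    continue
                pairs.append((i, serial_to_pose[ps]))
        elif self.correspondence == "by_atom_name":
            name_to_pose: dict[str, int] = {}
            for k, a in enumerate(pose.atoms):
                if a.is_hydrogen:
                    continue
                if allowed is not None and a.serial not in allowed:
                    continue
                name_to_pose.setdefault(a.name, k)
            for i in ref_heavy:
                name = self.molecule.atoms[i].name
                if name in name_to_pose:
                    pairs.append((i, name_to_pose[name]))
                else:
                    unmatched.append(f"name {name!r}")
        else:
            raise ValueError(f"unknown correspondence spec {self.correspondence!r}")
        if unmatched:
            raise CorrespondenceError(
                "reference atoms with no pose counterpart: " + ", ".join(unmatched)
            )
        if len(pairs) < 3:
            raise CorrespondenceError(
                f"only {len(pairs)} corresponded heavy atoms; need at least 3"
            )
        return pairs


def anchor_rmsd(pose: Molecule, anchor_atom_serials: set[int] | None,
                ref: AnchorReference) -> float:
    """Heavy-atom RMSD (A) of the pose's anchor atoms to the reference,
    in the shared receptor frame (no superposition)."""
    pairs = ref.resolve(pose, anchor_atom_serials)
    diffs = np.array([
        pose.atoms[pi].coords - ref.molecule.atoms[ri].coords
        for ri, pi in pairs
    ])
    return float(np.sqrt(np.mean(np.sum(diffs * diffs, axis=1))))


def select_pose(poses: PoseSet, anchor_atom_serials: set[int] | None,
                ref: AnchorReference) -> tuple[int, pd.DataFrame]:
    """Pick the pose minimising anchor RMSD; near-ties (< 0.01 A) go to the
    better docking score. Returns (chosen rank, full RMSD-vs-rank table)."""
    if len(poses) == 0:
        raise ValueError("empty pose set")
    rows = []
    for p in poses.poses:
        rows.append({
            "rank": p.rank,
            "anchor_rmsd": anchor_rmsd(p.ligand, anchor_atom_serials, ref),
            "score": p.score.value if p.score is not None else np.nan,
        })
    table = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)

    best_rmsd = table["anchor_rmsd"].min()
    tied = table[table["anchor_rmsd"] <= best_rmsd + RMSD_TIE_TOL]
    if len(tied) > 1 and tied["score"].notna().any():
        # favorable direction: all built-in / Vina-style scores are
        # negative-is-better; adapters with the opposite convention should
        # pre-negate before building the PoseSet
        chosen = int(tied.loc[tied["score"].idxmin(), "rank"])
    else:
        chosen = int(tied.iloc[0]["rank"])
    table["chosen"] = table["rank"] == chosen
    return chosen, table


def read_pose_set(path: str | Path, format: str | None = None) -> PoseSet:
    """Read a multi-model PDB / multi-pose PDBQT file into a PoseSet.

    Pose ranks follow MODEL numbers; AutoDock Vina ``REMARK VINA RESULT``
    scores are attached when present.
    """
    poses = []
    for mol, meta in read_models(path, format):
        sv = None
        if meta.get("vina_score") is not None:
            sv = ScoreValue(value=float(meta["vina_score"]), units="kcal_per_mol",
                            backend_id="vina_remark")
        poses.append(Pose(rank=int(meta.get("model", len(poses) + 1)),
                          ligand=mol, score=sv))
    return PoseSet(poses=poses)
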
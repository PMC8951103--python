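"""End-to-end partition analysis across scoring backends, with decision flags.

For each backend the chain is: cut-and-cap the ligand per the scheme, score
every capped fragment in place against the receptor, normalise the scores
into stakeholder shares, scale the input affinity into per-fragment energy
contributions, and convert those to group efficiencies. Per-backend columns
are aggregated into a consensus table (unweighted mean +- SD of GE across
backends — GE is unit-consistent even when raw backend scores are not).

Decision heuristics on the consensus:

* ``below_threshold`` — mean GE under the drug-likeness threshold
  (0.30 kcal/mol/atom by default); the lowest of these is the suggested
  optimisation focus.
* ``anchor_violation`` — some non-anchor fragment's mean |E_scaled| matches
  or exceeds the anchor fragment's. The anchor is the experimentally placed
  fragment the whole growth strategy rests on; a grown arm out-contributing
  it signals a spurious binding mode, and the pose should not be used for
  further optimisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complex_io import ComplexGeometry, assign_interaction_types
from .efficiency import DEFAULT_GE_THRESHOLD, group_efficiency
from .fragmentation import FragmentScheme, cut_and_cap, validate_scheme
from .partition import (BindingAffinity, FragmentScoreSet, scaled_contributions,
                        share_vector)
from .scoring import SFParameters, get_builtin_params, score_pose

__all__ = ["ConsensusTable", "run_partition_analysis", "flag_decisions"]


@dataclass
class ConsensusTable:
    """Per-fragment consensus across backends plus full provenance."""

    frame: pd.DataFrame  # one row per fragment
    backends: list[str]
    affinity: BindingAffinity
    raw_scores: dict[str, list[tuple[str, float]]]  # backend -> (fragment, score)
    metadata: dict = field(default_factory=dict)
    threshold: float = DEFAULT_GE_THRESHOLD
    anchor_fragment_id: str | None = None

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "backends": self.backends,
            "affinity": {"delta_e_mol_kcal_mol": self.affinity.delta_e_mol,
                         "source": self.affinity.source,
                         "note": self.affinity.note},
            "threshold_kcal_mol_atom": self.threshold,
            "anchor_fragment_id": self.anchor_fragment_id,
            "metadata": self.metadata,
            "raw_scores": {b: dict(v) for b, v in self.raw_scores.items()},
            "fragments": self.frame.to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _resolve_backend(backend) -> tuple[str, SFParameters]:
    if isinstance(backend, SFParameters):
        return backend.parameter_set_id, backend
    if isinstance(backend, str):
        params = get_builtin_params(backend)
        return params.parameter_set_id, params
    raise TypeError(f"backend must be a builtin id or SFParameters, got {backend!r}")


def run_partition_analysis(
    complex_geometry: ComplexGeometry,
    scheme: FragmentScheme,
    backends: list,
    affinity: BindingAffinity,
    mixed_sign_policy: str = "error",
    threshold: float = DEFAULT_GE_THRESHOLD,
) -> ConsensusTable:
    """Run the full fragment-contribution chain for every backend.

    ``backends`` may mix built-in backend ids (``builtin_vina``,
    ``builtin_vinardo``) and explicit :class:`SFParameters`. Raw per-fragment
    scores are kept in the result for audit; regeneration of the table from
    them is deterministic.
    """
    if not backends:
        raise ValueError("at least one scoring backend is required")
    report = validate_scheme(complex_geometry.ligand, scheme)
    if not report.ok:
        raise ValueError("fragment scheme invalid for this ligand: "
                         + "; ".join(report.messages))

    fragments = cut_and_cap(complex_geometry.ligand, scheme)
    receptor = assign_interaction_types(complex_geometry.receptor)

    per_backend: dict[str, dict] = {}
    raw_scores: dict[str, list[tuple[str, float]]] = {}
    for backend in backends:
        backend_id, params = _resolve_backend(backend)
        try:
            scored = []
            for frag in fragments:
                typed = assign_interaction_types(frag.molecule)
                scored.append((frag.fragment_id, score_pose(receptor, typed, params)))
            score_set = FragmentScoreSet.from_score_values(scored)
            shares = share_vector(score_set, mixed_sign_policy=mixed_sign_policy)
            contribs = scaled_contributions(shares, affinity)
            nh_by_id = {f.fragment_id: f.nh for f in fragments}
            records = {}
            for c in contribs:
                c.nh = nh_by_id[c.fragment_id]
                ge_rec = group_efficiency(c, threshold=threshold)
                records[c.fragment_id] = {
                    "score": dict(score_set.entries)[c.fragment_id],
                    "omega": c.omega, "e_scaled": c.e_scaled, "ge": ge_rec.ge,
                }
            per_backend[backend_id] = records
            raw_scores[backend_id] = list(score_set.entries)
        except Exception as exc:
            raise RuntimeError(
                f"partition analysis failed at backend {backend_id!r}: {exc}"
            ) from exc

    rows = []
    for frag in fragments:
        row = {"fragment_id": frag.fragment_id, "label": frag.label, "nh": frag.nh,
               "n_caps": frag.n_caps}
        for backend_id, records in per_backend.items():
            rec = records[frag.fragment_id]
            row[f"score[{backend_id}]"] = rec["score"]
            row[f"omega[{backend_id}]"] = rec["omega"]
            row[f"e_scaled[{backend_id}]"] = rec["e_scaled"]
            row[f"ge[{backend_id}]"] = rec["ge"]
        ges = [per_backend[b][frag.fragment_id]["ge"] for b in per_backend]
        es = [per_backend[b][frag.fragment_id]["e_scaled"] for b in per_backend]
        row["ge_mean"] = float(np.mean(ges))
        row["ge_sd"] = float(np.std(ges, ddof=1)) if len(ges) > 1 else 0.0
        row["e_scaled_mean"] = float(np.mean(es))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["below_threshold"] = frame["ge_mean"] < threshold

    table = ConsensusTable(
        frame=frame, backends=[_resolve_backend(b)[0] for b in backends],
        affinity=affinity, raw_scores=raw_scores, threshold=threshold,
        metadata={
            "frame_note": complex_geometry.frame_note,
            "receptor": complex_geometry.receptor.provenance,
            "ligand": complex_geometry.ligand.provenance,
            "cap_kind": scheme.cap_kind,
            "mixed_sign_policy": mixed_sign_policy,
        },
    )
    return table


def flag_decisions(table: ConsensusTable,
                   threshold: float | None = None,
                   anchor_fragment_id: str | None = None,
                   anchor_slack: float = 0.0) -> ConsensusTable:
    """Annotate a consensus table with decision flags.

    Sets ``below_threshold`` per fragment, names the ``optimization_focus``
    (lowest mean GE among below-threshold fragments, or an explicit
    no-suboptimal-fragment note), and — when an anchor is given — raises
    ``anchor_violation`` if any non-anchor fragment's mean contribution
    magnitude reaches the anchor's within ``anchor_slack`` (kcal/mol).
    """
    thr = table.threshold if threshold is None else threshold
    frame = table.frame.copy()
    frame["below_threshold"] = frame["ge_mean"] < thr

    below = frame[frame["below_threshold"]]
    if len(below):
        focus = below.loc[below["ge_mean"].idxmin(), "fragment_id"]
        note = f"optimization focus: fragment {focus!r} (lowest mean GE)"
    else:
        focus = None
        note = "no suboptimal fragment: all GE values at or above threshold"

    anchor_violation = False
    violators: list[str] = []
    if anchor_fragment_id is not None:
        if anchor_fragment_id not in set(frame["fragment_id"]):
            raise KeyError(f"unknown anchor fragment id {anchor_fragment_id!r}")
        anchor_mag = abs(float(
            frame.loc[frame["fragment_id"] == anchor_fragment_id,
                      "e_scaled_mean"].iloc[0]))
        for _, row in frame.iterrows():
            if row["fragment_id"] == anchor_fragment_id:
                continue
            if abs(row["e_scaled_mean"]) >= anchor_mag - anchor_slack:
                anchor_violation = True
                violators.append(row["fragment_id"])
        frame["anchor_violation"] = frame["fragment_id"].isin(violators)
    else:
        frame["anchor_violation"] = False

    out = ConsensusTable(
        frame=frame, backends=table.backends, affinity=table.affinity,
        raw_scores=table.raw_scores, threshold=thr,
        anchor_fragment_id=anchor_fragment_id,
        metadata={**table.metadata,
                  "optimization_focus": focus,
                  "decision_note": note,
                  "anchor_violation": anchor_violation,
                  "anchor_violators": violators,
                  "anchor_slack_kcal_mol": anchor_slack},
    )
    return out
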
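"""Stakeholder partition of a binding affinity into fragment contributions.

Per-fragment single-point scores are normalised into unitless shares

    omega_j = Score(Fragment_j) / sum_i Score(Fragment_i)

and the shares scale the whole-molecule interaction energy into additive
contributions E_scaled_j = omega_j * dE_mol, which by construction conserve
the total: sum_j E_scaled_j = dE_mol. Because the share is a ratio, any
common multiplicative error of the scoring backend cancels exactly — the
reason the scheme is robust to the backend choice — and any backend's units
(kcal/mol, pKd, knowledge-based) can be used: scores are mapped so that
*favorable is positive* before normalisation, and only dE_mol carries
kcal/mol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .scoring import NEGATIVE_IS_BETTER, KCAL_PER_MOL, ScoreValue

__all__ = [
    "FragmentScoreSet",
    "ShareVector",
    "BindingAffinity",
    "ContributionRecord",
    "PartitionError",
    "MixedSignError",
    "NearZeroSumError",
    "share_vector",
    "scaled_contributions",
    "records_to_frame",
    "records_to_json",
]

NEAR_ZERO_TOL = 1e-6  # |sum of scores| below this (backend units) is degenerate


class PartitionError(ValueError):
    pass


class MixedSignError(PartitionError):
    """Favorable and unfavorable fragment scores mixed under the strict policy."""


class NearZeroSumError(PartitionError):
    """Score sum too close to zero for shares to be meaningful."""


@dataclass
class FragmentScoreSet:
    """Per-fragment scores from one backend, in one unit."""

    backend_id: str
    units: str
    entries: list[tuple[str, float]]
    favorable_direction: str = NEGATIVE_IS_BETTER

    def __post_init__(self) -> None:
        if not self.entries:
            raise PartitionError("a score set needs at least one fragment entry")
        ids = [fid for fid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise PartitionError("duplicate fragment ids in score set")

    @classmethod
    def from_score_values(cls, scores: list[tuple[str, ScoreValue]]) -> "FragmentScoreSet":
        if not scores:
            raise PartitionError("empty score list")
        backends = {sv.backend_id for _, sv in scores}
        units = {sv.units for _, sv in scores}
        directions = {sv.favorable_direction for _, sv in scores}
        if len(backends) > 1 or len(units) > 1 or len(directions) > 1:
            raise PartitionError(
                f"scores mix backends/units: {backends} / {units}"
            )
        return cls(backend_id=backends.pop(), units=units.pop(),
                   entries=[(fid, sv.value) for fid, sv in scores],
                   favorable_direction=directions.pop())

    def favorable_magnitudes(self) -> list[tuple[str, float]]:
        """Scores mapped so favorable binding is a positive number."""
        sign = -1.0 if self.favorable_direction == NEGATIVE_IS_BETTER else 1.0
        return [(fid, sign * v) for fid, v in self.entries]


@dataclass
class ShareVector:
    entries: list[tuple[str, float]]
    backend_id: str = ""
    mixed_sign: bool = False
    near_zero_sum: bool = False
    clipped: bool = False

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise PartitionError(f"shares must sum to 1 (got {total!r})")

    @property
    def omegas(self) -> list[float]:
        return [w for _, w in self.entries]

    @property
    def fragment_ids(self) -> list[str]:
        return [fid for fid, _ in self.entries]


@dataclass
class BindingAffinity:
    """The interaction energy to be partitioned, kcal/mol, negative favorable."""

    delta_e_mol: float
    source: str = "scored"  # experimental_kd / experimental_ki / experimental_ic50 / scored
    note: str = ""

    def __post_init__(self) -> None:
        if not pd.notna(self.delta_e_mol) or self.delta_e_mol in (float("inf"), float("-inf")):
            raise PartitionError("delta_e_mol must be finite")


@dataclass
class ContributionRecord:
    fragment_id: str
    omega: float
    e_scaled: float  # kcal/mol, signed
    label: str = ""
    score: float | None = None
    score_units: str | None = None
    nh: int | None = None
    ge: float | None = None
    meta: dict = field(default_factory=dict)


def share_vector(scores: FragmentScoreSet,
                 mixed_sign_policy: str = "error",
                 near_zero_tol: float = NEAR_ZERO_TOL) -> ShareVector:
    """Compute the stakeholder shares from per-fragment scores.

    Scores are first mapped so favorable is positive. If favorable and
    unfavorable values are mixed, the shares would leave [0, 1]:
    ``mixed_sign_policy='error'`` (default) raises; ``'clip_to_zero'``
    zeroes the unfavorable entries before normalising and flags the result.
    A score sum within ``near_zero_tol`` of zero is always an error (shares
    would blow up).
    """
    if mixed_sign_policy not in {"error", "clip_to_zero"}:
        raise ValueError(f"unknown mixed-sign policy {mixed_sign_policy!r}")
    mags = scores.favorable_magnitudes()
    values = [v for _, v in mags]
    has_pos = any(v > 0 for v in values)
    has_neg = any(v < 0 for v in values)
    mixed = has_pos and has_neg
    clipped = False
    if mixed:
        if mixed_sign_policy == "error":
            raise MixedSignError(
                "fragment scores mix favorable and unfavorable values; shares "
                "would leave [0,1]. Use mixed_sign_policy='clip_to_zero' to "
                "zero the unfavorable fragments explicitly."
            )
        mags = [(fid, max(v, 0.0)) for fid, v in mags]
        clipped = True
    total = sum(v for _, v in mags)
    if abs(total) < near_zero_tol:
        raise NearZeroSumError(
            f"|sum of fragment scores| = {abs(total):.3g} < {near_zero_tol:g}; "
            "shares are undefined"
        )
    entries = [(fid, v / total) for fid, v in mags]
    return ShareVector(entries=entries, backend_id=scores.backend_id,
                       mixed_sign=mixed, near_zero_sum=False, clipped=clipped)


def scaled_contributions(shares: ShareVector,
                         affinity: BindingAffinity) -> list[ContributionRecord]:
    """Scale the whole-molecule energy by the shares: E_scaled_j = omega_j * dE_mol.

    Conservation (sum_j E_scaled_j = dE_mol) holds by construction since the
    shares sum to one.
    """
    return [
        ContributionRecord(fragment_id=fid, omega=w,
                           e_scaled=w * affinity.delta_e_mol,
                           meta={"affinity_source": affinity.source,
                                 "backend_id": shares.backend_id})
        for fid, w in shares.entries
    ]


def records_to_frame(records: list[ContributionRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"fragment_id": r.fragment_id, "label": r.label or r.fragment_id,
         "score": r.score, "score_units": r.score_units, "omega": r.omega,
         "e_scaled_kcal_mol": r.e_scaled, "nh": r.nh, "ge": r.ge}
        for r in records
    ])


def records_to_json(records: list[ContributionRecord],
                    path: str | Path | None = None) -> str:
    text = json.dumps(records_to_frame(records).to_dict(orient="records"), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
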
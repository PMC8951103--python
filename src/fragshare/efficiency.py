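"""Ligand efficiency, group efficiency, and measurement-to-energy conversion.

LE = -dG / NH (kcal/mol per heavy atom, positive favorable) compares
binders of different sizes; GE is its per-fragment analog, dividing a
fragment's scaled energy contribution by the fragment's own heavy-atom
count. Experimental K_D / K_i / IC50 values convert to free energies via
dG = RT ln(K); the IC50 route is an approximation (it ignores the assay's
substrate dependence) and is flagged as such.

The commonly used drug-likeness threshold is 0.30 kcal/mol/atom: fragments
below it are candidates for further optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .partition import BindingAffinity, ContributionRecord

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_GE_THRESHOLD",
    "ThermoContext",
    "GroupEfficiencyRecord",
    "delta_g_from_measurement",
    "ligand_efficiency",
    "group_efficiency",
]

GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal / (mol K)
DEFAULT_GE_THRESHOLD = 0.30        # kcal/mol/atom, the usual LE cut for drug-like


@dataclass(frozen=True)
class ThermoContext:
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def rt(self) -> float:
        """RT in kcal/mol (~0.593 at 298.15 K)."""
        return GAS_CONSTANT_KCAL * self.temperature


@dataclass(frozen=True)
class GroupEfficiencyRecord:
    fragment_id: str
    ge: float  # kcal/mol/atom, positive favorable
    nh: int
    below_threshold: bool
    threshold: float = DEFAULT_GE_THRESHOLD


def delta_g_from_measurement(value: float, kind: str,
                             ctx: ThermoContext = ThermoContext()) -> BindingAffinity:
    """Convert an experimental K_D / K_i / IC50 (molar) to dG = RT ln(value).

    Sub-molar binders give negative (favorable) energies; 1 M gives 0.
    """
    kind = kind.lower()
    if kind not in {"kd", "ki", "ic50"}:
        raise ValueError(f"unknown measurement kind {kind!r} (expected kd/ki/ic50)")
    if not (value > 0):
        raise ValueError(f"measurement must be a positive molar concentration, got {value!r}")
    dg = ctx.rt * math.log(value)
    note = f"RT ln({value:g} M) at T = {ctx.temperature:g} K"
    if kind == "ic50":
        note += " [IC50 route: approximation, assay-dependent]"
    return BindingAffinity(delta_e_mol=dg, source=f"experimental_{kind}", note=note)


def ligand_efficiency(affinity: BindingAffinity | float, nh: int) -> float:
    """LE = -dG / NH, kcal/mol per heavy atom, positive for favorable binding.

    Full precision is kept; round to 2 decimals only when reporting.
    """
    if nh < 1:
        raise ValueError(f"NH must be >= 1, got {nh}")
    dg = affinity.delta_e_mol if isinstance(affinity, BindingAffinity) else float(affinity)
    return -dg / nh


def group_efficiency(contrib: ContributionRecord,
                     threshold: float = DEFAULT_GE_THRESHOLD) -> GroupEfficiencyRecord:
    """GE_j = E_scaled_j / NH_j, reported positive-favorable like LE.

    For a single-fragment scheme this reduces exactly to the ligand's LE.
    """
    if contrib.nh is None or contrib.nh < 1:
        raise ValueError(
            f"fragment {contrib.fragment_id!r}: NH must be a positive heavy-atom "
            f"count, got {contrib.nh!r} (a fragment of only hydrogens cannot "
            "carry a group efficiency)"
        )
    ge = -contrib.e_scaled / contrib.nh
    return GroupEfficiencyRecord(
        fragment_id=contrib.fragment_id, ge=ge, nh=contrib.nh,
        below_threshold=ge < threshold, threshold=threshold,
    )
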
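"""Phospholipid compositions and cholesterol phase boundaries.

Lens fiber-cell membranes are mixtures of four phospholipid (PL) classes —
phosphatidylcholine (PC), phosphatidylethanolamine (PE), phosphatidylserine
(PS) and sphingomyelin (SM) — loaded with cholesterol (Chol) up to and beyond
its saturation limit.  Two Chol contents matter:

* the **saturation limit**, above which pure-cholesterol bilayer domains
  (CBDs) form inside the PL bilayer, and
* the **cholesterol solubility threshold (CST)**, above which Chol crystals
  form outside the bilayer.

For a PL mixture both boundaries are modelled as the mole-fraction-weighted
sum of the per-PL boundaries taken from an EPR/DSC fluid phase diagram of
the binary PL/Chol systems.  Per-PL defaults live in
``data/phase_boundaries.json`` (PE 33/50, PC=PS=SM 50/66 mol% Chol) and can
be overridden, since literature CST values depend strongly on how the
bilayers were prepared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping

__all__ = [
    "PL_CLASSES",
    "PLComposition",
    "PhaseBoundaryParams",
    "PhaseState",
    "Phase",
    "normalize_composition",
    "predict_saturation_limit",
    "predict_cst",
    "ratio_to_molpercent",
    "molpercent_to_ratio",
    "classify_phase",
    "default_phase_boundaries",
    "load_species_presets",
]

PL_CLASSES = ("PC", "PE", "PS", "SM")

_NORM_TOL = 1e-9


def _load_data(name: str) -> dict:
    with resources.files("lensepr.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PLComposition:
    """A normalized phospholipid headgroup composition.

    ``fractions`` holds mole fractions over the PL-only pool (Chol excluded)
    for each of PC, PE, PS, SM; they sum to 1.  ``raw_molpercent`` keeps the
    values as given, which need not sum to 100 (e.g. when DHSM has been
    folded into SM).
    """

    species_label: str
    fractions: Mapping[str, float]
    raw_molpercent: Mapping[str, float] = field(default_factory=dict)
    lifespan_years: float | None = None

    def __post_init__(self) -> None:
        if set(self.fractions) != set(PL_CLASSES):
            raise ValueError(f"fractions keys must be exactly {PL_CLASSES}")
        for pl, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative mole fraction for {pl}: {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"fractions sum to {total!r}, expected 1")


@dataclass(frozen=True)
class PhaseBoundaryParams:
    """Per-PL cholesterol phase boundaries in mol% Chol."""

    sat_limit_per_pl: Mapping[str, float]
    cst_per_pl: Mapping[str, float]

    def __post_init__(self) -> None:
        for pl in PL_CLASSES:
            sat = self.sat_limit_per_pl[pl]
            cst = self.cst_per_pl[pl]
            if not (0 < sat < cst < 100):
                raise ValueError(
                    f"{pl}: need 0 < sat_limit ({sat}) < cst ({cst}) < 100"
                )


class Phase(str, Enum):
    """Membrane phase state with respect to cholesterol content."""

    UNIFORM_PL_CHOL = "UNIFORM_PL_CHOL"
    WITH_CBD = "WITH_CBD"
    WITH_CBD_AND_CRYSTALS = "WITH_CBD_AND_CRYSTALS"


@dataclass(frozen=True)
class PhaseState:
    phase: Phase
    chol_molpercent: float
    boundaries: tuple[float, float]  # (saturation limit, CST), mol% Chol


def default_phase_boundaries() -> PhaseBoundaryParams:
    """Phase-boundary defaults from the binary PL/Chol phase diagram."""
    data = _load_data("phase_boundaries.json")
    return PhaseBoundaryParams(
        sat_limit_per_pl=data["sat_limit_per_pl"],
        cst_per_pl=data["cst_per_pl"],
    )


def load_species_presets() -> dict[str, PLComposition]:
    """Shipped species composition presets (mouse, pig, human), normalized."""
    data = _load_data("species_presets.json")
    out = {}
    for entry in data["presets"]:
        comp = normalize_composition(
            entry["molpercent"], species_label=entry["species"]
        )
        out[entry["species"]] = PLComposition(
            species_label=comp.species_label,
            fractions=comp.fractions,
            raw_molpercent=comp.raw_molpercent,
            lifespan_years=entry["lifespan_years"],
        )
    return out


def normalize_composition(
    raw_molpercent: Mapping[str, float], species_label: str = ""
) -> PLComposition:
    """Normalize mol% values (any positive total) to mole fractions.

    Printed lens compositions do not sum to 100 because DHSM was merged into
    SM as total sphingolipid; normalization makes the PL-only pool explicit.
    Missing PL classes get fraction 0.
    """
    unknown = set(raw_molpercent) - set(PL_CLASSES)
    if unknown:
        raise ValueError(f"unknown PL classes: {sorted(unknown)}")
    for pl, v in raw_molpercent.items():
        if v < 0:
            raise ValueError(f"negative mol% for {pl}: {v}")
    total = sum(raw_molpercent.values())
    if total <= 0:
        raise ValueError("empty composition")
    fractions = {pl: raw_molpercent.get(pl, 0.0) / total for pl in PL_CLASSES}
    return PLComposition(
        species_label=species_label,
        fractions=fractions,
        raw_molpercent=dict(raw_molpercent),
    )


def _weighted_sum(comp: PLComposition, per_pl: Mapping[str, float]) -> float:
    return sum(comp.fractions[pl] * per_pl[pl] for pl in PL_CLASSES)


def predict_saturation_limit(
    comp: PLComposition, params: PhaseBoundaryParams | None = None
) -> float:
    """Chol saturation limit (mol%) of a PL mixture.

    Weighted sum of per-PL saturation limits with weights equal to the PL
    mole fractions of the PL-only pool.
    """
    params = params or default_phase_boundaries()
    return _weighted_sum(comp, params.sat_limit_per_pl)


def predict_cst(
    comp: PLComposition, params: PhaseBoundaryParams | None = None
) -> float:
    """Chol solubility threshold (mol%) of a PL mixture (weighted sum)."""
    params = params or default_phase_boundaries()
    return _weighted_sum(comp, params.cst_per_pl)


def ratio_to_molpercent(r: float) -> float:
    """Convert a Chol/PL mole mixing ratio to mol% Chol: 100*r/(1+r)."""
    if r < 0:
        raise ValueError(f"mixing ratio must be >= 0, got {r}")
    return 100.0 * r / (1.0 + r)


def molpercent_to_ratio(m: float) -> float:
    """Convert mol% Chol to a Chol/PL mole mixing ratio: m/(100-m)."""
    if not (0 <= m < 100):
        raise ValueError(f"mol% must be in [0, 100), got {m}")
    return m / (100.0 - m)


def classify_phase(
    comp: PLComposition,
    chol_molpercent: float,
    params: PhaseBoundaryParams | None = None,
) -> PhaseState:
    """Classify the membrane phase state at a given Chol content.

    Exactly at a boundary the lower-phase label is kept: a domain starts to
    form strictly above its threshold.
    """
    if not (0 <= chol_molpercent < 100):
        raise ValueError(f"mol% must be in [0, 100), got {chol_molpercent}")
    params = params or default_phase_boundaries()
    sat = predict_saturation_limit(comp, params)
    cst = predict_cst(comp, params)
    if chol_molpercent <= sat:
        phase = Phase.UNIFORM_PL_CHOL
    elif chol_molpercent <= cst:
        phase = Phase.WITH_CBD
    else:
        phase = Phase.WITH_CBD_AND_CRYSTALS
    return PhaseState(
        phase=phase, chol_molpercent=chol_molpercent, boundaries=(sat, cst)
    )
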
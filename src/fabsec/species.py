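"""Immune-complex species: composition, classification, fluorescence weighting.

A species is a (drug, ADA, Fab) composition at a concentration.  The SEC
assay detects only the dye on the Fab, so a species' fluorescence
contribution is proportional to concentration x number of Fabs it carries
(``n_fab``), except the free dye and the unspecific serum component, which
carry one fluorophore-equivalent each.

``n_fab`` is a float: with the Fab in excess it saturates the two epitopes
per drug (``n_fab = 2*n_drug``), but when drug sites outnumber the Fab, or
when steric crowding in large complexes displaces Fab, the effective
occupancy per drug is lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["SpeciesClass", "ComplexSpecies"]


class SpeciesClass(str, Enum):
    FREE_DYE = "FREE_DYE"
    FAB488 = "FAB488"
    DRUG_FAB = "DRUG_FAB"
    ADA1_DRUG1 = "ADA1_DRUG1"
    ADA1_DRUG2 = "ADA1_DRUG2"
    LARGE_COMPLEX = "LARGE_COMPLEX"
    UNSPECIFIC = "UNSPECIFIC"


@dataclass(frozen=True)
class ComplexSpecies:
    """A molecular species with composition counts and concentration (nM).

    ``n_fab`` may not exceed the available epitopes, ``2 * n_drug`` (two Fab
    epitopes per drug molecule), except for the pure detection reagent
    (``n_drug == 0, n_fab == 1``).
    """

    n_drug: float
    n_ada: float
    n_fab: float
    concentration: float
    label: SpeciesClass | None = None

    def __post_init__(self) -> None:
        if min(self.n_drug, self.n_ada, self.n_fab, self.concentration) < 0:
            raise ValueError("counts and concentration must be non-negative")
        if self.n_drug > 0 and self.n_fab > 2 * self.n_drug + 1e-9:
            raise ValueError("n_fab may not exceed 2 * n_drug")

    @property
    def species_class(self) -> SpeciesClass:
        if self.label is not None:
            return self.label
        if self.n_drug == 0 and self.n_ada == 0:
            return SpeciesClass.FAB488 if self.n_fab > 0 else SpeciesClass.FREE_DYE
        if self.n_ada == 0:
            return SpeciesClass.DRUG_FAB
        if self.n_ada == 1 and self.n_drug == 1:
            return SpeciesClass.ADA1_DRUG1
        if self.n_ada == 1 and self.n_drug == 2:
            return SpeciesClass.ADA1_DRUG2
        return SpeciesClass.LARGE_COMPLEX

    @property
    def fluorescence_weight(self) -> float:
        """Fluorophore-equivalents per particle (dye and unspecific count as 1)."""
        cls = self.species_class
        if cls in (SpeciesClass.FREE_DYE, SpeciesClass.UNSPECIFIC):
            return 1.0
        return self.n_fab

    @property
    def fluorescence_abundance(self) -> float:
        """Concentration-weighted fluorescence, the species' trace area in nM-equivalents."""
        return self.concentration * self.fluorescence_weight

    # convenience constructors -------------------------------------------------
    @staticmethod
    def free_dye(concentration: float) -> "ComplexSpecies":
        return ComplexSpecies(0, 0, 0, concentration, label=SpeciesClass.FREE_DYE)

    @staticmethod
    def free_fab(concentration: float) -> "ComplexSpecies":
        return ComplexSpecies(0, 0, 1, concentration, label=SpeciesClass.FAB488)

    @staticmethod
    def unspecific(area: float) -> "ComplexSpecies":
        return ComplexSpecies(0, 0, 0, area, label=SpeciesClass.UNSPECIFIC)
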
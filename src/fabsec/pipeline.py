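"""End-to-end analyses: ADA-titration complex profiling, precipitation mass
balance, and multi-dose timecourse quantification of study samples.

The mass-balance inversion corrects for the volume split of the
fractionation: the pellet lane of the gel receives all precipitated protein
*plus* the soluble protein dissolved in the pellet fraction's share of the
reaction volume (20% by default), so a fully soluble protein already shows
20% of its band intensity in the pellet lane.  Precipitation is therefore
whatever exceeds that baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatogram import (Chromatogram, SpeciesWindow, integrate_window,
                           percent_complex)
from .species import ComplexSpecies, SpeciesClass

__all__ = [
    "ComplexSpecies", "PelletQuant", "PelletFraction", "TimecoursePoint",
    "pellet_mass_balance", "ada_series_analysis", "AdaSeriesResult",
    "timecourse_analysis", "TimecourseResult", "concordance_check",
    "ConcordanceReport", "LBA_LLOQ_UG_ML", "SEC_SENSITIVITY_SERUM_UG_ML",
]

#: lower limit of quantitation of the ligand-binding assay (µg/mL serum);
#: below-quantitation values are carried as a flag with this bound, never as zero
LBA_LLOQ_UG_ML = 0.136
#: SEC detection bound for drug in 100% serum (µg/mL)
SEC_SENSITIVITY_SERUM_UG_ML = 10.0

#: drug-linked species classes (fluorescence attributable to drug)
DRUG_LINKED_CLASSES = (SpeciesClass.DRUG_FAB, SpeciesClass.ADA1_DRUG1,
                       SpeciesClass.ADA1_DRUG2, SpeciesClass.LARGE_COMPLEX)


@dataclass
class PelletQuant:
    """Densitometry of one fractionated sample: band intensity per protein
    in the pellet and supernatant lanes, plus the volume split."""

    pellet: dict[str, float]
    supernatant: dict[str, float]
    pellet_volume_fraction: float = 0.20
    supernatant_volume_fraction: float = 0.80

    def __post_init__(self) -> None:
        if abs(self.pellet_volume_fraction + self.supernatant_volume_fraction - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if not (0 < self.pellet_volume_fraction < 1):
            raise ValueError("pellet volume fraction must be in (0, 1)")
        for lane in (self.pellet, self.supernatant):
            if any(v < 0 for v in lane.values()):
                raise ValueError("band intensities must be non-negative")
        if set(self.pellet) != set(self.supernatant):
            raise ValueError("pellet and supernatant lanes must list the same proteins")


@dataclass(frozen=True)
class PelletFraction:
    fraction: float
    clipped: bool


def pellet_mass_balance(q: PelletQuant) -> dict[str, PelletFraction]:
    """Per-protein precipitated fraction from the two-lane densitometry.

    With volume fractions ``v_p + v_s = 1``, the soluble amount is
    ``S_lane / v_s`` and the precipitated amount ``P_lane - v_p * soluble``.
    The fraction precipitated is clipped to [0, 1]; clipping (which arises
    from densitometry noise producing a slightly negative precipitate
    estimate) is flagged, never silent.
    """
    out: dict[str, PelletFraction] = {}
    for protein in q.pellet:
        p, s = q.pellet[protein], q.supernatant[protein]
        if p + s == 0:
            raise ValueError(f"both lanes are zero for {protein!r}")
        soluble = s / q.supernatant_volume_fraction
        precipitated = p - q.pellet_volume_fraction * soluble
        frac = precipitated / (precipitated + soluble)
        clipped = frac < 0 or frac > 1
        out[protein] = PelletFraction(min(max(frac, 0.0), 1.0), clipped)
    return out


# ---------------------------------------------------------------------------
# ADA titration series

@dataclass
class AdaSeriesResult:
    table: pd.DataFrame
    argmax_conc: float
    decline_from_max: float


def ada_series_analysis(series: Sequence[tuple[float, Chromatogram]],
                        calibration: Sequence[SpeciesWindow]) -> AdaSeriesResult:
    """Percent-complex profile across an ADA concentration series.

    Reports, per sample, the ADA-window shares and the overall % complex,
    plus the concentration of maximal complex detection and the relative
    decline from that maximum to the highest-ADA sample (the signature of
    complex precipitation at antibody excess).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 ADA concentrations")
    rows = []
    for ada_conc, chrom in series:
        row = {"ada_conc_nM": ada_conc,
               "percent_complex": percent_complex(chrom, calibration)}
        for w in calibration:
            row[f"percent_{w.species_class.value}"] = \
                integrate_window(chrom, w).percent_of_total
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("ada_conc_nM", ignore_index=True)
    pc = table["percent_complex"].to_numpy()
    imax = int(np.argmax(pc))
    decline = 1.0 - pc[-1] / pc[imax] if pc[imax] > 0 else 0.0
    return AdaSeriesResult(table, float(table["ada_conc_nM"].iloc[imax]), float(decline))


# ---------------------------------------------------------------------------
# Study timecourse

@dataclass
class TimecoursePoint:
    """One study sample: dose number, nominal time offset, SEC trace, and the
    orthogonal read-outs (ligand-binding assay, western densitometry)."""

    dose_index: int
    time_offset: str
    chromatogram: Chromatogram | None
    lba_conc: float | None = None       # µg/mL in 100% serum; None when BQL
    lba_bql: bool = False
    western_intensity: float | None = None
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dose_index < 1:
            raise ValueError("dose_index must be >= 1")


@dataclass
class TimecourseResult:
    table: pd.DataFrame
    peak_time: dict[str, tuple[int, str]]   # class -> (dose_index, time_offset)


def timecourse_analysis(points: Sequence[TimecoursePoint],
                        calibration: Sequence[SpeciesWindow]) -> TimecourseResult:
    """Quantify free drug and complex classes across a dosing timecourse.

    All points share one retention calibration.  Points without a
    chromatogram are skipped with a warning.  The unspecific serum window is
    reported but excluded from the drug-linked total.
    """
    rows = []
    for pt in points:
        if pt.chromatogram is None:
            warnings.warn(f"dose {pt.dose_index} {pt.time_offset}: missing "
                          "chromatogram, point skipped")
            continue
        row = {"dose_index": pt.dose_index, "time_offset": pt.time_offset}
        drug_linked = 0.0
        for w in calibration:
            pct = integrate_window(pt.chromatogram, w).percent_of_total
            row[f"percent_{w.species_class.value}"] = pct
            if w.species_class in DRUG_LINKED_CLASSES:
                drug_linked += pct
        row["drug_linked_percent"] = drug_linked
        row["lba_conc_ug_ml"] = pt.lba_conc
        row["lba_bql"] = pt.lba_bql
        row["western_intensity"] = pt.western_intensity
        rows.append(row)
    table = pd.DataFrame(rows)
    peak_time: dict[str, tuple[int, str]] = {}
    for cls in DRUG_LINKED_CLASSES:
        col = f"percent_{cls.value}"
        if col in table.columns and table[col].max() > 0:
            i = int(table[col].idxmax())
            peak_time[cls.value] = (int(table.loc[i, "dose_index"]),
                                    str(table.loc[i, "time_offset"]))
    return TimecourseResult(table, peak_time)


@dataclass
class ConcordanceReport:
    n_discordant: int
    discordant: list[tuple[int, str]]
    n_checked: int


def concordance_check(points: Sequence[TimecoursePoint],
                      calibration: Sequence[SpeciesWindow],
                      sec_bound_serum_ug_ml: float = SEC_SENSITIVITY_SERUM_UG_ML,
                      min_detectable_percent: float = 0.01) -> ConcordanceReport:
    """Cross-check the SEC assay against the ligand-binding assay.

    A sample is discordant when the LBA reports drug above the SEC
    sensitivity bound in serum but the trace carries no drug-linked
    fluorescence.  On internally consistent data the count is zero.
    """
    discordant: list[tuple[int, str]] = []
    n_checked = 0
    for pt in points:
        if pt.lba_conc is None or pt.lba_bql or pt.chromatogram is None:
            continue
        n_checked += 1
        if pt.lba_conc <= sec_bound_serum_ug_ml:
            continue
        drug_linked = sum(
            integrate_window(pt.chromatogram, w).percent_of_total
            for w in calibration if w.species_class in DRUG_LINKED_CLASSES)
        if drug_linked < min_detectable_percent:
            discordant.append((pt.dose_index, pt.time_offset))
    return ConcordanceReport(len(discordant), discordant, n_checked)
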
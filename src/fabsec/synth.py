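"""Seeded generators for every input the pipeline consumes.

Each generator emulates one experiment of the assay-characterisation study:

* :func:`gen_titration` — drug titration (1–2500 nM) into 678 nM detection
  Fab in 20% serum, rendered as SEC traces with a drug-free blank, for the
  detection-limit analysis.
* :func:`gen_kd_points` — the 22-point saturation titration (585 nM Fab,
  0.32–20560.8 nM drug, site-doubled) used for the equilibrium K_D fit.
* :func:`gen_sensorgrams` — the SPR concentration series (0.49–2000 nM
  analyte, 300 s association / 600 s dissociation).
* :func:`gen_ada_series` — anti-drug-antibody titrations against a fixed
  drug/Fab mixture, with complex-size redistribution and precipitation at
  ADA excess, plus the matching supernatant/pellet densitometry.
* :func:`gen_study` — a multi-dose serum timecourse with SEC traces,
  ligand-binding-assay values and western intensities.

Every generator exposes its pre-noise truth alongside the data so recovery
tests can assert against it.  Identical seeds give bit-identical output.

The complex-composition rule in :func:`gen_ada_series` is a scenario of this
module, not a measured property: class fractions, the precipitation curve
and the Fab retention of large complexes are calibrated once so that the
default series peaks at 1.5 µM ADA and that at 3.5 µM ADA the pellet holds
40% of the drug, 20% of the ADA and 20% of the Fab.  The analysis stages are
scenario-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding
from .binding import (BindingCurveParams, effective_site_concentration,
                      mass_to_molar, signal_model, solve_bound_complex)
from .chromatogram import (Chromatogram, SpeciesWindow, default_calibration,
                           render_chromatogram)
from .kdfit import TitrationPoint
from .pipeline import PelletQuant, TimecoursePoint
from .species import ComplexSpecies, SpeciesClass
from .spr import KineticParams, Sensorgram, simulate_sensorgram

__all__ = ["GeneratorConfig", "gen_titration", "gen_kd_points",
           "gen_sensorgrams", "gen_ada_series", "gen_study",
           "TitrationData", "AdaSeriesData"]

#: broad serum-background component (autofluorescence / weak unspecific
#: binding of the Fab to serum proteins): centre (min), sigma (min), area.
#: The area is a one-time calibration of the blank's complex-window share so
#: that the default titration reproduces the assay's stated sensitivity
#: (S/N > 1.5 first reached at 10 nM drug).
SERUM_BACKGROUND = (14.0, 2.0, 134.0)

#: free-dye carry-over in the detection reagent (nM fluorophore-equivalents)
FREE_DYE_NM = 30.0


@dataclass
class GeneratorConfig:
    """Truths and noise levels shared by the generators.

    Defaults are the study conditions: K_D 22.5 nM for the SEC equilibrium,
    18.2 nM for SPR kinetics, 678 nM (detection) or 585 nM (K_D titration)
    Fab, and modest instrument noise.
    """

    seed: int = 0
    kd_nM: float = 22.5
    a_total_nM: float = 678.0
    chrom_noise_sd: float = 1.0       # AU on the rendered trace
    sensorgram_noise_sd: float = 0.5  # RU
    densitometry_cv: float = 0.05
    titration_cv: float = 0.02        # multiplicative noise on % bound
    spr_kon: float = 1e5              # 1/(M*s)
    spr_kd_nM: float = 18.2
    spr_rmax: float = 37.0            # RU
    calibration: list[SpeciesWindow] = field(default_factory=default_calibration)
    scenario: str = "default"

    def __post_init__(self) -> None:
        for name in ("chrom_noise_sd", "sensorgram_noise_sd",
                     "densitometry_cv", "titration_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# Detection-limit titration (drug into fixed Fab, 20% serum)

#: default drug concentrations (nM in assay) for the sensitivity titration
TITRATION_CONCS_NM = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 125.0, 250.0,
                      500.0, 830.0, 1250.0, 2500.0)


@dataclass
class TitrationData:
    samples: list[tuple[float, Chromatogram]]
    blank: Chromatogram
    truth: dict


def _titration_species(conc_nm: float, a_total: float, kd: float
                       ) -> tuple[list[ComplexSpecies], float]:
    """Species mix at one drug concentration; returns (species, bound Fab)."""
    species = [ComplexSpecies.free_dye(FREE_DYE_NM)]
    bound = 0.0
    if conc_nm > 0:
        sites = effective_site_concentration(conc_nm, 2)
        bound = solve_bound_complex(a_total, sites, kd)
        species.append(ComplexSpecies(1, 0, bound / conc_nm, conc_nm))
    free_fab = a_total - bound
    if free_fab > 0:
        species.append(ComplexSpecies.free_fab(free_fab))
    return species, bound


def gen_titration(config: GeneratorConfig | None = None) -> TitrationData:
    """Drug titration into 678 nM Fab in 20% serum, with a drug-free blank.

    At each concentration the drug partitions between free and Fab-bound
    sites by the closed-form equilibrium at the configured K_D; the bound
    Fab carries the complex-peak fluorescence.  The broad serum background
    present in every run (including the blank) is what gives the drug-free
    control its nonzero complex-window share.
    """
    config = config or GeneratorConfig()
    rng = config.rng(stream=1)
    truth_bound = {}
    samples = []
    for conc in TITRATION_CONCS_NM:
        species, bound = _titration_species(conc, config.a_total_nM, config.kd_nM)
        truth_bound[conc] = bound
        samples.append((conc, render_chromatogram(
            species, config.calibration, noise_sd=config.chrom_noise_sd,
            seed=rng, extra_components=[SERUM_BACKGROUND],
            label=f"drug_{conc:g}nM")))
    blank_species, _ = _titration_species(0.0, config.a_total_nM, config.kd_nM)
    blank = render_chromatogram(
        blank_species, config.calibration, noise_sd=config.chrom_noise_sd,
        seed=rng, extra_components=[SERUM_BACKGROUND], label="blank")
    return TitrationData(samples, blank,
                         truth={"bound_fab_nM": truth_bound,
                                "kd_nM": config.kd_nM,
                                "a_total_nM": config.a_total_nM})


# ---------------------------------------------------------------------------
# Equilibrium K_D titration points

KD_TITRATION_A_NM = 585.0
KD_TITRATION_DRUG_RANGE_NM = (0.32, 20560.8)
KD_TITRATION_N_POINTS = 22


def gen_kd_points(config: GeneratorConfig | None = None,
                  noiseless: bool = False) -> list[TitrationPoint]:
    """22 log-spaced points of the saturation titration (585 nM Fab).

    Drug concentrations span 0.32–20560.8 nM and enter site-doubled; the
    observable is the complex share of total fluorescence on a 0–100 scale,
    with multiplicative Gaussian noise of the configured CV.
    """
    config = config or GeneratorConfig()
    rng = config.rng(stream=2)
    lo, hi = KD_TITRATION_DRUG_RANGE_NM
    drug = np.geomspace(lo, hi, KD_TITRATION_N_POINTS)
    x = effective_site_concentration(drug, 2)
    params = BindingCurveParams(0.0, 100.0, config.kd_nM)
    y = signal_model(x, params, KD_TITRATION_A_NM)
    if not noiseless and config.titration_cv > 0:
        y = y * (1.0 + rng.normal(0.0, config.titration_cv, size=y.shape))
    return [TitrationPoint(float(xi), float(yi)) for xi, yi in zip(x, y)]


# ---------------------------------------------------------------------------
# SPR sensorgram series

SPR_CONCS_NM = tuple(np.geomspace(0.49, 2000.0, 12))
SPR_T_ASSOC_S = 300.0
SPR_T_DISSOC_S = 600.0


def gen_sensorgrams(config: GeneratorConfig | None = None,
                    noiseless: bool = False) -> list[Sensorgram]:
    """Twelve-concentration analyte series (0.49–2000 nM) at the kinetic truth."""
    config = config or GeneratorConfig()
    rng = config.rng(stream=3)
    koff = config.spr_kon * config.spr_kd_nM * 1e-9
    params = KineticParams(config.spr_kon, koff, config.spr_rmax)
    sd = 0.0 if noiseless else config.sensorgram_noise_sd
    return [simulate_sensorgram(params, c, SPR_T_ASSOC_S, SPR_T_DISSOC_S,
                                noise_sd=sd, seed=rng)
            for c in SPR_CONCS_NM]


# ---------------------------------------------------------------------------
# ADA complex series with precipitation

ADA_SERIES_DRUG_NM = 830.0
ADA_SERIES_FAB_NM = 678.0
ADA_SERIES_CONCS_NM = (0.0, 750.0, 1500.0, 2000.0, 3500.0)

# scenario tables: drug-class fractions, large-complex precipitation and Fab
# retention, interpolated over ADA concentration (see module docstring)
_ADA_KNOTS = np.array([0.0, 750.0, 1500.0, 2000.0, 3500.0])
_FRAC_DRUG_FAB = np.array([1.00, 0.55, 0.25, 0.15, 0.10])
_FRAC_AD1 = np.array([0.00, 0.15, 0.25, 0.22, 0.10])
_FRAC_AD2 = np.array([0.00, 0.25, 0.30, 0.25, 0.12])
_FRAC_LARGE = np.array([0.00, 0.05, 0.20, 0.38, 0.68])
#: fraction of LARGE_COMPLEX drug that precipitates
_PRECIP_OF_LARGE = np.array([0.00, 0.05, 0.15, 0.40, 0.40 / 0.68])
#: Fab retained per drug in LARGE_COMPLEX relative to the soluble occupancy
#: (steric crowding displaces Fab from large lattices; calibrated so the
#: pellet carries 20% of the Fab at 3.5 µM ADA)
_LARGE_FAB_RETENTION = np.array([1.00, 0.90, 0.80, 0.60, 0.511])
#: ADA per drug in LARGE_COMPLEX (antibody-rich lattices; calibrated so the
#: pellet carries 20% of the ADA at 3.5 µM ADA)
_LARGE_ADA_PER_DRUG = 700.0 / 332.0


@dataclass
class AdaSeriesData:
    samples: list[tuple[float, Chromatogram]]
    pellets: dict[float, PelletQuant]
    truth: dict


def _ada_partition(ada_nm: float, drug_nm: float, fab_nm: float, kd: float) -> dict:
    """Pre-noise truth of the species distribution at one ADA concentration."""
    sites = effective_site_concentration(drug_nm, 2)
    bound_fab = solve_bound_complex(fab_nm, sites, kd)
    occ = bound_fab / drug_nm                      # Fab per drug molecule
    f_free = float(np.interp(ada_nm, _ADA_KNOTS, _FRAC_DRUG_FAB))
    f_ad1 = float(np.interp(ada_nm, _ADA_KNOTS, _FRAC_AD1))
    f_ad2 = float(np.interp(ada_nm, _ADA_KNOTS, _FRAC_AD2))
    f_large = float(np.interp(ada_nm, _ADA_KNOTS, _FRAC_LARGE))
    p_large = float(np.interp(ada_nm, _ADA_KNOTS, _PRECIP_OF_LARGE))
    eta = float(np.interp(ada_nm, _ADA_KNOTS, _LARGE_FAB_RETENTION))

    drug_large = f_large * drug_nm
    drug_pellet = drug_large * p_large
    drug_large_sol = drug_large - drug_pellet
    fab_pellet = drug_pellet * occ * eta
    ada_pellet = drug_pellet * _LARGE_ADA_PER_DRUG if ada_nm > 0 else 0.0

    fab_bound_sol = (f_free + f_ad1 + f_ad2) * drug_nm * occ + drug_large_sol * occ * eta
    fab_free = fab_nm - fab_bound_sol - fab_pellet
    return {
        "occ": occ,
        "drug": {"free_fab_class": f_free * drug_nm, "ad1": f_ad1 * drug_nm,
                 "ad2": f_ad2 * drug_nm, "large_soluble": drug_large_sol,
                 "pellet": drug_pellet},
        "fab": {"bound_soluble": fab_bound_sol, "free": fab_free,
                "pellet": fab_pellet},
        "ada": {"pellet": ada_pellet},
        "eta": eta,
        "pellet_fraction": {
            "huDVD": drug_pellet / drug_nm,
            "ADA": ada_pellet / ada_nm if ada_nm > 0 else 0.0,
            "Fab488": fab_pellet / fab_nm,
        },
    }


def _pellet_lanes(fraction: float, rng: np.random.Generator, cv: float,
                  v_p: float = 0.20, v_s: float = 0.80) -> tuple[float, float]:
    """Forward-simulate the two lane intensities for one protein."""
    p = fraction + v_p * (1.0 - fraction)
    s = v_s * (1.0 - fraction)
    if cv > 0:
        p *= max(1.0 + rng.normal(0.0, cv), 0.0)
        s *= max(1.0 + rng.normal(0.0, cv), 0.0)
    return p, s


def gen_ada_series(config: GeneratorConfig | None = None) -> AdaSeriesData:
    """ADA titration against 830 nM drug / 678 nM Fab, with precipitation.

    Drug redistributes from the binary drug-Fab complex into ADA complexes
    of increasing size as ADA rises; at antibody excess a growing share of
    the largest complexes precipitates and is removed from the trace and
    routed to the pellet densitometry.  Total drug (soluble + pellet) is
    conserved exactly.
    """
    config = config or GeneratorConfig()
    rng = config.rng(stream=4)
    samples: list[tuple[float, Chromatogram]] = []
    pellets: dict[float, PelletQuant] = {}
    truth: dict = {"partition": {}}
    for ada in ADA_SERIES_CONCS_NM:
        part = _ada_partition(ada, ADA_SERIES_DRUG_NM, ADA_SERIES_FAB_NM,
                              config.kd_nM)
        truth["partition"][ada] = part
        occ, eta = part["occ"], part["eta"]
        d = part["drug"]
        species = [ComplexSpecies.free_dye(FREE_DYE_NM)]
        if d["free_fab_class"] > 0:
            species.append(ComplexSpecies(1, 0, occ, d["free_fab_class"]))
        if d["ad1"] > 0:
            species.append(ComplexSpecies(1, 1, occ, d["ad1"]))
        if d["ad2"] > 0:
            species.append(ComplexSpecies(2, 1, 2 * occ, d["ad2"] / 2))
        if d["large_soluble"] > 0:
            species.append(ComplexSpecies(4, 3, 4 * occ * eta,
                                          d["large_soluble"] / 4))
        if part["fab"]["free"] > 0:
            species.append(ComplexSpecies.free_fab(part["fab"]["free"]))
        samples.append((ada, render_chromatogram(
            species, config.calibration, noise_sd=config.chrom_noise_sd,
            seed=rng, extra_components=[SERUM_BACKGROUND],
            label=f"ada_{ada:g}nM")))
        lanes_p, lanes_s = {}, {}
        for protein, frac in part["pellet_fraction"].items():
            lanes_p[protein], lanes_s[protein] = _pellet_lanes(
                frac, rng, config.densitometry_cv)
        pellets[ada] = PelletQuant(lanes_p, lanes_s)
    truth["drug_total_nM"] = ADA_SERIES_DRUG_NM
    truth["fab_total_nM"] = ADA_SERIES_FAB_NM
    return AdaSeriesData(samples, pellets, truth)


# ---------------------------------------------------------------------------
# Multi-dose study timecourse

STUDY_OFFSETS = ("pre", "15 min", "4 h", "24 h", "48 h", "96 h", "168 h")
#: free-drug concentration in 100% serum (µg/mL) by time offset
_FREE_DRUG_PROFILE = {"pre": 0.0, "15 min": 500.0, "4 h": 480.0, "24 h": 400.0,
                      "48 h": 330.0, "96 h": 220.0, "168 h": 120.0}
#: complex drug (µg/mL serum, per class) by dose and offset; complexes appear
#: transiently after repeat dosing and have cleared by 24 h
_COMPLEX_PROFILE: dict[int, dict[str, tuple[float, float, float]]] = {
    1: {},
    6: {"15 min": (20.0, 20.0, 10.0), "4 h": (10.0, 10.0, 5.0)},
    13: {"15 min": (15.0, 15.0, 40.0), "4 h": (8.0, 8.0, 20.0)},
}
#: offsets missing per dose (samples not drawn)
_MISSING = {13: ("15 min", "168 h")}
#: constant-area unspecific serum peak (fluorophore-equivalents, nM)
UNSPECIFIC_AREA_NM = 25.0
DRUG_MASS_DA = binding.DEFAULT_MASSES["huDVD"]
SERUM_DILUTION = 5.0


def _study_species(free_serum: float, complexes: tuple[float, float, float],
                   fab_nm: float, kd: float) -> list[ComplexSpecies]:
    """Species mix for one study sample given serum µg/mL truths."""
    to_nm = lambda ugml: mass_to_molar(ugml / SERUM_DILUTION, DRUG_MASS_DA)
    free_nm = to_nm(free_serum)
    c1, c2, cl = (to_nm(c) for c in complexes)
    total_drug = free_nm + c1 + c2 + cl
    species = [ComplexSpecies.free_dye(FREE_DYE_NM),
               ComplexSpecies.unspecific(UNSPECIFIC_AREA_NM)]
    bound = 0.0
    if total_drug > 0:
        sites = effective_site_concentration(total_drug, 2)
        bound = solve_bound_complex(fab_nm, sites, kd)
        occ = bound / total_drug
        if free_nm > 0:
            species.append(ComplexSpecies(1, 0, occ, free_nm))
        if c1 > 0:
            species.append(ComplexSpecies(1, 1, occ, c1))
        if c2 > 0:
            species.append(ComplexSpecies(2, 1, 2 * occ, c2 / 2))
        if cl > 0:
            species.append(ComplexSpecies(4, 3, 4 * occ, cl / 4))
    free_fab = fab_nm - bound
    if free_fab > 0:
        species.append(ComplexSpecies.free_fab(free_fab))
    return species


def gen_study(config: GeneratorConfig | None = None,
              doses: tuple[int, ...] = (1, 6, 13)) -> list[TimecoursePoint]:
    """Serum timecourse around selected doses of a repeat-dose study.

    Dose 1 shows only the binary drug-Fab complex, maximal at 15 min and
    decaying monotonically to 168 h.  After repeat dosing (doses 6 and 13)
    immune complexes appear transiently at the early post-dose samples, the
    last dose with a larger share of large complexes; they are gone by 24 h.
    Ligand-binding-assay values track the free-drug truth (floored at the
    assay's quantitation limit and flagged), western intensities track total
    drug, and the unspecific serum peak is present in every sample.
    """
    config = config or GeneratorConfig()
    rng = config.rng(stream=5)
    from .pipeline import LBA_LLOQ_UG_ML
    points: list[TimecoursePoint] = []
    for dose in doses:
        for offset in STUDY_OFFSETS:
            if offset in _MISSING.get(dose, ()):
                continue
            free_serum = _FREE_DRUG_PROFILE[offset]
            complexes = _COMPLEX_PROFILE.get(dose, {}).get(offset, (0.0, 0.0, 0.0))
            species = _study_species(free_serum, complexes,
                                     config.a_total_nM, config.kd_nM)
            # the study's serum signature is the constant unspecific peak;
            # no broad background so windowed drug quantification stays clean
            chrom = render_chromatogram(
                species, config.calibration, noise_sd=config.chrom_noise_sd,
                seed=rng, label=f"dose{dose}_{offset.replace(' ', '')}")
            lba = free_serum * (1.0 + rng.normal(0.0, 0.05))
            bql = lba < LBA_LLOQ_UG_ML
            total_serum = free_serum + sum(complexes)
            western = max(total_serum * (1.0 + rng.normal(0.0, 0.10)), 0.0)
            points.append(TimecoursePoint(
                dose_index=dose, time_offset=offset, chromatogram=chrom,
                lba_conc=None if bql else float(lba), lba_bql=bool(bql),
                western_intensity=float(western),
                truth={"free_drug_serum_ug_ml": free_serum,
                       "complex_drug_serum_ug_ml": complexes}))
    return points
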
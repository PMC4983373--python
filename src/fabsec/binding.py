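"""Mass-action equilibrium for a fluorescent detection Fab binding a therapeutic antibody.

The detection reagent (a dye-labelled monovalent Fab, ``Fab488``) binds each of
the two epitopes on the drug molecule (a ~200 kDa dual-variable-domain
immunoglobulin, ``huDVD``) independently.  With total Fab concentration ``a``,
total epitope (site) concentration ``x`` and dissociation constant ``K_D``,
the bound-complex concentration ``[AB]`` is the smaller root of the quadratic
obtained from ``K_D = [A][B]/[AB]`` with mass conservation:

    [AB] = (a + x + K_D)/2 - sqrt(((a + x + K_D)/2)^2 - a*x)

All internal concentrations are in nM; unit conversions (µg/mL <-> nM, serum
dilution) happen at the boundary through the helpers in this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "BindingSystem",
    "BindingCurveParams",
    "MolecularMasses",
    "solve_bound_complex",
    "fraction_bound",
    "signal_model",
    "effective_site_concentration",
    "mass_to_molar",
    "molar_to_mass",
    "assay_to_serum",
]

#: default molecular masses in Da; the ADA mass is the standard IgG value
#: (it is configurable because the true polyclonal mass is not known).
DEFAULT_MASSES: dict[str, float] = {
    "huDVD": 200_000.0,
    "Fab488": 47_150.0,
    "free_dye": 1_011.0,
    "ADA": 150_000.0,
}


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and affinity for the Fab/drug equilibrium.

    Parameters
    ----------
    a_total : float
        Total detection-Fab concentration (nM).
    x_total : float
        Total drug *binding-site* concentration (nM).  For a drug with two
        Fab epitopes this is twice the molar drug concentration; see
        :func:`effective_site_concentration`.
    kd : float
        Equilibrium dissociation constant (nM).
    n_sites : int
        Fab epitopes per drug molecule (default 2).
    """

    a_total: float
    x_total: float
    kd: float
    n_sites: int = 2

    def __post_init__(self) -> None:
        if self.a_total < 0 or self.x_total < 0 or self.kd < 0:
            raise ValueError("concentrations and kd must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def bound(self) -> float:
        """Concentration of the Fab·site complex [AB] (nM)."""
        return float(solve_bound_complex(self.a_total, self.x_total, self.kd))

    def free_fab(self) -> float:
        return self.a_total - self.bound()

    def free_sites(self) -> float:
        return self.x_total - self.bound()


@dataclass(frozen=True)
class BindingCurveParams:
    """Saturation-curve parameters: baseline F, plateau F_max, affinity kd (nM)."""

    f_min: float
    f_max: float
    kd: float

    def __post_init__(self) -> None:
        if self.f_max < self.f_min:
            raise ValueError("f_max must be >= f_min")
        if self.kd < 0:
            raise ValueError("kd must be non-negative")


@dataclass
class MolecularMasses:
    """Named table of species molecular masses (Da)."""

    masses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MASSES))

    def __post_init__(self) -> None:
        for name, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"mass of {name!r} must be positive, got {m}")

    def __getitem__(self, species: str) -> float:
        return self.masses[species]

    @classmethod
    def from_file(cls, path: str | Path) -> "MolecularMasses":
        """Load a mass table from YAML or JSON; missing species keep defaults."""
        path = Path(path)
        text = path.read_text()
        data: Mapping[str, float]
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        merged = dict(DEFAULT_MASSES)
        merged.update({str(k): float(v) for k, v in data.items()})
        return cls(merged)


def solve_bound_complex(a_total, x_total, kd):
    """Bound complex [AB] (nM) for totals ``a_total``, ``x_total`` and ``kd``.

    Uses the numerically stable form of the smaller quadratic root,
    ``c = a*x / (s + sqrt(s^2 - a*x))`` with ``s = (a+x+kd)/2``, which avoids
    catastrophic cancellation when ``kd`` is far below the totals.
    Accepts scalars or arrays (broadcast).
    """
    a = np.asarray(a_total, dtype=float)
    x = np.asarray(x_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(a < 0) or np.any(x < 0) or np.any(k < 0):
        raise ValueError("a_total, x_total and kd must be non-negative")
    s = (a + x + k) / 2.0
    disc = np.maximum(s * s - a * x, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        c = np.where(denom > 0, a * x / np.where(denom > 0, denom, 1.0), 0.0)
    # guard against rounding above the stoichiometric ceiling
    c = np.minimum(c, np.minimum(a, x))
    if np.isscalar(a_total) and np.isscalar(x_total) and np.isscalar(kd):
        return float(c)
    return c


def fraction_bound(a_total, x_total, kd):
    """Fraction of drug sites occupied, ``[AB] / x_total`` in [0, 1].

    In the dilute-site limit (``x_total`` far below ``a_total``) this tends to
    the hyperbolic ``a / (a + kd)``.
    """
    x = np.asarray(x_total, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fraction_bound is undefined at x_total = 0")
    return solve_bound_complex(a_total, x_total, kd) / x_total


def signal_model(x_total, params: BindingCurveParams, a_total):
    """Saturation signal Y at total site concentration ``x_total``.

    ``Y = F + (F_max - F) * [AB]/a`` — the observable is the fraction of the
    detection Fab in the complex (the complex-peak share of total
    fluorescence), scaled between baseline ``F`` and plateau ``F_max``.
    """
    a = np.asarray(a_total, dtype=float)
    if np.any(a <= 0):
        raise ValueError("a_total must be positive for the signal model")
    bound = solve_bound_complex(a_total, x_total, params.kd)
    return params.f_min + (params.f_max - params.f_min) * bound / a_total


def effective_site_concentration(drug_total, n_sites: int):
    """Binding-site concentration for ``drug_total`` nM of drug with ``n_sites`` epitopes.

    Independent-sites convention: a drug with two identical Fab epitopes is
    represented as twice its molar concentration of sites.
    """
    d = np.asarray(drug_total, dtype=float)
    if np.any(d < 0):
        raise ValueError("drug_total must be non-negative")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    out = d * n_sites
    return float(out) if np.isscalar(drug_total) else out


def mass_to_molar(conc_ug_ml, mass_da):
    """Convert µg/mL to nM at molecular mass ``mass_da`` (Da)."""
    if np.any(np.asarray(mass_da) <= 0):
        raise ValueError("molecular mass must be positive")
    out = np.asarray(conc_ug_ml, dtype=float) * 1e6 / mass_da
    return float(out) if np.isscalar(conc_ug_ml) else out


def molar_to_mass(conc_nm, mass_da):
    """Convert nM to µg/mL at molecular mass ``mass_da`` (Da)."""
    if np.any(np.asarray(mass_da) <= 0):
        raise ValueError("molecular mass must be positive")
    out = np.asarray(conc_nm, dtype=float) * mass_da / 1e6
    return float(out) if np.isscalar(conc_nm) else out


def assay_to_serum(conc_assay, dilution_factor=5.0):
    """Back-convert an in-assay concentration to 100% serum (default 1:5 dilution)."""
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    out = np.asarray(conc_assay, dtype=float) * dilution_factor
    return float(out) if np.isscalar(conc_assay) else out
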
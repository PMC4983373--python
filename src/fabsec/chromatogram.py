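"""SEC fluorescence traces: forward rendering, peak integration, S/N and LOD.

A chromatogram is a fluorescence trace on a uniform time grid.  Species are
quantified by integrating retention windows from a by-species calibration —
never from a mass-to-time formula, because small dyes adsorb and elute later
than their mass predicts on this column.  The signal-to-noise statistic used
for the detection limit is a ratio of *percentage* areas: the complex
window's share of total trace area in a sample divided by the same window's
share in a drug-free control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .species import ComplexSpecies, SpeciesClass

__all__ = [
    "Chromatogram", "SpeciesWindow", "PeakQuant", "default_calibration",
    "render_chromatogram", "integrate_window", "snr", "detect_lod",
    "percent_complex", "NOT_DETECTED", "INFINITE_SNR",
    "read_chromatogram_csv", "write_chromatogram_csv",
    "read_calibration_yaml", "write_calibration_yaml",
]

#: sentinel returned by detect_lod when no concentration reaches the threshold
NOT_DETECTED = float("inf")
#: sentinel returned by snr when the blank window percentage is zero
INFINITE_SNR = float("inf")

#: ADA-containing complex classes summed by percent_complex
ADA_CLASSES = (SpeciesClass.ADA1_DRUG1, SpeciesClass.ADA1_DRUG2,
               SpeciesClass.LARGE_COMPLEX)

#: default Gaussian peak width (min); same for all species
DEFAULT_PEAK_SIGMA = 0.18
#: fraction of the trace at each end used for the constant-baseline estimate
BASELINE_EDGE_FRACTION = 0.05


@dataclass
class Chromatogram:
    """A time (minutes) / fluorescence trace with flow-rate metadata."""

    time: np.ndarray
    signal: np.ndarray
    flow_rate: float = 0.3
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def baseline(self) -> float:
        """Constant baseline: median of the first and last 5% of the trace."""
        n = max(1, int(round(BASELINE_EDGE_FRACTION * self.time.size)))
        edges = np.concatenate([self.signal[:n], self.signal[-n:]])
        return float(np.median(edges))

    def total_area(self) -> float:
        """Trapezoidal area above baseline over the full trace (AU*min)."""
        corrected = self.signal - self.baseline()
        return float(np.trapezoid(corrected, self.time))


@dataclass(frozen=True)
class SpeciesWindow:
    """A retention window assigned to one species class."""

    species_class: SpeciesClass
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def center(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class PeakQuant:
    window: SpeciesWindow
    area: float
    percent_of_total: float

    def __post_init__(self) -> None:
        if self.percent_of_total < -1e-9 or self.percent_of_total > 1 + 1e-9:
            raise ValueError("percent_of_total must lie in [0, 1]")


def default_calibration() -> list[SpeciesWindow]:
    """Retention calibration at 0.3 mL/min.

    Free dye (19.5 min), free Fab (18 min) and the drug-Fab complex (15 min)
    are anchored to observed retention times; the ADA-complex and unspecific
    windows are figure-informed placeholders and should be recalibrated per
    column.  Windows are disjoint.
    """
    return [
        SpeciesWindow(SpeciesClass.LARGE_COMPLEX, 9.5, 11.9),
        SpeciesWindow(SpeciesClass.ADA1_DRUG2, 11.9, 12.8),
        SpeciesWindow(SpeciesClass.ADA1_DRUG1, 12.8, 13.7),
        SpeciesWindow(SpeciesClass.UNSPECIFIC, 13.7, 14.3),
        SpeciesWindow(SpeciesClass.DRUG_FAB, 14.3, 15.7),
        SpeciesWindow(SpeciesClass.FAB488, 17.3, 18.7),
        SpeciesWindow(SpeciesClass.FREE_DYE, 18.8, 20.2),
    ]


def _check_disjoint(calibration: Sequence[SpeciesWindow]) -> None:
    ordered = sorted(calibration, key=lambda w: w.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end:
            raise ValueError(
                f"windows {a.species_class.value} and {b.species_class.value} overlap")


def _window_for(calibration: Sequence[SpeciesWindow],
                cls: SpeciesClass) -> SpeciesWindow | None:
    for w in calibration:
        if w.species_class == cls:
            return w
    return None


def render_chromatogram(
    species: Sequence[ComplexSpecies],
    calibration: Sequence[SpeciesWindow] | None = None,
    peak_width: float = DEFAULT_PEAK_SIGMA,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    t_start: float = 8.0,
    t_end: float = 22.0,
    dt: float = 0.02,
    extra_components: Sequence[tuple[float, float, float]] = (),
    label: str = "",
) -> Chromatogram:
    """Forward-render a trace from species concentrations.

    Each species contributes a Gaussian centred in its calibration window
    with area equal to its fluorescence abundance (concentration x Fab
    count; the free dye counts one fluorophore).  ``extra_components`` are
    additional ``(center_min, sigma_min, area)`` Gaussians — used for the
    broad serum-background component.  Additive Gaussian baseline noise with
    sd ``noise_sd``.
    """
    if calibration is None:
        calibration = default_calibration()
    _check_disjoint(calibration)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(t_start, t_end + dt / 2, dt)
    y = np.zeros_like(t)
    for sp in species:
        w = _window_for(calibration, sp.species_class)
        if w is None:
            raise ValueError(f"species class {sp.species_class.value} is not calibrated")
        area = sp.fluorescence_abundance
        if area == 0:
            continue
        y += area / (peak_width * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - w.center) / peak_width) ** 2)
    for center, sigma, area in extra_components:
        y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - center) / sigma) ** 2)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Chromatogram(t, y, label=label)


def integrate_window(chrom: Chromatogram, window: SpeciesWindow) -> PeakQuant:
    """Trapezoidal window area above the constant baseline, and its share of total area."""
    mask = (chrom.time >= window.t_start) & (chrom.time <= window.t_end)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two samples of the trace")
    corrected = chrom.signal - chrom.baseline()
    area = float(np.trapezoid(corrected[mask], chrom.time[mask]))
    total = float(np.trapezoid(corrected, chrom.time))
    percent = area / total if total != 0 else 0.0
    return PeakQuant(window, area, min(max(percent, 0.0), 1.0))


def snr(sample: Chromatogram, blank: Chromatogram, window: SpeciesWindow) -> float:
    """Percentage-area signal-to-noise ratio against a drug-free control.

    Ratio of the window's share of total trace area in the sample to its
    share in the blank.  Scale-invariant by construction.  A zero blank share
    yields the ``INFINITE_SNR`` sentinel.
    """
    if sample.time.shape != blank.time.shape or not np.allclose(sample.time, blank.time):
        raise ValueError("sample and blank must share the same time grid")
    ps = integrate_window(sample, window).percent_of_total
    pb = integrate_window(blank, window).percent_of_total
    if pb == 0:
        return INFINITE_SNR
    return ps / pb


def detect_lod(
    titration: Sequence[tuple[float, Chromatogram]],
    blank: Chromatogram,
    window: SpeciesWindow,
    threshold: float = 1.5,
) -> float:
    """Lowest concentration whose complex-window S/N reaches ``threshold``.

    ``titration`` must be sorted by ascending concentration.  Returns the
    ``NOT_DETECTED`` sentinel when no concentration qualifies.
    """
    if len(titration) < 2:
        raise ValueError("need at least 2 titration concentrations")
    concs = [c for c, _ in titration]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("titration must be sorted by ascending concentration")
    for conc, chrom in titration:
        if snr(chrom, blank, window) >= threshold:
            return conc
    return NOT_DETECTED


def percent_complex(chrom: Chromatogram,
                    calibration: Sequence[SpeciesWindow]) -> float:
    """Share of total fluorescence in ADA-containing complex windows, in [0, 1]."""
    total = chrom.total_area()
    if total == 0:
        raise ValueError("trace has zero total area")
    windows = [w for w in calibration if w.species_class in ADA_CLASSES]
    if not windows:
        raise ValueError("calibration defines no ADA-containing windows")
    area = sum(integrate_window(chrom, w).area for w in windows)
    return min(max(area / total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# I/O

def write_chromatogram_csv(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": chrom.time,
                  "fluorescence": chrom.signal}).to_csv(path, index=False)


def read_chromatogram_csv(path: str | Path, flow_rate: float = 0.3,
                          label: str = "") -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(df["time_min"].to_numpy(), df["fluorescence"].to_numpy(),
                        flow_rate=flow_rate, label=label or Path(path).stem)


def write_calibration_yaml(calibration: Sequence[SpeciesWindow],
                           path: str | Path) -> None:
    data = [{"species": w.species_class.value, "t_start_min": w.t_start,
             "t_end_min": w.t_end} for w in calibration]
    Path(path).write_text(yaml.safe_dump(data))


def read_calibration_yaml(path: str | Path) -> list[SpeciesWindow]:
    data = yaml.safe_load(Path(path).read_text())
    cal = [SpeciesWindow(SpeciesClass(d["species"]), float(d["t_start_min"]),
                         float(d["t_end_min"])) for d in data]
    _check_disjoint(cal)
    return cal
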
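"""1:1 Langmuir SPR kinetics: simulation, global fitting, stoichiometry arithmetic.

The 1:1 model ``dR/dt = kon*C*(Rmax - R) - koff*R`` has closed-form solutions
for constant analyte concentration, so sensorgrams are generated and fitted
analytically rather than by ODE integration:

    association:  R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                  Req  = Rmax * C / (C + KD),  KD = koff/kon
    dissociation: R(t) = R(t_assoc) * exp(-koff * (t - t_assoc))

Mass-transport limitation, baseline drift and bulk refractive-index jumps are
not modelled; noise is additive Gaussian.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

__all__ = ["KineticParams", "Sensorgram", "simulate_sensorgram",
           "global_fit_langmuir", "expected_rmax",
           "read_sensorgram_csv", "write_sensorgram_csv"]


@dataclass(frozen=True)
class KineticParams:
    """Association rate kon (1/(M*s)), dissociation rate koff (1/s), capacity rmax (RU)."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise ValueError("kon must be positive")
        if self.koff < 0:
            raise ValueError("koff must be non-negative")
        if self.rmax <= 0:
            raise ValueError("rmax must be positive")

    def kd(self) -> float:
        """Equilibrium dissociation constant koff/kon in molar."""
        return self.koff / self.kon

    def kd_nm(self) -> float:
        return self.kd() * 1e9


@dataclass
class Sensorgram:
    """One RU trace at a single analyte concentration (nM)."""

    analyte_conc: float
    time: np.ndarray
    response: np.ndarray
    t_assoc_end: float
    truth: KineticParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.t_assoc_end <= self.time[-1]):
            raise ValueError("t_assoc_end must lie within the time range")


def _langmuir_response(t: np.ndarray, conc_nm: float, params: KineticParams,
                       t_assoc_end: float) -> np.ndarray:
    c_molar = conc_nm * 1e-9
    kobs = params.kon * c_molar + params.koff
    kd_nm = params.kd_nm()
    req = params.rmax * conc_nm / (conc_nm + kd_nm) if conc_nm + kd_nm > 0 else 0.0
    r = np.where(
        t <= t_assoc_end,
        req * (1.0 - np.exp(-kobs * t)),
        req * (1.0 - np.exp(-kobs * t_assoc_end)) * np.exp(-params.koff * (t - t_assoc_end)),
    )
    return r


def simulate_sensorgram(params: KineticParams, conc: float, t_assoc: float,
                        t_dissoc: float, noise_sd: float = 0.0,
                        seed: int | np.random.Generator | None = None,
                        dt: float = 1.0) -> Sensorgram:
    """Simulate a 1:1 Langmuir sensorgram at analyte concentration ``conc`` (nM).

    ``t_assoc`` and ``t_dissoc`` are phase durations in seconds; samples are
    on a uniform grid of step ``dt``.  ``noise_sd = 0`` gives the exact
    closed-form curve.
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("phase durations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = _langmuir_response(t, conc, params, t_assoc)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(conc, t, r, t_assoc, truth=params)


def _initial_guess(sensorgrams: list[Sensorgram]) -> KineticParams:
    """Heuristic start: koff from the top-concentration dissociation tail,
    kon from the observed association rate at the top concentration."""
    top = max(sensorgrams, key=lambda s: s.analyte_conc)
    rmax0 = max(1e-6, 1.2 * max(float(s.response.max()) for s in sensorgrams))

    diss = top.time > top.t_assoc_end
    koff0 = 1e-3
    if diss.sum() >= 3:
        td = top.time[diss] - top.t_assoc_end
        rd = np.maximum(top.response[diss], 1e-9)
        slope = np.polyfit(td, np.log(rd), 1)[0]
        if np.isfinite(slope) and slope < 0:
            koff0 = min(max(-slope, 1e-7), 1.0)

    # time to ~63% of plateau during association gives kobs = kon*C + koff
    assoc = top.time <= top.t_assoc_end
    ta, ra = top.time[assoc], top.response[assoc]
    plateau = ra[-1] if ra.size else 1.0
    kon0 = 1e5
    if plateau > 0:
        crossing = ta[ra >= 0.632 * plateau]
        if crossing.size and crossing[0] > 0:
            kobs0 = 1.0 / crossing[0]
            kon0 = max((kobs0 - koff0) / (top.analyte_conc * 1e-9), 1e2)
    return KineticParams(kon0, koff0, rmax0)


def global_fit_langmuir(sensorgrams: list[Sensorgram],
                        init: KineticParams | None = None,
                        shared_rmax: bool = True):
    """Globally fit kon, koff, rmax across a concentration series.

    All curves share all three parameters (per-curve rmax available via
    ``shared_rmax=False``).  Returns ``(KineticParams, stderr_dict, success)``;
    non-convergence is flagged, not raised.
    """
    if len(sensorgrams) < 3:
        raise ValueError("global fit needs at least 3 analyte concentrations")
    if init is None:
        init = _initial_guess(sensorgrams)

    p = lmfit.Parameters()
    p.add("log_kon", value=np.log10(init.kon), min=1, max=10)
    p.add("log_koff", value=np.log10(max(init.koff, 1e-7)), min=-7, max=1)
    if shared_rmax:
        p.add("rmax", value=init.rmax, min=1e-9)
    else:
        for i in range(len(sensorgrams)):
            p.add(f"rmax_{i}", value=init.rmax, min=1e-9)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        kon = 10.0 ** pars["log_kon"].value
        koff = 10.0 ** pars["log_koff"].value
        out = []
        for i, s in enumerate(sensorgrams):
            rmax = pars["rmax"].value if shared_rmax else pars[f"rmax_{i}"].value
            kp = KineticParams(kon, koff, rmax)
            out.append(_langmuir_response(s.time, s.analyte_conc, kp, s.t_assoc_end)
                       - s.response)
        return np.concatenate(out)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(residual, p, method="leastsq")

    kon = 10.0 ** out.params["log_kon"].value
    koff = 10.0 ** out.params["log_koff"].value
    rmax = (out.params["rmax"].value if shared_rmax
            else np.mean([out.params[f"rmax_{i}"].value for i in range(len(sensorgrams))]))
    fitted = KineticParams(kon, koff, float(rmax))

    # delta-method standard errors on the linear scale
    ln10 = np.log(10.0)
    se = {}
    for name, value in (("kon", kon), ("koff", koff)):
        s = out.params[f"log_{name}"].stderr
        se[name] = value * ln10 * s if s is not None else None
    se["rmax"] = out.params["rmax"].stderr if shared_rmax else None
    return fitted, se, bool(out.success)


def expected_rmax(ru_ligand: float, mass_ligand: float, mass_analyte: float,
                  n_sites: int) -> float:
    """Expected saturating analyte response (RU) from the captured-ligand response.

    SPR response is proportional to bound mass, so an immobilised ligand giving
    ``ru_ligand`` RU with ``n_sites`` analyte sites per molecule saturates at
    ``ru_ligand * n_sites * mass_analyte / mass_ligand`` RU of analyte.
    """
    if min(ru_ligand, mass_ligand, mass_analyte) <= 0 or n_sites <= 0:
        raise ValueError("all arguments must be positive")
    return ru_ligand * n_sites * mass_analyte / mass_ligand


def write_sensorgram_csv(sensorgrams: list[Sensorgram], path: str | Path) -> None:
    """Write a series as long-form CSV: conc_nM, time_s, response_RU."""
    frames = [pd.DataFrame({"conc_nM": s.analyte_conc, "time_s": s.time,
                            "response_RU": s.response}) for s in sensorgrams]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgram_csv(path: str | Path, t_assoc_end: float) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("conc_nM", sort=True):
        out.append(Sensorgram(float(conc), grp["time_s"].to_numpy(),
                              grp["response_RU"].to_numpy(), t_assoc_end))
    return out


def write_spr_report(params: KineticParams, stderr: dict, success: bool,
                     path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "kon_per_M_s": params.kon, "koff_per_s": params.koff,
        "rmax_RU": params.rmax, "kd_nM": params.kd_nm(),
        "stderr": stderr, "converged": success}, indent=2))
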
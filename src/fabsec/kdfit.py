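"""Nonlinear least-squares estimation of K_D from a saturation titration.

Fits the tight-binding (quadratic) saturation model of :mod:`fabsec.binding`
to percent-bound observations versus total drug-site concentration.  The
caller is responsible for site-doubling the drug concentrations
(:func:`fabsec.binding.effective_site_concentration`); the fitter never
rescales its inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from .binding import BindingCurveParams, signal_model

__all__ = ["TitrationPoint", "FitResult", "fit_kd", "read_titration_csv",
           "write_titration_csv", "write_fit_report"]

#: above this ratio of Fab concentration to fitted kd the titration is
#: stoichiometric rather than affinity-limited and kd is weakly identified
IDENTIFIABILITY_RATIO = 50.0


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: total site concentration (nM) and signal."""

    x_total: float
    y: float

    def __post_init__(self) -> None:
        if self.x_total < 0:
            raise ValueError("x_total must be non-negative")
        if not np.isfinite(self.y):
            raise ValueError("y must be finite")


@dataclass
class FitResult:
    params: BindingCurveParams
    stderr: dict[str, float | None]
    rss: float
    converged: bool
    weak_kd_identifiability: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "f_min": self.params.f_min,
            "f_max": self.params.f_max,
            "kd_nM": self.params.kd,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "weak_kd_identifiability": self.weak_kd_identifiability,
            "message": self.message,
        }


def _residual(p: lmfit.Parameters, x: np.ndarray, y: np.ndarray,
              a_total: float, weights: np.ndarray | None) -> np.ndarray:
    model = signal_model(
        x, BindingCurveParams(p["f_min"].value, p["f_max"].value, p["kd"].value),
        a_total,
    )
    r = model - y
    return r if weights is None else r * weights


def fit_kd(points: list[TitrationPoint], a_total: float,
           init: BindingCurveParams | None = None,
           relative_weights: bool = False) -> FitResult:
    """Fit (F, F_max, K_D) to a titration by unweighted least squares.

    Parameters
    ----------
    points : list of TitrationPoint
        At least 4 points spanning a >= 10-fold range of x_total.
    a_total : float
        Total detection-Fab concentration (nM), fixed during the fit.
    init : BindingCurveParams, optional
        Starting values.  The default heuristic uses min/max of y and the
        x at half-maximal signal — robust and derivative-free.
    relative_weights : bool
        Weight residuals by 1/|y| (off by default; the standard fit is
        unweighted).

    Returns
    -------
    FitResult
        Carries a convergence flag rather than raising on non-convergence,
        and flags weak kd identifiability when ``a_total`` exceeds 50x the
        fitted kd (the titration is then stoichiometric: the Fab
        concentration cannot be far above the dissociation constant if the
        affinity itself is to be measured).
    """
    if a_total <= 0:
        raise ValueError("a_total must be positive")
    if len(points) < 4:
        raise ValueError("need at least 4 titration points")
    x = np.array([p.x_total for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    xpos = x[x > 0]
    if xpos.size == 0 or xpos.max() / xpos.min() < 10:
        raise ValueError("titration must span at least a 10-fold concentration range")

    if init is None:
        f0, fmax0 = float(y.min()), float(y.max())
        half = f0 + 0.5 * (fmax0 - f0)
        above = x[y >= half]
        kd0 = float(above.min()) if above.size else float(np.median(xpos))
        kd0 = max(kd0, 1e-3)
        init = BindingCurveParams(f0, fmax0, kd0)

    p = lmfit.Parameters()
    p.add("f_min", value=init.f_min)
    p.add("f_max", value=max(init.f_max, init.f_min + 1e-9))
    p.add("kd", value=init.kd, min=1e-9)

    weights = 1.0 / np.maximum(np.abs(y), 1e-12) if relative_weights else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(_residual, p, args=(x, y, a_total, weights),
                             method="leastsq")

    fitted = BindingCurveParams(out.params["f_min"].value,
                                out.params["f_max"].value,
                                out.params["kd"].value)
    resid = _residual(out.params, x, y, a_total, None)
    return FitResult(
        params=fitted,
        stderr={k: out.params[k].stderr for k in ("f_min", "f_max", "kd")},
        rss=float(np.sum(resid ** 2)),
        converged=bool(out.success),
        weak_kd_identifiability=bool(a_total > IDENTIFIABILITY_RATIO * fitted.kd),
        message=str(out.message),
    )


def read_titration_csv(path: str | Path) -> list[TitrationPoint]:
    """Read a titration table with columns ``x_total_nM``, ``percent_bound``."""
    df = pd.read_csv(path)
    return [TitrationPoint(float(r.x_total_nM), float(r.percent_bound))
            for r in df.itertuples()]


def write_titration_csv(points: list[TitrationPoint], path: str | Path) -> None:
    pd.DataFrame({"x_total_nM": [p.x_total for p in points],
                  "percent_bound": [p.y for p in points]}).to_csv(path, index=False)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))
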
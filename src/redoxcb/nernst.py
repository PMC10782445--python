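"""One-electron Nernst model and midpoint-potential fitting.

Spectro-electrochemical titrations record a normalized absorbance change
against the applied potential E_app.  For a one-electron couple the
reduced fraction follows

    [red]/([red]+[ox]) = 1 / (1 + exp(nF(E_app − E)/(RT))),

a sigmoid decreasing in E_app whose half-height sits at the midpoint
potential E.  Fitting floats the midpoint plus a free amplitude and
baseline (experimental normalization is imperfect); the electron count
stays fixed at 1 unless explicitly freed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DataError, IllConditionedFitError, InvalidParameterError
from .thermo import BOLTZMANN_KJ_PER_MOL_K, FARADAY_KJ_PER_MOL_MV


@dataclass
class TitrationCurve:
    """Applied potentials (mV) with normalized responses (dimensionless)."""

    applied_potential: np.ndarray
    response: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.applied_potential = np.asarray(self.applied_potential, dtype=float).ravel()
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.applied_potential.size != self.response.size:
            raise DataError("applied_potential and response lengths differ")
        if not np.all(np.isfinite(self.applied_potential)):
            raise DataError("non-finite applied potential")


@dataclass(frozen=True)
class NernstFit:
    """Fitted midpoint potential (mV) with standard error and nuisances."""

    midpoint: float
    midpoint_se: float
    n_electrons: float
    amplitude: float
    baseline: float
    rss: float

    def to_json_dict(self) -> dict:
        return {
            "midpoint_mV": self.midpoint,
            "midpoint_se_mV": self.midpoint_se,
            "n_electrons": self.n_electrons,
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "rss": self.rss,
        }


def nernst_fraction(
    e_app,
    midpoint: float,
    temperature: float = 298.0,
    n_electrons: float = 1,
):
    """Reduced fraction at applied potential ``e_app`` (both mV).

    Strictly decreasing in e_app; equals 1/2 at the midpoint, and at
    298 K drops one decade of [red]/[ox] every RT·ln10/F ≈ 59 mV.
    """
    if not temperature > 0:
        raise InvalidParameterError("temperature must be > 0")
    rt = BOLTZMANN_KJ_PER_MOL_K * temperature  # kJ/mol
    x = n_electrons * FARADAY_KJ_PER_MOL_MV * (np.asarray(e_app, float) - midpoint) / rt
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(x))


def fit_nernst(
    curve: TitrationCurve,
    temperature: float = 298.0,
    free_n: bool = False,
) -> NernstFit:
    """Least-squares fit of ``baseline + amplitude · nernst_fraction``.

    The midpoint is initialized at the potential whose response is
    closest to mid-range; amplitude and baseline start at 1 and 0.  The
    electron count is fixed at 1 unless ``free_n`` is set.  Data must
    span both plateaus (response range >= 0.3) or the sigmoid is
    unconstrained.
    """
    e = curve.applied_potential
    r = curve.response
    if e.size < 4:
        raise DataError(f"fit_nernst needs >= 4 points, got {e.size}")
    span = float(r.max() - r.min())
    if span < 0.3:
        raise IllConditionedFitError(
            f"response range {span:.3g} < 0.3: curve does not leave one plateau"
        )
    mid_response = 0.5 * (r.max() + r.min())
    mid0 = float(e[np.argmin(np.abs(r - mid_response))])

    if free_n:
        def model(x, midpoint, amplitude, baseline, n):
            return baseline + amplitude * nernst_fraction(x, midpoint, temperature, n)

        p0 = [mid0, 1.0, 0.0, 1.0]
        bounds = ([-np.inf, -np.inf, -np.inf, 0.1], [np.inf, np.inf, np.inf, 4.0])
    else:
        def model(x, midpoint, amplitude, baseline):
            return baseline + amplitude * nernst_fraction(x, midpoint, temperature, 1)

        p0 = [mid0, 1.0, 0.0]
        bounds = (-np.inf, np.inf)

    try:
        popt, pcov = curve_fit(model, e, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise IllConditionedFitError(f"Nernst fit did not converge: {exc}") from exc
    resid = r - model(e, *popt)
    rss = float(resid @ resid)
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return NernstFit(
        midpoint=float(popt[0]),
        midpoint_se=se,
        n_electrons=float(popt[3]) if free_n else 1.0,
        amplitude=float(popt[1]),
        baseline=float(popt[2]),
        rss=rss,
    )


def read_titration_csv(path: str | Path) -> TitrationCurve:
    """Read a titration CSV with columns potential_mV,response[,replicate]."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("potential_mV", "response"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    rep = None
    if "replicate" in df.columns and df["replicate"].nunique() == 1:
        rep = str(df["replicate"].iloc[0])
    return TitrationCurve(
        applied_potential=df["potential_mV"].to_numpy(float),
        response=df["response"].to_numpy(float),
        replicate=rep,
    )


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("potential_mV,response\n")
        for e, r in zip(curve.applied_potential, curve.response):
            fh.write(f"{float(e)!r},{float(r)!r}\n")
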
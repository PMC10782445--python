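"""Free-energy estimators for two-sided nonequilibrium work data.

The core estimator is the Crooks–Bayes (CB) posterior: under the Crooks
fluctuation relation, the probability that a work value came from the
forward rather than the backward protocol is a logistic function of
β(W − Δg), so the likelihood of a free-energy hypothesis Δg given all
work values is a product of logistic terms

    L(Δg) = Π_fwd f(β(W_i − Δg) + M) · Π_bwd f(β(W_j + Δg) − M),

with f(x) = 1/(1 + e^(−x)) and M = ln(n_forward / n_backward).  With a
flat prior this is also the posterior density; its mean is the
square-error-optimal point estimate and its standard deviation the
reported error.  The Bennett acceptance ratio (BAR) is the maximum of
the same likelihood, so the BAR root coincides with the posterior mode.

One-sided comparison estimators (Jarzynski/FEP exponential averaging,
the Gaussian linear-response formula) and the classic histogram-crossing
construction are provided for benchmarking.  All heavy lifting is done
in the log domain: raw work values of hundreds of kJ/mol would overflow
any direct exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .exceptions import (
    ConvergenceError,
    DataError,
    DegenerateCrossingError,
    NoCrossingError,
    UnsupportedMethodError,
)
from .thermo import ThermoState, make_thermo
from .work import WorkSet

__all__ = [
    "PosteriorDensity",
    "FreeEnergyEstimate",
    "ConvergenceSeries",
    "crooks_bayes_posterior",
    "crooks_bayes_estimate",
    "crooks_bayes",
    "bar_estimate",
    "histogram_crossing",
    "jarzynski_estimate",
    "fep_estimate",
    "lr_estimate",
    "convergence_curve",
    "write_posterior_tsv",
]

_NORM_TOL = 1e-6
_EDGE_MASS_TOL = 1e-4
_MAX_WIDEN = 8


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG estimate (kJ/mol) with standard error and method tag."""

    delta_g: float
    std_error: float | None
    method: str
    n_forward: int
    n_backward: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.std_error is not None and self.std_error < 0:
            raise ValueError("std_error must be >= 0 when defined")

    def to_json_dict(self, label: str = "") -> dict:
        return {
            "label": label,
            "method": self.method,
            "delta_g_kjmol": self.delta_g,
            "stderr_kjmol": self.std_error,
            "n_forward": self.n_forward,
            "n_backward": self.n_backward,
        }


@dataclass
class PosteriorDensity:
    """Normalized posterior density over free-energy hypotheses Δg.

    ``grid`` is strictly increasing with uniform spacing (>= 101 points);
    ``density`` integrates to 1 by the trapezoid rule within 1e-6.
    """

    grid: np.ndarray
    density: np.ndarray
    thermo: ThermoState
    n_forward: int = 0
    n_backward: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.size < 101:
            raise ValueError("posterior grid needs >= 101 points")
        steps = np.diff(self.grid)
        if not np.all(steps > 0):
            raise ValueError("posterior grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
            raise ValueError("posterior grid must be uniformly spaced")
        if np.any(self.density < 0):
            raise ValueError("posterior density must be non-negative")
        integral = np.trapezoid(self.density, self.grid)
        if abs(integral - 1.0) > _NORM_TOL:
            raise ValueError(f"posterior not normalized: integral = {integral}")

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def std(self) -> float:
        m = self.mean()
        var = float(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid))
        return float(np.sqrt(max(var, 0.0)))

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class ConvergenceSeries:
    """CB estimate and posterior SD as a function of the sample count μ."""

    mu_values: np.ndarray
    estimates: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.mu_values = np.asarray(self.mu_values, dtype=int)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (self.mu_values.size == self.estimates.size == self.errors.size):
            raise ValueError("mu_values, estimates and errors must have equal length")


def _log_mixture_offset(n_forward: int, n_backward: int) -> float:
    return float(np.log(n_forward / n_backward))


def _log_likelihood_on_grid(
    grid: np.ndarray,
    forward: np.ndarray,
    backward: np.ndarray,
    beta: float,
    m_offset: float,
    chunk: int = 2048,
) -> np.ndarray:
    """log L(Δg) on the grid, accumulated in chunks to bound memory.

    log f(x) = −log(1 + e^(−x)) = −logaddexp(0, −x), stable for any |x|.
    """
    ll = np.zeros_like(grid)
    for start in range(0, forward.size, chunk):
        w = forward[start : start + chunk, None]
        x = beta * (w - grid[None, :]) + m_offset
        ll -= np.logaddexp(0.0, -x).sum(axis=0)
    for start in range(0, backward.size, chunk):
        w = backward[start : start + chunk, None]
        x = beta * (w + grid[None, :]) - m_offset
        ll -= np.logaddexp(0.0, -x).sum(axis=0)
    return ll


def _require_two_sided(ws: WorkSet, what: str) -> None:
    if ws.n_forward < 1 or ws.n_backward < 1:
        raise UnsupportedMethodError(
            f"{what} needs work values in both directions "
            f"(n_forward={ws.n_forward}, n_backward={ws.n_backward}); "
            "use jarzynski_estimate / fep_estimate for one-sided data"
        )


def crooks_bayes_posterior(
    ws: WorkSet,
    grid: np.ndarray | None = None,
    n_points: int = 4001,
    half_span: float | None = None,
    center: float | None = None,
) -> PosteriorDensity:
    """Posterior density over Δg from a two-sided WorkSet.

    The default grid is centered on the BAR estimate and spans
    ±max(10 k_BT, 5 × pooled work SD); it widens automatically (up to 8
    doublings) if more than 1e-4 of the posterior mass sits in the outer
    2% of the grid, and errors out if the mass is still clipped.
    """
    _require_two_sided(ws, "crooks_bayes_posterior")
    beta = ws.thermo.beta
    m_offset = _log_mixture_offset(ws.n_forward, ws.n_backward)

    if grid is not None:
        grids = [np.asarray(grid, dtype=float)]
    else:
        if center is None:
            center = bar_estimate(ws).delta_g
        if half_span is None:
            pooled = np.concatenate([ws.forward, -ws.backward])
            spread = float(np.std(pooled)) if pooled.size > 1 else 0.0
            half_span = max(10.0 * ws.thermo.kbt, 5.0 * spread)
        grids = [
            np.linspace(center - half_span * 2**k, center + half_span * 2**k, n_points)
            for k in range(_MAX_WIDEN + 1)
        ]

    last_edge_mass = None
    for g in grids:
        ll = _log_likelihood_on_grid(g, ws.forward, ws.backward, beta, m_offset)
        ll -= ll.max()
        dens = np.exp(ll)
        norm = np.trapezoid(dens, g)
        dens /= norm
        edge = max(2, g.size // 50)  # outer 2% of points per side
        edge_mass = np.trapezoid(dens[:edge], g[:edge]) + np.trapezoid(
            dens[-edge:], g[-edge:]
        )
        last_edge_mass = edge_mass
        if edge_mass <= _EDGE_MASS_TOL:
            return PosteriorDensity(g, dens, ws.thermo, ws.n_forward, ws.n_backward)
    raise ConvergenceError(
        f"posterior mass clipped at grid edges (edge mass {last_edge_mass:.3g}) "
        f"after {_MAX_WIDEN} widenings"
    )


def crooks_bayes_estimate(post: PosteriorDensity) -> FreeEnergyEstimate:
    """Posterior mean ± posterior SD, the square-error-optimal CB estimate."""
    integral = np.trapezoid(post.density, post.grid)
    if abs(integral - 1.0) > _NORM_TOL:
        raise RuntimeError(f"posterior not normalized (integral={integral})")
    return FreeEnergyEstimate(
        delta_g=post.mean(),
        std_error=post.std(),
        method="cb",
        n_forward=post.n_forward,
        n_backward=post.n_backward,
    )


def crooks_bayes(ws: WorkSet, **kwargs) -> FreeEnergyEstimate:
    """Convenience wrapper: posterior construction + moment estimate."""
    return crooks_bayes_estimate(crooks_bayes_posterior(ws, **kwargs))


def _bar_residual(delta_g, forward, backward, beta, m_offset):
    """Increasing-in-Δg residual whose root is the BAR/ML estimate.

    Stationarity of the logistic likelihood:
        Σ_fwd f(−β(W_i − Δg) − M) − Σ_bwd f(−β(W_j + Δg) + M) = 0.
    """
    a = expit(-(beta * (forward - delta_g) + m_offset)).sum()
    b = expit(-(beta * (backward + delta_g) - m_offset)).sum()
    return a - b


def bar_estimate(ws: WorkSet) -> FreeEnergyEstimate:
    """Bennett acceptance ratio (maximum-likelihood two-sided) estimate.

    The root is bracketed starting from the two one-sided Jarzynski
    estimates, expanding until the residual changes sign (at most
    50 k_BT beyond the data range), then refined with Brent's method.
    The standard error is the asymptotic ML variance
    ``(1/β²)·([Σ f(x)f(−x)]⁻¹ − 1/n_F − 1/n_R)`` evaluated at the root.
    """
    _require_two_sided(ws, "bar_estimate")
    beta = ws.thermo.beta
    m_offset = _log_mixture_offset(ws.n_forward, ws.n_backward)
    fwd, bwd = ws.forward, ws.backward

    g_f = jarzynski_estimate(fwd, ws.thermo).delta_g
    g_b = -jarzynski_estimate(bwd, ws.thermo).delta_g
    lo, hi = min(g_f, g_b), max(g_f, g_b)
    if lo == hi:
        lo -= 1e-6
        hi += 1e-6

    data_lo = float(min(fwd.min(), (-bwd).min()))
    data_hi = float(max(fwd.max(), (-bwd).max()))
    limit_lo = data_lo - 50.0 * ws.thermo.kbt
    limit_hi = data_hi + 50.0 * ws.thermo.kbt

    def resid(g):
        return _bar_residual(g, fwd, bwd, beta, m_offset)

    # residual is increasing in Δg: expand downward while positive, upward
    # while negative
    step = max(hi - lo, ws.thermo.kbt)
    while resid(lo) > 0:
        if lo <= limit_lo:
            raise ConvergenceError("BAR root not bracketed within ±50 kT of data range")
        lo = max(lo - step, limit_lo)
        step *= 2.0
    step = max(hi - lo, ws.thermo.kbt)
    while resid(hi) < 0:
        if hi >= limit_hi:
            raise ConvergenceError("BAR root not bracketed within ±50 kT of data range")
        hi = min(hi + step, limit_hi)
        step *= 2.0

    root = float(brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16))

    x = beta * (fwd - root) + m_offset
    y = beta * (bwd + root) - m_offset
    fisher = float((expit(x) * expit(-x)).sum() + (expit(y) * expit(-y)).sum())
    if fisher > 0:
        var = (1.0 / fisher - 1.0 / ws.n_forward - 1.0 / ws.n_backward) / beta**2
        se = float(np.sqrt(var)) if var > 0 else 0.0
    else:
        se = None
    return FreeEnergyEstimate(
        delta_g=root,
        std_error=se,
        method="bar",
        n_forward=ws.n_forward,
        n_backward=ws.n_backward,
    )


def histogram_crossing(ws: WorkSet, bins: int | str = "fd") -> FreeEnergyEstimate:
    """Crossing point of the forward and negated-backward work histograms.

    By the Crooks relation the two densities cross exactly at W* = ΔG.
    Both samples are binned on shared uniform bins (Freedman–Diaconis by
    default) over the union support; the crossing is located by linear
    interpolation between adjacent bin centers where the density
    difference changes sign.  With several crossings, the one inside the
    overlap region closest to the BAR estimate wins.  No standard error
    is defined for this construction.
    """
    if ws.n_forward < 10 or ws.n_backward < 10:
        raise DataError(
            "histogram_crossing needs >= 10 samples per direction "
            f"(got {ws.n_forward}/{ws.n_backward})"
        )
    a = ws.forward
    b = -ws.backward  # negated oxidation work, same axis as forward work

    overlap_lo = max(a.min(), b.min())
    overlap_hi = min(a.max(), b.max())
    if overlap_lo > overlap_hi:
        raise NoCrossingError(
            "forward and negated-backward histograms have disjoint support"
        )
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        raise DegenerateCrossingError(
            "forward and negated-backward samples are identical; crossing "
            "undefined — use the CB or BAR estimator"
        )

    pooled = np.concatenate([a, b])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    dens_a, _ = np.histogram(a, bins=edges, density=True)
    dens_b, _ = np.histogram(b, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    diff = dens_a - dens_b

    if np.all(diff == 0):
        raise DegenerateCrossingError("work histograms coincide in every bin")

    crossings: list[float] = []
    for i in range(diff.size - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0 and (dens_a[i] > 0 or dens_b[i] > 0):
            crossings.append(float(centers[i]))
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            crossings.append(float(centers[i] + frac * (centers[i + 1] - centers[i])))
    if diff[-1] == 0.0 and (dens_a[-1] > 0 or dens_b[-1] > 0):
        crossings.append(float(centers[-1]))

    inside = [c for c in crossings if overlap_lo <= c <= overlap_hi]
    if not inside:
        raise NoCrossingError(
            "no histogram crossing found inside the overlap region "
            f"[{overlap_lo:.3g}, {overlap_hi:.3g}]"
        )
    anchor = bar_estimate(ws).delta_g
    best = min(inside, key=lambda c: abs(c - anchor))
    return FreeEnergyEstimate(
        delta_g=best,
        std_error=None,
        method="crossing",
        n_forward=ws.n_forward,
        n_backward=ws.n_backward,
        diagnostics={"n_crossings": len(inside), "bar_anchor": anchor},
    )


def jarzynski_estimate(
    values: Sequence[float] | np.ndarray,
    thermo: ThermoState | None = None,
    method: str = "jarzynski",
) -> FreeEnergyEstimate:
    """One-sided exponential work average, ΔG = −β⁻¹ ln⟨e^(−βW)⟩.

    Computed with log-sum-exp.  For instantaneous switches this is
    identical to Zwanzig's free-energy-perturbation formula
    (``fep_estimate`` is an alias).  Applied to *backward* (oxidation)
    work values, the number returned estimates the free energy of the
    backward process, i.e. −ΔG of reduction; the caller flips the sign.
    """
    thermo = thermo or make_thermo()
    w = np.asarray(values, dtype=float).ravel()
    if w.size == 0:
        raise DataError("jarzynski_estimate needs at least one work value")
    beta = thermo.beta
    log_mean = logsumexp(-beta * w) - np.log(w.size)
    return FreeEnergyEstimate(
        delta_g=float(-log_mean / beta),
        std_error=None,
        method=method,
        n_forward=int(w.size),
        n_backward=0,
    )


def fep_estimate(
    values: Sequence[float] | np.ndarray, thermo: ThermoState | None = None
) -> FreeEnergyEstimate:
    """Zwanzig FEP — the Jarzynski estimator under another name."""
    return jarzynski_estimate(values, thermo, method="fep")


def lr_estimate(
    values: Sequence[float] | np.ndarray, thermo: ThermoState | None = None
) -> FreeEnergyEstimate:
    """Linear-response (Gaussian work) estimate ΔG = ⟨W⟩ − βσ²/2."""
    thermo = thermo or make_thermo()
    w = np.asarray(values, dtype=float).ravel()
    if w.size < 2:
        raise DataError("lr_estimate needs at least two work values")
    mean = float(w.mean())
    var = float(w.var(ddof=1))
    return FreeEnergyEstimate(
        delta_g=mean - thermo.beta * var / 2.0,
        std_error=None,
        method="lr",
        n_forward=int(w.size),
        n_backward=0,
    )


def convergence_curve(
    ws: WorkSet, mu_schedule: Sequence[int], **cb_kwargs
) -> ConvergenceSeries:
    """CB estimate on growing prefix subsets of the work samples.

    For each μ in the (increasing) schedule the estimate uses the first μ
    forward and first μ backward values in trajectory order, mirroring
    how the posterior sharpens as more switching events accumulate.
    Schedule entries beyond the available data are dropped with a warning.
    """
    _require_two_sided(ws, "convergence_curve")
    mus = [int(m) for m in mu_schedule]
    if any(b <= a for a, b in zip(mus, mus[1:])):
        raise DataError("mu_schedule must be strictly increasing")
    if any(m < 1 for m in mus):
        raise DataError("mu_schedule entries must be >= 1")
    n_max = min(ws.n_forward, ws.n_backward)
    kept = [m for m in mus if m <= n_max]
    if len(kept) < len(mus):
        warnings.warn(
            f"mu_schedule truncated at the available {n_max} samples/direction",
            stacklevel=2,
        )
    if not kept:
        raise DataError("mu_schedule has no entry within the available data")
    estimates, errors = [], []
    for mu in kept:
        sub = WorkSet(ws.forward[:mu], ws.backward[:mu], ws.thermo, ws.label)
        est = crooks_bayes(sub, **cb_kwargs)
        estimates.append(est.delta_g)
        errors.append(est.std_error)
    return ConvergenceSeries(np.array(kept), np.array(estimates), np.array(errors))


def write_posterior_tsv(post: PosteriorDensity, path: str | Path) -> None:
    """Two-column TSV export (delta_g_kjmol, density) for plotting."""
    with open(path, "w") as fh:
        fh.write("delta_g_kjmol\tdensity\n")
        for g, d in zip(post.grid, post.density):
            fh.write(f"{float(g)!r}\t{float(d)!r}\n")
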
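"""Crooks-consistent synthetic work data and titration curves.

A Gaussian forward work distribution N(ΔG + βσ²/2, σ²) paired with a
backward (oxidation) work distribution N(−ΔG + βσ²/2, σ²) satisfies the
Crooks fluctuation relation exactly with free-energy difference ΔG, so
every estimator can be validated against an analytic ground truth
without running any simulation.  A Gaussian-mixture variant (each
component exponentially tilted into its exact backward conjugate) serves
as a non-Gaussian stress test, still exactly Crooks-consistent.

None of this emulates force-field physics, solvent contributions or the
time-correlation structure of real trajectories; it only fixes the work
*distributions* and the ground truth they encode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidParameterError
from .nernst import TitrationCurve, nernst_fraction
from .thermo import make_thermo
from .work import OXIDIZED, REDUCED, SnapshotEnergyPair, WorkSet


@dataclass(frozen=True)
class SyntheticWorkSpec:
    """Ground truth and sampling plan for synthetic work values.

    delta_g_true : kJ/mol, the encoded free-energy difference.
    sigma : kJ/mol >= 0, the work-distribution SD (0 = quasistatic limit).
    n_per_direction : samples per protocol direction.
    temperature : kelvin (default 298, the simulation temperature).
    seed : integer feeding a single named PRNG; no global state.
    """

    delta_g_true: float
    sigma: float
    n_per_direction: int
    temperature: float = 298.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.n_per_direction < 1:
            raise InvalidParameterError("n_per_direction must be >= 1")


def generate_crooks_gaussian(spec: SyntheticWorkSpec) -> WorkSet:
    """Sample a Crooks-exact Gaussian WorkSet with known ΔG.

    Forward ~ N(ΔG + βσ²/2, σ²), backward ~ N(−ΔG + βσ²/2, σ²).  The
    dissipated work βσ²/2 appears symmetrically in both directions, which
    is exactly what the Crooks relation demands of Gaussian work.  At
    σ = 0 every forward value equals ΔG (the quasistatic limit).
    """
    thermo = make_thermo(spec.temperature)
    rng = np.random.default_rng(spec.seed)
    diss = thermo.beta * spec.sigma**2 / 2.0
    fwd = rng.normal(spec.delta_g_true + diss, spec.sigma, spec.n_per_direction)
    bwd = rng.normal(-spec.delta_g_true + diss, spec.sigma, spec.n_per_direction)
    return WorkSet(fwd, bwd, thermo, label=f"synthetic(dg={spec.delta_g_true})")


def mixture_ground_truth(
    weights: np.ndarray, means: np.ndarray, sigmas: np.ndarray, beta: float
) -> float:
    """Closed-form ΔG encoded by a Gaussian-mixture forward work density.

    From ⟨e^(−βW)⟩ = e^(−βΔG):  ΔG = −β⁻¹ ln Σ_k w_k e^(−βm_k + β²s_k²/2).
    """
    w = np.asarray(weights, float)
    m = np.asarray(means, float)
    s = np.asarray(sigmas, float)
    log_terms = np.log(w) - beta * m + beta**2 * s**2 / 2.0
    return float(-logsumexp(log_terms) / beta)


def generate_crooks_mixture(
    weights,
    means,
    sigmas,
    n_per_direction: int,
    temperature: float = 298.0,
    seed: int = 0,
) -> tuple[WorkSet, float]:
    """Crooks-exact Gaussian-mixture WorkSet; returns (workset, ΔG_true).

    Each forward component N(m, s²) with weight w has the exactly
    conjugate backward component N(m − βs², s²) with weight
    ∝ w·e^(−βm + β²s²/2) (tilting by e^(−β(W−ΔG)) maps a Gaussian to a
    shifted Gaussian); backward work values are the negated draws.
    """
    thermo = make_thermo(temperature)
    beta = thermo.beta
    w = np.asarray(weights, float)
    w = w / w.sum()
    m = np.asarray(means, float)
    s = np.asarray(sigmas, float)
    dg = mixture_ground_truth(w, m, s, beta)

    rng = np.random.default_rng(seed)
    comp_f = rng.choice(w.size, size=n_per_direction, p=w)
    fwd = rng.normal(m[comp_f], s[comp_f])

    log_wb = np.log(w) - beta * m + beta**2 * s**2 / 2.0
    wb = np.exp(log_wb - logsumexp(log_wb))
    comp_b = rng.choice(w.size, size=n_per_direction, p=wb)
    # negated-backward coordinate is distributed as the tilted mixture
    bwd = -rng.normal(m[comp_b] - beta * s[comp_b] ** 2, s[comp_b])
    return WorkSet(fwd, bwd, thermo, label="synthetic-mixture"), dg


def generate_energy_table(
    spec: SyntheticWorkSpec,
    n_replicates: int = 10,
    baseline_sd: float = 100.0,
    system: str = "synthetic",
) -> list[SnapshotEnergyPair]:
    """Snapshot-energy pairs whose Kubo–Onsager works reproduce the spec.

    Oxidized-ensemble frames get a baseline eps_ox ~ N(0, baseline_sd²)
    and eps_red = eps_ox + W_fwd; reduced-ensemble frames the mirror
    construction.  The default baseline_sd of 100 kJ/mol mimics the
    magnitude of protein potential-energy fluctuations relative to the
    few-kJ/mol redox signal.  Frames are split evenly over replicates.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    ws = generate_crooks_gaussian(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_per_direction
    base_ox = rng.normal(0.0, baseline_sd, n)
    base_red = rng.normal(0.0, baseline_sd, n)
    pairs: list[SnapshotEnergyPair] = []
    per_rep = -(-n // n_replicates)  # ceil
    for i in range(n):
        rep = str(i // per_rep)
        pairs.append(
            SnapshotEnergyPair(
                system=system,
                replicate=rep,
                frame=f"ox{i}",
                source_ensemble=OXIDIZED,
                eps_ox=float(base_ox[i]),
                eps_red=float(base_ox[i] + ws.forward[i]),
            )
        )
    for i in range(n):
        rep = str(i // per_rep)
        pairs.append(
            SnapshotEnergyPair(
                system=system,
                replicate=rep,
                frame=f"red{i}",
                source_ensemble=REDUCED,
                eps_red=float(base_red[i]),
                eps_ox=float(base_red[i] + ws.backward[i]),
            )
        )
    return pairs


def generate_titration(
    midpoint: float,
    n_points: int = 25,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 298.0,
) -> TitrationCurve:
    """Synthetic 1-electron titration curve around a known midpoint (mV).

    Applied potentials span midpoint ± 150 mV uniformly; the response is
    the Nernst reduced fraction (decreasing with potential: reduction is
    favored at low applied potential) plus N(0, noise_sd²) noise, clipped
    to [−0.1, 1.1] as a crude model of normalized-absorbance excursions.
    """
    if n_points < 4:
        raise InvalidParameterError("n_points must be >= 4")
    rng = np.random.default_rng(seed)
    e_app = np.linspace(midpoint - 150.0, midpoint + 150.0, n_points)
    resp = nernst_fraction(e_app, midpoint, temperature=temperature)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, n_points)
    resp = np.clip(resp, -0.1, 1.1)
    return TitrationCurve(applied_potential=e_app, response=resp)
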
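"""Redox-shift tables, error propagation and correlation benchmarking.

Absolute potentials from molecular-mechanics energies are uncalibrated
(force-field energy differences omit quantum contributions such as the
heme's ionization energy and polarization), so predictions are reported
as shifts δE relative to a reference protein, with errors combined in
quadrature.  Benchmarking correlates each prediction column against the
experimental shifts, excluding the reference's trivial (0, 0) row, both
over all mutants and over single mutants only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, UndefinedCorrelationError
from .thermo import RedoxEstimate


@dataclass(frozen=True)
class ShiftResult:
    """δE = E_mut − E_ref (mV) with quadrature-propagated error."""

    system: str
    reference: str
    delta_e: float
    std_error: float

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


def compute_shift(
    est_mut: RedoxEstimate,
    est_ref: RedoxEstimate,
    system: str = "",
    reference: str = "",
) -> ShiftResult:
    """Subtract the reference potential from the mutant's, propagating errors."""
    if est_mut.method != est_ref.method:
        warnings.warn(
            f"comparing estimates from different methods "
            f"({est_mut.method!r} vs {est_ref.method!r})",
            stacklevel=2,
        )
    e1 = est_mut.std_error or 0.0
    e2 = est_ref.std_error or 0.0
    return ShiftResult(
        system=system,
        reference=reference,
        delta_e=est_mut.potential - est_ref.potential,
        std_error=math.hypot(e1, e2),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors out on short or constant input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise DataError("sequences must have equal length")
    if xa.size < 3:
        raise DataError("pearson_correlation needs at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("zero variance in one of the sequences")
    return float(stats.pearsonr(xa, ya).statistic)


# Published benchmark for the m4D2 maquette (a de novo four-helix-bundle
# heme protein) and its point variants: experimental shifts vs the
# reference protein, the MD-based Crooks–Bayes predictions, and
# continuum-electrostatics (Poisson–Boltzmann + Monte Carlo) predictions.
# δE in mV; DM is the T19D-T77D double mutant.
M4D2_REFERENCE = "m4D2"
M4D2_DOUBLE_MUTANTS = ("DM",)


def m4d2_shift_table() -> pd.DataFrame:
    """The m4D2 mutant benchmark as a ShiftTable DataFrame."""
    return pd.DataFrame(
        {
            "system": ["m4D2", "T19D", "M23N", "R34Q", "R92Q", "DM"],
            "exp_dE_mV": [0.0, -28.0, 1.0, -31.0, -32.0, -56.0],
            "exp_err_mV": [0.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            "md_cb_dE_mV": [0.0, -4.0, 14.0, -12.0, -14.0, -12.0],
            "md_cb_err_mV": [0.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            "pb_mc_dE_mV": [0.0, -35.0, 0.0, -11.0, -14.0, -67.0],
        }
    )


def _method_columns(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c.endswith("_dE_mV") and c != "exp_dE_mV"
    ]


def benchmark_report(
    table: pd.DataFrame,
    reference: str | None = None,
    double_mutants: Sequence[str] | None = None,
) -> dict:
    """Per-method Pearson correlations of predicted vs experimental shifts.

    ``table`` needs columns system, exp_dE_mV and at least one
    ``<method>_dE_mV`` prediction column.  The reference row (δE = 0; by
    label if given, else detected) is excluded from all correlations.
    Correlations are reported over all mutants and over single mutants
    only (``double_mutants`` labels excluded; default: labels equal to
    "DM" or containing '-').  The mean signed offset between prediction
    and experiment over single mutants is reported with both sign
    conventions.
    """
    if "exp_dE_mV" not in table.columns:
        raise DataError("shift table lacks the experimental column exp_dE_mV")
    if "system" not in table.columns:
        raise DataError("shift table lacks a system column")
    methods = _method_columns(table)
    if not methods:
        raise DataError("shift table has no prediction columns (*_dE_mV)")

    if reference is None:
        ref_rows = table.index[table["exp_dE_mV"] == 0.0]
        if len(ref_rows) == 0:
            raise DataError("no reference row (exp_dE_mV == 0) in shift table")
        ref_idx = ref_rows[0]
    else:
        ref_rows = table.index[table["system"] == reference]
        if len(ref_rows) == 0:
            raise DataError(f"reference system {reference!r} not in shift table")
        ref_idx = ref_rows[0]

    mutants = table.drop(index=ref_idx)
    if len(mutants) < 3:
        raise DataError("benchmark needs >= 3 non-reference rows")
    if double_mutants is None:
        double_mutants = [
            s for s in mutants["system"] if "-" in str(s) or str(s).upper() == "DM"
        ]
    singles = mutants[~mutants["system"].isin(double_mutants)]

    report: dict = {
        "reference": str(table.loc[ref_idx, "system"]),
        "n_mutants": int(len(mutants)),
        "n_single_mutants": int(len(singles)),
        "methods": {},
    }
    exp_all = mutants["exp_dE_mV"].to_numpy(float)
    exp_single = singles["exp_dE_mV"].to_numpy(float)
    for col in methods:
        name = col[: -len("_dE_mV")]
        pred_all = mutants[col].to_numpy(float)
        pred_single = singles[col].to_numpy(float)
        entry = {"pearson_all": pearson_correlation(exp_all, pred_all)}
        if len(singles) >= 3:
            entry["pearson_single"] = pearson_correlation(exp_single, pred_single)
            offset = float(np.mean(pred_single - exp_single))
            entry["mean_offset_pred_minus_exp_mV"] = offset
            entry["mean_offset_exp_minus_pred_mV"] = -offset
        report["methods"][name] = entry
    return report


def render_benchmark_tsv(report: dict) -> str:
    """Human-readable TSV rendering (correlations to 2 decimal places)."""
    lines = ["method\tpearson_all\tpearson_single"]
    for name, entry in report["methods"].items():
        single = entry.get("pearson_single")
        single_txt = "NA" if single is None else f"{single:.2f}"
        lines.append(f"{name}\t{entry['pearson_all']:.2f}\t{single_txt}")
    return "\n".join(lines) + "\n"


def render_benchmark_json(report: dict) -> str:
    """Full-precision JSON rendering, deterministically ordered."""
    return json.dumps(report, indent=2, sort_keys=True)


def read_shift_table(path) -> pd.DataFrame:
    """Read a shift-table CSV (system,exp_dE_mV,exp_err_mV,<method>_dE_mV,...)."""
    df = pd.read_csv(path)
    if "system" not in df.columns or "exp_dE_mV" not in df.columns:
        raise DataError(f"{path}: shift table needs system and exp_dE_mV columns")
    return df
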
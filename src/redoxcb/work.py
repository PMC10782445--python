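"""Per-snapshot energy pairs and nonequilibrium work bookkeeping.

The instantaneous-switching (Kubo–Onsager) picture: each equilibrium
snapshot of one redox state is re-evaluated with the other state's
Hamiltonian, and the statistical work is the final-minus-initial energy
difference.  Snapshots from the *oxidized* ensemble define the forward
(reduction) protocol; snapshots from the *reduced* ensemble define the
backward (oxidation) protocol.  Energies are protein-only contributions,
in kJ/mol, taken as given.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .thermo import ThermoState, make_thermo

FORWARD = "forward"   # reduction: electron appears
BACKWARD = "backward"  # oxidation: electron removed

OXIDIZED = "oxidized"
REDUCED = "reduced"

# accepted spellings for the source_ensemble column
_ENSEMBLE_ALIASES = {
    "oxidized": OXIDIZED,
    "oxidised": OXIDIZED,
    "ox": OXIDIZED,
    "reduced": REDUCED,
    "red": REDUCED,
}

_REQUIRED_COLUMNS = (
    "system",
    "replicate",
    "frame",
    "source_ensemble",
    "eps_ox_kjmol",
    "eps_red_kjmol",
)


@dataclass(frozen=True)
class SnapshotEnergyPair:
    """Potential energies of one MD snapshot evaluated in both redox states.

    ``source_ensemble`` names the ensemble the snapshot was drawn from
    ("oxidized" or "reduced"); ``eps_ox``/``eps_red`` are the protein
    potential energies (kJ/mol) with the oxidized/reduced Hamiltonian.
    """

    system: str
    replicate: str
    frame: str
    source_ensemble: str
    eps_ox: float
    eps_red: float

    def __post_init__(self) -> None:
        ens = _ENSEMBLE_ALIASES.get(str(self.source_ensemble).strip().lower())
        if ens is None:
            raise DataError(
                f"unknown source_ensemble {self.source_ensemble!r} "
                f"(system={self.system}, replicate={self.replicate}, frame={self.frame})"
            )
        object.__setattr__(self, "source_ensemble", ens)
        if not (math.isfinite(self.eps_ox) and math.isfinite(self.eps_red)):
            raise DataError(
                f"non-finite energy in snapshot (system={self.system}, "
                f"replicate={self.replicate}, frame={self.frame}): "
                f"eps_ox={self.eps_ox}, eps_red={self.eps_red}"
            )


@dataclass(frozen=True)
class WorkSample:
    """One statistical work value (kJ/mol) with its protocol direction."""

    value: float
    direction: str
    origin: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, BACKWARD):
            raise DataError(f"direction must be forward/backward, got {self.direction!r}")
        if not math.isfinite(self.value):
            raise DataError(f"non-finite work value (origin={self.origin})")


def compute_work(pair: SnapshotEnergyPair) -> WorkSample:
    """Kubo–Onsager work for one snapshot.

    Oxidized-ensemble snapshot -> forward (reduction) work ``eps_red − eps_ox``;
    reduced-ensemble snapshot -> backward (oxidation) work ``eps_ox − eps_red``.
    """
    origin = (pair.replicate, pair.frame)
    if pair.source_ensemble == OXIDIZED:
        return WorkSample(pair.eps_red - pair.eps_ox, FORWARD, origin)
    return WorkSample(pair.eps_ox - pair.eps_red, BACKWARD, origin)


@dataclass
class WorkSet:
    """Forward (reduction) and backward (oxidation) work samples, pooled.

    Values are kJ/mol; ``thermo`` supplies the inverse temperature every
    Boltzmann factor downstream uses.  Either direction may be empty, but
    two-sided estimators require at least one sample in each.
    """

    forward: np.ndarray
    backward: np.ndarray
    thermo: ThermoState
    label: str = ""
    is_empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float).ravel()
        self.backward = np.asarray(self.backward, dtype=float).ravel()
        for name, arr in (("forward", self.forward), ("backward", self.backward)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite {name} work values in WorkSet {self.label!r}")
        self.is_empty = self.forward.size == 0 and self.backward.size == 0

    @property
    def n_forward(self) -> int:
        return int(self.forward.size)

    @property
    def n_backward(self) -> int:
        return int(self.backward.size)

    def swapped(self) -> "WorkSet":
        """Exchange the two protocol directions (ΔG -> −ΔG for all estimators)."""
        return WorkSet(self.backward.copy(), self.forward.copy(), self.thermo, self.label)


def build_workset(
    pairs: Sequence[SnapshotEnergyPair],
    thermo: ThermoState | None = None,
    system: str | None = None,
) -> WorkSet:
    """Pool work values from snapshot pairs into one :class:`WorkSet`.

    All pairs must belong to one system; input order is preserved within
    each direction.  An empty input yields an empty WorkSet and a warning.
    """
    thermo = thermo or make_thermo()
    if not pairs:
        warnings.warn("building WorkSet from an empty pair list", stacklevel=2)
        return WorkSet(np.empty(0), np.empty(0), thermo, label=system or "")
    systems = {p.system for p in pairs}
    if system is not None:
        systems.add(system)
    if len(systems) > 1:
        raise DataError(f"pairs span multiple systems: {sorted(systems)}")
    fwd = [compute_work(p).value for p in pairs if p.source_ensemble == OXIDIZED]
    bwd = [compute_work(p).value for p in pairs if p.source_ensemble == REDUCED]
    return WorkSet(np.array(fwd), np.array(bwd), thermo, label=next(iter(systems)))


def build_worksets_by_replicate(
    pairs: Sequence[SnapshotEnergyPair],
    thermo: ThermoState | None = None,
) -> dict[str, WorkSet]:
    """Per-replicate WorkSets for convergence / outlier diagnostics."""
    groups: dict[str, list[SnapshotEnergyPair]] = {}
    for p in pairs:
        groups.setdefault(p.replicate, []).append(p)
    return {rep: build_workset(grp, thermo) for rep, grp in groups.items()}


def read_energy_table(path: str | Path, dialect: str = "csv") -> list[SnapshotEnergyPair]:
    """Read a snapshot-energy table (CSV or TSV, header row required).

    Required columns: system, replicate, frame, source_ensemble,
    eps_ox_kjmol, eps_red_kjmol.  Errors name the offending line
    (1-based, counting the header as line 1).
    """
    if dialect not in ("csv", "tsv"):
        raise DataError(f"unknown dialect {dialect!r}; use 'csv', 'tsv' or read_xvg_pairs()")
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    pairs: list[SnapshotEnergyPair] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            eps_ox = float(row["eps_ox_kjmol"])
            eps_red = float(row["eps_red_kjmol"])
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path}:{line_no}: unparseable energy value") from exc
        try:
            pairs.append(
                SnapshotEnergyPair(
                    system=str(row["system"]),
                    replicate=str(row["replicate"]),
                    frame=str(row["frame"]),
                    source_ensemble=str(row["source_ensemble"]),
                    eps_ox=eps_ox,
                    eps_red=eps_red,
                )
            )
        except DataError as exc:
            raise DataError(f"{path}:{line_no}: {exc}") from None
    return pairs


def _read_xvg_column(path: str | Path) -> np.ndarray:
    """Last numeric column of a lenient xvg file ('#'/'@' lines skipped)."""
    values = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            tokens = line.split()
            try:
                values.append(float(tokens[-1]))
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: unparseable numeric {tokens[-1]!r}") from exc
    return np.asarray(values, dtype=float)


def read_xvg_pairs(
    ox_path: str | Path,
    red_path: str | Path,
    source_ensemble: str,
    system: str = "",
    replicate: str = "0",
) -> list[SnapshotEnergyPair]:
    """Match two xvg energy files frame-by-frame into snapshot pairs.

    ``ox_path``/``red_path`` hold the same frames re-evaluated with the
    oxidized / reduced Hamiltonian; ``source_ensemble`` says which ensemble
    the frames were sampled from.
    """
    eps_ox = _read_xvg_column(ox_path)
    eps_red = _read_xvg_column(red_path)
    if eps_ox.size != eps_red.size:
        raise DataError(
            f"xvg pair length mismatch: {ox_path} has {eps_ox.size} frames, "
            f"{red_path} has {eps_red.size}"
        )
    return [
        SnapshotEnergyPair(
            system=system,
            replicate=replicate,
            frame=str(i),
            source_ensemble=source_ensemble,
            eps_ox=float(o),
            eps_red=float(r),
        )
        for i, (o, r) in enumerate(zip(eps_ox, eps_red))
    ]


def _read_work_column(path: str | Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            # tolerate the unicode minus some tools emit
            token = line.replace("−", "-")
            try:
                values.append(float(token))
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: unparseable work value {line!r}") from exc
    return np.asarray(values, dtype=float)


def read_work_file(
    path_forward: str | Path,
    path_backward: str | Path,
    thermo: ThermoState | None = None,
    label: str = "",
) -> WorkSet:
    """Read plain-text work files (one kJ/mol value per line, '#' comments)."""
    fwd = _read_work_column(path_forward)
    bwd = _read_work_column(path_backward)
    if fwd.size == 0 and bwd.size == 0:
        raise DataError(
            f"both work files are empty: {path_forward}, {path_backward}"
        )
    return WorkSet(fwd, bwd, thermo or make_thermo(), label=label)


def write_work_file(ws: WorkSet, path_forward: str | Path, path_backward: str | Path) -> None:
    """Write a WorkSet to forward/backward text files, round-trip exact."""
    for path, values, direction in (
        (path_forward, ws.forward, FORWARD),
        (path_backward, ws.backward, BACKWARD),
    ):
        with open(path, "w") as fh:
            fh.write(f"# {ws.label or 'workset'} {direction} work values (kJ/mol)\n")
            for v in values:
                fh.write(f"{float(v)!r}\n")
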
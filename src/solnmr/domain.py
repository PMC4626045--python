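"""Core domain types and errors shared across the pipeline.

Conventions used throughout the package:

* residue numbering is 1-based (a 196-residue construct is residues 1..196);
* relaxation delays and time constants are in milliseconds;
* chemical shifts are in ppm;
* coordinates are in angstroms;
* peak heights and noise estimates are in arbitrary spectrometer units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SolnmrError",
    "FormatError",
    "UsageError",
    "InputError",
    "DegenerateInputError",
    "EstimatorDomainError",
    "RangeError",
    "SimulationError",
    "RelaxationExperiment",
    "PeakHeightSeries",
    "ShiftList",
    "Ensemble",
    "ConstraintRecord",
]


class SolnmrError(Exception):
    """Base class for every error raised by this package."""


class FormatError(SolnmrError):
    """An input file does not conform to its documented dialect."""


class UsageError(SolnmrError):
    """An operation was invoked with an unknown option or dialect."""


class InputError(SolnmrError, ValueError):
    """Input values violate an operation's preconditions."""


class DegenerateInputError(InputError):
    """Input is formally valid but carries no usable information."""


class EstimatorDomainError(InputError):
    """Inputs fall outside an estimator's domain of validity."""


class RangeError(InputError):
    """A value falls outside the representable range of an output format."""


class SimulationError(SolnmrError):
    """A synthetic-data request is internally inconsistent or unachievable."""


class RelaxationExperiment(str, Enum):
    """Which relaxation time a peak-height decay measures."""

    T1 = "T1"
    T2 = "T2"


@dataclass
class PeakHeightSeries:
    """One residue's peak heights across relaxation delays for one experiment.

    Delays are sorted on construction (heights are reordered with them) and
    must be strictly positive and distinct; at least three points are required
    for an exponential fit to be meaningful.
    """

    residue_number: int
    experiment: RelaxationExperiment
    delays_ms: np.ndarray
    heights: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.experiment = RelaxationExperiment(self.experiment)
        delays = np.asarray(self.delays_ms, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if delays.ndim != 1 or heights.shape != delays.shape:
            raise InputError(
                f"residue {self.residue_number}: delays and heights must be "
                f"1-D arrays of equal length"
            )
        if len(delays) < 3:
            raise InputError(
                f"residue {self.residue_number}: need >= 3 (delay, height) "
                f"pairs, got {len(delays)}"
            )
        order = np.argsort(delays)
        delays, heights = delays[order], heights[order]
        if not np.all(delays > 0):
            raise InputError(
                f"residue {self.residue_number}: delays must be strictly positive"
            )
        if not np.all(np.diff(delays) > 0):
            raise InputError(
                f"residue {self.residue_number}: duplicate relaxation delays"
            )
        if not (self.noise_sd >= 0):
            raise InputError(
                f"residue {self.residue_number}: noise_sd must be >= 0"
            )
        self.delays_ms = delays
        self.heights = heights

    def __len__(self) -> int:
        return len(self.delays_ms)


@dataclass
class ShiftList:
    """Backbone amide chemical shifts: residue -> (delta 1H, delta 15N) in ppm."""

    entries: Dict[int, Tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        clean: Dict[int, Tuple[float, float]] = {}
        for res, (dh, dn) in self.entries.items():
            dh, dn = float(dh), float(dn)
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise InputError(
                    f"shift list {self.label!r}: non-finite shift for residue {res}"
                )
            clean[int(res)] = (dh, dn)
        self.entries = clean

    def residues(self) -> set[int]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, residue: int) -> bool:
        return residue in self.entries

    def __getitem__(self, residue: int) -> Tuple[float, float]:
        return self.entries[residue]


ATOM_TABLE_COLUMNS = ["residue_number", "residue_name", "atom_name", "chain_id"]


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one atom table.

    ``atom_table`` has one row per atom with columns residue_number,
    residue_name, atom_name, chain_id; ``coords`` has shape
    (n_models, n_atoms, 3) in angstroms, rows aligned with the atom table.
    """

    atom_table: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InputError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise InputError("an ensemble needs at least one model")
        if list(self.atom_table.columns) != ATOM_TABLE_COLUMNS:
            self.atom_table = self.atom_table[ATOM_TABLE_COLUMNS]
        if len(self.atom_table) != coords.shape[1]:
            raise InputError(
                f"atom table has {len(self.atom_table)} rows but coordinates "
                f"have {coords.shape[1]} atoms"
            )
        self.atom_table = self.atom_table.reset_index(drop=True)
        self.coords = coords

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, index: int) -> np.ndarray:
        """Coordinates of one conformer, shape (n_atoms, 3)."""
        return self.coords[index]

    def residue_numbers(self) -> list[int]:
        """Distinct residue numbers in atom-table order."""
        seen: dict[int, None] = {}
        for r in self.atom_table["residue_number"]:
            seen.setdefault(int(r), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Ensemble":
        return Ensemble(atom_table=self.atom_table, coords=coords)


@dataclass(frozen=True)
class ConstraintRecord:
    """One NOE-derived upper-limit distance restraint between two protons."""

    residue_i: int
    residue_name_i: str
    atom_i: str
    residue_j: int
    residue_name_j: str
    atom_j: str
    upper_limit: float

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise InputError(
                f"restraint residues must be >= 1, got "
                f"({self.residue_i}, {self.residue_j})"
            )
        if not self.upper_limit > 0:
            raise InputError(
                f"restraint upper limit must be positive, got {self.upper_limit}"
            )
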
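"""Distance-restraint bookkeeping: sequence-separation bins and per-residue averages.

NOESY-derived upper-limit restraints are conventionally binned by the
sequence separation s = |i - j| of the two residues they connect.  Two
binning conventions are supported:

* ``"wide_medium"`` (default): intra s = 0, sequential s = 1,
  medium 1 < s <= 5, long s > 5;
* ``"narrow_medium"``: intra s = 0, sequential s = 1, medium 2 <= s <= 4,
  long s >= 5 (a common alternative in the literature).

Per-residue averages divide by the construct length:
total/residue = (distance + phi + psi restraints) / n_residues and
long/residue = long-range count / n_residues.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .domain import ConstraintRecord, InputError, UsageError

logger = logging.getLogger(__name__)

SEPARATION_BINS = ("intra", "sequential", "medium", "long")


@dataclass(frozen=True)
class ConstraintSummary:
    """Restraint counts per bin plus per-residue averages."""

    n_intra: int
    n_sequential: int
    n_medium: int
    n_long: int
    n_phi: int
    n_psi: int
    n_residues: int

    @property
    def n_total(self) -> int:
        return self.n_intra + self.n_sequential + self.n_medium + self.n_long

    @property
    def per_residue_total(self) -> float:
        return (self.n_total + self.n_phi + self.n_psi) / self.n_residues

    @property
    def per_residue_long(self) -> float:
        return self.n_long / self.n_residues


def classify_separation(
    residue_i: int, residue_j: int, convention: str = "wide_medium"
) -> str:
    """Bin a restraint by the absolute sequence separation of its residues."""
    if residue_i < 1 or residue_j < 1:
        raise InputError(
            f"residue numbers must be >= 1, got ({residue_i}, {residue_j})"
        )
    s = abs(residue_i - residue_j)
    if s == 0:
        return "intra"
    if s == 1:
        return "sequential"
    if convention == "wide_medium":
        return "medium" if s <= 5 else "long"
    if convention == "narrow_medium":
        return "medium" if s <= 4 else "long"
    raise UsageError(f"unknown binning convention {convention!r}")


def summarize_constraints(
    records: Sequence[ConstraintRecord],
    n_phi: int = 0,
    n_psi: int = 0,
    n_residues: int = 1,
    convention: str = "wide_medium",
) -> ConstraintSummary:
    """Count restraints per separation bin and form per-residue averages.

    Duplicate identical records are counted as written (a restraint list may
    legitimately repeat a pair with different limits); exact duplicates are
    logged so careless concatenation is visible.
    """
    if n_residues < 1:
        raise InputError(f"n_residues must be >= 1, got {n_residues}")
    if n_phi < 0 or n_psi < 0:
        raise InputError("dihedral restraint counts must be >= 0")
    duplicates = [rec for rec, cnt in Counter(records).items() if cnt > 1]
    if duplicates:
        logger.warning(
            "%d restraint(s) appear more than once and are counted as written",
            len(duplicates),
        )
    counts = Counter(
        classify_separation(rec.residue_i, rec.residue_j, convention)
        for rec in records
    )
    return ConstraintSummary(
        n_intra=counts.get("intra", 0),
        n_sequential=counts.get("sequential", 0),
        n_medium=counts.get("medium", 0),
        n_long=counts.get("long", 0),
        n_phi=n_phi,
        n_psi=n_psi,
        n_residues=n_residues,
    )


def format_summary_table(summary: ConstraintSummary) -> str:
    """Render the summary as a TSV in the conventional statistics layout."""
    lines = [
        "category\tvalue",
        "Conformationally restricting distance constraints (number)\t",
        f"Intraresidue [s = 0]\t{summary.n_intra}",
        f"Sequential [s = 1]\t{summary.n_sequential}",
        f"Medium range [1 < s <= 5]\t{summary.n_medium}",
        f"Long range [s > 5]\t{summary.n_long}",
        f"Total\t{summary.n_total}",
        "Dihedral angle constraints (number)\t",
        f"phi\t{summary.n_phi}",
        f"psi\t{summary.n_psi}",
        "Constraints per residue (average number)\t",
        f"Total\t{summary.per_residue_total:.1f}",
        f"Long-range\t{summary.per_residue_long:.1f}",
    ]
    return "\n".join(lines) + "\n"
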
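"""Readers and writers for every external representation the pipeline touches.

All other modules operate on the domain types in :mod:`solnmr.domain`; file
formats never leak past this module.  Supported dialects:

* relaxation tables — TSV/CSV, one header row naming delay columns in ms,
  one row per residue (optionally a ``noise_sd`` column);
* NOE tables — TSV/CSV with columns residue, height_sat, height_unsat,
  noise_sat, noise_unsat;
* shift lists — a three-column TSV (residue, delta 1H, delta 15N) or the
  assigned-chemical-shift loop of an NMR-STAR file restricted to backbone
  H and N atoms;
* coordinates — multi-model PDB (via gemmi);
* distance restraints — upper-limit lines in the CYANA style
  ``res_i name_i atom_i res_j name_j atom_j limit``.

Every parse failure raises a typed error; readers never return a partial
silent result.  Writers round-trip their readers up to the documented
column precision.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .domain import (
    ATOM_TABLE_COLUMNS,
    ConstraintRecord,
    Ensemble,
    FormatError,
    InputError,
    PeakHeightSeries,
    RangeError,
    RelaxationExperiment,
    ShiftList,
    UsageError,
)

logger = logging.getLogger(__name__)

NOE_TABLE_COLUMNS = [
    "residue",
    "height_sat",
    "height_unsat",
    "noise_sat",
    "noise_unsat",
]

_NOISE_COLUMN = "noise_sd"


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma."""
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse table: {exc}") from exc


# ---------------------------------------------------------------------------
# relaxation peak-height tables


def read_relaxation_table(
    path: str | Path, experiment: RelaxationExperiment | str
) -> list[PeakHeightSeries]:
    """Read one peak-height-vs-delay table into per-residue series.

    The header names delay columns in ms; the first column is the residue
    number.  Rows with fewer than three finite heights are skipped with a
    warning (the fit would be under-determined).
    """
    experiment = RelaxationExperiment(experiment)
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected a residue column plus delay columns")
    delay_cols: list[str] = []
    delays: list[float] = []
    noise_col: Optional[str] = None
    for token in frame.columns[1:]:
        name = str(token).strip()
        if name.lower() == _NOISE_COLUMN:
            noise_col = token
            continue
        try:
            delays.append(float(name))
        except ValueError:
            raise FormatError(
                f"{path}: header token {name!r} is neither a delay in ms "
                f"nor '{_NOISE_COLUMN}'"
            ) from None
        delay_cols.append(token)
    residues = pd.to_numeric(frame.iloc[:, 0], errors="coerce")
    if residues.isna().any():
        bad = frame.iloc[int(residues.isna().idxmax()), 0]
        raise FormatError(f"{path}: non-numeric residue number {bad!r}")
    residues = residues.astype(int)
    if residues.duplicated().any():
        dup = int(residues[residues.duplicated()].iloc[0])
        raise FormatError(f"{path}: duplicate residue number {dup}")

    series: list[PeakHeightSeries] = []
    delays_arr = np.asarray(delays, dtype=float)
    for row_idx in range(len(frame)):
        heights = pd.to_numeric(
            frame.iloc[row_idx][delay_cols], errors="coerce"
        ).to_numpy(dtype=float)
        finite = np.isfinite(heights)
        if finite.sum() < 3:
            logger.warning(
                "%s: residue %d has %d finite heights (<3), skipped",
                path,
                int(residues.iloc[row_idx]),
                int(finite.sum()),
            )
            continue
        noise = 0.0
        if noise_col is not None:
            value = pd.to_numeric(frame.iloc[row_idx][noise_col], errors="coerce")
            noise = float(value) if np.isfinite(value) else 0.0
        series.append(
            PeakHeightSeries(
                residue_number=int(residues.iloc[row_idx]),
                experiment=experiment,
                delays_ms=delays_arr[finite],
                heights=heights[finite],
                noise_sd=noise,
            )
        )
    return series


def write_relaxation_table(
    series: Sequence[PeakHeightSeries], path: str | Path
) -> Path:
    """Write per-residue peak-height series as a TSV (inverse of the reader).

    The delay header is the union of all delays; residues missing a delay get
    a blank cell.
    """
    path = Path(path)
    all_delays = sorted({float(d) for s in series for d in s.delays_ms})
    has_noise = any(s.noise_sd != 0.0 for s in series)
    with path.open("w") as fh:
        header = ["residue"] + [_format_number(d) for d in all_delays]
        if has_noise:
            header.append(_NOISE_COLUMN)
        fh.write("\t".join(header) + "\n")
        for s in series:
            lookup = {float(d): h for d, h in zip(s.delays_ms, s.heights)}
            cells = [str(s.residue_number)]
            for d in all_delays:
                cells.append(_format_number(lookup[d]) if d in lookup else "")
            if has_noise:
                cells.append(_format_number(s.noise_sd))
            fh.write("\t".join(cells) + "\n")
    return path


def _format_number(x: float) -> str:
    return format(float(x), ".6f").rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# saturated/unsaturated NOE tables


def read_noe_table(path: str | Path) -> pd.DataFrame:
    """Read paired saturated/unsaturated peak heights, one row per residue."""
    frame = _read_table(path)
    missing = [c for c in NOE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: NOE table lacks columns {missing}")
    frame = frame[NOE_TABLE_COLUMNS].copy()
    for col in NOE_TABLE_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame = frame.dropna()
    if frame.empty:
        raise FormatError(f"{path}: no parsable NOE rows")
    frame["residue"] = frame["residue"].astype(int)
    if frame["residue"].duplicated().any():
        dup = int(frame["residue"][frame["residue"].duplicated()].iloc[0])
        raise FormatError(f"{path}: duplicate residue number {dup}")
    return frame.reset_index(drop=True)


def write_noe_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame[NOE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# chemical shift lists


def read_shift_table(
    path: str | Path, dialect: str = "tsv", label: str = ""
) -> ShiftList:
    """Read a backbone amide shift list.

    ``dialect`` is ``"tsv"`` (columns residue, delta 1H, delta 15N) or
    ``"nmrstar_loop"`` (an assigned-chemical-shift loop; only H and N rows
    are used).  Residues lacking either shift are omitted with a warning.
    """
    if dialect == "tsv":
        entries = _read_shift_tsv(path)
    elif dialect == "nmrstar_loop":
        entries = _read_shift_star(path)
    else:
        raise UsageError(f"unknown shift-list dialect {dialect!r}")
    if not entries:
        raise FormatError(f"{path}: no parsable shift rows")
    return ShiftList(entries=entries, label=label or str(path))


def _read_shift_tsv(path: str | Path) -> dict[int, tuple[float, float]]:
    frame = _read_table(path)
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: expected columns residue, delta_h, delta_n")
    entries: dict[int, tuple[float, float]] = {}
    for _, row in frame.iterrows():
        res = pd.to_numeric(row.iloc[0], errors="coerce")
        dh = pd.to_numeric(row.iloc[1], errors="coerce")
        dn = pd.to_numeric(row.iloc[2], errors="coerce")
        if not np.isfinite(res):
            raise FormatError(f"{path}: non-numeric residue {row.iloc[0]!r}")
        res = int(res)
        if not (np.isfinite(dh) and np.isfinite(dn)):
            logger.warning("%s: residue %d lacks an H or N shift, omitted", path, res)
            continue
        if res in entries:
            raise FormatError(f"{path}: duplicate residue number {res}")
        entries[res] = (float(dh), float(dn))
    return entries


_STAR_SEQ_TAGS = {"seq_id", "comp_index_id"}
_STAR_ATOM_TAG = "atom_id"
_STAR_VALUE_TAG = "val"


def _read_shift_star(path: str | Path) -> dict[int, tuple[float, float]]:
    """Minimal NMR-STAR tokenizer for the assigned-chemical-shift loop.

    Only the Seq_ID/Comp_index_ID, Atom_ID and Val tags are consumed; any
    loop that carries all three is accepted.  This is deliberately not a full
    STAR parser.
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    per_res: dict[int, dict[str, float]] = {}
    found_loop = False
    while i < len(lines):
        if lines[i] != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(lines) and lines[i].startswith("_"):
            tags.append(lines[i].split()[0])
            i += 1
        cols = {}
        for idx, tag in enumerate(tags):
            leaf = tag.split(".")[-1].lower()
            if leaf in _STAR_SEQ_TAGS:
                cols.setdefault("seq", idx)
            elif leaf == _STAR_ATOM_TAG:
                cols["atom"] = idx
            elif leaf == _STAR_VALUE_TAG:
                cols["val"] = idx
        usable = {"seq", "atom", "val"} <= cols.keys()
        while i < len(lines):
            line = lines[i]
            if line in ("stop_", "loop_") or line.startswith("save_"):
                break
            if usable and line and not line.startswith("#"):
                fields = line.split()
                if len(fields) != len(tags):
                    raise FormatError(
                        f"{path}: loop row has {len(fields)} fields for "
                        f"{len(tags)} tags: {line!r}"
                    )
                try:
                    res = int(fields[cols["seq"]])
                    atom = fields[cols["atom"]]
                    value = float(fields[cols["val"]])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad loop row {line!r}") from exc
                if atom in ("H", "HN", "N"):
                    key = "H" if atom in ("H", "HN") else "N"
                    per_res.setdefault(res, {})[key] = value
            if line == "loop_":
                break
            i += 1
        if usable:
            found_loop = True
        if i < len(lines) and lines[i] == "stop_":
            i += 1
    if not found_loop:
        raise FormatError(
            f"{path}: no loop with Seq_ID/Comp_index_ID, Atom_ID and Val tags"
        )
    entries: dict[int, tuple[float, float]] = {}
    for res in sorted(per_res):
        shifts = per_res[res]
        if "H" in shifts and "N" in shifts:
            entries[res] = (shifts["H"], shifts["N"])
        else:
            logger.warning(
                "%s: residue %d lacks an %s shift, omitted",
                path,
                res,
                "H" if "H" not in shifts else "N",
            )
    return entries


def write_shift_table(shifts: ShiftList, path: str | Path) -> Path:
    """Write a shift list in the three-column TSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("residue\tdelta_h\tdelta_n\n")
        for res in sorted(shifts.entries):
            dh, dn = shifts.entries[res]
            fh.write(f"{res}\t{dh:.4f}\t{dn:.4f}\n")
    return path


# ---------------------------------------------------------------------------
# PDB ensembles


def read_pdb_ensemble(path: str | Path, chain: Optional[str] = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Only ATOM records of one chain are kept (default: the first chain
    encountered); altlocs other than blank/'A' and all HETATM records
    (waters, ligands) are dropped.  Models must agree on the atom table.
    """
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse PDB: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path}: no models found")

    def atoms_of(model: "gemmi.Model", chain_id: Optional[str]):
        rows, xyz = [], []
        picked = chain_id
        for ch in model:
            if picked is None:
                picked = ch.name
            if ch.name != picked:
                continue
            for res in ch:
                if res.het_flag != "A":
                    continue
                for atom in res:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    rows.append(
                        (res.seqid.num, res.name, atom.name, ch.name)
                    )
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        return picked, rows, np.asarray(xyz, dtype=float)

    chain_id, ref_rows, ref_xyz = atoms_of(structure[0], chain)
    if not ref_rows:
        raise FormatError(f"{path}: no ATOM records for chain {chain_id!r}")
    coords = [ref_xyz]
    for model in list(structure)[1:]:
        _, rows, xyz = atoms_of(model, chain_id)
        if rows != ref_rows:
            mismatch = _first_mismatch(ref_rows, rows)
            raise FormatError(
                f"{path}: model {model.num} atom set differs from model "
                f"{structure[0].num}: {mismatch}"
            )
        coords.append(xyz)
    table = pd.DataFrame(ref_rows, columns=ATOM_TABLE_COLUMNS)
    return Ensemble(atom_table=table, coords=np.stack(coords))


def _first_mismatch(ref: list, other: list) -> str:
    for idx, (a, b) in enumerate(zip(ref, other)):
        if a != b:
            return f"at atom {idx}: expected {a}, found {b}"
    return f"atom counts differ ({len(ref)} vs {len(other)})"


def _build_structure(
    ensemble: Ensemble,
    bfactors: Optional[np.ndarray] = None,
    model_indices: Optional[Iterable[int]] = None,
) -> "gemmi.Structure":
    structure = gemmi.Structure()
    structure.name = "solnmr"
    indices = list(model_indices) if model_indices is not None else range(
        ensemble.n_models
    )
    table = ensemble.atom_table
    for out_num, mi in enumerate(indices, start=1):
        model = gemmi.Model(out_num)
        chains: dict[str, gemmi.Chain] = {}
        current_res = None
        residue = None
        for atom_idx in range(ensemble.n_atoms):
            resnum = int(table.at[atom_idx, "residue_number"])
            resname = str(table.at[atom_idx, "residue_name"])
            chain_id = str(table.at[atom_idx, "chain_id"])
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
            key = (chain_id, resnum, resname)
            if key != current_res:
                if residue is not None:
                    prev_chain = chains[current_res[0]]
                    prev_chain.add_residue(residue)
                residue = gemmi.Residue()
                residue.name = resname
                residue.seqid = gemmi.SeqId(resnum, " ")
                residue.het_flag = "A"
                current_res = key
            atom = gemmi.Atom()
            name = str(table.at[atom_idx, "atom_name"])
            atom.name = name
            atom.element = gemmi.Element(_element_of(name))
            x, y, z = ensemble.coords[mi, atom_idx]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            atom.b_iso = float(bfactors[atom_idx]) if bfactors is not None else 0.0
            residue.add_atom(atom)
        if residue is not None:
            chains[current_res[0]].add_residue(residue)
        for ch in chains.values():
            model.add_chain(ch)
        structure.add_model(model)
    return structure


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] if stripped else "X"


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write all conformers of an ensemble as a multi-model PDB file."""
    path = Path(path)
    _build_structure(ensemble).write_pdb(str(path))
    return path


def write_pdb_with_values(
    ensemble: Ensemble,
    residue_values: Mapping[int, float],
    path: str | Path,
    model_index: int = 0,
    sentinel: float = 0.0,
) -> Path:
    """Write one conformer with per-residue values in the B-factor column.

    The written file can be colored by B-factor in any molecular viewer.
    Residues absent from ``residue_values`` get ``sentinel``.  Values are
    limited to [-999.99, 999.99] (the fixed-width column) and rounded to two
    decimals on output.
    """
    for res, value in residue_values.items():
        if not math.isfinite(value):
            raise InputError(f"non-finite value for residue {res}")
        if not (-999.99 <= value <= 999.99):
            raise RangeError(
                f"value {value} for residue {res} outside the B-factor "
                f"column range [-999.99, 999.99]"
            )
    resnums = ensemble.atom_table["residue_number"].to_numpy(dtype=int)
    bfactors = np.array(
        [float(residue_values.get(int(r), sentinel)) for r in resnums]
    )
    path = Path(path)
    _build_structure(ensemble, bfactors=bfactors, model_indices=[model_index]).write_pdb(
        str(path)
    )
    return path


def read_pdb_bfactors(path: str | Path, chain: Optional[str] = None) -> dict[int, float]:
    """Read per-residue B-factor values (first atom of each residue)."""
    structure = gemmi.read_pdb(str(path))
    values: dict[int, float] = {}
    picked = chain
    for ch in structure[0]:
        if picked is None:
            picked = ch.name
        if ch.name != picked:
            continue
        for res in ch:
            if res.het_flag != "A" or len(res) == 0:
                continue
            values.setdefault(res.seqid.num, float(res[0].b_iso))
    return values


# ---------------------------------------------------------------------------
# upper-limit distance restraints


def read_upl_constraints(path: str | Path) -> list[ConstraintRecord]:
    """Read CYANA-style upper-limit lines; ``#`` starts a comment."""
    records: list[ConstraintRecord] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 fields "
                    f"(res_i name_i atom_i res_j name_j atom_j limit), "
                    f"got {len(fields)}"
                )
            try:
                res_i, res_j = int(fields[0]), int(fields[3])
                limit = float(fields[6])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric residue number or limit"
                ) from exc
            try:
                records.append(
                    ConstraintRecord(
                        residue_i=res_i,
                        residue_name_i=fields[1],
                        atom_i=fields[2],
                        residue_j=res_j,
                        residue_name_j=fields[4],
                        atom_j=fields[5],
                        upper_limit=limit,
                    )
                )
            except InputError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_upl_constraints(
    records: Sequence[ConstraintRecord], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(
                f"{rec.residue_i:4d} {rec.residue_name_i:<4s} {rec.atom_i:<5s} "
                f"{rec.residue_j:4d} {rec.residue_name_j:<4s} {rec.atom_j:<5s} "
                f"{rec.upper_limit:6.2f}\n"
            )
    return path
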
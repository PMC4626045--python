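"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data a backbone-dynamics/titration/ensemble study
produces, at the acquisition design of a typical 196-residue protein
characterized at 600 MHz:

* mono-exponential peak-height decays sampled at nine T1 delays
  (10..1400 ms) and seven T2 delays (10..150 ms) with additive Gaussian
  noise proportional to the amplitude;
* paired saturated/unsaturated peak heights consistent with a target
  heteronuclear NOE, with flexible segments (defaults 8-20 and 133-153)
  given a lower NOE;
* apo/holo amide shift lists with a chosen set of perturbed residues and
  optional exchange-broadened disappearances in the holo state;
* coordinate ensembles built from a smooth synthetic backbone template with
  controlled per-residue spread and a random rigid motion per conformer;
* upper-limit restraint lists with exact per-bin counts.

All randomness flows from a single integer seed through an independent
stream per generator (seeded as ``[seed, stream_index]``), so adding one
generator call never perturbs another's output.  Written files use fixed
number formatting: the same seed yields byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .domain import (
    ATOM_TABLE_COLUMNS,
    ConstraintRecord,
    Ensemble,
    PeakHeightSeries,
    RelaxationExperiment,
    SimulationError,
)
from .io_formats import (
    write_noe_table,
    write_relaxation_table,
    write_shift_table,
    write_upl_constraints,
)
from .domain import ShiftList

#: delay series (ms) of the interleaved T1 experiment.
T1_DELAYS_MS: Tuple[float, ...] = (10, 100, 200, 400, 600, 800, 1000, 1200, 1400)
#: delay series (ms) of the interleaved T2 experiment.
T2_DELAYS_MS: Tuple[float, ...] = (10, 30, 50, 70, 90, 110, 150)

# stream indices: one per generator, so streams stay independent
_STREAM_T1 = 0
_STREAM_T2 = 1
_STREAM_NOE = 2
_STREAM_SHIFTS = 3
_STREAM_ENSEMBLE = 4
_STREAM_CONSTRAINTS = 5

_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

PerResidue = Union[float, Mapping[int, float]]


@dataclass
class SyntheticSpec:
    """Ground truth and noise model for all generators.

    Scalars for ``t1_true``/``t2_true``/``noe_true``/``ensemble_spread``
    apply uniformly (NOE and spread are overridden inside
    ``flexible_segments``); mappings give explicit per-residue values.
    """

    seed: int = 0
    n_residues: int = 196
    t1_true: PerResidue = 750.0  # ms
    t2_true: PerResidue = 70.0  # ms
    noe_true: PerResidue = 0.80
    noise_fraction: float = 0.02  # of the decay amplitude
    amplitude: float = 100.0
    t1_delays_ms: Tuple[float, ...] = T1_DELAYS_MS
    t2_delays_ms: Tuple[float, ...] = T2_DELAYS_MS
    flexible_segments: Tuple[Tuple[int, int], ...] = ((8, 20), (133, 153))
    flexible_noe: float = 0.40
    csp_perturbed: Mapping[int, Tuple[float, float]] = dataclass_field(
        default_factory=dict
    )
    dropped_residues: Tuple[int, ...] = ()
    ensemble_spread: PerResidue = 0.3  # angstrom per coordinate
    flexible_spread: float = 1.2
    n_models: int = 20

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise SimulationError("noise_fraction must be >= 0")
        if self.n_residues < 1:
            raise SimulationError("n_residues must be >= 1")
        bad = [r for r in self.csp_perturbed if not 1 <= r <= self.n_residues]
        if bad:
            raise SimulationError(
                f"perturbed residues outside 1..{self.n_residues}: {bad}"
            )
        clash = set(self.csp_perturbed) & set(self.dropped_residues)
        if clash:
            raise SimulationError(
                f"residues {sorted(clash)} are both perturbed and dropped; "
                f"a disappeared peak cannot carry a shift change"
            )

    def _is_flexible(self, residue: int) -> bool:
        return any(lo <= residue <= hi for lo, hi in self.flexible_segments)

    def resolve(self, value: PerResidue, flexible_value: Optional[float] = None) -> np.ndarray:
        """Per-residue array (index 0 -> residue 1) from scalar or mapping."""
        out = np.empty(self.n_residues)
        if isinstance(value, Mapping):
            for i in range(self.n_residues):
                res = i + 1
                if res not in value:
                    raise SimulationError(f"no value for residue {res}")
                out[i] = value[res]
            return out
        out[:] = float(value)
        if flexible_value is not None:
            for i in range(self.n_residues):
                if self._is_flexible(i + 1):
                    out[i] = flexible_value
        return out

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def gen_relaxation_series(
    spec: SyntheticSpec, experiment: RelaxationExperiment | str
) -> list[PeakHeightSeries]:
    """Noisy mono-exponential decays, one series per residue."""
    experiment = RelaxationExperiment(experiment)
    if experiment is RelaxationExperiment.T1:
        delays = np.asarray(spec.t1_delays_ms, dtype=float)
        truth = spec.resolve(spec.t1_true)
        rng = spec.rng(_STREAM_T1)
    else:
        delays = np.asarray(spec.t2_delays_ms, dtype=float)
        truth = spec.resolve(spec.t2_true)
        rng = spec.rng(_STREAM_T2)
    noise_sd = spec.noise_fraction * spec.amplitude
    series = []
    for i in range(spec.n_residues):
        clean = spec.amplitude * np.exp(-delays / truth[i])
        noisy = clean + rng.normal(0.0, noise_sd, size=delays.shape) if noise_sd > 0 else clean
        series.append(
            PeakHeightSeries(
                residue_number=i + 1,
                experiment=experiment,
                delays_ms=delays,
                heights=noisy,
                noise_sd=noise_sd,
            )
        )
    return series


def gen_noe_pairs(spec: SyntheticSpec) -> pd.DataFrame:
    """Paired saturated/unsaturated peak heights consistent with the NOE truth."""
    truth = spec.resolve(spec.noe_true, flexible_value=spec.flexible_noe)
    rng = spec.rng(_STREAM_NOE)
    noise_sd = spec.noise_fraction * spec.amplitude
    rows = []
    for i in range(spec.n_residues):
        unsat = spec.amplitude
        sat = truth[i] * spec.amplitude
        if noise_sd > 0:
            sat += rng.normal(0.0, noise_sd)
            unsat += rng.normal(0.0, noise_sd)
        rows.append(
            {
                "residue": i + 1,
                "height_sat": sat,
                "height_unsat": unsat,
                "noise_sat": noise_sd,
                "noise_unsat": noise_sd,
            }
        )
    return pd.DataFrame(rows)


def gen_relaxation_tables(
    spec: SyntheticSpec, outdir: str | Path
) -> Dict[str, Path]:
    """Write the T1, T2 and NOE tables; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "t1": write_relaxation_table(
            gen_relaxation_series(spec, RelaxationExperiment.T1), outdir / "t1.tsv"
        ),
        "t2": write_relaxation_table(
            gen_relaxation_series(spec, RelaxationExperiment.T2), outdir / "t2.tsv"
        ),
        "noe": write_noe_table(gen_noe_pairs(spec), outdir / "noe.tsv"),
    }
    return paths


def gen_titration_shiftlists(spec: SyntheticSpec) -> Tuple[ShiftList, ShiftList]:
    """Apo and holo amide shift lists with the spec's injected perturbations.

    Baseline shifts are drawn from amide-plausible ranges (¹H 7-10 ppm,
    ¹⁵N 105-130 ppm); the holo list adds the stated perturbations and drops
    ``dropped_residues`` to emulate exchange-broadened disappearances.
    """
    rng = spec.rng(_STREAM_SHIFTS)
    apo: Dict[int, Tuple[float, float]] = {}
    holo: Dict[int, Tuple[float, float]] = {}
    dropped = set(spec.dropped_residues)
    for res in range(1, spec.n_residues + 1):
        dh = float(rng.uniform(7.0, 10.0))
        dn = float(rng.uniform(105.0, 130.0))
        apo[res] = (round(dh, 4), round(dn, 4))
        if res in dropped:
            continue
        ph, pn = spec.csp_perturbed.get(res, (0.0, 0.0))
        holo[res] = (round(dh + ph, 4), round(dn + pn, 4))
    return (
        ShiftList(entries=apo, label="apo"),
        ShiftList(entries=holo, label="holo"),
    )


def make_backbone_template(n_residues: int, chain_id: str = "A") -> Ensemble:
    """Single-model synthetic backbone (N, CA, C, O per residue).

    CA atoms follow a smooth superhelical curve; the other backbone atoms
    are placed at fixed local offsets.  The geometry is not stereochemically
    refined — it only needs realistic scale and non-degenerate shape for
    superposition and rmsd statistics.
    """
    rows, xyz = [], []
    offsets = {
        "N": np.array([-1.20, 0.35, -0.40]),
        "CA": np.zeros(3),
        "C": np.array([1.25, 0.30, 0.35]),
        "O": np.array([1.60, 1.35, 0.70]),
    }
    for i in range(n_residues):
        theta = 0.55 * i
        ca = np.array(
            [
                9.0 * math.cos(theta) + 2.5 * math.cos(0.07 * i),
                9.0 * math.sin(theta) + 2.5 * math.sin(0.07 * i),
                1.6 * i,
            ]
        )
        resname = _AA3[i % len(_AA3)]
        for name in ("N", "CA", "C", "O"):
            rows.append((i + 1, resname, name, chain_id))
            xyz.append(ca + offsets[name])
    table = pd.DataFrame(rows, columns=ATOM_TABLE_COLUMNS)
    return Ensemble(atom_table=table, coords=np.asarray(xyz)[np.newaxis, :, :])


def gen_ensemble(
    spec: SyntheticSpec, template: Optional[Ensemble] = None
) -> Ensemble:
    """Conformer ensemble: template + per-residue jitter + random rigid motion.

    Each of ``n_models`` conformers is the template with isotropic Gaussian
    jitter of the per-residue sigma (``ensemble_spread``, elevated to
    ``flexible_spread`` inside flexible segments) on every atom coordinate,
    then rotated and translated rigidly at random so that downstream
    statistics must superpose.
    """
    if template is None:
        template = make_backbone_template(spec.n_residues)
    rng = spec.rng(_STREAM_ENSEMBLE)
    resnums = template.atom_table["residue_number"].to_numpy(dtype=int)
    sigma_by_res: Dict[int, float] = {}
    spread = spec.ensemble_spread
    for res in sorted(set(resnums)):
        if isinstance(spread, Mapping):
            if res not in spread:
                raise SimulationError(f"no ensemble spread for residue {res}")
            sigma_by_res[res] = float(spread[res])
        else:
            sigma_by_res[res] = (
                spec.flexible_spread if spec._is_flexible(res) else float(spread)
            )
    sigma_atoms = np.array([sigma_by_res[r] for r in resnums])[:, np.newaxis]
    base = template.coords[0]
    models = []
    for _ in range(spec.n_models):
        jittered = base + rng.normal(0.0, 1.0, size=base.shape) * sigma_atoms
        quat = rng.normal(size=4)
        rotation = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        translation = rng.uniform(-10.0, 10.0, size=3)
        models.append(jittered @ rotation.T + translation)
    return Ensemble(atom_table=template.atom_table, coords=np.stack(models))


def gen_constraint_list(
    counts: Mapping[str, int],
    n_residues: int,
    seed: int,
    path: Optional[str | Path] = None,
) -> list[ConstraintRecord]:
    """Random restraints with exact per-bin counts (intra/sequential/medium/long).

    Optionally writes the list in the upper-limit dialect.  Raises when a
    requested bin is unachievable for the construct length (long range needs
    a separation > 5, hence at least 7 residues).
    """
    needed_span = {"intra": 1, "sequential": 2, "medium": 3, "long": 7}
    for bin_name, count in counts.items():
        if bin_name not in needed_span:
            raise SimulationError(f"unknown restraint bin {bin_name!r}")
        if count < 0:
            raise SimulationError(f"negative count for bin {bin_name!r}")
        if count > 0 and n_residues < needed_span[bin_name]:
            raise SimulationError(
                f"bin {bin_name!r} unachievable with {n_residues} residues"
            )
    rng = np.random.default_rng([int(seed), _STREAM_CONSTRAINTS])
    records: list[ConstraintRecord] = []

    def add(res_i: int, res_j: int, atom_i: str, atom_j: str) -> None:
        records.append(
            ConstraintRecord(
                residue_i=res_i,
                residue_name_i=_AA3[(res_i - 1) % len(_AA3)],
                atom_i=atom_i,
                residue_j=res_j,
                residue_name_j=_AA3[(res_j - 1) % len(_AA3)],
                atom_j=atom_j,
                upper_limit=float(round(rng.uniform(2.5, 6.0), 2)),
            )
        )

    for _ in range(counts.get("intra", 0)):
        res = int(rng.integers(1, n_residues + 1))
        add(res, res, "HA", "HN")
    for _ in range(counts.get("sequential", 0)):
        res = int(rng.integers(1, n_residues))
        add(res, res + 1, "HA", "HN")
    for _ in range(counts.get("medium", 0)):
        sep = int(rng.integers(2, min(5, n_residues - 1) + 1))
        res = int(rng.integers(1, n_residues - sep + 1))
        add(res, res + sep, "HA", "HN")
    for _ in range(counts.get("long", 0)):
        sep = int(rng.integers(6, n_residues))
        res = int(rng.integers(1, n_residues - sep + 1))
        add(res, res + sep, "HA", "HN")
    if path is not None:
        write_upl_constraints(records, path)
    return records


def gen_all(spec: SyntheticSpec, outdir: str | Path) -> Dict[str, Path]:
    """Generate the full fixture set for an end-to-end pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = gen_relaxation_tables(spec, outdir)
    apo, holo = gen_titration_shiftlists(spec)
    paths["apo_shifts"] = write_shift_table(apo, outdir / "apo_shifts.tsv")
    paths["holo_shifts"] = write_shift_table(holo, outdir / "holo_shifts.tsv")
    from .io_formats import write_pdb_ensemble  # local import avoids cycle noise

    ensemble = gen_ensemble(spec)
    paths["ensemble"] = write_pdb_ensemble(ensemble, outdir / "ensemble.pdb")
    default_counts = {"intra": 1049, "sequential": 903, "medium": 470, "long": 824}
    gen_constraint_list(
        default_counts, spec.n_residues, spec.seed, outdir / "constraints.upl"
    )
    paths["upl"] = outdir / "constraints.upl"
    return paths
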
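"""End-to-end orchestration: relaxation -> tau_c -> verdict, apo vs holo ->
CSP map, ensemble + restraints -> precision/bookkeeping statistics.

`run_full` consumes a flat key-value configuration (YAML on disk), runs every
stage whose inputs are present, and writes per-stage TSVs, a combined text
report, a B-factor-mapped PDB and a versioned machine-readable summary.
A stage failure aborts the run, names the stage, and removes partial
outputs.  The NOE table is the one optional input: without it the
relaxation section is reported without NOE/flexibility columns and the run
finishes as success-with-warnings.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import constraints as constraints_mod
from . import csp as csp_mod
from . import ensemble_stats, io_formats, relaxation
from .domain import InputError, SolnmrError
from .ensemble_stats import DEFAULT_ORDERED_RANGES, ResidueSelection, parse_residue_ranges
from .synthetic_data import SyntheticSpec, gen_all

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA = "solnmr-summary/1"


class PipelineStageError(SolnmrError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Flat run configuration; file-based fields may be None to skip a stage."""

    outdir: str = "solnmr_out"
    seed: int = 0
    simulate: bool = False
    field_mhz: float = 600.0
    noe_floor: float = relaxation.DEFAULT_NOE_FLOOR
    tau_c_window: Optional[Tuple[float, float]] = None
    csp_method: str = "mean_sd"
    csp_cutoff: Optional[float] = None
    shift_dialect: str = "tsv"
    selections: str = DEFAULT_ORDERED_RANGES
    atom_policy: str = "backbone_heavy"
    n_residues: int = 196
    n_phi: int = 0
    n_psi: int = 0
    t1_table: Optional[str] = None
    t2_table: Optional[str] = None
    noe_table: Optional[str] = None
    apo_shifts: Optional[str] = None
    holo_shifts: Optional[str] = None
    ensemble_pdb: Optional[str] = None
    upl: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat YAML mapping; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        config = cls(**data)
        if isinstance(config.tau_c_window, (list, tuple)):
            config.tau_c_window = (
                float(config.tau_c_window[0]),
                float(config.tau_c_window[1]),
            )
        return config

    def validate(self) -> List[str]:
        """Check invariants; returns warnings for tolerated problems."""
        warnings: List[str] = []
        if not self.field_mhz > 0:
            raise InputError(f"field_mhz must be positive, got {self.field_mhz}")
        required = {
            "t1_table": self.t1_table,
            "t2_table": self.t2_table,
            "apo_shifts": self.apo_shifts,
            "holo_shifts": self.holo_shifts,
            "ensemble_pdb": self.ensemble_pdb,
            "upl": self.upl,
        }
        for name, value in required.items():
            if value is not None and not Path(value).exists():
                raise InputError(f"config {name} = {value!r}: file not found")
        if self.noe_table is not None and not Path(self.noe_table).exists():
            warnings.append(
                f"NOE table {self.noe_table!r} not found; relaxation section "
                f"will lack NOE and flexibility columns"
            )
        return warnings


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    outdir: Path
    sections: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    summary: Dict[str, object] = field(default_factory=dict)
    outputs: List[Path] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "success-with-warnings" if self.warnings else "success"


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def run_full(config: RunConfig) -> RunReport:
    """Run every configured stage; see module docstring for the contract."""
    config_warnings = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)
    report.warnings.extend(config_warnings)
    summary: Dict[str, object] = {"schema": SUMMARY_SCHEMA, "seed": config.seed}

    def emit(path: Path, text: str) -> None:
        path.write_text(text)
        report.outputs.append(path)

    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            started = time.perf_counter()
            spec = SyntheticSpec(seed=config.seed, n_residues=config.n_residues)
            fixture_paths = gen_all(spec, outdir / "fixtures")
            report.outputs.extend(fixture_paths.values())
            for key, attr in (
                ("t1", "t1_table"),
                ("t2", "t2_table"),
                ("noe", "noe_table"),
                ("apo_shifts", "apo_shifts"),
                ("holo_shifts", "holo_shifts"),
                ("ensemble", "ensemble_pdb"),
                ("upl", "upl"),
            ):
                if getattr(config, attr) is None:
                    setattr(config, attr, str(fixture_paths[key]))
            report.sections["simulate"] = (
                f"generated synthetic fixtures for {config.n_residues} residues "
                f"(seed {config.seed}) in {outdir / 'fixtures'}"
            )
            logger.info("simulate: %.2f s", time.perf_counter() - started)

        if config.t1_table and config.t2_table:
            stage = "relaxation"
            started = time.perf_counter()
            t1 = io_formats.read_relaxation_table(config.t1_table, "T1")
            t2 = io_formats.read_relaxation_table(config.t2_table, "T2")
            noe = None
            if config.noe_table and Path(config.noe_table).exists():
                noe = io_formats.read_noe_table(config.noe_table)
            profiles = relaxation.analyze_residues(
                t1, t2, noe_table=noe, field_mhz=config.field_mhz
            )
            summary_dyn = relaxation.summarize_dynamics(
                profiles,
                noe_floor=config.noe_floor,
                expected_monomer_tau_c=config.tau_c_window,
            )
            frame = relaxation.profiles_to_frame(profiles, noe_floor=config.noe_floor)
            path = outdir / "relaxation.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            report.outputs.append(path)
            verdict = summary_dyn.oligomer_verdict or "not-assessed"
            lines = [
                f"residues analyzed: {summary_dyn.n_residues}",
                f"mean T1: {summary_dyn.mean_t1:.1f} ms",
                f"mean T2: {summary_dyn.mean_t2:.1f} ms",
                f"mean tau_c: {summary_dyn.mean_tau_c:.2f} ns "
                f"(across-residue SD {summary_dyn.sd_tau_c:.2f} ns)",
                f"oligomeric state: {verdict}",
            ]
            if summary_dyn.mean_noe is not None:
                lines.insert(
                    3, f"mean hetNOE: {summary_dyn.mean_noe:.3f}"
                )
                lines.append(
                    f"flexible residues (NOE < {config.noe_floor}): "
                    f"{len(summary_dyn.flexible_residues)}"
                )
            else:
                report.warnings.append(
                    "relaxation: no NOE table; NOE and flexibility not reported"
                )
            report.sections["relaxation"] = "\n".join(lines)
            summary["relaxation"] = {
                "n_residues": summary_dyn.n_residues,
                "mean_t1_ms": summary_dyn.mean_t1,
                "mean_t2_ms": summary_dyn.mean_t2,
                "mean_noe": summary_dyn.mean_noe,
                "mean_tau_c_ns": summary_dyn.mean_tau_c,
                "sd_tau_c_ns": summary_dyn.sd_tau_c,
                "n_flexible": len(summary_dyn.flexible_residues),
                "oligomer_verdict": verdict,
            }
            logger.info("relaxation: %.2f s", time.perf_counter() - started)

        if config.apo_shifts and config.holo_shifts:
            stage = "csp"
            started = time.perf_counter()
            apo = io_formats.read_shift_table(
                config.apo_shifts, dialect=config.shift_dialect, label="apo"
            )
            holo = io_formats.read_shift_table(
                config.holo_shifts, dialect=config.shift_dialect, label="holo"
            )
            profile = csp_mod.compare_states(
                apo, holo, classify=config.csp_method, cutoff=config.csp_cutoff
            )
            rows = csp_mod.profile_to_rows(profile)
            path = outdir / "csp.tsv"
            import pandas as pd

            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
            report.outputs.append(path)
            for res in sorted(profile.unmatched_in_a | profile.unmatched_in_b):
                report.warnings.append(
                    f"csp: residue {res} present in only one state (no CSP)"
                )
            report.sections["csp"] = "\n".join(
                [
                    f"residues compared: {len(profile.per_residue)}",
                    f"threshold ({config.csp_method}): {profile.threshold:.4f} ppm",
                    f"significant residues: {sorted(profile.significant)}",
                    f"unmatched: {len(profile.unmatched_in_a)} apo-only, "
                    f"{len(profile.unmatched_in_b)} holo-only",
                ]
            )
            summary["csp"] = {
                "n_compared": len(profile.per_residue),
                "threshold_ppm": profile.threshold,
                "significant": sorted(profile.significant),
                "n_unmatched": len(profile.unmatched_in_a)
                + len(profile.unmatched_in_b),
            }
            if config.ensemble_pdb:
                model = io_formats.read_pdb_ensemble(config.ensemble_pdb)
                values = csp_mod.csp_to_structure(profile, model)
                mapped = outdir / "csp_mapped.pdb"
                io_formats.write_pdb_with_values(model, values, mapped)
                report.outputs.append(mapped)
            logger.info("csp: %.2f s", time.perf_counter() - started)

        if config.ensemble_pdb:
            stage = "ensemble"
            started = time.perf_counter()
            ensemble = io_formats.read_pdb_ensemble(config.ensemble_pdb)
            residues = parse_residue_ranges(config.selections)
            present = set(ensemble.residue_numbers())
            residues = tuple(r for r in residues if r in present)
            selection = ResidueSelection(
                residue_numbers=residues, atom_policy=config.atom_policy
            )
            mean_rmsd, sd_rmsd = ensemble_stats.rmsd_to_mean(ensemble, selection)
            profile = ensemble_stats.per_residue_rmsd(
                ensemble, atom_policy=config.atom_policy
            )
            path = outdir / "per_residue_rmsd.tsv"
            emit(
                path,
                "residue\trmsd\n"
                + "".join(f"{r}\t{v:.4f}\n" for r, v in sorted(profile.items())),
            )
            report.sections["ensemble"] = "\n".join(
                [
                    f"models: {ensemble.n_models}",
                    f"selection: {config.selections} ({config.atom_policy})",
                    f"rmsd to mean: {mean_rmsd:.2f} +/- {sd_rmsd:.2f} A",
                ]
            )
            summary["ensemble"] = {
                "n_models": ensemble.n_models,
                "selection": config.selections,
                "atom_policy": config.atom_policy,
                "rmsd_to_mean_A": mean_rmsd,
                "rmsd_to_mean_sd_A": sd_rmsd,
            }
            logger.info("ensemble: %.2f s", time.perf_counter() - started)

        if config.upl:
            stage = "constraints"
            started = time.perf_counter()
            records = io_formats.read_upl_constraints(config.upl)
            summary_con = constraints_mod.summarize_constraints(
                records,
                n_phi=config.n_phi,
                n_psi=config.n_psi,
                n_residues=config.n_residues,
            )
            path = outdir / "constraints.tsv"
            emit(path, constraints_mod.format_summary_table(summary_con))
            report.sections["constraints"] = "\n".join(
                [
                    f"distance restraints: {summary_con.n_total} "
                    f"({summary_con.n_intra} intra, {summary_con.n_sequential} "
                    f"sequential, {summary_con.n_medium} medium, "
                    f"{summary_con.n_long} long)",
                    f"constraints per residue: {summary_con.per_residue_total:.1f} "
                    f"total, {summary_con.per_residue_long:.1f} long-range",
                ]
            )
            summary["constraints"] = {
                "n_intra": summary_con.n_intra,
                "n_sequential": summary_con.n_sequential,
                "n_medium": summary_con.n_medium,
                "n_long": summary_con.n_long,
                "n_total": summary_con.n_total,
                "per_residue_total": summary_con.per_residue_total,
                "per_residue_long": summary_con.per_residue_long,
            }
            logger.info("constraints: %.2f s", time.perf_counter() - started)
    except SolnmrError as exc:
        for path in report.outputs:
            Path(path).unlink(missing_ok=True)
        raise PipelineStageError(stage, str(exc)) from exc

    if not report.sections:
        raise InputError("configuration enables no stage (no inputs given)")

    summary["status"] = report.status
    summary["warnings"] = report.warnings
    report.summary = summary
    text = [f"solnmr pipeline report (status: {report.status})", ""]
    for name, body in report.sections.items():
        text.append(f"== {name} ==")
        text.append(body)
        text.append("")
    if report.warnings:
        text.append("== warnings ==")
        text.extend(report.warnings)
        text.append("")
    emit(outdir / "report.txt", "\n".join(text))
    emit(
        outdir / "summary.json",
        json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n",
    )
    return report
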
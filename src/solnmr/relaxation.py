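"""Per-residue ¹⁵N relaxation analysis.

Fits T1/T2 from peak-height decays, computes the steady-state heteronuclear
NOE with signal-to-noise-propagated uncertainty, converts the T1/T2 ratio
into a rotational correlation time, and aggregates per-residue results into
a dynamics summary with an oligomeric-state verdict.

The correlation-time estimator is the standard large-molecule approximation

    tau_c = (1 / (4 pi nu_N)) * sqrt(6 (T1/T2) - 7)

with nu_N the ¹⁵N Larmor frequency.  It assumes isotropic tumbling and
tau_c * omega_N >> 1, and is undefined for T1/T2 < 7/6 (small molecules or
residues dominated by fast internal motion / exchange).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .domain import (
    DegenerateInputError,
    EstimatorDomainError,
    InputError,
    PeakHeightSeries,
)

logger = logging.getLogger(__name__)

#: gyromagnetic-ratio magnitude of 15N relative to 1H; nu_N = ratio * nu_H.
N15_FREQUENCY_RATIO = 0.10132912

#: default hetNOE below which a residue is flagged as locally flexible.
DEFAULT_NOE_FLOOR = 0.65

#: fits whose time constant exceeds this multiple of the sampled delay span
#: are declared failed (the decay is not resolved by the experiment).
MAX_TIME_CONSTANT_SPAN_FACTOR = 50.0


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of heights to A * exp(-t / T)."""

    time_constant: float  # ms
    time_constant_sd: float
    amplitude: float
    amplitude_sd: float
    residual_rms: float
    n_points: int


@dataclass(frozen=True)
class HetNoeValue:
    """Heteronuclear NOE ratio with S/N-propagated uncertainty."""

    noe: float
    noe_sd: float


@dataclass
class ResidueRelaxation:
    """Fitted relaxation parameters for one residue (absent pieces are None)."""

    residue_number: int
    t1: Optional[ExponentialFit] = None
    t2: Optional[ExponentialFit] = None
    hetnoe: Optional[HetNoeValue] = None
    tau_c: Optional[float] = None  # ns
    tau_c_sd: Optional[float] = None  # ns, propagated from T1/T2 sds


@dataclass
class DynamicsSummary:
    """Ensemble-averaged dynamics and the oligomeric-state verdict.

    ``sd_tau_c`` is the across-residue standard deviation of tau_c;
    per-residue propagated errors live on each :class:`ResidueRelaxation`.
    ``oligomer_verdict`` is ``"monomer-consistent"`` when the mean tau_c
    falls inside the user-supplied window expected for a monomer of the
    protein's mass, ``"larger-than-monomer"`` otherwise, and None when no
    window was supplied.
    """

    mean_t1: float
    mean_t2: float
    mean_noe: Optional[float]
    mean_tau_c: float
    sd_tau_c: float
    flexible_residues: list[int]
    oligomer_verdict: Optional[str]
    n_residues: int


def _decay(t: np.ndarray, amplitude: float, time_constant: float) -> np.ndarray:
    return amplitude * np.exp(-t / time_constant)


def fit_single_exponential(
    series: PeakHeightSeries, weighted: bool = False
) -> Optional[ExponentialFit]:
    """Fit one residue's peak heights to a single exponential decay.

    Unweighted least squares by default (uncertainties are the square roots
    of the covariance diagonal, scaled by the residual variance); with
    ``weighted=True`` and a positive ``noise_sd`` the fit uses the spectral
    noise as an absolute per-point sigma.

    Returns None when the solver fails to converge or the fitted time
    constant exceeds 50x the sampled delay span (the data do not constrain
    the decay); raises for fewer than three points or all-constant heights.
    """
    t = series.delays_ms
    h = series.heights
    if len(t) < 3:
        raise InputError(
            f"residue {series.residue_number}: need >= 3 points to fit"
        )
    if np.ptp(h) == 0:
        raise DegenerateInputError(
            f"residue {series.residue_number}: all heights equal; "
            f"no decay to fit"
        )
    a0 = float(np.max(h))
    below = t[h < a0 / math.e]
    t0 = float(below[0]) if below.size else 0.5 * float(t[-1] - t[0])
    t0 = max(t0, 1e-9)
    sigma = None
    absolute_sigma = False
    if weighted and series.noise_sd > 0:
        sigma = np.full_like(h, series.noise_sd)
        absolute_sigma = True
    try:
        popt, pcov = curve_fit(
            _decay,
            t,
            h,
            p0=[a0, t0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            sigma=sigma,
            absolute_sigma=absolute_sigma,
            maxfev=10000,
        )
    except RuntimeError:
        logger.warning(
            "residue %d: exponential fit did not converge", series.residue_number
        )
        return None
    amplitude, time_constant = float(popt[0]), float(popt[1])
    span = float(t[-1] - t[0])
    if time_constant > MAX_TIME_CONSTANT_SPAN_FACTOR * span:
        logger.warning(
            "residue %d: fitted time constant %.1f ms exceeds 50x the delay "
            "span, fit rejected",
            series.residue_number,
            time_constant,
        )
        return None
    diag = np.diag(pcov)
    sds = np.sqrt(np.where(np.isfinite(diag) & (diag >= 0), diag, np.nan))
    residuals = h - _decay(t, amplitude, time_constant)
    return ExponentialFit(
        time_constant=time_constant,
        time_constant_sd=float(sds[1]) if np.isfinite(sds[1]) else 0.0,
        amplitude=amplitude,
        amplitude_sd=float(sds[0]) if np.isfinite(sds[0]) else 0.0,
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        n_points=len(t),
    )


def compute_hetnoe(
    height_sat: float,
    height_unsat: float,
    noise_sat: float = 0.0,
    noise_unsat: float = 0.0,
) -> HetNoeValue:
    """Heteronuclear NOE from one saturated/unsaturated peak-height pair.

    noe = I_sat / I_unsat; the uncertainty propagates the spectral noise of
    both spectra:  sd = |noe| * sqrt((n_sat/I_sat)^2 + (n_unsat/I_unsat)^2).
    """
    if height_unsat == 0:
        raise InputError("unsaturated peak height is zero; NOE ratio undefined")
    if noise_sat < 0 or noise_unsat < 0:
        raise InputError("noise estimates must be >= 0")
    noe = height_sat / height_unsat
    # algebraically identical to |noe|*sqrt((n_s/I_s)^2+(n_u/I_u)^2) but
    # finite when the saturated peak vanishes
    sd = math.hypot(noise_sat / height_unsat, height_sat * noise_unsat / height_unsat**2)
    return HetNoeValue(noe=noe, noe_sd=sd)


def nitrogen_larmor(proton_freq_mhz: float) -> float:
    """¹⁵N Larmor frequency (MHz, magnitude) at a given ¹H frequency."""
    if not proton_freq_mhz > 0:
        raise InputError(f"proton frequency must be positive, got {proton_freq_mhz}")
    return proton_freq_mhz * N15_FREQUENCY_RATIO


def tau_c_from_t1_t2(t1_ms: float, t2_ms: float, nu_n_mhz: float) -> float:
    """Rotational correlation time (ns) from the T1/T2 ratio.

    Evaluates tau_c = (1/(4 pi nu_N)) * sqrt(6 (T1/T2) - 7).  The radicand
    must be non-negative (T1/T2 >= 7/6); at the boundary the estimate is 0.
    """
    if t1_ms <= 0 or t2_ms <= 0:
        raise InputError("relaxation times must be positive")
    if nu_n_mhz <= 0:
        raise InputError("nitrogen frequency must be positive")
    radicand = 6.0 * (t1_ms / t2_ms) - 7.0
    if radicand < 0:
        raise EstimatorDomainError(
            f"T1/T2 = {t1_ms / t2_ms:.3f} ratio too small for this estimator "
            f"(needs T1/T2 >= 7/6)"
        )
    return 1e3 / (4.0 * math.pi * nu_n_mhz) * math.sqrt(radicand)


def tau_c_sd_from_fits(
    t1_ms: float, t2_ms: float, sd_t1: float, sd_t2: float, nu_n_mhz: float
) -> float:
    """First-order propagation of T1/T2 fit uncertainties into tau_c (ns)."""
    ratio = t1_ms / t2_ms
    radicand = 6.0 * ratio - 7.0
    if radicand <= 0:
        raise EstimatorDomainError("tau_c undefined: T1/T2 <= 7/6")
    prefactor = 1e3 / (4.0 * math.pi * nu_n_mhz)
    dtau_dratio = prefactor * 3.0 / math.sqrt(radicand)
    sd_ratio = ratio * math.hypot(sd_t1 / t1_ms, sd_t2 / t2_ms)
    return dtau_dratio * sd_ratio


def analyze_residues(
    t1_series: Sequence[PeakHeightSeries],
    t2_series: Sequence[PeakHeightSeries],
    noe_table: Optional[pd.DataFrame] = None,
    field_mhz: float = 600.0,
    weighted: bool = False,
) -> list[ResidueRelaxation]:
    """Fit all residues and attach tau_c where the T1/T2 ratio allows it.

    ``noe_table`` is the frame returned by
    :func:`solnmr.io_formats.read_noe_table` (or None when the NOE
    experiment is unavailable).  tau_c is attached only for residues with
    both fits and strictly T1/T2 > 7/6.
    """
    nu_n = nitrogen_larmor(field_mhz)
    t1_by_res = {s.residue_number: s for s in t1_series}
    t2_by_res = {s.residue_number: s for s in t2_series}
    noe_by_res: dict[int, tuple[float, float, float, float]] = {}
    if noe_table is not None:
        for row in noe_table.itertuples(index=False):
            noe_by_res[int(row.residue)] = (
                row.height_sat,
                row.height_unsat,
                row.noise_sat,
                row.noise_unsat,
            )
    residues = sorted(set(t1_by_res) | set(t2_by_res) | set(noe_by_res))
    profiles: list[ResidueRelaxation] = []
    for res in residues:
        profile = ResidueRelaxation(residue_number=res)
        for attr, lookup in (("t1", t1_by_res), ("t2", t2_by_res)):
            series = lookup.get(res)
            if series is None:
                continue
            try:
                setattr(profile, attr, fit_single_exponential(series, weighted=weighted))
            except InputError as exc:
                logger.warning("%s fit skipped: %s", attr.upper(), exc)
        if res in noe_by_res:
            hs, hu, ns, nu = noe_by_res[res]
            try:
                profile.hetnoe = compute_hetnoe(hs, hu, ns, nu)
            except InputError as exc:
                logger.warning("residue %d: NOE skipped: %s", res, exc)
        if profile.t1 is not None and profile.t2 is not None:
            t1v, t2v = profile.t1.time_constant, profile.t2.time_constant
            if 6.0 * (t1v / t2v) - 7.0 > 0:
                profile.tau_c = tau_c_from_t1_t2(t1v, t2v, nu_n)
                profile.tau_c_sd = tau_c_sd_from_fits(
                    t1v,
                    t2v,
                    profile.t1.time_constant_sd,
                    profile.t2.time_constant_sd,
                    nu_n,
                )
            else:
                logger.warning(
                    "residue %d: T1/T2 = %.2f too small for a tau_c estimate",
                    res,
                    t1v / t2v,
                )
        profiles.append(profile)
    return profiles


def summarize_dynamics(
    profiles: Sequence[ResidueRelaxation],
    noe_floor: float = DEFAULT_NOE_FLOOR,
    expected_monomer_tau_c: Optional[tuple[float, float]] = None,
) -> DynamicsSummary:
    """Aggregate per-residue relaxation into means, flags and a verdict.

    ``expected_monomer_tau_c`` is the (low, high) tau_c window in ns expected
    for a monomer of the protein's mass, supplied by the user (for example
    from an empirical tau_c-vs-mass rule); no mass model is built in.  With
    no window the verdict is None ("not assessed").
    """
    tau_values = [p.tau_c for p in profiles if p.tau_c is not None]
    if not tau_values:
        raise InputError("no residue has a valid tau_c; nothing to summarize")
    t1_values = [p.t1.time_constant for p in profiles if p.t1 is not None]
    t2_values = [p.t2.time_constant for p in profiles if p.t2 is not None]
    noe_values = [p.hetnoe.noe for p in profiles if p.hetnoe is not None]
    mean_tau = float(np.mean(tau_values))
    sd_tau = float(np.std(tau_values, ddof=1)) if len(tau_values) > 1 else 0.0
    flexible = sorted(
        p.residue_number
        for p in profiles
        if p.hetnoe is not None and p.hetnoe.noe < noe_floor
    )
    verdict: Optional[str] = None
    if expected_monomer_tau_c is not None:
        low, high = expected_monomer_tau_c
        verdict = (
            "monomer-consistent" if low <= mean_tau <= high else "larger-than-monomer"
        )
    return DynamicsSummary(
        mean_t1=float(np.mean(t1_values)),
        mean_t2=float(np.mean(t2_values)),
        mean_noe=float(np.mean(noe_values)) if noe_values else None,
        mean_tau_c=mean_tau,
        sd_tau_c=sd_tau,
        flexible_residues=flexible,
        oligomer_verdict=verdict,
        n_residues=len(profiles),
    )


def profiles_to_frame(
    profiles: Sequence[ResidueRelaxation], noe_floor: float = DEFAULT_NOE_FLOOR
) -> pd.DataFrame:
    """Tabulate per-residue results (the `relax fit` report layout)."""
    rows = []
    has_noe = any(p.hetnoe is not None for p in profiles)
    for p in profiles:
        row: dict[str, object] = {"residue": p.residue_number}
        row["T1"] = p.t1.time_constant if p.t1 else np.nan
        row["sdT1"] = p.t1.time_constant_sd if p.t1 else np.nan
        row["T2"] = p.t2.time_constant if p.t2 else np.nan
        row["sdT2"] = p.t2.time_constant_sd if p.t2 else np.nan
        if has_noe:
            row["NOE"] = p.hetnoe.noe if p.hetnoe else np.nan
            row["sdNOE"] = p.hetnoe.noe_sd if p.hetnoe else np.nan
        row["tau_c"] = p.tau_c if p.tau_c is not None else np.nan
        row["sd_tau_c"] = p.tau_c_sd if p.tau_c_sd is not None else np.nan
        if has_noe:
            row["flexible_flag"] = int(
                p.hetnoe is not None and p.hetnoe.noe < noe_floor
            )
        rows.append(row)
    return pd.DataFrame(rows)
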
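"""Exponential fitting, hetNOE propagation, tau_c and dynamics aggregation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solnmr.domain import (
    DegenerateInputError,
    EstimatorDomainError,
    InputError,
    PeakHeightSeries,
)
from solnmr.relaxation import (
    ExponentialFit,
    ResidueRelaxation,
    HetNoeValue,
    compute_hetnoe,
    fit_single_exponential,
    nitrogen_larmor,
    summarize_dynamics,
    tau_c_from_t1_t2,
    tau_c_sd_from_fits,
)


class TestFitSingleExponential:
    def test_noiseless_recovery_at_standard_delays(self, noiseless_t1_series):
        fit = fit_single_exponential(noiseless_t1_series)
        assert fit.time_constant == pytest.approx(750.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.time_constant_sd == pytest.approx(0.0, abs=1e-3)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_time_constant(self, noiseless_t1_series):
        scaled = PeakHeightSeries(
            residue_number=1,
            experiment="T1",
            delays_ms=noiseless_t1_series.delays_ms,
            heights=noiseless_t1_series.heights * 3.0,
        )
        fit = fit_single_exponential(noiseless_t1_series)
        fit3 = fit_single_exponential(scaled)
        assert fit3.time_constant == pytest.approx(fit.time_constant, rel=1e-9)
        assert fit3.amplitude == pytest.approx(3.0 * fit.amplitude, rel=1e-9)

    def test_permutation_invariance(self, t2_delays):
        rng = np.random.default_rng(5)
        heights = 80.0 * np.exp(-t2_delays / 70.0) + rng.normal(0, 1.5, t2_delays.size)
        order = rng.permutation(t2_delays.size)
        fit = fit_single_exponential(
            PeakHeightSeries(1, "T2", t2_delays, heights)
        )
        fit_perm = fit_single_exponential(
            PeakHeightSeries(1, "T2", t2_delays[order], heights[order])
        )
        assert fit_perm.time_constant == pytest.approx(fit.time_constant, rel=1e-9)

    def test_all_constant_heights_degenerate(self, t2_delays):
        series = PeakHeightSeries(1, "T2", t2_delays, np.full(t2_delays.size, 5.0))
        with pytest.raises(DegenerateInputError):
            fit_single_exponential(series)

    def test_too_few_points_rejected_by_type(self, t2_delays):
        with pytest.raises(InputError):
            PeakHeightSeries(1, "T2", t2_delays[:2], np.array([9.0, 5.0]))

    def test_unresolved_decay_returns_none(self):
        # decay 1e5x slower than the sampled span: T is unconstrained
        delays = np.array([10.0, 20.0, 30.0, 40.0])
        heights = 100.0 * np.exp(-delays / 2.0e6)
        result = fit_single_exponential(PeakHeightSeries(1, "T2", delays, heights))
        assert result is None


class TestMonteCarloCalibration:
    def test_bias_and_coverage_of_reported_sd(self, t1_delays):
        """At 2% noise over 200 seeded replicates the fit is unbiased within
        2% and the +/-1 sd interval covers truth at the Gaussian rate."""
        rng = np.random.default_rng(42)
        truth, amplitude, n_rep = 750.0, 100.0, 200
        recovered, covered = [], 0
        for _ in range(n_rep):
            heights = amplitude * np.exp(-t1_delays / truth) + rng.normal(
                0, 0.02 * amplitude, t1_delays.size
            )
            fit = fit_single_exponential(PeakHeightSeries(1, "T1", t1_delays, heights))
            recovered.append(fit.time_constant)
            covered += abs(fit.time_constant - truth) <= fit.time_constant_sd
        assert np.mean(recovered) == pytest.approx(truth, rel=0.02)
        assert 0.61 <= covered / n_rep <= 0.75


class TestHetNoe:
    def test_noiseless_ratio(self):
        value = compute_hetnoe(80.0, 100.0, 0.0, 0.0)
        assert value.noe == pytest.approx(0.8)
        assert value.noe_sd == 0.0

    @given(st.floats(min_value=0.1, max_value=1e6),
           st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, derandomize=True)
    def test_identity_ratio_for_any_noise(self, height, noise):
        assert compute_hetnoe(height, height, noise, noise).noe == pytest.approx(1.0)

    def test_noise_propagation_hand_value(self):
        value = compute_hetnoe(80.0, 100.0, 2.0, 2.0)
        assert value.noe_sd == pytest.approx(
            0.8 * math.sqrt((2 / 80) ** 2 + (2 / 100) ** 2), rel=1e-12
        )
        assert value.noe_sd == pytest.approx(0.0256, abs=5e-5)

    def test_zero_unsaturated_height_rejected(self):
        with pytest.raises(InputError):
            compute_hetnoe(50.0, 0.0)


class TestNitrogenLarmor:
    def test_600_mhz(self):
        assert nitrogen_larmor(600.0) == pytest.approx(60.797, abs=5e-4)

    def test_linearity(self):
        assert nitrogen_larmor(900.0) == pytest.approx(1.5 * nitrogen_larmor(600.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            nitrogen_larmor(0.0)


class TestTauC:
    def test_reference_averages_give_9_9_ns(self):
        tau = tau_c_from_t1_t2(750.0, 70.0, nitrogen_larmor(600.0))
        assert round(tau, 1) == 9.9

    def test_zero_at_radicand_boundary(self):
        assert tau_c_from_t1_t2(7.0, 6.0, 60.8) == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        expected = 1e3 / (4 * math.pi * 60.8) * math.sqrt(6 * 10 - 7)
        assert tau_c_from_t1_t2(1000.0, 100.0, 60.8) == pytest.approx(expected)
        assert tau_c_from_t1_t2(1000.0, 100.0, 60.8) == pytest.approx(9.53, abs=5e-3)

    def test_small_ratio_is_domain_error(self):
        with pytest.raises(EstimatorDomainError, match="ratio too small"):
            tau_c_from_t1_t2(100.0, 100.0, 60.8)

    @given(st.floats(min_value=1.3, max_value=20.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_ratio_and_inverse_in_field(self, ratio):
        nu = nitrogen_larmor(600.0)
        tau = tau_c_from_t1_t2(ratio * 100.0, 100.0, nu)
        tau_up = tau_c_from_t1_t2((ratio + 0.1) * 100.0, 100.0, nu)
        assert tau_up > tau
        assert tau_c_from_t1_t2(ratio * 100.0, 100.0, 2 * nu) == pytest.approx(
            tau / 2
        )


def _profile(res, t1, t2, noe, nu):
    fit1 = ExponentialFit(t1, 10.0, 100.0, 1.0, 0.5, 9)
    fit2 = ExponentialFit(t2, 1.5, 100.0, 1.0, 0.5, 7)
    tau = tau_c_from_t1_t2(t1, t2, nu)
    sd = tau_c_sd_from_fits(t1, t2, 10.0, 1.5, nu)
    return ResidueRelaxation(
        residue_number=res,
        t1=fit1,
        t2=fit2,
        hetnoe=HetNoeValue(noe, 0.02),
        tau_c=tau,
        tau_c_sd=sd,
    )


class TestSummarizeDynamics:
    def test_uniform_profile_monomer_verdict(self):
        nu = nitrogen_larmor(600.0)
        profiles = [_profile(r, 750.0, 70.0, 0.8, nu) for r in range(1, 11)]
        summary = summarize_dynamics(profiles, expected_monomer_tau_c=(8.0, 12.0))
        assert summary.mean_tau_c == pytest.approx(9.9, abs=0.05)
        assert summary.oligomer_verdict == "monomer-consistent"
        assert summary.flexible_residues == []

    def test_low_noe_residue_flagged(self):
        nu = nitrogen_larmor(600.0)
        profiles = [_profile(r, 750.0, 70.0, 0.8, nu) for r in range(1, 6)]
        profiles[2] = _profile(3, 750.0, 70.0, 0.2, nu)
        summary = summarize_dynamics(profiles, noe_floor=0.65)
        assert summary.flexible_residues == [3]

    def test_outside_window_is_larger_than_monomer(self):
        nu = nitrogen_larmor(600.0)
        profiles = [_profile(r, 1500.0, 50.0, 0.8, nu) for r in range(1, 4)]
        summary = summarize_dynamics(profiles, expected_monomer_tau_c=(8.0, 12.0))
        assert summary.oligomer_verdict == "larger-than-monomer"

    def test_aggregates_match_direct_recomputation(self):
        nu = nitrogen_larmor(600.0)
        rng = np.random.default_rng(3)
        profiles = [
            _profile(r, rng.uniform(600, 900), rng.uniform(60, 90), 0.8, nu)
            for r in range(1, 21)
        ]
        summary = summarize_dynamics(profiles)
        taus = [p.tau_c for p in profiles]
        assert summary.mean_tau_c == pytest.approx(np.mean(taus))
        assert summary.sd_tau_c == pytest.approx(np.std(taus, ddof=1))
        assert summary.mean_t1 == pytest.approx(
            np.mean([p.t1.time_constant for p in profiles])
        )

    def test_empty_valid_set_rejected(self):
        with pytest.raises(InputError):
            summarize_dynamics([ResidueRelaxation(residue_number=1)])
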
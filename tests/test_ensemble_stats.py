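"""Kabsch superposition and ensemble precision statistics.

The Kabsch implementation is cross-checked against an independent
brute-force minimizer that searches rotation space directly (random
quaternion grid + Nelder-Mead polish on the quaternion), which never sees
the SVD solution.
"""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from solnmr.domain import InputError
from solnmr.ensemble_stats import (
    ResidueSelection,
    kabsch_superpose,
    mean_structure,
    parse_residue_ranges,
    per_residue_rmsd,
    rmsd_to_mean,
    superpose_ensemble,
)
from solnmr.synthetic_data import SyntheticSpec, gen_ensemble, make_backbone_template

from conftest import make_ensemble


def brute_force_min_rmsd(mobile, reference, n_grid=4000, seed=0):
    """Minimum rmsd over rotations by quaternion-grid search plus polish."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(quat):
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        diff = mobile @ rot.T - reference
        return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

    rng = np.random.default_rng(seed)
    grid = rng.normal(size=(n_grid, 4))
    best = min(grid, key=rmsd_of)
    result = minimize(rmsd_of, best, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return result.fun


TOY4 = np.array(
    [[0.0, 0.0, 0.0], [1.7, 0.2, -0.1], [0.3, 2.1, 0.4], [-0.5, 0.6, 1.9]]
)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        sup = kabsch_superpose(TOY4, TOY4)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        shift = np.array([5.0, -3.0, 2.0])
        sup = kabsch_superpose(TOY4, TOY4 + shift)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, shift, atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            target = TOY4 @ Rotation.random(rng=rng).as_matrix().T + rng.normal(
                0, 0.3, TOY4.shape
            )
            sup = kabsch_superpose(TOY4, target)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_reflection_branch_not_taken_for_mirrored_target(self):
        mirrored = TOY4 * np.array([1.0, 1.0, -1.0])
        sup = kabsch_superpose(TOY4, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0  # a mirror image cannot be superposed exactly

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            rotation = Rotation.random(rng=rng).as_matrix()
            target = TOY4 @ rotation.T + rng.normal(0, 0.2, TOY4.shape) + [1, -2, 3]
            sup = kabsch_superpose(TOY4, target)
            oracle = brute_force_min_rmsd(TOY4, target, seed=trial)
            assert sup.rmsd == pytest.approx(oracle, abs=1e-3)
            assert sup.rmsd <= oracle + 1e-9  # Kabsch is the exact minimizer

    def test_superposed_rmsd_never_worse_than_raw(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            kabsch_superpose(TOY4[:2], TOY4[:2])
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InputError):
            kabsch_superpose(line, line)


class TestEnsembleStatistics:
    def test_identical_models_zero_rmsd(self):
        base = make_backbone_template(6).coords[0]
        ens = make_ensemble([base, base, base])
        mean, sd = rmsd_to_mean(ens)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert all(
            v == pytest.approx(0.0, abs=1e-9) for v in per_residue_rmsd(ens).values()
        )

    def test_mean_of_mirrored_pair_lies_on_plane(self):
        # two models reflected about the z=0 plane through their centroid:
        # the mean must lie in that plane (z coordinate 0)
        base = make_backbone_template(5).coords[0]
        base = base - base.mean(axis=0)
        mirrored = base * np.array([1.0, 1.0, -1.0])
        ens = make_ensemble([base, mirrored])
        mean = mean_structure(ens, superpose=False)
        np.testing.assert_allclose(mean[:, 2], 0.0, atol=1e-12)

    def test_mean_minimizes_total_squared_deviation(self):
        ens = gen_ensemble(SyntheticSpec(seed=3, n_residues=8, n_models=6))
        sup = superpose_ensemble(ens)
        selection = ResidueSelection(tuple(range(1, 9)))
        mean = mean_structure(sup, selection, superpose=False)
        total = np.sum((sup.coords - mean) ** 2)
        for mi in range(sup.n_models):
            candidate = np.sum((sup.coords - sup.coords[mi]) ** 2)
            assert total <= candidate + 1e-9

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        sigma = 0.5
        spec = SyntheticSpec(
            seed=4, n_residues=40, n_models=20,
            ensemble_spread=sigma, flexible_segments=(),
        )
        mean, _ = rmsd_to_mean(gen_ensemble(spec))
        assert mean == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)

    def test_rigid_motion_invariance(self):
        ens = gen_ensemble(SyntheticSpec(seed=5, n_residues=10, n_models=8))
        rotation = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        moved = ens.with_coords(ens.coords @ rotation.T + np.array([3.0, -7.0, 11.0]))
        assert rmsd_to_mean(moved)[0] == pytest.approx(rmsd_to_mean(ens)[0], abs=1e-9)
        prof_a = per_residue_rmsd(ens)
        prof_b = per_residue_rmsd(moved)
        for res in prof_a:
            assert prof_b[res] == pytest.approx(prof_a[res], abs=1e-9)

    def test_localized_jitter_elevates_profile_there(self):
        spread = {r: (1.5 if 10 <= r <= 20 else 0.05) for r in range(1, 31)}
        spec = SyntheticSpec(seed=6, n_residues=30, n_models=15, ensemble_spread=spread)
        profile = per_residue_rmsd(gen_ensemble(spec))
        inside = [profile[r] for r in range(10, 21)]
        outside = [profile[r] for r in range(1, 31) if not 10 <= r <= 20]
        assert min(inside) > max(outside)

    def test_wider_selection_does_not_decrease_rmsd(self):
        # loop jitter >= core jitter: adding loops can only raise the rmsd
        spread = {r: (1.0 if r > 10 else 0.1) for r in range(1, 21)}
        spec = SyntheticSpec(seed=8, n_residues=20, n_models=12, ensemble_spread=spread)
        ens = gen_ensemble(spec)
        core, _ = rmsd_to_mean(ens, ResidueSelection(tuple(range(1, 11))))
        everything, _ = rmsd_to_mean(ens, ResidueSelection(tuple(range(1, 21))))
        assert everything >= core

    def test_profile_matches_double_loop_recomputation(self):
        ens = gen_ensemble(SyntheticSpec(seed=10, n_residues=6, n_models=5))
        sup = superpose_ensemble(
            ens, ResidueSelection(tuple(range(1, 7)))
        )
        profile = per_residue_rmsd(ens)
        table = sup.atom_table
        for res, value in profile.items():
            sq_sum, count = 0.0, 0
            idx = [
                i
                for i in range(sup.n_atoms)
                if int(table.at[i, "residue_number"]) == res
                and table.at[i, "atom_name"] in ("N", "CA", "C", "O")
            ]
            for i in idx:
                mean_pos = sup.coords[:, i].mean(axis=0)
                for mi in range(sup.n_models):
                    sq_sum += np.sum((sup.coords[mi, i] - mean_pos) ** 2)
                    count += 1
            assert value == pytest.approx(np.sqrt(sq_sum / count), rel=1e-9)

    def test_missing_atoms_reported_absent_not_zero(self):
        ens = gen_ensemble(SyntheticSpec(seed=11, n_residues=4, n_models=3))
        keep = ens.atom_table[ens.atom_table["residue_number"] != 2].index.to_numpy()
        from solnmr.domain import Ensemble

        trimmed = Ensemble(
            atom_table=ens.atom_table.iloc[keep].reset_index(drop=True),
            coords=ens.coords[:, keep],
        )
        profile = per_residue_rmsd(trimmed)
        assert 2 not in profile


def test_parse_residue_ranges():
    assert parse_residue_ranges("2-4,9,12-13") == (2, 3, 4, 9, 12, 13)
    with pytest.raises(InputError):
        parse_residue_ranges(" , ")
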
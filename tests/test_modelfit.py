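"""Kabsch superposition, dual-space validation, model splicing, combined
envelopes, flexible fitting, and map correlation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saxstruct.envelope import anneal_beads, AnnealParams, bead_density
from saxstruct.modelfit import (combine_envelopes, concentration_qmax_correlation,
                                corr, flexfit, kabsch, splice_models,
                                validate_dual)
from saxstruct.profile import debye_profile
from saxstruct.curves import ScatteringCurve
from saxstruct.structures import AtomicModel, BeadModel
from saxstruct.synth import DomainSpec, make_toy_structure, simulate_curve


def _quaternion_kabsch_oracle(P, Q):
    """Independent optimal-rotation solver via the quaternion method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


class TestKabsch:
    def test_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            P = rng.normal(0, 10, (25, 3))
            R_true = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
            Q = P @ R_true.T + rng.normal(0, 0.5, (25, 3)) + 5.0
            R, t, rmsd = kabsch(P, Q)
            R_oracle = _quaternion_kabsch_oracle(P, Q)
            rmsd_oracle = np.sqrt(np.mean(np.sum(
                ((P - P.mean(0)) @ R_oracle.T - (Q - Q.mean(0))) ** 2, axis=1)))
            assert rmsd == pytest.approx(rmsd_oracle, rel=1e-9)

    def test_exact_recovery(self, rng):
        P = rng.normal(0, 10, (30, 3))
        R_true = Rotation.from_euler("xyz", [10, -40, 77], degrees=True).as_matrix()
        Q = P @ R_true.T + np.array([4.0, 5.0, -6.0])
        R, t, rmsd = kabsch(P, Q)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, R_true, atol=1e-9)

    def test_proper_rotation(self, rng):
        P = rng.normal(0, 5, (20, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored target
        R, _, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestValidateDual:
    def test_exact_model_zero_chi2(self, dumbbell_toy):
        model = dumbbell_toy.model
        clean = simulate_curve(model, noise=(0.0, 0.0))
        envelope = BeadModel(centers=model.ca_coords(), bead_radius=3.0)
        report = validate_dual(model, clean, envelope)
        assert report.chi2 < 1e-3
        assert report.nsd is not None and report.nsd < 1.0

    def test_corruption_increases_both_metrics(self, dumbbell_toy, rng):
        model = dumbbell_toy.model
        curve = simulate_curve(model, noise=(0.01, 4.0), seed=8)
        envelope = BeadModel(centers=model.ca_coords(), bead_radius=3.0)
        base = validate_dual(model, curve, envelope)
        bad = model._subset(np.ones(len(model), bool))
        coords = bad.coords.copy()
        half = rng.random(len(bad)) < 0.5
        coords[half] += rng.normal(0, 30.0, (int(half.sum()), 3))
        bad.coords = coords
        worse = validate_dual(bad, curve, envelope)
        assert worse.chi2 > base.chi2
        assert worse.nsd > base.nsd


class TestSplice:
    def _chain(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 1, (n, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.cumsum(steps, axis=0)
        return AtomicModel.from_ca(coords)

    def test_identical_models(self):
        m = self._chain()
        out, rep = splice_models(m, m, (20, 40), (1, 30), (31, 60))
        assert len(out) == len(m)
        np.testing.assert_allclose(
            np.sort(out.coords, axis=0), np.sort(m.coords, axis=0), atol=1e-9)
        assert rep.overlap_rmsd < 1e-9
        assert rep.junctions_ok

    def test_rotated_copy_recovers_original(self):
        m = self._chain(seed=1)
        R = Rotation.from_euler("zx", [83, -21], degrees=True).as_matrix()
        m2 = m.transformed(R, np.array([30.0, -10.0, 5.0]))
        out, rep = splice_models(m, m2, (15, 45), (1, 30), (31, 60))
        assert rep.overlap_rmsd < 1e-9
        np.testing.assert_allclose(
            np.sort(out.coords, axis=0), np.sort(m.coords, axis=0), atol=1e-3)

    def test_perturbed_halves(self, rng):
        truth = self._chain(seed=2)
        a = truth._subset(truth.residue_index <= 45)
        b = truth._subset(truth.residue_index >= 16)
        pert = 1.0
        ca = a.coords.copy()
        ca[a.residue_index <= 15] += rng.normal(0, pert, (15, 3))
        a.coords = ca
        cb = b.coords.copy()
        cb[b.residue_index >= 46] += rng.normal(0, pert, (15, 3))
        b.coords = cb
        out, rep = splice_models(a, b, (16, 45), (1, 30), (31, 60))
        rmsd = np.sqrt(np.mean(np.sum(
            (out.coords - truth.coords) ** 2, axis=1)))
        assert rmsd < 3.0 * pert

    def test_conflicting_take_ranges(self):
        m = self._chain()
        with pytest.raises(ValueError, match="conflict|overlap"):
            splice_models(m, m, (20, 40), (1, 35), (30, 60))

    def test_short_overlap_raises(self):
        m = self._chain()
        with pytest.raises(ValueError, match="overlap"):
            splice_models(m, m, (20, 25), (1, 22), (23, 60))


class TestCombineEnvelopes:
    def test_single_envelope_degenerate_case(self, dumbbell_toy):
        model = dumbbell_toy.model
        env = BeadModel(centers=model.ca_coords(), bead_radius=3.0)
        lo = int(model.residue_index.min())
        hi = int(model.residue_index.max())
        combined = combine_envelopes(env, env, model, (lo, hi), (lo, hi))
        single = bead_density(env)
        assert combined.integral() == pytest.approx(single.integral(), rel=0.1)

    def test_covers_both_lobes_and_max_property(self, dumbbell_toy):
        model = dumbbell_toy.model
        (a0, a1), (b0, b1) = dumbbell_toy.domain_ranges
        env_a = BeadModel(centers=model.select_residues(a0, a1).ca_coords(),
                          bead_radius=3.0)
        env_b = BeadModel(centers=model.select_residues(b0, b1).ca_coords(),
                          bead_radius=3.0)
        combined = combine_envelopes(env_a, env_b, model, (a0, a1), (b0, b1))
        # density support contains both domain centroids
        for rng_ in ((a0, a1), (b0, b1)):
            c = model.select_residues(*rng_).ca_coords().mean(axis=0)
            assert combined.interpolate(c[None, :])[0] > 0.1 * combined.values.max()

    def test_commutative(self, dumbbell_toy):
        model = dumbbell_toy.model
        (a0, a1), (b0, b1) = dumbbell_toy.domain_ranges
        env_a = BeadModel(centers=model.select_residues(a0, a1).ca_coords(),
                          bead_radius=3.0)
        env_b = BeadModel(centers=model.select_residues(b0, b1).ca_coords(),
                          bead_radius=3.0)
        g1 = combine_envelopes(env_a, env_b, model, (a0, a1), (b0, b1))
        g2 = combine_envelopes(env_b, env_a, model, (b0, b1), (a0, a1))
        assert g1.integral() == pytest.approx(g2.integral(), rel=0.05)


class TestCorr:
    def test_self_density_is_one(self, dumbbell_toy):
        beads = BeadModel(centers=dumbbell_toy.model.ca_coords(), bead_radius=3.0)
        grid = bead_density(beads, kernel_sigma=3.0)
        assert corr(grid, dumbbell_toy.model) == pytest.approx(1.0, abs=1e-6)

    def test_displaced_model_decorrelates(self, dumbbell_toy):
        beads = BeadModel(centers=dumbbell_toy.model.ca_coords(), bead_radius=3.0)
        grid = bead_density(beads, kernel_sigma=3.0)
        shifted = dumbbell_toy.model.transformed(np.eye(3),
                                                 np.array([500.0, 0.0, 0.0]))
        assert corr(grid, shifted) < 0.1

    def test_invariant_to_linear_rescaling(self, dumbbell_toy):
        from saxstruct.structures import DensityGrid

        beads = BeadModel(centers=dumbbell_toy.model.ca_coords(), bead_radius=3.0)
        grid = bead_density(beads, kernel_sigma=3.0)
        scaled = DensityGrid(origin=grid.origin, voxel=grid.voxel,
                             values=3.7 * grid.values)
        assert corr(grid, dumbbell_toy.model) == pytest.approx(
            corr(scaled, dumbbell_toy.model), rel=1e-9)


@pytest.fixture(scope="module")
def rotated_dumbbell(dumbbell_toy):
    """Ground-truth map plus a start model with one domain rotated 30 deg."""
    truth = dumbbell_toy.model
    grid = bead_density(BeadModel(centers=truth.ca_coords(), bead_radius=3.0))
    start = truth._subset(np.ones(len(truth), bool))
    coords = start.coords.copy()
    lo, hi = dumbbell_toy.domain_ranges[1]
    sel = (start.residue_index >= lo) & (start.residue_index <= hi)
    pivot = coords[~sel][-1]
    R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
    coords[sel] = (coords[sel] - pivot) @ R.T + pivot
    start.coords = coords
    return grid, start, truth


class TestFlexFit:
    def test_stationary_at_truth(self, dumbbell_toy):
        truth = dumbbell_toy.model
        grid = bead_density(BeadModel(centers=truth.ca_coords(), bead_radius=3.0))
        res = flexfit(truth, grid, rigid_domains=dumbbell_toy.domain_ranges,
                      steps=40, corr_every=10)
        # already at the map optimum: correlation starts at its maximum and
        # the model barely moves (small settling into voxel maxima allowed)
        assert res.corr_series[0] > 0.99
        assert res.corr_series[-1] > 0.9
        assert res.rmsd_series[-1] < 0.5

    def test_rotated_domain_recovery(self, rotated_dumbbell, dumbbell_toy):
        grid, start, truth = rotated_dumbbell
        rmsd0 = np.sqrt(np.mean(np.sum((start.coords - truth.coords) ** 2,
                                       axis=1)))
        res = flexfit(start, grid, rigid_domains=dumbbell_toy.domain_ranges,
                      steps=200, corr_every=50)
        rmsd1 = np.sqrt(np.mean(np.sum((res.model.coords - truth.coords) ** 2,
                                       axis=1)))
        assert res.corr_series[-1] > res.corr_series[0]
        assert rmsd1 < 0.5 * rmsd0

    def test_frozen_domains_stay_rigid(self, rotated_dumbbell, dumbbell_toy):
        grid, start, _ = rotated_dumbbell
        res = flexfit(start, grid, rigid_domains=dumbbell_toy.domain_ranges,
                      steps=60, k_domain=1e6, corr_every=30)
        for lo, hi in dumbbell_toy.domain_ranges:
            m = (res.model.residue_index >= lo) & (res.model.residue_index <= hi)
            s = (start.residue_index >= lo) & (start.residue_index <= hi)
            _, _, rmsd = kabsch(res.model.coords[m], start.coords[s])
            assert rmsd < 0.1

    def test_energy_non_increasing(self, rotated_dumbbell, dumbbell_toy):
        grid, start, _ = rotated_dumbbell
        res = flexfit(start, grid, rigid_domains=dumbbell_toy.domain_ranges,
                      steps=80, corr_every=1, rigid_polish=False)
        assert np.all(np.diff(res.energy_series) <= 1e-9)

    def test_zn_restraint_pulls_to_target_distance(self, dumbbell_toy):
        truth = dumbbell_toy.model
        grid = bead_density(BeadModel(centers=truth.ca_coords(), bead_radius=3.0))
        # restrain two CA atoms 7.6 A apart toward 2.5 A
        res = flexfit(truth, grid, zn_restraints=[(0, 2)], steps=200,
                      k_zn=50.0, rigid_polish=False, corr_every=50)
        d = np.linalg.norm(res.model.coords[2] - res.model.coords[0])
        d0 = np.linalg.norm(truth.coords[2] - truth.coords[0])
        assert d < d0  # moved toward the 2.5 A reference


class TestConcentrationQmax:
    def test_study_table_rows(self):
        # NSD3-SET-PHD4: concentrations and pre-rebin q_max of the four runs
        r = concentration_qmax_correlation(
            [(4.3, 0.20), (1.6, 0.16), (1.6, 0.14), (1.0, 0.18)])
        assert r >= 0.6

    def test_perfect_line(self):
        x = np.arange(5.0)
        assert concentration_qmax_correlation(
            np.column_stack([x, 2 * x + 1])) == pytest.approx(1.0)

    def test_anti_correlation(self):
        x = np.arange(5.0)
        assert concentration_qmax_correlation(
            np.column_stack([x, -x])) == pytest.approx(-1.0)

    def test_dataframe_input(self):
        import pandas as pd

        df = pd.DataFrame({"concentration": [1.0, 2.0, 3.0],
                           "q_max": [0.1, 0.2, 0.3]})
        assert concentration_qmax_correlation(df) == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            concentration_qmax_correlation([(1.0, 0.1), (2.0, 0.2)])
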
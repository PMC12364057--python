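"""Tracking metrics against hand-computed values, reference geometry,
closed-loop trials on the exact fixture, and sweep bookkeeping."""

import numpy as np
import pytest

import manifoldmpc as mm


class TestNmse:
    def test_perfect_tracking_is_zero(self):
        z = np.random.default_rng(0).normal(size=(20, 2))
        np.testing.assert_allclose(mm.nmse(z, z), 0.0)

    def test_hand_computed_value(self):
        """z constant at 1 against a reference alternating {0, 2}:
        MSE = 1, range = 2, nMSE = 0.5."""
        z = np.ones((10, 1))
        ref = np.tile([[0.0], [2.0]], (5, 1))
        assert mm.nmse(z, ref)[0] == pytest.approx(0.5)

    def test_three_step_toy_sequence(self):
        z = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.0]])
        ref = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 0.0]])
        # dim 0: errors (1,0,1), MSE 2/3, range 4 -> 1/6
        # dim 1: errors (0,1,0), MSE 1/3, range 2 -> 1/6
        np.testing.assert_allclose(mm.nmse(z, ref), [1 / 6, 1 / 6])

    def test_scales_linearly_with_joint_scaling(self):
        """nMSE normalizes by range (not range^2), so scaling z and z*
        jointly by c scales nMSE by c."""
        rng = np.random.default_rng(1)
        z, ref = rng.normal(size=(30, 2)), rng.normal(size=(30, 2))
        base = mm.nmse(z, ref)
        np.testing.assert_allclose(mm.nmse(3.0 * z, 3.0 * ref), 3.0 * base)

    def test_constant_reference_falls_back_to_mse(self):
        z = np.zeros((4, 1))
        ref = np.ones((4, 1))
        assert mm.nmse(z, ref)[0] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.nmse(np.zeros((3, 2)), np.zeros((4, 2)))


class TestInputRms:
    def test_zero_and_constant_and_alternating(self):
        np.testing.assert_allclose(mm.input_rms(np.zeros((5, 2))), 0.0)
        np.testing.assert_allclose(mm.input_rms(np.full((5, 2), -0.7)), 0.7)
        alt = np.tile([[1.0], [-1.0]], (4, 1))
        assert mm.input_rms(alt)[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.input_rms(np.zeros((0, 2)))


class TestSetpointReference:
    def test_switch_at_500_total_1000(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(loc=(-3, 0), scale=0.1, size=(50, 2)),
                         rng.normal(loc=(3, 1), scale=0.1, size=(50, 2))])
        ref = mm.make_setpoint_reference(pts, seed=0)
        assert len(ref) == 1000
        assert ref.switch_times == (500,)
        assert np.all(ref.z_star[:500] == ref.z_star[0])
        assert np.all(ref.z_star[500:] == ref.z_star[-1])

    def test_set_points_near_blob_means(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(loc=(-5, -5), scale=0.2, size=(80, 2)),
                         rng.normal(loc=(5, 5), scale=0.2, size=(80, 2))])
        ref = mm.make_setpoint_reference(pts, seed=0)
        np.testing.assert_allclose(ref.z_star[0], [-5, -5], atol=0.2)
        np.testing.assert_allclose(ref.z_star[-1], [5, 5], atol=0.2)

    def test_determinism_and_degenerate_points(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(60, 2))
        a = mm.make_setpoint_reference(pts, seed=3)
        b = mm.make_setpoint_reference(pts, seed=3)
        np.testing.assert_array_equal(a.z_star, b.z_star)
        with pytest.raises(ValueError):
            mm.make_setpoint_reference(np.ones((10, 2)), seed=0)


class TestArcReferences:
    def test_equal_length_shared_endpoints(self):
        z0, zf = np.array([1.0, 2.0]), np.array([-2.0, 0.5])
        arc1, arc2 = mm.make_arc_references(z0, zf, duration=1000)
        for arc in (arc1, arc2):
            np.testing.assert_array_equal(arc.z_star[0], z0)
            np.testing.assert_array_equal(arc.z_star[-1], zf)
        len1 = np.sum(np.linalg.norm(np.diff(arc1.z_star, axis=0), axis=1))
        len2 = np.sum(np.linalg.norm(np.diff(arc2.z_star, axis=0), axis=1))
        assert abs(len1 - len2) < 1e-9
        # discrete length approaches the semicircle length pi * |zf-z0| / 2
        semicircle = np.pi * np.linalg.norm(zf - z0) / 2.0
        assert len1 == pytest.approx(semicircle, rel=1e-4)

    def test_midpoints_on_perpendicular_bisector(self):
        """Arc midpoints sit at center +/- radius along the perpendicular
        of the chord (analytic semicircle geometry)."""
        z0, zf = np.array([0.0, 0.0]), np.array([2.0, 0.0])
        arc1, arc2 = mm.make_arc_references(z0, zf, duration=1001)
        center = np.array([1.0, 0.0])
        mids = sorted([arc1.z_star[500][1], arc2.z_star[500][1]])
        np.testing.assert_allclose(mids, [-1.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(arc1.z_star[500][0], center[0], atol=1e-9)
        np.testing.assert_allclose(arc2.z_star[500][0], center[0], atol=1e-9)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            mm.make_arc_references(np.ones(2), np.ones(2))


class TestControlTrials:
    A = np.array([[0.95, 0.03], [0.0, 0.92]])
    B = np.array([[0.05, 0.01], [0.0, 0.05]])

    def test_mpc_tracks_reachable_setpoint_on_true_model(self):
        plant = mm.LinearFixturePlant(self.A, self.B)
        ref = mm.ReferenceTrajectory(np.tile([1.0, -0.5], (100, 1)))
        rec = mm.run_control_trial(plant, mm.MpcController(self.A, self.B),
                                   ref, seed=0)
        terminal_err = np.linalg.norm(rec.z[-1] - ref.z_star[-1])
        assert terminal_err < 1e-3
        assert rec.z.shape == rec.v.shape == (100, 2)

    def test_trial_fully_reproducible(self):
        plant = mm.LinearFixturePlant(self.A, self.B, noise_scale=0.05)
        ref = mm.ReferenceTrajectory(np.tile([0.5, 0.5], (60, 1)))
        recs = [mm.run_control_trial(plant, mm.MpcController(self.A, self.B),
                                     ref, seed=42) for _ in range(2)]
        np.testing.assert_array_equal(recs[0].z, recs[1].z)
        np.testing.assert_array_equal(recs[0].v, recs[1].v)

    def test_pid_with_protocol_gains_remains_bounded(self):
        plant = mm.LinearFixturePlant(self.A, self.B, noise_scale=0.02)
        ref = mm.ReferenceTrajectory(np.tile([1.0, -0.5], (200, 1)))
        rec = mm.run_control_trial(plant, mm.PidController(), ref, seed=1)
        assert np.isfinite(rec.z).all()
        assert np.abs(rec.z).max() < 10.0

    def test_mpc_beats_pid_on_noisy_fixture_setpoints(self):
        """Directional comparison on the ground-truth linear plant: MPC's
        trial-mean nMSE does not exceed PID's under the protocol gains and
        cost matrices."""
        ref_pts = np.vstack([np.tile([1.0, -0.5], (30, 1)),
                             np.tile([-0.5, 1.0], (30, 1))])
        ref = mm.ReferenceTrajectory(ref_pts, switch_times=(30,))
        scores = {}
        for name, mk in (("mpc", lambda: mm.MpcController(self.A, self.B)),
                         ("pid", mm.PidController)):
            nmses = []
            for trial in range(5):
                plant = mm.LinearFixturePlant(self.A, self.B, noise_scale=0.02)
                rec = mm.run_control_trial(plant, mk(), ref, seed=100 + trial)
                nmses.append(rec.nmse.mean())
            scores[name] = np.mean(nmses)
        assert scores["mpc"] <= scores["pid"]

    def test_stimulus_applied_same_step_in_circuit_plant(self):
        """The stimulus presented at step n is exactly the decode of the
        input computed at step n (no off-by-one)."""
        params = mm.CircuitParams.random(layer_sizes=(6, 4, 3), input_dim=8,
                                         seed=0, eta=0.0)
        nvae = mm.VaeModel(input_dim=3, k=2, hidden=(4,), seed=1)
        svae = mm.VaeModel(input_dim=8, k=2, hidden=(4,), seed=2)
        ldm = mm.LdmModel(A=np.eye(2) * 0.9, B=np.zeros((2, 2)), nvae=nvae,
                          svae=svae)
        ids = np.array([0, 6, 12])
        plant = mm.CircuitPlant(params, ids, ldm, svae)
        ref = mm.ReferenceTrajectory(np.tile([0.2, 0.2], (15, 1)))
        rec = mm.run_control_trial(plant, mm.PidController(), ref, seed=0)
        for n in range(15):
            np.testing.assert_array_equal(rec.stimuli[n],
                                          svae.decode(rec.v[n]))
        assert rec.spikes.shape == (15, 3)


class TestObservabilitySweep:
    def test_bookkeeping_shape_and_aggregation(self, default_fixture):
        """Row count matches fractions x ensembles x controllers x trials
        x dims, and per-condition mean nMSE equals an independent
        recomputation from the per-trial rows."""
        params = mm.CircuitParams.random(layer_sizes=(20, 10, 5), input_dim=6,
                                         seed=0, eta=0.05, w_scale=2.0)
        rng = np.random.default_rng(0)
        V = mm.synthetic_data.make_excitation_inputs(600, seed=1)
        svae = mm.VaeModel(input_dim=6, k=2, hidden=(4,), seed=3)
        stim = svae.decode(V)
        raster, _ = mm.simulate_circuit(stim, params, seed=2)
        from manifoldmpc.latent_dynamics import LdmConfig
        table = mm.run_observability_sweep(
            params, raster.spikes.astype(float), V, svae,
            fractions=[0.2, 0.5], n_ensembles=2, trials=2,
            controllers=("pid",), seed=0, nvae_epochs=2,
            ldm_config=LdmConfig(epochs=2, seed=0), trial_length=40,
            nvae_hidden=(8,))
        assert len(table) == 2 * 2 * 2 * 1 * 2
        grouped = table.groupby(["fraction", "ensemble", "controller"])["nmse"].mean()
        for (frac, ens, ctrl), mean_nmse in grouped.items():
            sub = table[(table.fraction == frac) & (table.ensemble == ens)
                        & (table.controller == ctrl)]
            assert mean_nmse == pytest.approx(sub["nmse"].to_numpy().mean())

    def test_too_small_fraction_skipped_with_warning(self, recwarn):
        params = mm.CircuitParams.random(layer_sizes=(5, 4, 3), input_dim=4,
                                         seed=0)
        svae = mm.VaeModel(input_dim=4, k=2, hidden=(4,), seed=0)
        table = mm.run_observability_sweep(
            params, np.zeros((50, 12)), np.zeros((50, 2)), svae,
            fractions=[0.01], n_ensembles=1, trials=1, seed=0)
        assert table.empty
        assert any("skipped" in str(w.message) for w in recwarn.list)
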
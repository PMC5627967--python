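"""Physics of the simulated rig: closed forms, limits and invariants."""

import dataclasses
import math

import numpy as np
import pytest

from fabricsense.apparatus import (ApparatusConfig, FabricSpec, PendulumSpec,
                                   SensorSpec, default_sensors)
from fabricsense.dynamics import (BaseKinematics, chain_rhs, generate_dataset,
                                  pendulum_energy, quantize,
                                  rigid_pendulum_rhs, simulate_pendulum,
                                  simulate_trial, virtual_accelerometer)


class TestPendulumRHS:
    def test_equilibria(self):
        spec = PendulumSpec()
        assert rigid_pendulum_rhs(spec, (0.0, 0.0)) == 0.0
        assert rigid_pendulum_rhs(spec, (math.pi, 0.0)) == pytest.approx(0.0)

    def test_restoring_direction_and_damping_sign(self):
        spec = PendulumSpec()
        assert rigid_pendulum_rhs(spec, (0.5, 0.0)) < 0
        assert rigid_pendulum_rhs(spec, (-0.5, 0.0)) > 0
        undamped = dataclasses.replace(spec, pivot_damping=0.0)
        assert rigid_pendulum_rhs(spec, (0.0, 1.0)) < rigid_pendulum_rhs(
            undamped, (0.0, 1.0))

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rigid_pendulum_rhs(PendulumSpec(), (math.nan, 0.0))

    def test_rod_only_small_angle_frequency_closed_form(self):
        # uniform rod: f = sqrt(3 g / 2 L) / 2 pi, ~0.809 Hz at L = 0.57 m
        spec = PendulumSpec(length=0.57, rod_mass=0.3, bob_mass=0.0,
                            pivot_damping=0.0, release_angle=0.01,
                            release_jitter_sd=0.0)
        expected = math.sqrt(3 * spec.gravity / (2 * spec.length)) / (2 * math.pi)
        assert spec.small_angle_frequency == pytest.approx(expected)
        assert expected == pytest.approx(0.8087, abs=1e-4)
        # verify against zero crossings of the simulated swing
        sol = simulate_pendulum(spec, duration=20.0)
        t = np.linspace(0, 20, 48000)
        theta = sol.sol(t)[0]
        crossings = t[1:][np.diff(np.sign(theta)) != 0]
        period = 2.0 * np.mean(np.diff(crossings))
        assert 1.0 / period == pytest.approx(expected, rel=1e-3)

    def test_undamped_energy_conserved_over_full_record(self):
        spec = PendulumSpec(pivot_damping=0.0, release_jitter_sd=0.0)
        sol = simulate_pendulum(spec, duration=10.0)
        t = np.linspace(0, 10, 6000)
        theta, dtheta = sol.sol(t)
        E = pendulum_energy(spec, theta, dtheta)
        scale = spec.mass_moment * spec.gravity  # available energy at release
        assert np.max(np.abs(E - E[0])) / scale < 1e-6


class TestChain:
    def test_hanging_chain_at_rest_is_equilibrium(self):
        fab = FabricSpec(material="jersey")
        acc = chain_rhs(fab, BaseKinematics(), (np.zeros(6), np.zeros(6)))
        np.testing.assert_allclose(acc, 0.0, atol=1e-12)

    def test_displaced_single_link_restores_toward_vertical(self):
        fab = FabricSpec(material="custom", segment_count=1,
                         bending_stiffness=0.0, joint_damping=0.0,
                         linear_density=0.05, drag_coefficient=0.0)
        acc = chain_rhs(fab, BaseKinematics(), (np.array([0.3]),
                                                np.array([0.0])))
        # free link displaced 0.3 rad: plain pendulum restoring torque
        expected = -1.5 * 9.81 / 0.18 * np.sin(0.3)
        np.testing.assert_allclose(acc, expected, rtol=1e-9)

    def test_bad_state_shape_rejected(self):
        fab = FabricSpec(material="jersey")
        with pytest.raises(ValueError, match="angles"):
            chain_rhs(fab, BaseKinematics(), (np.zeros(4), np.zeros(4)))

    def test_rigid_material_has_no_chain(self):
        with pytest.raises(ValueError, match="rigid"):
            chain_rhs(FabricSpec(material="rigid"), BaseKinematics(),
                      (np.zeros(6), np.zeros(6)))

    def test_stiff_limit_matches_rigid_extension(self):
        jersey = FabricSpec(material="jersey")
        stiff = FabricSpec(material="custom",
                           bending_stiffness=jersey.bending_stiffness * 1e4,
                           joint_damping=jersey.joint_damping,
                           linear_density=jersey.linear_density,
                           drag_coefficient=jersey.drag_coefficient)
        cfg_stiff = ApparatusConfig(
            fabric=stiff, sensors=default_sensors(jersey), duration=10.0)
        cfg_rigid = ApparatusConfig(fabric=FabricSpec(material="rigid"),
                                    duration=10.0)
        t_stiff = simulate_trial(cfg_stiff, seed=1, noise=False)
        t_rigid = simulate_trial(cfg_rigid, seed=1, noise=False)
        for soft, hard in (("F2", "R2"), ("F3", "R3")):
            a = t_stiff[soft].samples
            b = t_rigid[hard].samples
            rms = np.sqrt(np.mean(b**2))
            assert np.sqrt(np.mean((a - b) ** 2)) / rms < 0.01

    def test_softer_fabric_swings_further_than_stiffer(self):
        # tip sensor excursion: roma (softest) >= denim (stiffest)
        out = {}
        for mat in ("roma", "denim"):
            cfg = ApparatusConfig(fabric=FabricSpec(material=mat),
                                  duration=4.0)
            tr = simulate_trial(cfg, seed=2, noise=False)
            out[mat] = np.abs(tr["F3"].samples).max()
        assert out["roma"] >= out["denim"]


class TestVirtualAccelerometer:
    def test_static_hanging_reads_zero(self):
        s = SensorSpec("x", 0.5, noise_sd=0.0)
        assert virtual_accelerometer((0.0, 0.0), 0.0, s) == 0.0

    def test_static_horizontal_reads_one_g(self):
        s = SensorSpec("x", 0.5, noise_sd=0.0)
        assert virtual_accelerometer((0.0, 0.0), math.pi / 2, s) == (
            pytest.approx(1.0, abs=1e-4))

    def test_point_mass_pendulum_reads_zero_at_bob(self):
        # pure point-mass pendulum: d*theta'' + g*sin(theta) cancels exactly
        spec = PendulumSpec(rod_mass=1e-12, bob_mass=1.0, pivot_damping=0.0,
                            release_jitter_sd=0.0)
        cfg = ApparatusConfig(
            pendulum=spec, fabric=FabricSpec(material="rigid"),
            sensors=(SensorSpec("R1", spec.length, noise_sd=0.0),),
            duration=5.0)
        tr = simulate_trial(cfg, seed=0, noise=False)
        assert np.max(np.abs(tr["R1"].samples)) < 1e-6

    def test_noise_and_quantization(self, rng):
        s = SensorSpec("x", 0.5, noise_sd=0.05, full_scale=3.0, adc_bits=16)
        val = virtual_accelerometer((0.0, 0.0), 0.0, s, rng=rng)
        assert val != 0.0
        lsb = 6.0 / (2**16 - 2)
        assert abs(val / lsb - round(val / lsb)) < 1e-9

    def test_quantize_clips_and_snaps(self):
        s = SensorSpec("x", 0.5, full_scale=3.0, adc_bits=16)
        x = np.array([-5.0, 0.4, 5.0])
        q = quantize(x, s)
        assert q[0] == -3.0 and q[2] == 3.0
        lsb = 6.0 / (2**16 - 2)
        assert np.allclose(np.round(q / lsb), q / lsb)


class TestSimulateTrial:
    def test_default_trial_has_6000_samples_per_channel(self, default_dataset):
        tr = default_dataset.trials[0]
        assert set(tr.signals) == {"R1", "F2", "F3"}
        for sig in tr.signals.values():
            assert len(sig) == 6000
            assert sig.sample_rate == 600.0

    def test_zero_gravity_horizontal_release_is_silent(self):
        pend = PendulumSpec(gravity=0.0, pivot_damping=0.0,
                            release_jitter_sd=0.0)
        cfg = ApparatusConfig(pendulum=pend, duration=1.0)
        tr = simulate_trial(cfg, seed=0, noise=False)
        for sig in tr.signals.values():
            np.testing.assert_allclose(sig.samples, 0.0, atol=1e-9)

    def test_rigid_extension_amplitude_grows_with_radius(self):
        cfg = ApparatusConfig(fabric=FabricSpec(material="rigid"),
                              duration=10.0)
        tr = simulate_trial(cfg, seed=4, noise=False)
        rms = {k: np.sqrt(np.mean(v.samples**2)) for k, v in tr.signals.items()}
        assert rms["R1"] < rms["R2"] < rms["R3"]

    def test_r1_unaffected_by_fabric(self):
        # one-way coupling: the appendage never back-reacts on the pendulum
        trials = {}
        for mat in ("jersey", "rigid", "roma"):
            cfg = ApparatusConfig(fabric=FabricSpec(material=mat),
                                  duration=2.0)
            trials[mat] = simulate_trial(cfg, seed=11, noise=False)
        r1 = {m: t["R1"].samples for m, t in trials.items()}
        np.testing.assert_array_equal(r1["jersey"], r1["rigid"])
        np.testing.assert_array_equal(r1["jersey"], r1["roma"])

    def test_weighted_and_unweighted_develop_phase_offset(self):
        # periods differ, so the offset between matching zero crossings of
        # the two swings accumulates over the record
        def crossings(tip_load):
            spec = dataclasses.replace(PendulumSpec(release_jitter_sd=0.0),
                                       tip_load=tip_load)
            sol = simulate_pendulum(spec, duration=10.0)
            t = np.linspace(0, 10, 60000)
            theta = sol.sol(t)[0]
            return t[1:][np.diff(np.sign(theta)) < 0]

        c0, c3 = crossings(0.0), crossings(3.0)
        k = min(len(c0), len(c3))
        offsets = np.abs(c3[:k] - c0[:k])
        assert offsets[-1] > offsets[0]
        assert offsets[-1] > 3.0 * np.median(np.diff(c0)) * 0.001

    def test_all_samples_on_adc_grid_within_full_scale(self, default_dataset):
        tr = default_dataset.trials[0]
        lsb = 6.0 / (2**16 - 2)
        for sig in tr.signals.values():
            assert np.all(np.abs(sig.samples) <= 3.0 + 1e-12)
            np.testing.assert_allclose(
                np.round(sig.samples / lsb), sig.samples / lsb, atol=1e-6)


class TestGenerateDataset:
    def test_study_shape_and_labels(self, default_dataset):
        assert len(default_dataset.trials) == 20
        assert default_dataset.labels == ["0N", "3N"]
        assert len(default_dataset.select("0N")) == 10
        assert len(default_dataset.select("3N")) == 10

    def test_deterministic_for_fixed_master_seed(self):
        cfg = ApparatusConfig(duration=1.0)
        a = generate_dataset(cfg, 2, (0.0, 3.0), master_seed=5)
        b = generate_dataset(cfg, 2, (0.0, 3.0), master_seed=5)
        for ta, tb in zip(a.trials, b.trials):
            for sid in ta.signals:
                np.testing.assert_array_equal(ta[sid].samples,
                                              tb[sid].samples)

    def test_single_trial_per_condition_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_dataset(ApparatusConfig(duration=1.0), 1, (0.0,),
                             master_seed=0)

    def test_trials_differ_across_seeds_within_condition(self):
        cfg = ApparatusConfig(duration=1.0)
        ds = generate_dataset(cfg, 3, (0.0,), master_seed=8)
        a, b = ds.trials[0]["F3"].samples, ds.trials[1]["F3"].samples
        assert not np.array_equal(a, b)
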
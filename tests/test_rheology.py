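"""mOsc force design, demodulation, immersion geometry and G* estimation."""

import math

import numpy as np
import pytest

from afsrheo.calibration import ConversionMap
from afsrheo.forcemodel import Trajectory
from afsrheo.rheology import (
    ImmersionGeometry,
    OscProtocol,
    aggregate_beads,
    amplitude_from_force,
    design_mosc_force,
    estimate_modulus_window,
    geometry_factor,
    immersion_correction,
    immersion_half_angle,
    reconstruct_force,
    sliding_window_series,
    window_starts,
)
from afsrheo.viscomodels import GKVParams, gkv_modulus


def _const_map(c=1.5):
    return ConversionMap(
        x=np.array([0.0, 700.0, 0.0, 700.0]),
        y=np.array([0.0, 0.0, 550.0, 550.0]),
        c=np.full(4, c),
    )


class TestProtocol:
    def test_default_windows_hold_integer_cycles(self):
        p = OscProtocol()
        for f, cycles in zip(p.frequencies, (50, 250, 750)):
            assert f * p.window == pytest.approx(cycles)

    def test_non_integer_cycle_window_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            OscProtocol(frequencies=(0.123,), amplitudes=(10.0,), offset=20.0)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            OscProtocol(amplitudes=(100.0, 100.0, 100.0), offset=200.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="sampling"):
            OscProtocol(frequencies=(0.1, 40.0), amplitudes=(10.0, 10.0),
                        offset=50.0, sampling_rate=59.0, window=500.0)


class TestForceDesign:
    def test_single_component_extremes(self):
        p = OscProtocol(frequencies=(0.1,), amplitudes=(50.0,), offset=50.0,
                        duration=500.0)
        _, f = design_mosc_force(p)
        # sampling grid does not hit the sine extremes exactly
        assert f.min() == pytest.approx(0.0, abs=0.01)
        assert f.min() >= 0.0
        assert f.max() == pytest.approx(100.0, abs=0.01)

    def test_component_orthogonality(self):
        """Discrete Fourier analysis returns each amplitude at its own bin."""
        p = OscProtocol(duration=500.0)
        t, f = design_mosc_force(p)
        n = t.size
        for freq, amp in zip(p.frequencies, p.amplitudes):
            proj = 2.0 / n * np.abs(np.sum((f - f.mean()) * np.exp(-2j * math.pi * freq * t)))
            assert proj == pytest.approx(amp, rel=1e-10)
        # an off-protocol frequency with integer cycles in the window sees ~0
        proj0 = 2.0 / n * np.abs(np.sum((f - f.mean()) * np.exp(-2j * math.pi * 0.3 * t)))
        assert proj0 < 1e-9

    def test_amplitude_round_trip(self):
        p = OscProtocol(duration=500.0)
        _, f = design_mosc_force(p)
        c = 1.394
        v = amplitude_from_force(f, c)
        assert np.allclose(c * v**2, f, rtol=1e-14)
        assert amplitude_from_force(np.array([c]), c)[0] == pytest.approx(1.0)
        assert amplitude_from_force(np.array([4 * c]), c)[0] == pytest.approx(2.0)

    def test_negative_force_not_invertible(self):
        with pytest.raises(ValueError):
            amplitude_from_force(np.array([-1.0]), 1.0)


class TestImmersion:
    def test_half_angle_geometry(self):
        R = 5e-6
        assert immersion_half_angle(2 * R, R) == pytest.approx(math.pi / 2)
        assert immersion_half_angle(R, R) == pytest.approx(math.radians(30.0))

    def test_population_mean_half_angle(self):
        theta = immersion_half_angle(4.807e-6, 5e-6)
        assert math.degrees(theta) == pytest.approx(28.73, abs=0.05)

    def test_contact_larger_than_bead_rejected(self):
        with pytest.raises(ValueError):
            immersion_half_angle(11e-6, 5e-6)

    def test_correction_below_one_and_monotone(self):
        thetas = np.radians(np.linspace(10.5, 89.5, 100))
        f = np.array([immersion_correction(t) for t in thetas])
        assert np.all(f < 1.0)
        assert np.all(f > 0.0)
        assert np.all(np.diff(f) > 0)

    def test_gser_reduction_at_full_immersion(self):
        """At theta = 90 deg the geometry factor is exactly 6 pi R."""
        R = 5e-6
        geom = ImmersionGeometry(bead_radius=R, theta=math.pi / 2)
        assert geometry_factor(geom) == pytest.approx(6 * math.pi * R, rel=1e-12)


class TestReconstructForce:
    def test_constant_map(self):
        t = np.arange(59) / 59.0
        amp = np.linspace(1.0, 2.0, 59)
        traj = Trajectory(time=t, z=np.zeros(59), x=np.full(59, 100.0),
                          y=np.full(59, 100.0), amplitude=amp)
        f = reconstruct_force(traj, _const_map(2.0))
        assert np.allclose(f, 2.0 * amp**2)

    def test_drifting_bead_on_ramp_field(self):
        # c varies linearly in x; a drifting bead samples the ramp
        conv = ConversionMap(
            x=np.array([0.0, 200.0, 0.0, 200.0]),
            y=np.array([0.0, 0.0, 200.0, 200.0]),
            c=np.array([1.0, 3.0, 1.0, 3.0]),
        )
        t = np.arange(100) / 59.0
        x = np.linspace(50.0, 150.0, 100)
        traj = Trajectory(time=t, z=np.zeros(100), x=x, y=np.full(100, 100.0),
                          amplitude=np.ones(100))
        f = reconstruct_force(traj, conv)
        c_true = 1.0 + 2.0 * x / 200.0
        assert np.allclose(f, c_true, rtol=1e-10)


def _synthesize_response(protocol, g_of_omega, geom, duration=500.0):
    """Invert the estimator: z(t) from the force and a modulus function."""
    n = int(round(duration * protocol.sampling_rate))
    t = np.arange(n) / protocol.sampling_rate
    _, force = design_mosc_force(protocol, t)
    z = np.zeros(n)
    gfac = geometry_factor(geom)
    for freq, amp in zip(protocol.frequencies, protocol.amplitudes):
        w = 2 * math.pi * freq
        fh = -1j * amp * 1e-12
        z += (fh / (gfac * g_of_omega(w)) * np.exp(1j * w * t)).real
    return t, force, z


class TestModulusEstimation:
    def test_newtonian_fluid_limit(self, default_geometry):
        """Purely viscous response: delta = pi/2 and G'' = omega eta."""
        eta = 0.5  # Pa s, stiff fluid for a measurable response
        p = OscProtocol(duration=500.0)
        t, force, z = _synthesize_response(p, lambda w: 1j * w * eta, default_geometry)
        g, valid = estimate_modulus_window(t, force, z, p.frequencies, default_geometry)
        assert valid.all()
        for freq, gi in zip(p.frequencies, g):
            w = 2 * math.pi * freq
            assert np.angle(gi) == pytest.approx(math.pi / 2, abs=1e-9)
            assert gi.imag == pytest.approx(w * eta, rel=1e-9)
            assert abs(gi.real) < 1e-9 * abs(gi.imag)

    def test_pure_spring_limit(self, default_geometry):
        k = 800.0  # Pa
        p = OscProtocol(duration=500.0)
        t, force, z = _synthesize_response(p, lambda w: k + 0j, default_geometry)
        g, valid = estimate_modulus_window(t, force, z, p.frequencies, default_geometry)
        assert valid.all()
        assert np.allclose(np.abs(g), k, rtol=1e-10)
        assert np.allclose(np.angle(g), 0.0, atol=1e-10)

    def test_gkv_transfer_function_recovery(self, default_geometry):
        truth = GKVParams(G0=1000.0, alpha=0.8, beta=0.0)
        p = OscProtocol(duration=500.0)
        t, force, z = _synthesize_response(
            p, lambda w: gkv_modulus(w, truth), default_geometry
        )
        g, _ = estimate_modulus_window(t, force, z, p.frequencies, default_geometry)
        for freq, gi in zip(p.frequencies, g):
            expected = gkv_modulus(2 * math.pi * freq, truth)
            assert abs(gi - expected) / abs(expected) < 0.02

    def test_leakage_free_exactness_with_drift(self, default_geometry):
        """Offset + linear drift do not bias the drive-bin estimates."""
        truth = GKVParams(G0=1000.0, alpha=0.8, beta=0.0)
        p = OscProtocol(duration=500.0)
        t, force, z = _synthesize_response(
            p, lambda w: gkv_modulus(w, truth), default_geometry
        )
        z_drift = z + 5e-6 + 2e-9 * t
        g0, _ = estimate_modulus_window(t, force, z, p.frequencies, default_geometry)
        g1, _ = estimate_modulus_window(t, force, z_drift, p.frequencies, default_geometry)
        assert np.allclose(g0, g1, rtol=1e-7)

    def test_pipeline_linearity(self, default_geometry):
        truth = GKVParams(G0=1000.0, alpha=0.8, beta=0.0)
        p = OscProtocol(duration=500.0)
        t, force, z = _synthesize_response(
            p, lambda w: gkv_modulus(w, truth), default_geometry
        )
        g1, _ = estimate_modulus_window(t, force, z, p.frequencies, default_geometry)
        g2, _ = estimate_modulus_window(t, 7.0 * force, 7.0 * z, p.frequencies, default_geometry)
        assert np.allclose(g1, g2, rtol=1e-12)

    def test_vanishing_position_flagged(self, default_geometry):
        p = OscProtocol(duration=500.0)
        n = int(round(500.0 * p.sampling_rate))
        t = np.arange(n) / p.sampling_rate
        _, force = design_mosc_force(p, t)
        g, valid = estimate_modulus_window(t, force, np.zeros(n), p.frequencies, default_geometry)
        assert not valid.any()
        assert np.all(np.isnan(g.real))


class TestSlidingWindows:
    def test_window_count_3700s(self):
        starts = window_starts(3700.0, 500.0, 100.0)
        assert starts.size == math.floor((3700 - 500) / 100) + 1 == 33
        centers = starts + 250.0
        assert centers[0] == 250.0 and centers[1] == 350.0

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="window"):
            window_starts(400.0, 500.0, 100.0)

    def test_stationary_material_constant_series(self, default_geometry, huvec_gkv):
        from afsrheo.synthdata import SyntheticScenario, gen_mosc_experiment

        p = OscProtocol(duration=1500.0)
        scen = SyntheticScenario(seed=2, noise_z=0.0, drift_rate=0.0, n_beads=2,
                                 duration=1500.0, bead_g0_cv=0.0)
        trajs, conv, _ = gen_mosc_experiment(huvec_gkv, p, default_geometry, scen)
        series = sliding_window_series(trajs, conv, p, default_geometry)
        # all windows agree to floating point for a stationary material
        for k in range(3):
            col = series.g_abs[:, k]
            assert np.nanmax(col) - np.nanmin(col) < 1e-6 * np.nanmean(col)

    def test_independent_window_marking(self, default_geometry, huvec_gkv):
        from afsrheo.synthdata import SyntheticScenario, gen_mosc_experiment

        p = OscProtocol(duration=1600.0)
        scen = SyntheticScenario(seed=2, noise_z=0.0, n_beads=1, duration=1600.0,
                                 bead_g0_cv=0.0)
        trajs, conv, _ = gen_mosc_experiment(huvec_gkv, p, default_geometry, scen)
        series = sliding_window_series(trajs, conv, p, default_geometry)
        # starts at 0, 100, ..., 1100; independent = starts 0, 500, 1000
        assert series.independent.sum() == 3
        assert series.independent[0] and series.independent[5] and series.independent[10]

    def test_step_change_transition_support(self, default_geometry, huvec_gkv):
        """A stiffness step at t0 moves the series only in windows covering t0."""
        from afsrheo.synthdata import (
            StiffnessSchedule,
            SyntheticScenario,
            gen_mosc_experiment,
        )

        p = OscProtocol(duration=2000.0)
        t_step = 1000.0
        scen = SyntheticScenario(
            seed=3, noise_z=0.0, drift_rate=0.0, n_beads=1, duration=2000.0,
            bead_g0_cv=0.0,
            stiffness_schedule=StiffnessSchedule(breakpoints=(t_step,), factors=(1.0, 0.5)),
        )
        trajs, conv, _ = gen_mosc_experiment(huvec_gkv, p, default_geometry, scen)
        series = sliding_window_series(trajs, conv, p, default_geometry)
        g = series.g_abs[:, 0]
        starts = series.window_centers - 250.0
        before = starts + 500.0 <= t_step
        after = starts >= t_step
        # plateaus are flat; only straddling windows are transitional
        assert np.nanmax(g[before]) - np.nanmin(g[before]) < 1e-6 * np.nanmean(g[before])
        assert np.nanmax(g[after]) - np.nanmin(g[after]) < 1e-6 * np.nanmean(g[after])
        assert np.nanmean(g[after]) < 0.7 * np.nanmean(g[before])
        n_transition = int(np.sum(~before & ~after))
        assert n_transition <= int(500.0 / 100.0) + 1


class TestAggregation:
    def _series(self, g_per_bead):
        n_b = len(g_per_bead)
        g = np.array(g_per_bead, dtype=complex).reshape(n_b, 1, 1)
        from afsrheo.rheology import ModulusSpectrumSeries

        return ModulusSpectrumSeries(
            window_centers=np.array([250.0]),
            frequencies=np.array([0.5]),
            g_complex=g,
            valid=np.ones_like(g, dtype=bool),
            independent=np.array([True]),
        )

    def test_single_bead_passthrough(self):
        s = aggregate_beads(self._series([1000.0 + 500.0j]))
        assert s.g_storage[0, 0] == pytest.approx(1000.0)
        assert s.g_storage_sem[0, 0] == 0.0

    def test_identical_beads_zero_sem(self):
        s = aggregate_beads(self._series([1000.0 + 500.0j] * 4))
        assert s.g_storage_sem[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert s.g_loss_sem[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_two_bead_mean_and_sem(self):
        s = aggregate_beads(self._series([1000.0 + 0j, 3000.0 + 0j]))
        assert s.g_storage[0, 0] == pytest.approx(2000.0)
        assert s.g_storage_sem[0, 0] == pytest.approx(1000.0)

    def test_phase_in_passive_range(self):
        s = aggregate_beads(self._series([1000.0 + 500.0j, 1200.0 + 700.0j]))
        assert 0.0 <= s.delta[0, 0] <= math.pi / 2
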
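"""Membrane physics, driven-oscillator simulation, and frame rendering."""

import numpy as np
import pytest
from scipy import special

from vibrotrace.membrane_optics import (MembraneSpec, OpticalGeometry,
                                        bessel_j0_first_zero,
                                        fundamental_frequency, membrane_area,
                                        render_frames,
                                        simulate_spot_trajectory,
                                        surface_density,
                                        tension_from_resonance)
from vibrotrace.sonify import AudioWaveform


class TestClosedFormPhysics:
    def test_worked_example_reproduces_printed_values(self):
        spec = MembraneSpec.from_resonance(a=0.04, m=0.002, f01=187.0)
        assert float(f"{spec.area:.3g}") == 5.03e-3
        assert float(f"{spec.sigma:.3g}") == 0.398
        assert abs(spec.T - 152.0) < 0.5

    def test_area_scaling(self):
        assert membrane_area(1.0) == pytest.approx(np.pi)
        assert membrane_area(0.5) == pytest.approx(np.pi / 4)
        with pytest.raises(ValueError):
            membrane_area(0.0)

    def test_surface_density_linearity(self):
        assert surface_density(3.0, 3.0) == 1.0
        assert surface_density(0.004, 5e-3) == 2 * surface_density(0.002, 5e-3)
        with pytest.raises(ValueError):
            surface_density(-1.0, 1.0)

    def test_bessel_zero(self):
        x = bessel_j0_first_zero()
        assert round(x, 4) == 2.4048
        assert abs(special.j0(x)) < 1e-10
        assert 2.0 < x < 3.0
        # cross-check against the library's dedicated zero finder
        assert abs(x - special.jn_zeros(0, 1)[0]) < 1e-10

    def test_tension_frequency_round_trip_on_log_grid(self):
        for a in np.logspace(-2, -0.5, 5):
            for m in np.logspace(-4, -2, 5):
                for f in np.logspace(1, 3, 5):
                    spec = MembraneSpec(a=a, m=m, f01=f)
                    assert abs(fundamental_frequency(spec) - f) < 1e-9 * f

    def test_square_and_sqrt_laws(self):
        base = MembraneSpec(a=0.04, m=0.002, f01=100.0)
        quad = MembraneSpec(a=0.04, m=0.002, f01=400.0)
        assert quad.T == pytest.approx(16 * base.T)
        t4 = MembraneSpec(a=0.04, m=0.002, T=4 * base.T)
        assert t4.f01 == pytest.approx(2 * base.f01)
        # doubling the radius at fixed T and sigma halves f01
        big = MembraneSpec(a=0.08, m=0.002 * 4, T=base.T)
        assert big.f01 == pytest.approx(base.f01 / 2)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            MembraneSpec(a=0.04, m=0.002, T=152.0, f01=50.0)
        with pytest.raises(ValueError):
            tension_from_resonance(-5.0, MembraneSpec())


def _spec(q=50.0):
    return MembraneSpec.from_resonance(f01=187.0, q_factor=q)


class TestSpotTrajectory:
    def test_silent_audio_stays_at_rest_spot(self):
        geom = OpticalGeometry(rest_spot=(0.05, -0.1))
        audio = AudioWaveform(samples=np.zeros(4410))
        traj = simulate_spot_trajectory(audio, _spec(), geom)
        assert np.allclose(traj.x, 0.05) and np.allclose(traj.y, -0.1)
        assert not traj.clipped.any()

    def test_resonant_steady_state_matches_closed_form(self):
        fs = 44100
        f01, q, kappa = 187.0, 50.0, 1.0
        t = np.arange(int(2.0 * fs)) / fs
        drive = 0.5 * np.sin(2 * np.pi * f01 * t)
        geom = OpticalGeometry()
        # tiny gain keeps tan() in its linear regime for readout
        traj = simulate_spot_trajectory(
            AudioWaveform(samples=drive), _spec(q), geom, gain=1e-3,
            axis_delay=0.0)
        w0 = 2 * np.pi * f01
        u_expected = 0.5 * kappa * q / w0**2
        stretch = 1 / np.cos(np.deg2rad(geom.incidence_angle))
        x_expected = geom.mirror_to_screen * 2 * 1e-3 * u_expected * stretch
        x_measured = np.max(np.abs(traj.x[int(1.5 * fs):]))
        assert abs(x_measured - x_expected) / x_expected < 0.01

    def test_linearity_in_drive_amplitude(self):
        fs = 44100
        t = np.arange(fs) / fs
        drive = 0.2 * np.sin(2 * np.pi * 30 * t)
        geom = OpticalGeometry()
        a = simulate_spot_trajectory(AudioWaveform(samples=drive), _spec(),
                                     geom, gain=1e-3, axis_delay=0.0)
        b = simulate_spot_trajectory(AudioWaveform(samples=2 * drive),
                                     _spec(), geom, gain=1e-3, axis_delay=0.0)
        tail = slice(fs // 2, None)
        ratio = np.max(np.abs(b.x[tail])) / np.max(np.abs(a.x[tail]))
        assert abs(ratio - 2.0) < 0.01

    def test_resonance_amplifies_at_least_tenfold(self):
        fs = 44100
        t = np.arange(2 * fs) / fs
        geom = OpticalGeometry()
        def excursion(f):
            drive = 0.1 * np.sin(2 * np.pi * f * t)
            tr = simulate_spot_trajectory(AudioWaveform(samples=drive),
                                          _spec(q=50), geom, gain=1e-3,
                                          axis_delay=0.0)
            return np.max(np.abs(tr.x[fs:]))
        assert excursion(187.0) >= 10 * excursion(4 * 187.0)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            simulate_spot_trajectory(AudioWaveform(samples=np.empty(0)),
                                     _spec(), OpticalGeometry())

    def test_clipping_flagged_and_clamped(self):
        fs = 44100
        t = np.arange(fs) / fs
        drive = 0.99 * np.sin(2 * np.pi * 5 * t)
        geom = OpticalGeometry()
        traj = simulate_spot_trajectory(AudioWaveform(samples=drive), _spec(),
                                        geom, gain=5e6)
        assert traj.clipped.any()
        assert np.max(np.abs(traj.x)) <= geom.screen_width / 2 + 1e-12
        assert np.max(np.abs(traj.y)) <= geom.screen_height / 2 + 1e-12


def _circle_traj(fs=44100, duration=1.0, radius=0.08, hz=40.0):
    t = np.arange(int(duration * fs)) / fs
    from vibrotrace.membrane_optics import SpotTrajectory
    return SpotTrajectory(t=t, x=radius * np.cos(2 * np.pi * hz * t),
                          y=radius * np.sin(2 * np.pi * hz * t),
                          clipped=np.zeros(len(t), bool))


class TestRenderFrames:
    def test_stationary_spot_centroid_within_half_pixel(self):
        from vibrotrace.membrane_optics import SpotTrajectory
        n = 4410
        t = np.arange(n) / 44100
        traj = SpotTrajectory(t=t, x=np.full(n, 0.05), y=np.full(n, -0.1),
                              clipped=np.zeros(n, bool))
        geom = OpticalGeometry()
        seq = render_frames(traj, geom, fps=10, resolution=(180, 120),
                            noise_sigma=0.0, black_level=0.0,
                            intensity_scale=1.0)
        f = seq.frames[0].astype(float)
        rows, cols = np.indices(f.shape)
        cy = (rows * f).sum() / f.sum()
        cx = (cols * f).sum() / f.sum()
        exp_col = (0.05 + 0.2) / 0.4 * 120
        exp_row = (0.3 - (-0.1)) / 0.6 * 180
        assert abs(cx - exp_col) < 0.5 and abs(cy - exp_row) < 0.5

    def test_constant_speed_energy_constant_within_2pct(self):
        seq = render_frames(_circle_traj(duration=1.0), OpticalGeometry(),
                            fps=10, resolution=(180, 120), noise_sigma=0.0,
                            black_level=0.0, intensity_scale=1.0)
        sums = seq.frames.reshape(len(seq), -1).astype(float).sum(axis=1)
        assert sums.max() / sums.min() < 1.02

    def test_fast_circle_renders_annulus(self):
        geom = OpticalGeometry()
        psf = 1.5
        seq = render_frames(_circle_traj(hz=60.0), geom, fps=10,
                            resolution=(180, 120), psf_sigma=psf,
                            noise_sigma=0.0, black_level=0.0,
                            intensity_scale=40.0)
        f = seq.frames[0]
        rows, cols = np.nonzero(f > 25)
        cx, cy = (0.2 / 0.4) * 120, (0.3 / 0.6) * 180
        r_px = 0.08 / 0.4 * 120  # pixels are isotropic at this resolution
        d = np.hypot(cols - cx, rows - cy)
        assert np.all(d >= r_px - 3 * psf - 1)
        assert np.all(d <= r_px + 3 * psf + 1)

    def test_deterministic_given_seed(self):
        traj = _circle_traj(duration=0.5)
        a = render_frames(traj, OpticalGeometry(), noise_sigma=2.0, seed=9)
        b = render_frames(traj, OpticalGeometry(), noise_sigma=2.0, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            render_frames(_circle_traj(duration=0.05), OpticalGeometry(),
                          fps=10)

    def test_exposure_cannot_exceed_frame_interval(self):
        with pytest.raises(ValueError):
            render_frames(_circle_traj(), OpticalGeometry(), fps=10,
                          exposure=0.2)
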
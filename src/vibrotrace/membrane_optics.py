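"""Physics of the speaker-membrane-mirror-laser-screen apparatus.

A circular membrane of radius ``a`` and mass ``m`` (surface density
sigma = m / (pi a^2)) under tension T has fundamental axisymmetric mode
(0,1) at

    f01 = (c01 / (2 pi a)) * sqrt(T / sigma),

with c01 the first zero of the Bessel function J0. Measuring f01
acoustically therefore yields the tension T = sigma (2 pi a f01 / c01)^2.

The simulator stands in for the physical rig: audio pressure drives the
fundamental mode as a damped harmonic oscillator, the mirror glued to the
membrane tilts in proportion to the modal displacement, and the reflected
laser spot is traced on a screen and rendered into camera-style frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, special

from .frameproc import FrameSequence
from .sonify import AudioWaveform

__all__ = [
    "MembraneSpec",
    "OpticalGeometry",
    "SpotTrajectory",
    "membrane_area",
    "surface_density",
    "bessel_j0_first_zero",
    "tension_from_resonance",
    "fundamental_frequency",
    "simulate_spot_trajectory",
    "render_frames",
]


def membrane_area(a: float) -> float:
    """Area of a circular membrane of radius ``a`` (m): pi a^2."""
    if a <= 0:
        raise ValueError("radius must be positive")
    return np.pi * a * a


def surface_density(m: float, A: float) -> float:
    """Surface density sigma = m / A in kg/m^2."""
    if m <= 0 or A <= 0:
        raise ValueError("mass and area must be positive")
    return m / A


def bessel_j0_first_zero() -> float:
    """First positive zero of J0, by bracketed root finding on (2, 3)."""
    return float(optimize.brentq(special.j0, 2.0, 3.0, xtol=1e-14))


#: c01 = 2.40482555769577... (first zero of J0)
C01 = bessel_j0_first_zero()


@dataclass
class MembraneSpec:
    """Physical parameters of the membrane; derived fields auto-filled.

    Provide radius ``a`` and mass ``m`` plus either the tension ``T`` or
    the measured fundamental resonance ``f01``; the missing one is
    derived from the mode-(0,1) relation.
    """

    a: float = 0.04          # radius, m
    m: float = 0.002         # mass, kg
    sigma: float | None = None   # surface density, kg/m^2
    T: float | None = None       # tension, N/m
    f01: float | None = None     # fundamental resonance, Hz
    c01: float = C01
    q_factor: float = 50.0   # modal quality factor (simulator only)

    def __post_init__(self):
        if self.a <= 0 or self.m <= 0:
            raise ValueError("radius and mass must be positive")
        A = membrane_area(self.a)
        sigma = surface_density(self.m, A)
        if self.sigma is None:
            self.sigma = sigma
        elif abs(self.sigma - sigma) > 1e-9 * sigma:
            raise ValueError("sigma inconsistent with m / (pi a^2)")
        if self.T is None and self.f01 is not None:
            self.T = tension_from_resonance(self.f01, self)
        elif self.f01 is None and self.T is not None:
            self.f01 = fundamental_frequency(self)
        elif self.T is not None and self.f01 is not None:
            f_check = fundamental_frequency(self)
            if abs(self.f01 - f_check) > 1e-9 * f_check:
                raise ValueError("f01 inconsistent with T, sigma, a")
        if self.q_factor <= 0:
            raise ValueError("q_factor must be positive")

    @property
    def area(self) -> float:
        return membrane_area(self.a)

    @classmethod
    def from_resonance(cls, a: float = 0.04, m: float = 0.002,
                       f01: float = 187.0, q_factor: float = 50.0):
        """Build a spec from a measured fundamental resonance."""
        return cls(a=a, m=m, f01=f01, q_factor=q_factor)


def tension_from_resonance(f01: float, spec: MembraneSpec) -> float:
    """T = sigma (2 pi a f01 / c01)^2, in N/m."""
    if f01 <= 0:
        raise ValueError("resonance frequency must be positive")
    sigma = spec.sigma if spec.sigma is not None else spec.m / membrane_area(spec.a)
    return sigma * (2.0 * np.pi * spec.a * f01 / spec.c01) ** 2


def fundamental_frequency(spec: MembraneSpec) -> float:
    """f01 = (c01 / (2 pi a)) sqrt(T / sigma), in Hz."""
    if spec.T is None or spec.T <= 0:
        raise ValueError("spec.T must be a positive tension")
    sigma = spec.sigma if spec.sigma is not None else spec.m / membrane_area(spec.a)
    return spec.c01 / (2.0 * np.pi * spec.a) * np.sqrt(spec.T / sigma)


@dataclass
class OpticalGeometry:
    """Mirror / laser / screen layout."""

    incidence_angle: float = 30.0   # degrees
    screen_width: float = 0.40      # m
    screen_height: float = 0.60     # m
    mirror_diameter: float = 0.025  # m
    laser_wavelength: float = 650.0  # nm, metadata only
    mirror_to_screen: float = 0.50  # m
    rest_spot: tuple = (0.0, 0.0)   # screen coords, m, origin at center

    def __post_init__(self):
        if self.screen_width <= 0 or self.screen_height <= 0:
            raise ValueError("screen dimensions must be positive")
        if not 0 < self.incidence_angle < 90:
            raise ValueError("incidence angle must lie in (0, 90) degrees")
        if self.mirror_to_screen <= 0:
            raise ValueError("mirror_to_screen must be positive")


@dataclass
class SpotTrajectory:
    """Laser-spot path on the screen (meters, origin at screen center)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    clipped: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.clipped = np.asarray(self.clipped, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.clipped) == n):
            raise ValueError("t, x, y, clipped must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


def _modal_response(p: np.ndarray, fs: float, f01: float, q: float,
                    kappa: float) -> np.ndarray:
    """Displacement of the driven damped fundamental mode.

    Integrates  u'' + (w01/Q) u' + w01^2 u = kappa p(t)  by exact
    zero-order-hold discretization of the transfer function
    kappa / (s^2 + (w01/Q) s + w01^2) at the audio rate.
    """
    w = 2.0 * np.pi * f01
    numd, dend, _ = signal.cont2discrete(([kappa], [1.0, w / q, w * w]),
                                         1.0 / fs, method="zoh")
    return signal.lfilter(np.atleast_1d(numd.squeeze()), dend, p)


def simulate_spot_trajectory(audio: AudioWaveform, spec: MembraneSpec,
                             geom: OpticalGeometry, gain: float = 5.5e5,
                             kappa: float = 1.0,
                             axis_delay: float = 0.0025) -> SpotTrajectory:
    """Trace the laser spot driven by an audio waveform.

    The fundamental mode's displacement u(t) follows a driven damped
    harmonic oscillator at resonance ``spec.f01`` with quality factor
    ``spec.q_factor`` and drive coupling ``kappa`` (modal force per unit
    audio amplitude). The mirror tilts by ``gain * u`` radians about two
    orthogonal axes; the second axis is driven by a copy of the audio
    delayed by ``axis_delay`` seconds (0 disables it), so oscillatory
    drives trace Lissajous-like 2-D figures instead of a line. A mirror
    tilt theta deflects the reflected beam by 2 theta; the screen offset
    is mirror_to_screen * tan(2 theta) per axis, with the horizontal axis
    stretched by 1 / cos(incidence) for the oblique screen. The spot is
    clamped to the screen and flagged ``clipped`` where it left it.
    """
    p = np.asarray(audio.samples, dtype=np.float64)
    if p.size == 0:
        raise ValueError("audio is empty")
    if spec.f01 is None:
        raise ValueError("membrane spec lacks a fundamental frequency")
    fs = float(audio.fs_audio)
    ux = _modal_response(p, fs, spec.f01, spec.q_factor, kappa)
    if axis_delay > 0:
        d = int(round(axis_delay * fs))
        pd = np.concatenate([np.zeros(d), p[:len(p) - d]]) if d else p
        uy = _modal_response(pd, fs, spec.f01, spec.q_factor, kappa)
    else:
        uy = np.zeros_like(ux)

    stretch = 1.0 / np.cos(np.deg2rad(geom.incidence_angle))
    L = geom.mirror_to_screen
    x = geom.rest_spot[0] + L * np.tan(2.0 * gain * ux) * stretch
    y = geom.rest_spot[1] + L * np.tan(2.0 * gain * uy)

    hw, hh = geom.screen_width / 2.0, geom.screen_height / 2.0
    clipped = (np.abs(x) > hw) | (np.abs(y) > hh)
    x = np.clip(x, -hw, hw)
    y = np.clip(y, -hh, hh)
    t = np.arange(len(p)) / fs
    return SpotTrajectory(t=t, x=x, y=y, clipped=clipped)


def render_frames(traj: SpotTrajectory, geom: OpticalGeometry,
                  fps: float = 10.0, resolution: tuple = (180, 120),
                  psf_sigma: float = 1.2, exposure: float | None = None,
                  noise_sigma: float = 0.0, black_level: float = 8.0,
                  intensity_scale: float = 40.0, texture_sigma: float = 0.0,
                  seed: int = 0) -> FrameSequence:
    """Integrate the spot trajectory into camera-style grayscale frames.

    Each frame accumulates the trajectory samples falling inside its
    exposure window (default: full-frame, 1/fps) onto a (height, width)
    pixel grid covering the screen and convolves with a Gaussian point-
    spread function of ``psf_sigma`` px. Intensity uses a fixed camera
    response — ``black_level`` pedestal plus ``intensity_scale`` counts
    of intensity per accumulated trajectory sample, saturating at 255 —
    like a sensor at fixed exposure/ISO: slow (dwelling) spots render
    bright and saturated, fast sweeps render dimmer, and the mapping is
    identical for every sequence rather than renormalized per run.
    The pedestal mimics the sensor's nonzero output on an unlit matte
    screen and keeps background noise symmetric instead of half-
    rectified at zero. Optional Gaussian sensor noise is added last,
    clamped to [0, 255]. Deterministic given ``seed``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if exposure is None:
        exposure = 1.0 / fps
    if exposure > 1.0 / fps + 1e-12:
        raise ValueError("exposure cannot exceed the frame interval")
    h_px, w_px = resolution
    duration = traj.t[-1] - traj.t[0] + (traj.t[1] - traj.t[0] if len(traj.t) > 1 else 0)
    n_frames = int(np.floor(duration * fps + 1e-9))
    if n_frames < 1:
        raise ValueError("trajectory shorter than one frame")

    # screen coords -> pixel indices (row 0 = top = +y)
    col = (traj.x + geom.screen_width / 2.0) / geom.screen_width * w_px
    row = (geom.screen_height / 2.0 - traj.y) / geom.screen_height * h_px
    col = np.clip(col.astype(np.int64), 0, w_px - 1)
    row = np.clip(row.astype(np.int64), 0, h_px - 1)

    fs_traj = traj.fs
    t_rel = traj.t - traj.t[0]
    acc = np.zeros((n_frames, h_px, w_px), dtype=np.float32)
    for k in range(n_frames):
        t_start = k / fps
        i0 = int(np.ceil(t_start * fs_traj - 1e-9))
        i1 = min(int(np.ceil((t_start + exposure) * fs_traj - 1e-9)),
                 len(t_rel))
        if i1 <= i0:
            i1 = min(i0 + 1, len(t_rel))  # collapse: at least one sample
        hist = np.zeros((h_px, w_px), dtype=np.float32)
        np.add.at(hist, (row[i0:i1], col[i0:i1]), 1.0)
        acc[k] = ndimage.gaussian_filter(hist, psf_sigma, mode="constant")

    acc *= intensity_scale
    acc += black_level
    if texture_sigma > 0:
        # static screen grain / fixed-pattern sensor response: a property
        # of the apparatus, so its seed is a constant, not a run parameter
        tex_rng = np.random.default_rng(101)
        acc += tex_rng.normal(0.0, texture_sigma,
                              (h_px, w_px)).astype(np.float32)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        acc = acc + rng.normal(0.0, noise_sigma, acc.shape).astype(np.float32)
    frames = np.clip(np.round(acc), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=fps, t0=float(traj.t[0]),
                         source_id="simulated")
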
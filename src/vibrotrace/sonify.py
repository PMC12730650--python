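"""Direct-mapping sonification of EEG into 16-bit PCM audio.

EEG amplitude is mapped linearly to sound pressure: channels are mixed to
one mono series, band-limited-resampled onto the 44.1 kHz audio grid
(optionally time-compressed), peak-normalized to prevent clipping, and
quantized to 16-bit PCM WAV. No frequency modulation or other spectral
transformation is applied, so the waveform's temporal morphology is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .eeg_core import EEGRecording

__all__ = [
    "AudioWaveform",
    "mix_channels",
    "normalize_amplitude",
    "resample_to_audio",
    "write_wav",
    "read_wav",
    "sonify_eeg",
]

AUDIO_FS_DEFAULT = 44100


@dataclass
class AudioWaveform:
    """Mono audio in [-1, 1] at an audio sampling rate."""

    samples: np.ndarray
    fs_audio: int = AUDIO_FS_DEFAULT
    bit_depth: int = 16

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs_audio <= 0:
            raise ValueError("audio sampling rate must be positive")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("audio samples must lie within [-1, 1]")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs_audio


def mix_channels(eeg: EEGRecording, mode: str = "mean",
                 channel: str | None = None) -> np.ndarray:
    """Collapse a multichannel recording to one mono series.

    ``mode="mean"`` takes the per-sample arithmetic mean across channels;
    ``mode="single_channel"`` returns the named channel verbatim.
    """
    if eeg.n_samples == 0:
        raise ValueError("cannot mix an empty recording")
    if mode == "mean":
        return eeg.data.mean(axis=0)
    if mode == "single_channel":
        if channel is None:
            raise ValueError("single_channel mode requires a channel label")
        return eeg.channel(channel).copy()
    raise ValueError(f"unknown mix mode {mode!r}")


def normalize_amplitude(series, headroom: float = 0.99) -> np.ndarray:
    """Scale a series so its peak magnitude equals ``headroom``.

    All-zero input is returned unchanged. Idempotent up to floating point.
    """
    if not 0 < headroom <= 1:
        raise ValueError("headroom must lie in (0, 1]")
    series = np.asarray(series, dtype=np.float64)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    peak = np.max(np.abs(series), initial=0.0)
    if peak == 0:
        return series.copy()
    return series * (headroom / peak)


def loudness_normalize(series, target_rms: float = 0.25,
                       limit: float = 0.99) -> np.ndarray:
    """Scale a series to a fixed RMS level, hard-limiting rare peaks.

    Unlike peak normalization, RMS normalization pins the *typical*
    amplitude of every rendering to the same level, so two recordings of
    the same process land on identical excursion scales instead of
    inheriting the run-to-run fluctuation of the sample maximum. Samples
    beyond ``limit`` after scaling (a few per million at the default
    level) are clipped to the limit, keeping the output saturation-free.
    """
    if target_rms <= 0 or not 0 < limit <= 1:
        raise ValueError("target_rms must be positive and limit in (0, 1]")
    series = np.asarray(series, dtype=np.float64)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    rms = np.sqrt(np.mean(series ** 2)) if series.size else 0.0
    if rms == 0:
        return series.copy()
    return np.clip(series * (target_rms / rms), -limit, limit)


def resample_to_audio(series, fs_in: float, fs_audio: int = AUDIO_FS_DEFAULT,
                      time_scale: float = 1.0) -> AudioWaveform:
    """Band-limited resampling of a mono series onto the audio grid.

    ``time_scale`` compresses the time base: the output lasts
    ``len(series)/fs_in/time_scale`` seconds, so a factor of 2 plays the
    signal twice as fast (all frequencies doubled). Polyphase filtering
    prevents aliasing; the result is peak-normalized to |x| <= 0.99
    because interpolation can overshoot the input extremes.
    """
    if fs_in <= 0:
        raise ValueError("input sampling rate must be positive")
    if time_scale <= 0:
        raise ValueError("time_scale must be positive")
    series = np.asarray(series, dtype=np.float64).ravel()
    ratio = Fraction(fs_audio) / Fraction(fs_in * time_scale).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    n_out = int(len(series) * up / down)
    if n_out < 2:
        raise ValueError("resampled output would be shorter than 2 samples")
    out = signal.resample_poly(series, up, down)
    peak = np.max(np.abs(out), initial=0.0)
    if peak > 0.99:
        out = out * (0.99 / peak)
    return AudioWaveform(samples=out, fs_audio=fs_audio)


def write_wav(w: AudioWaveform, path) -> None:
    """Write 16-bit PCM mono little-endian WAV."""
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    try:
        wavfile.write(path, w.fs_audio, pcm)
    except OSError as exc:
        raise OSError(f"cannot write WAV file {path}: {exc}") from exc


def read_wav(path) -> AudioWaveform:
    """Read a 16-bit PCM WAV back into [-1, 1] floats."""
    fs, pcm = wavfile.read(path)
    if pcm.ndim > 1:
        pcm = pcm[:, 0]
    if pcm.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got dtype {pcm.dtype}")
    return AudioWaveform(samples=pcm.astype(np.float64) / 32767.0, fs_audio=int(fs))


def sonify_eeg(eeg: EEGRecording, mode: str = "mean", channel: str | None = None,
               time_scale: float = 2.7, fs_audio: int = AUDIO_FS_DEFAULT,
               headroom: float = 0.99, level: str = "rms",
               target_rms: float = 0.25) -> AudioWaveform:
    """Full sonification chain: mix -> resample -> level-normalize.

    ``level="rms"`` (default) sets a fixed RMS of ``target_rms`` with a
    hard limiter at ``headroom``; ``level="peak"`` scales the maximum to
    ``headroom``. Both keep every sample inside the PCM dynamic range.
    The default ``time_scale`` of 2.7 maps a ~13.5 min recording onto
    ~5 min of audio; set 1.0 for a real-time mapping.
    """
    mono = mix_channels(eeg, mode=mode, channel=channel)
    wave = resample_to_audio(mono, fs_in=eeg.fs, fs_audio=fs_audio,
                             time_scale=time_scale)
    if level == "rms":
        out = loudness_normalize(wave.samples, target_rms, headroom)
    elif level == "peak":
        out = normalize_amplitude(wave.samples, headroom)
    else:
        raise ValueError(f"unknown level mode {level!r}")
    return AudioWaveform(samples=out, fs_audio=wave.fs_audio)
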
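"""End-to-end orchestration: synthetic EEG -> sonification -> membrane
simulation -> frame processing -> descriptors -> classification.

A :class:`PipelineConfig` holds one parameter block per stage, all
defaulting to the published processing settings (31 px window / C = 2 /
3x3 elliptical opening / 10 fps / 275 s analysis window / noise sigma 5 /
100-tree gini forest seeded at 42). Every random stage derives its seed
from the single global seed, so identical configs reproduce identical
feature tables and reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import classify, descriptors, eeg_core, frameproc, membrane_optics, sonify

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "validate_config",
    "run_all",
    "run_group",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists all violations."""


@dataclass
class EEGBlock:
    n_subjects_ad: int = 36
    n_subjects_nc: int = 29
    n_channels: int = 19
    fs: float = 500.0
    profile_ad: str = "ad"   # spectral profile driving the AD group
    profile_nc: str = "nc"

    def check(self, errs):
        if self.n_subjects_ad < 1 or self.n_subjects_nc < 1:
            errs.append("eeg.n_subjects_*: need at least 1 subject per group")
        if self.n_channels < 1:
            errs.append("eeg.n_channels: must be >= 1")
        if self.fs <= 0:
            errs.append("eeg.fs: must be positive")
        for key in ("profile_ad", "profile_nc"):
            if getattr(self, key) not in ("ad", "nc"):
                errs.append(f"eeg.{key}: must be 'ad' or 'nc'")


@dataclass
class SonifyBlock:
    time_scale: float = 2.7
    fs_audio: int = 44100
    headroom: float = 0.99
    mix: str = "mean"

    def check(self, errs):
        if self.time_scale <= 0:
            errs.append("sonify.time_scale: must be positive")
        if self.fs_audio <= 0:
            errs.append("sonify.fs_audio: must be positive")
        if not 0 < self.headroom <= 1:
            errs.append("sonify.headroom: must lie in (0, 1]")


@dataclass
class MembraneBlock:
    a: float = 0.04
    m: float = 0.002
    f01: float = 187.0
    q_factor: float = 50.0
    gain: float = 5.5e5
    kappa: float = 1.0
    axis_delay: float = 0.0025

    def check(self, errs):
        for key in ("a", "m", "f01", "q_factor"):
            if getattr(self, key) <= 0:
                errs.append(f"membrane.{key}: must be positive")


@dataclass
class RenderBlock:
    fps: float = 10.0
    resolution: tuple = (180, 120)   # (height, width) px
    psf_sigma: float = 1.2
    camera_noise_sigma: float = 1.0
    black_level: float = 8.0
    intensity_scale: float = 40.0

    def check(self, errs):
        if self.fps <= 0:
            errs.append("render.fps: must be positive")
        if len(self.resolution) != 2 or min(self.resolution) < 8:
            errs.append("render.resolution: need (height, width) >= 8 px")


@dataclass
class FrameprocBlock:
    window: int = 31
    C: float = 2.0
    weighting: str = "gaussian"
    noise_sigma: float = 5.0
    mask_phase: str = "bright"
    mask_on_clean: bool = True
    trim_start_ad: float = 12.0
    trim_start_nc: float = 0.0
    trim_duration: float = 275.0

    def check(self, errs):
        if self.window < 3 or self.window % 2 == 0:
            errs.append("frameproc.window: must be an odd integer >= 3")
        if self.weighting not in ("gaussian", "mean"):
            errs.append("frameproc.weighting: must be 'gaussian' or 'mean'")
        if self.mask_phase not in ("bright", "dark"):
            errs.append("frameproc.mask_phase: must be 'bright' or 'dark'")
        if self.noise_sigma < 0:
            errs.append("frameproc.noise_sigma: must be >= 0")
        if self.trim_start_ad < 0 or self.trim_start_nc < 0:
            errs.append("frameproc.trim_start_*: must be >= 0")
        if self.trim_duration <= 0:
            errs.append("frameproc.trim_duration: must be positive")


@dataclass
class ClassifyBlock:
    test_fraction: float = 0.20
    k: int = 5
    mode: str = "paper"
    n_estimators: int = 100
    random_state: int = 42

    def check(self, errs):
        if not 0 < self.test_fraction < 1:
            errs.append("classify.test_fraction: must lie in (0, 1)")
        if self.k < 2:
            errs.append("classify.k: must be >= 2")
        if self.mode not in ("paper", "grouped"):
            errs.append("classify.mode: must be 'paper' or 'grouped'")

    def rf_config(self) -> classify.RFConfig:
        return classify.RFConfig(n_estimators=self.n_estimators,
                                 random_state=self.random_state)


@dataclass
class PipelineConfig:
    """Global settings plus one block per stage."""

    seed: int = 0
    duration: float = 290.0   # per-group audio/video duration, s
    save_intermediates: bool = False
    eeg: EEGBlock = field(default_factory=EEGBlock)
    sonify: SonifyBlock = field(default_factory=SonifyBlock)
    membrane: MembraneBlock = field(default_factory=MembraneBlock)
    render: RenderBlock = field(default_factory=RenderBlock)
    frameproc: FrameprocBlock = field(default_factory=FrameprocBlock)
    classify: ClassifyBlock = field(default_factory=ClassifyBlock)

    def check(self):
        errs = []
        if self.duration <= 0:
            errs.append("duration: must be positive")
        if not 0 <= self.seed < 2**31:
            errs.append("seed: must lie in [0, 2^31)")
        for block in (self.eeg, self.sonify, self.membrane, self.render,
                      self.frameproc, self.classify):
            block.check(errs)
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        block_names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        errs = []
        for key, val in d.items():
            if key not in block_names:
                errs.append(f"unknown key {key!r}")
                continue
            if isinstance(val, dict):
                block_cls = type(getattr(cls(), key))
                valid_names = {bf.name for bf in dataclasses.fields(block_cls)}
                unknown = set(val) - valid_names
                for u in sorted(unknown):
                    errs.append(f"unknown key {key}.{u}")
                clean = {k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in val.items() if k in valid_names}
                kwargs[key] = block_cls(**clean)
            else:
                kwargs[key] = val
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
        return cls(**kwargs).check()


def validate_config(path) -> PipelineConfig:
    """Load and validate a TOML configuration file."""
    import tomllib

    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    return PipelineConfig.from_dict(data)


def _subseed(seed: int, tag: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    return (seed * 1000003 + zlib.crc32(tag.encode())) % (2**31)


def _profile(name: str, seed: int):
    return eeg_core.ad_profile(seed) if name == "ad" else eeg_core.nc_profile(seed)


def run_group(cfg: PipelineConfig, group: str):
    """Run one group's chain; returns (feature table, stage manifest).

    ``group`` is ``"AD"`` or ``"NC"``. The analysis trim window is
    applied when the rendered sequence is long enough to contain it;
    otherwise the full sequence is analyzed (logged).
    """
    if group not in ("AD", "NC"):
        raise ValueError("group must be 'AD' or 'NC'")
    label = "Alzheimer" if group == "AD" else "Control"
    n_subj = cfg.eeg.n_subjects_ad if group == "AD" else cfg.eeg.n_subjects_nc
    prof_name = cfg.eeg.profile_ad if group == "AD" else cfg.eeg.profile_nc
    eeg_duration = cfg.duration * cfg.sonify.time_scale

    recs = [
        eeg_core.synth_eeg(
            _profile(prof_name, _subseed(cfg.seed, f"{group}-subj{i}")),
            n_channels=cfg.eeg.n_channels, duration=eeg_duration,
            fs=cfg.eeg.fs, subject_id=f"{group}-{i:02d}", group_label=group)
        for i in range(n_subj)
    ]
    avg = eeg_core.group_average(recs)
    del recs

    wave = sonify.sonify_eeg(avg, mode=cfg.sonify.mix,
                             time_scale=cfg.sonify.time_scale,
                             fs_audio=cfg.sonify.fs_audio,
                             headroom=cfg.sonify.headroom)

    spec = membrane_optics.MembraneSpec.from_resonance(
        a=cfg.membrane.a, m=cfg.membrane.m, f01=cfg.membrane.f01,
        q_factor=cfg.membrane.q_factor)
    geom = membrane_optics.OpticalGeometry()
    traj = membrane_optics.simulate_spot_trajectory(
        wave, spec, geom, gain=cfg.membrane.gain, kappa=cfg.membrane.kappa,
        axis_delay=cfg.membrane.axis_delay)
    seq = membrane_optics.render_frames(
        traj, geom, fps=cfg.render.fps, resolution=cfg.render.resolution,
        psf_sigma=cfg.render.psf_sigma,
        noise_sigma=cfg.render.camera_noise_sigma,
        black_level=cfg.render.black_level,
        intensity_scale=cfg.render.intensity_scale,
        seed=_subseed(cfg.seed, f"{group}-camera"))
    rendered_count = len(seq)

    offset = (cfg.frameproc.trim_start_ad if group == "AD"
              else cfg.frameproc.trim_start_nc)
    want = offset + cfg.frameproc.trim_duration
    if seq.duration >= want:
        seq = frameproc.trim_window(seq, offset, cfg.frameproc.trim_duration)
    else:
        logger.info("%s: sequence (%.1f s) shorter than trim window "
                    "(%.1f s); analyzing full sequence", group,
                    seq.duration, want)

    masked = frameproc.process_sequence(
        seq, window=cfg.frameproc.window, C=cfg.frameproc.C,
        weighting=cfg.frameproc.weighting,
        noise_sigma=cfg.frameproc.noise_sigma,
        mask_phase=cfg.frameproc.mask_phase,
        mask_on_clean=cfg.frameproc.mask_on_clean,
        seed=_subseed(cfg.seed, f"{group}-noise"))
    table = descriptors.features_table(masked, fps=seq.fps,
                                       group_label=label,
                                       source_id=f"{group}-run{cfg.seed}")
    manifest = {
        "group": group,
        "label": label,
        "profile": prof_name,
        "n_subjects": n_subj,
        "eeg_duration_s": eeg_duration,
        "audio_duration_s": wave.duration,
        "frame_count": rendered_count,
        "analyzed_frames": len(seq),
        "trim_offset_s": offset,
        "feature_checksum": int(zlib.crc32(
            table.to_csv(index=False).encode())),
    }
    return table, manifest


def run_all(cfg: PipelineConfig, out_dir=None):
    """Execute the full two-group pipeline.

    Returns ``(report, manifest, features)``: the evaluation report, a
    manifest recording every stage's parameters / seeds / checksums, and
    the combined per-frame feature table. If ``out_dir`` is given,
    ``features.csv``, ``report.json`` and ``manifest.json`` are written
    there (directory created if missing).
    """
    cfg.check()
    tables, manifests = {}, {}
    for group in ("AD", "NC"):
        try:
            table, man = run_group(cfg, group)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for group {group}: "
                               f"{exc}") from exc
        tables[man["label"]] = table
        manifests[group] = man

    try:
        report = classify.run_protocol(
            tables, config=cfg.classify.rf_config(), seed=cfg.seed or 42,
            test_fraction=cfg.classify.test_fraction, k=cfg.classify.k,
            mode=cfg.classify.mode)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed for classify: {exc}") from exc

    import pandas as pd
    features = pd.concat(tables.values(), ignore_index=True)
    manifest = {
        "config": asdict(cfg),
        "groups": manifests,
        "overall_accuracy": report.overall_accuracy,
        "auc": report.auc,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        features.to_csv(os.path.join(out_dir, "features.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return report, manifest, features
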
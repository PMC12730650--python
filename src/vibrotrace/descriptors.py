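"""Per-frame spatial descriptors and centroid-trajectory dynamics.

For each masked binary frame the pipeline computes:

* active area — number of white (255) pixels inside the envelope mask;
* spatial entropy — Shannon entropy (bits) of the binary pixel-intensity
  distribution, H = -sum_k p(k) log2 p(k) over k in {0, 255};
* fractal dimension — box-counting estimate: slope of log N(eps) versus
  log(1/eps) for grids of decreasing cell size eps;
* centroid — mean (x, y) of the white pixels;

and, across frames, the centroid trajectory with per-step and cumulative
Euclidean displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frameproc import MaskedFrame

__all__ = [
    "FrameDescriptors",
    "TrajectoryMetrics",
    "active_area",
    "spatial_entropy",
    "fractal_dimension",
    "default_box_sizes",
    "centroid",
    "frame_descriptors",
    "trajectory_metrics",
    "features_table",
    "FEATURE_COLUMNS",
]

#: Per-frame feature vector used for classification.
FEATURE_COLUMNS = ("active_area", "entropy", "fractal_dim",
                   "centroid_x", "centroid_y", "step_disp")


@dataclass
class FrameDescriptors:
    """Quantitative descriptors of one masked frame."""

    active_area: int
    entropy: float
    fractal_dim: float  # NaN when undefined (no foreground)
    centroid: tuple     # (x_c, y_c) in px; (nan, nan) when invalid
    valid: bool


@dataclass
class TrajectoryMetrics:
    """Centroid path across frames with step and cumulative displacement."""

    path: np.ndarray                 # (n_valid, 2) centroids, (x, y)
    step_displacements: np.ndarray   # (n_valid - 1,)
    cumulative_displacement: np.ndarray  # (n_valid - 1,) prefix sums
    valid_indices: np.ndarray        # original frame indices of path points


def _pixels_of(f) -> np.ndarray:
    return f.pixels if isinstance(f, MaskedFrame) else np.asarray(f)


def active_area(f) -> int:
    """Count of white (255) pixels."""
    return int(np.count_nonzero(_pixels_of(f) == 255))


def spatial_entropy(f) -> float:
    """Shannon entropy (bits) of the binary intensity distribution.

    For a binary image this is h2(p) with p the white-pixel fraction;
    0 for a degenerate frame, 1 bit at p = 0.5. 0 log 0 is taken as 0.
    """
    px = _pixels_of(f)
    if px.size == 0:
        raise ValueError("frame is empty")
    p = np.count_nonzero(px == 255) / px.size
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            h -= q * np.log2(q)
    return h


def default_box_sizes(shape) -> np.ndarray:
    """Powers of two from min(height, width)/2 down to 2 px, decreasing."""
    m = min(shape)
    sizes = []
    s = 2
    while s <= m // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        sizes = [1, 2][:max(2, len(sizes))]
    return np.array(sorted(sizes, reverse=True))


def _box_count(fg: np.ndarray, eps: int) -> int:
    """Number of eps x eps grid cells (anchored at the origin) containing
    at least one foreground pixel."""
    h, w = fg.shape
    ph = (-h) % eps
    pw = (-w) % eps
    if ph or pw:
        fg = np.pad(fg, ((0, ph), (0, pw)))
    H, W = fg.shape
    blocks = fg.reshape(H // eps, eps, W // eps, eps)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(f, box_sizes=None) -> float:
    """Box-counting fractal dimension of a binary raster.

    D is the least-squares slope of log N(eps) against log(1/eps) over
    all box sizes (no scaling-region pruning), clamped to [0, 2].
    Returns NaN for a frame with no foreground.
    """
    px = _pixels_of(f)
    if px.size == 0:
        raise ValueError("frame is empty")
    fg = px == 255 if px.dtype != bool else px
    if not fg.any():
        return float("nan")
    if box_sizes is None:
        box_sizes = default_box_sizes(fg.shape)
    box_sizes = np.asarray(box_sizes, dtype=int)
    if len(box_sizes) < 2:
        raise ValueError("need at least 2 box sizes")
    counts = np.array([_box_count(fg, int(e)) for e in box_sizes])
    slope = np.polyfit(np.log(1.0 / box_sizes), np.log(counts), 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def centroid(f) -> tuple:
    """Mean (x, y) of white pixels; (nan, nan) if there are none."""
    px = _pixels_of(f)
    rows, cols = np.nonzero(px == 255)
    if len(rows) == 0:
        return (float("nan"), float("nan"))
    return (float(cols.mean()), float(rows.mean()))


def frame_descriptors(f) -> FrameDescriptors:
    """All per-frame descriptors for one masked frame."""
    area = active_area(f)
    valid = area > 0 and (not isinstance(f, MaskedFrame) or f.valid)
    return FrameDescriptors(
        active_area=area,
        entropy=spatial_entropy(f),
        fractal_dim=fractal_dimension(f) if valid else float("nan"),
        centroid=centroid(f),
        valid=valid,
    )


def trajectory_metrics(descriptors) -> TrajectoryMetrics:
    """Reconstruct the centroid trajectory from an ordered descriptor list.

    Invalid frames (no white pixels) are skipped; their positions are
    recorded via ``valid_indices``.
    """
    idx = [i for i, d in enumerate(descriptors) if d.valid]
    if not idx:
        raise ValueError("no valid frames: empty trajectory")
    path = np.array([descriptors[i].centroid for i in idx], dtype=float)
    steps = (np.linalg.norm(np.diff(path, axis=0), axis=1)
             if len(path) > 1 else np.empty(0))
    return TrajectoryMetrics(
        path=path,
        step_displacements=steps,
        cumulative_displacement=np.cumsum(steps),
        valid_indices=np.array(idx),
    )


def features_table(masked_frames, fps: float, group_label: str,
                   source_id: str = "") -> pd.DataFrame:
    """Build the per-frame feature table for classification.

    One row per frame with the descriptor features plus the step
    displacement from the previous valid frame (0 for the first valid
    frame). Invalid frames get NaN features and ``valid=False``.
    """
    descs = [frame_descriptors(f) for f in masked_frames]
    rows = []
    prev_centroid = None
    for i, d in enumerate(descs):
        step = np.nan
        if d.valid:
            step = (0.0 if prev_centroid is None
                    else float(np.hypot(d.centroid[0] - prev_centroid[0],
                                        d.centroid[1] - prev_centroid[1])))
            prev_centroid = d.centroid
        rows.append({
            "frame_index": i,
            "time_s": i / fps,
            "group_label": group_label,
            "source_id": source_id,
            "active_area": d.active_area,
            "entropy": d.entropy,
            "fractal_dim": d.fractal_dim,
            "centroid_x": d.centroid[0],
            "centroid_y": d.centroid[1],
            "step_disp": step,
            "valid": d.valid,
        })
    return pd.DataFrame(rows)
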
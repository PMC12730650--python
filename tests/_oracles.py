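"""Brute-force reference implementations used as independent oracles.

Everything here is written as directly as possible from the set-theoretic
or arithmetic definition (explicit loops, flood fills), deliberately
sharing no code with the package implementations it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_threshold_mean(frame, window, C):
    """Per-pixel T = mean(window) - C with replicate padding, strict '>'."""
    frame = np.asarray(frame, dtype=np.int64)
    h, w = frame.shape
    r = window // 2
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            s = 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    s += frame[ii, jj]
            mu = s / float(window * window)
            out[i, j] = 255 if frame[i, j] > mu - C else 0
    return out


def brute_erode(fg, selem):
    """Set erosion; outside the image counts as background."""
    fg = np.asarray(fg, dtype=bool)
    h, w = fg.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(fg)
    for i in range(h):
        for j in range(w):
            keep = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not selem[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w) or not fg[ii, jj]:
                        keep = False
                        break
                if not keep:
                    break
            out[i, j] = keep
    return out


def brute_dilate(fg, selem):
    """Set dilation (symmetric element)."""
    fg = np.asarray(fg, dtype=bool)
    h, w = fg.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(fg)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not selem[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and fg[ii, jj]:
                        hit = True
                        break
                if hit:
                    break
            out[i, j] = hit
    return out


def brute_opening(fg, selem):
    return brute_dilate(brute_erode(fg, selem), selem)


def _components_8(mask):
    """8-connected components labelled in row-major first-found order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                lab = len(comps) + 1
                q = deque([(i, j)])
                labels[i, j] = lab
                cells = []
                while q:
                    a, b = q.popleft()
                    cells.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            aa, bb = a + da, b + db
                            if (0 <= aa < h and 0 <= bb < w
                                    and mask[aa, bb] and labels[aa, bb] == 0):
                                labels[aa, bb] = lab
                                q.append((aa, bb))
                comps.append(cells)
    return comps


def _fill_holes(cells, shape):
    """Component cells plus any enclosed holes (4-connected outside fill)."""
    comp = np.zeros(shape, dtype=bool)
    for a, b in cells:
        comp[a, b] = True
    h, w = shape
    outside = np.zeros((h + 2, w + 2), dtype=bool)
    blocked = np.zeros((h + 2, w + 2), dtype=bool)
    blocked[1:-1, 1:-1] = comp
    q = deque([(0, 0)])
    outside[0, 0] = True
    while q:
        a, b = q.popleft()
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            aa, bb = a + da, b + db
            if (0 <= aa < h + 2 and 0 <= bb < w + 2
                    and not outside[aa, bb] and not blocked[aa, bb]):
                outside[aa, bb] = True
                q.append((aa, bb))
    return comp | ~outside[1:-1, 1:-1]


def brute_envelope(px, phase="bright"):
    """Largest filled candidate region; returns (pixels, mask, valid)."""
    px = np.asarray(px, dtype=np.uint8)
    shape = px.shape
    if px.max(initial=0) == 0:
        return np.zeros(shape, np.uint8), np.zeros(shape, bool), False
    cand = px == 255 if phase == "bright" else px == 0
    if not cand.any():
        return np.zeros(shape, np.uint8), np.zeros(shape, bool), False
    comps = _components_8(cand)
    best_mask, best_area = None, -1
    for cells in comps:  # first-found order; strict '>' keeps earliest tie
        filled = _fill_holes(cells, shape)
        area = int(filled.sum())
        if area > best_area:
            best_mask, best_area = filled, area
    out = np.where(best_mask, px, 0).astype(np.uint8)
    return out, best_mask, bool(out.any())


def brute_box_count(fg, eps):
    """Number of eps-grid cells (anchored at origin) touching foreground."""
    fg = np.asarray(fg, dtype=bool)
    h, w = fg.shape
    n = 0
    for i0 in range(0, h, eps):
        for j0 in range(0, w, eps):
            if fg[i0:i0 + eps, j0:j0 + eps].any():
                n += 1
    return n


def sierpinski(order):
    """Sierpinski-triangle raster of side 2**order via the bit trick."""
    n = 2 ** order
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return ((i & j) == 0)


def mann_whitney_auc(pos_scores, neg_scores):
    """AUC as the Mann-Whitney U statistic (ties count half)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
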
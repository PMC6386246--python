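"""Brute-force reference implementations used to cross-check the package.

Everything here is written for clarity, not speed: pixelwise loops over
explicit structuring-element offsets, breadth-first flood fills, and
first-moment centroids.  Out-of-image neighbors are ignored (the same
convention the morphology backend uses), i.e. grayscale erosion pads
with +inf, dilation with -inf, binary erosion with True, dilation with
False.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def selem_offsets(footprint: np.ndarray) -> list[tuple[int, int]]:
    """Center-relative (dr, dc) offsets of a structuring element."""
    fr, fc = footprint.shape
    cr, cc = fr // 2, fc // 2
    return [(r - cr, c - cc) for r, c in zip(*np.nonzero(footprint))]


def grey_erode(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    offs = selem_offsets(footprint)
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = [img[r + dr, c + dc] for dr, dc in offs
                    if 0 <= r + dr < h and 0 <= c + dc < w]
            out[r, c] = min(vals)
    return out


def grey_dilate(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    offs = selem_offsets(footprint)
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = [img[r + dr, c + dc] for dr, dc in offs
                    if 0 <= r + dr < h and 0 <= c + dc < w]
            out[r, c] = max(vals)
    return out


def grey_open(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return grey_dilate(grey_erode(img, footprint), footprint)


def grey_white_tophat(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return img - grey_open(img, footprint)


def binary_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return grey_erode(mask.astype(float), footprint) > 0.5


def binary_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return grey_dilate(mask.astype(float), footprint) > 0.5


def binary_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return binary_erode(binary_dilate(mask, footprint), footprint)


def binary_open(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return binary_dilate(binary_erode(mask, footprint), footprint)


_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def bfs_component_count(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components, by BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                for dr, dc in _NEIGH8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
    return count


def flood_fill_interval(img: np.ndarray, seed: np.ndarray,
                        lo: float, hi: float) -> np.ndarray:
    """8-connected BFS flood fill from seed pixels with fixed interval
    membership: a pixel joins iff lo <= value <= hi.  Seed pixels are
    always members."""
    h, w = img.shape
    region = seed.copy()
    queue = deque(zip(*np.nonzero(seed)))
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGH8:
            rr, cc = r + dr, c + dc
            if (0 <= rr < h and 0 <= cc < w and not region[rr, cc]
                    and lo <= img[rr, cc] <= hi):
                region[rr, cc] = True
                queue.append((rr, cc))
    return region


def centroid_first_moment(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())
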
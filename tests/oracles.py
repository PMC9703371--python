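"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written as direct per-pixel enumeration or fixpoint
iteration, deliberately avoiding the library code paths the package
uses, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Offsets (dy, dx) of pixels whose centre distance is <= radius."""
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def _neighborhood_extremum(image: np.ndarray, radius: int, kind: str) -> np.ndarray:
    """Min or max over the disk neighborhood, clipped at the image border."""
    h, w = image.shape
    pad_val = np.inf if kind == "min" else -np.inf
    padded = np.pad(image, radius, mode="constant", constant_values=pad_val)
    out = np.full_like(image, pad_val)
    for dy, dx in disk_offsets(radius):
        window = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
        out = np.minimum(out, window) if kind == "min" else np.maximum(out, window)
    return out


def tophat_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat by explicit min-then-max over the disk neighborhood."""
    opened = _neighborhood_extremum(
        _neighborhood_extremum(image, radius, "min"), radius, "max"
    )
    return image - opened


def reconstruct_dilation_oracle(
    seed: np.ndarray, mask: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Morphological reconstruction by dilation, iterated to fixpoint.

    Repeats: dilate by one step of the connectivity neighborhood, then
    clip under the mask, until nothing changes.
    """
    if connectivity == 8:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    else:
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = seed.shape
    cur = np.minimum(seed, mask)
    while True:
        padded = np.pad(cur, 1, mode="constant", constant_values=-np.inf)
        dil = np.full_like(cur, -np.inf)
        for dy, dx in offsets:
            dil = np.maximum(dil, padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w])
        nxt = np.minimum(dil, mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def regional_maxima_count(image: np.ndarray, connectivity: int = 8) -> int:
    """Number of regional-maximum plateaus, by flood-fill enumeration."""
    if connectivity == 8:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = image.shape
    visited = np.zeros((h, w), dtype=bool)
    count = 0
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            level = image[sy, sx]
            stack = [(sy, sx)]
            plateau = []
            is_max = True
            seen = {(sy, sx)}
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w):
                        continue
                    if image[ny, nx] > level:
                        is_max = False
                    elif image[ny, nx] == level and (ny, nx) not in seen:
                        seen.add((ny, nx))
                        stack.append((ny, nx))
            for y, x in plateau:
                visited[y, x] = True
            if is_max:
                count += 1
    return count


def bilinear_warp_oracle(
    image: np.ndarray,
    inverse_map,
    out_shape: tuple[int, int],
    fill: float,
) -> np.ndarray:
    """Per-pixel inverse warp with explicit bilinear weights.

    ``inverse_map`` takes (x, y) in the output frame and returns the
    source-frame (x, y).  Samples outside the source blend with the
    fill value, matching constant-padding interpolation.
    """
    h, w = image.shape
    out_h, out_w = out_shape
    out = np.empty((out_h, out_w))
    for oy in range(out_h):
        for ox in range(out_w):
            sx, sy = inverse_map(float(ox), float(oy))
            x0, y0 = int(np.floor(sx)), int(np.floor(sy))
            fx, fy = sx - x0, sy - y0
            acc = 0.0
            for (yy, xx, wgt) in (
                (y0, x0, (1 - fx) * (1 - fy)),
                (y0, x0 + 1, fx * (1 - fy)),
                (y0 + 1, x0, (1 - fx) * fy),
                (y0 + 1, x0 + 1, fx * fy),
            ):
                val = image[yy, xx] if 0 <= yy < h and 0 <= xx < w else fill
                acc += wgt * val
            out[oy, ox] = acc
    return out


def region_stats_oracle(labels: np.ndarray, image: np.ndarray) -> dict[int, dict]:
    """Per-label area, intensity sum/mean and centroid by a python loop."""
    stats: dict[int, dict] = {}
    h, w = labels.shape
    for y in range(h):
        for x in range(w):
            k = int(labels[y, x])
            if k == 0:
                continue
            s = stats.setdefault(k, {"area": 0, "sum": 0.0, "sx": 0.0, "sy": 0.0})
            s["area"] += 1
            s["sum"] += float(image[y, x])
            s["sx"] += x
            s["sy"] += y
    for s in stats.values():
        s["mean"] = s["sum"] / s["area"]
        s["cx"] = s["sx"] / s["area"]
        s["cy"] = s["sy"] / s["area"]
    return stats
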
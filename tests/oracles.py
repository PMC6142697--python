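"""Exhaustive per-pixel reference implementations.

Every function here recomputes a pipeline quantity by plain nested loops
over pixels, independent of the vectorised library code, for use as an
oracle on small fixtures.
"""

from __future__ import annotations

import numpy as np


def brute_range_filter(values: np.ndarray, window: int) -> np.ndarray:
    """Window max minus min per pixel, reflective borders, by explicit scan."""
    k = window // 2
    padded = np.pad(values, k, mode="reflect")
    h, w = values.shape
    out = np.empty_like(values, dtype=float)
    for i in range(h):
        for j in range(w):
            patch = padded[i : i + window, j : j + window]
            lo, hi = patch[0, 0], patch[0, 0]
            for row in patch:
                for v in row:
                    lo = v if v < lo else lo
                    hi = v if v > hi else hi
            out[i, j] = hi - lo
    return out


def brute_foreground_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean over masked pixels by explicit summation."""
    total, count = 0.0, 0
    h, w = values.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                total += values[i, j]
                count += 1
    if count == 0:
        raise ValueError("empty mask")
    return total / count


def brute_threshold(values: np.ndarray, mask: np.ndarray, moment: float) -> np.ndarray:
    """Strict global threshold restricted to the mask, pixel by pixel."""
    h, w = values.shape
    bits = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            bits[i, j] = bool(mask[i, j]) and values[i, j] > moment
    return bits


def brute_edge_pixels(bits: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Bright pixels with a dark/out-of-image neighbour, by neighbour scan."""
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    h, w = bits.shape
    edges = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if not bits[i, j]:
                continue
            for di, dj in offsets:
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not bits[ni, nj]:
                    edges[i, j] = True
                    break
    return edges


def brute_edge_match_score(
    bits_a: np.ndarray, bits_b: np.ndarray, connectivity: int = 4
) -> float:
    """Edge-pixel matching: co-edge count over the larger bright count."""
    ea = brute_edge_pixels(bits_a, connectivity)
    eb = brute_edge_pixels(bits_b, connectivity)
    num = 0
    for i in range(bits_a.shape[0]):
        for j in range(bits_a.shape[1]):
            if ea[i, j] and eb[i, j]:
                num += 1
    denom = max(int(bits_a.sum()), int(bits_b.sum()))
    return 0.0 if denom == 0 else num / denom


def brute_agreement_score(
    bits_a: np.ndarray, bits_b: np.ndarray, mask: np.ndarray
) -> float:
    """Pixel-wise matching: foreground agreement over foreground count."""
    agree, n_t = 0, 0
    for i in range(bits_a.shape[0]):
        for j in range(bits_a.shape[1]):
            if mask[i, j]:
                n_t += 1
                if bits_a[i, j] == bits_b[i, j]:
                    agree += 1
    if n_t == 0:
        raise ValueError("empty mask")
    return agree / n_t


def brute_spearman(xs, ys) -> float:
    """rho = 1 - 6 sum(d^2) / (n^3 - n) with average ranks, from scratch."""

    def average_ranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = average_ranks(list(xs)), average_ranks(list(ys))
    n = len(rx)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n**3 - n)
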
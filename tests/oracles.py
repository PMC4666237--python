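"""Independent brute-force reimplementations used as test oracles.

Everything here is written as plain double loops over pixels, deliberately
sharing no code with the package, so the vectorized implementations are
checked against a second derivation.
"""

import math

import numpy as np

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_histogram(roi: np.ndarray) -> tuple[np.ndarray, int]:
    """Co-occurrence counts over all ordered in-bounds 8-neighbor pairs."""
    roi = np.asarray(roi, dtype=int)
    m, n = roi.shape
    lo, hi = roi.min(), roi.max()
    counts = np.zeros((hi - lo + 1, hi - lo + 1), dtype=np.int64)
    for i in range(m):
        for j in range(n):
            for dy, dx in OFFSETS:
                y, x = i + dy, j + dx
                if 0 <= y < m and 0 <= x < n:
                    counts[roi[i, j] - lo, roi[y, x] - lo] += 1
    return counts, int(lo)


def brute_mask(
    roi: np.ndarray,
    offset: int,
    x_range: tuple[int, int],
    y_range: tuple[int, int],
    counts: np.ndarray,
) -> np.ndarray:
    """Pixels with some in-bounds neighbor pair landing in the block
    (and a positive histogram count at that cell)."""
    roi = np.asarray(roi, dtype=int)
    m, n = roi.shape
    mask = np.zeros((m, n), dtype=np.uint8)
    for i in range(m):
        for j in range(n):
            a = roi[i, j] - offset
            if not (x_range[0] <= a < x_range[1]):
                continue
            for dy, dx in OFFSETS:
                y, x = i + dy, j + dx
                if 0 <= y < m and 0 <= x < n:
                    b = roi[y, x] - offset
                    if y_range[0] <= b < y_range[1] and counts[a, b] > 0:
                        mask[i, j] = 1
    return mask


def brute_mse(c: np.ndarray, s: np.ndarray) -> float:
    m, n = c.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            d = float(c[i, j]) - float(s[i, j])
            total += d * d
    return total / (m * n)


def brute_psnr(c: np.ndarray, s: np.ndarray, max_value: int = 255) -> float:
    err = brute_mse(c, s)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(max_value * max_value / err)


def brute_average_gradient(s: np.ndarray) -> float:
    m, n = s.shape
    total = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dr = float(s[i + 1, j]) - float(s[i, j])
            dc = float(s[i, j + 1]) - float(s[i, j])
            total += math.sqrt((dr * dr + dc * dc) / 2.0)
    return total / ((m - 1) * (n - 1))


def brute_two_pass_std(values) -> float:
    """Population standard deviation via an explicit two-pass sum."""
    values = [float(v) for v in np.asarray(values).ravel()]
    mu = sum(values) / len(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))


def brute_hist_equalize(img: np.ndarray, max_value: int = 255) -> np.ndarray:
    """v -> round-half-up(max * cdf(v)) computed per pixel from scratch."""
    img = np.asarray(img)
    flat = img.ravel()
    total = flat.size
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            rank = int((flat <= img[i, j]).sum())
            out[i, j] = math.floor(max_value * rank / total + 0.5)
    return out
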
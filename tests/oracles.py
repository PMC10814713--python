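"""Naive set-definition implementations used as independent oracles.

These are deliberately slow triple-loop translations of the mathematical
definitions (shift-union dilation, flood-fill component labeling,
pairwise-comparison AUC) so that the production implementations can be
checked bit-exactly against them on small inputs.
"""

from __future__ import annotations

import numpy as np


def naive_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Z(i,j) = 1 iff the footprint centered at (i,j) overlaps a 1 of mask
    (out-of-bounds cells read as 0)."""
    m, n = mask.shape
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask)
    for i in range(m):
        for j in range(n):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if footprint[di + r, dj + r]:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < m and 0 <= jj < n and mask[ii, jj]:
                            hit = True
            out[i, j] = 1 if hit else 0
    return out


def naive_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """E(i,j) = 1 iff every footprint cell centered at (i,j) lies on a 1
    (out-of-bounds cells read as 0, so borders erode)."""
    m, n = mask.shape
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask)
    for i in range(m):
        for j in range(n):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if footprint[di + r, dj + r]:
                        ii, jj = i + di, j + dj
                        if not (0 <= ii < m and 0 <= jj < n and mask[ii, jj]):
                            ok = False
            out[i, j] = 1 if ok else 0
    return out


def naive_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return naive_erode(naive_dilate(mask, footprint), footprint)


def naive_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Flood-fill connected components as sets of (i, j) pixels."""
    m, n = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(m):
        for j in range(n):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    ci, cj = stack.pop()
                    comp.add((ci, cj))
                    for di, dj in steps:
                        ii, jj = ci + di, cj + dj
                        if 0 <= ii < m and 0 <= jj < n and mask[ii, jj] and not seen[ii, jj]:
                            seen[ii, jj] = True
                            stack.append((ii, jj))
                comps.append(comp)
    return comps


def naive_remove_small(mask: np.ndarray, area_threshold: int, connectivity: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for comp in naive_components(mask, connectivity):
        if len(comp) > area_threshold:
            for i, j in comp:
                out[i, j] = 1
    return out


def mann_whitney_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the pairwise-comparison probability with ties counted 1/2."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def exhaustive_otsu(image: np.ndarray) -> int:
    """Between-class-variance scan over all 256 thresholds; smallest tie wins."""
    x = image.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = x[x <= t]
        hi = x[x > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / x.size, hi.size / x.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t
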
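"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the
implementation under test (explicit kernels + dense convolution,
per-pixel eigen solves, BFS flood fill, all-pairs matching, direct
distance checks) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# Frangi vesselness: explicit-kernel convolution + per-pixel eigen solve
# ---------------------------------------------------------------------------


def gaussian_kernels_1d(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian and its first/second exact derivatives, radius 4 sigma."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * x**2 / sigma**2)
    g /= g.sum()
    g1 = (-x / sigma**2) * g
    g2 = (x**2 / sigma**4 - 1.0 / sigma**2) * g
    g2 -= g2.sum() * g  # exact zero DC, mirroring the filter's convention
    return g, g1, g2


def _conv2_sep(img: np.ndarray, k_row: np.ndarray, k_col: np.ndarray) -> np.ndarray:
    """Dense 2-D convolution with the outer-product kernel, symmetric padding."""
    pr, pc = len(k_row) // 2, len(k_col) // 2
    padded = np.pad(img, ((pr, pr), (pc, pc)), mode="symmetric")
    kernel = np.outer(k_row, k_col)
    out = np.zeros_like(img, dtype=float)
    kr, kc = kernel.shape
    for i in range(kr):
        for j in range(kc):
            out += kernel[i, j] * padded[i : i + img.shape[0], j : j + img.shape[1]]
    return out


def frangi_oracle(
    img: np.ndarray,
    scales,
    beta1: float = 0.95,
    beta2: float = 0.35,
    bright: bool = True,
) -> np.ndarray:
    """Multiscale Frangi response via explicit kernels and numpy eigvalsh."""
    out = np.zeros_like(img, dtype=float)
    for sigma in scales:
        g, g1, g2 = gaussian_kernels_1d(sigma)
        s2 = sigma * sigma
        h_rr = _conv2_sep(img, g2, g) * s2
        h_cc = _conv2_sep(img, g, g2) * s2
        h_rc = _conv2_sep(img, g1, g1) * s2
        v = np.zeros_like(img, dtype=float)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                H = np.array([[h_rr[i, j], h_rc[i, j]], [h_rc[i, j], h_cc[i, j]]])
                e = np.linalg.eigvalsh(H)
                l1, l2 = (e[0], e[1]) if abs(e[0]) <= abs(e[1]) else (e[1], e[0])
                if (bright and l2 >= 0) or (not bright and l2 <= 0):
                    continue
                s_sq = l1 * l1 + l2 * l2
                if s_sq == 0:
                    continue
                rb_sq = (l1 / l2) ** 2
                v[i, j] = np.exp(-rb_sq / (2 * beta1**2)) * (
                    1.0 - np.exp(-s_sq / (2 * beta2**2))
                )
        out = np.maximum(out, v)
    return out


# ---------------------------------------------------------------------------
# Connected components: BFS flood fill
# ---------------------------------------------------------------------------

_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_OFFSETS_8 = _OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components as pixel sets, in row-major first-pixel order."""
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                pr, pc = queue.popleft()
                comp.add((pr, pc))
                for dr, dc in offsets:
                    qr, qc = pr + dr, pc + dc
                    if 0 <= qr < nr and 0 <= qc < nc and mask[qr, qc] and not seen[qr, qc]:
                        seen[qr, qc] = True
                        queue.append((qr, qc))
            components.append(comp)
    return components


# ---------------------------------------------------------------------------
# Morphology: per-pixel Chebyshev distance check
# ---------------------------------------------------------------------------


def interior_brute_force(mask: np.ndarray, margin: int) -> np.ndarray:
    """Pixels whose Chebyshev distance to the nearest background > margin.

    Pixels beyond the image border count as background.
    """
    nr, nc = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    bg = np.argwhere(~mask)
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            d_border = min(r, c, nr - 1 - r, nc - 1 - c) + 1
            if bg.size:
                d_bg = np.max(np.abs(bg - (r, c)), axis=1).min()
                d = min(d_border, d_bg)
            else:
                d = d_border
            out[r, c] = d > margin
    return out


# ---------------------------------------------------------------------------
# Bounding-box matching: all-pairs
# ---------------------------------------------------------------------------


def _overlap_1d(a0, a1, b0, b1, reach) -> bool:
    return (b0 - a1) <= reach and (a0 - b1) <= reach


def match_brute_force(ref, cand, tol_px: float, dilate_both: bool = True):
    """All-pairs matcher over (slice_index, bbox) tuples.

    Returns (n_ref_matched, n_cand_matched).
    """
    reach = 2.0 * tol_px if dilate_both else float(tol_px)
    ref_hit = [False] * len(ref)
    cand_hit = [False] * len(cand)
    for i, (ks, ra) in enumerate(ref):
        for j, (kc, rb) in enumerate(cand):
            if ks != kc:
                continue
            if _overlap_1d(ra[0], ra[2], rb[0], rb[2], reach) and _overlap_1d(
                ra[1], ra[3], rb[1], rb[3], reach
            ):
                ref_hit[i] = True
                cand_hit[j] = True
    return sum(ref_hit), sum(cand_hit)
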
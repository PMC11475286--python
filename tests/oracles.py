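"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (python sets, BFS flood fill,
exhaustive threshold search, matrix-power recurrences) kept free of any
pectseg internals, so they can cross-check the package's vectorized
code paths.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """Label 4-connected components by BFS flood fill (raster-scan order)."""
    mask = np.asarray(mask)
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    h, w = mask.shape
    for sr in range(h):
        for sc in range(w):
            if mask[sr, sc] and not labels[sr, sc]:
                next_label += 1
                queue = deque([(sr, sc)])
                labels[sr, sc] = next_label
                while queue:
                    r, c = queue.popleft()
                    for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not labels[nr, nc]:
                            labels[nr, nc] = next_label
                            queue.append((nr, nc))
    return labels


def brute_overlap_scores(pred: np.ndarray, truth: np.ndarray, k: int):
    """(dice, jaccard) for class k via python-set pixel enumeration."""
    p = {(r, c) for r, c in zip(*np.nonzero(np.asarray(pred) == k))}
    g = {(r, c) for r, c in zip(*np.nonzero(np.asarray(truth) == k))}
    if not p and not g:
        return 1.0, 1.0
    inter = len(p & g)
    dice = 2 * inter / (len(p) + len(g))
    jacc = inter / len(p | g)
    return dice, jacc


def otsu_partition(image: np.ndarray) -> np.ndarray:
    """Foreground mask from exhaustive between-class-variance maximization."""
    x = np.asarray(image).ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in np.unique(x)[:-1]:
        fg = x > t
        w1 = fg.mean()
        w0 = 1 - w1
        if w0 == 0 or w1 == 0:
            continue
        v = w0 * w1 * (x[fg].mean() - x[~fg].mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return (np.asarray(image) > best_t).astype(np.uint8)


def sgdm_trajectory_quadratic(w0: float, eta: float, mu: float, steps: int):
    """SGDM on L(w) = w^2 / 2 via the exact linear recurrence in matrix form.

    State s_t = (w_t, v_t) evolves as s_{t+1} = A s_t with
    A = [[1 - eta, mu], [-eta, mu]]; returns the list of w_t for
    t = 1..steps computed by explicit matrix powers.
    """
    a = np.array([[1 - eta, mu], [-eta, mu]], dtype=np.float64)
    s0 = np.array([w0, 0.0])
    out = []
    for t in range(1, steps + 1):
        out.append(float((np.linalg.matrix_power(a, t) @ s0)[0]))
    return out
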
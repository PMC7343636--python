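"""Brute-force reference implementations used to validate the fast paths.

These are deliberately naive (exhaustive search, BFS flood fill) so their
correctness is self-evident; the unit and acceptance tests compare the
package's implementations against them.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def otsu_bruteforce(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive intra-class variance minimization over all histogram cuts.

    Returns the upper edge of the last background bin of the best cut —
    the same convention as sccpipe.segmentation.otsu_threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_k, best_wcv = None, np.inf
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        v0 = (counts[: k + 1] * (centers[: k + 1] - m0) ** 2).sum() / w0
        v1 = (counts[k + 1:] * (centers[k + 1:] - m1) ** 2).sum() / w1
        wcv = (w0 * v0 + w1 * v1) / (w0 + w1)
        if wcv < best_wcv - 1e-12:
            best_wcv, best_k = wcv, k
    return float(edges[best_k + 1])


def _neighbors(connectivity: int):
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                manhattan = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def flood_fill_components(binary: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """BFS connected-component labeling; labels in lexicographic scan order."""
    binary = np.asarray(binary).astype(bool)
    labels = np.zeros(binary.shape, dtype=np.int64)
    offsets = _neighbors(connectivity)
    Z, Y, X = binary.shape
    next_label = 0
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not binary[z, y, x] or labels[z, y, x]:
                    continue
                next_label += 1
                queue = deque([(z, y, x)])
                labels[z, y, x] = next_label
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offsets:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X
                            and binary[nz, ny, nx] and not labels[nz, ny, nx]
                        ):
                            labels[nz, ny, nx] = next_label
                            queue.append((nz, ny, nx))
    return labels


def balanced_anova_closed_form(table):
    """Textbook balanced two-way decomposition with interaction.

    Returns factor -> (sum of squares, degrees of freedom). Only valid when
    every cell holds the same number of observations.
    """
    grand = table["value"].mean()
    n = len(table)
    cells = table.groupby(["cell_type", "treatment"])["value"]
    sizes = cells.size()
    assert sizes.nunique() == 1, "closed form requires a balanced design"
    n_cell = sizes.iloc[0]
    a_means = table.groupby("cell_type")["value"].mean()
    b_means = table.groupby("treatment")["value"].mean()
    cell_means = cells.mean()
    levels_a, levels_b = len(a_means), len(b_means)
    ss_a = n_cell * levels_b * ((a_means - grand) ** 2).sum()
    ss_b = n_cell * levels_a * ((b_means - grand) ** 2).sum()
    ss_cells = n_cell * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((g - g.mean()) ** 2).sum() for _, g in cells)
    return {
        "cell_type": (ss_a, levels_a - 1),
        "treatment": (ss_b, levels_b - 1),
        "interaction": (ss_ab, (levels_a - 1) * (levels_b - 1)),
        "residual": (ss_err, n - levels_a * levels_b),
    }
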
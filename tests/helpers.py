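"""Shared fixtures and independent oracles used across the test modules.

The oracles are deliberately naive (O(n^2) enumeration, exhaustive grid
search) and share no code with the package implementation.
"""

import numpy as np
import pandas as pd

from loopstate.io_formats import LocalisationTable


def make_table(points, marks, rois="roi_0"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    if isinstance(marks, str):
        marks = [marks] * n
    if isinstance(rois, str):
        rois = [rois] * n
    return LocalisationTable(
        pd.DataFrame({"x": points[:, 0], "y": points[:, 1], "mark": list(marks), "roi": list(rois)})
    )


def mcf_bruteforce(points, labels, bin_edges):
    """Per-bin cross-pair probability by exhaustive enumeration of all pairs."""
    points = np.asarray(points, dtype=float)
    n_bins = len(bin_edges) - 1
    total = np.zeros(n_bins, dtype=int)
    cross = np.zeros(n_bins, dtype=int)
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = float(np.hypot(*(points[i] - points[j])))
            for b in range(n_bins):
                if bin_edges[b] <= d < bin_edges[b + 1]:
                    total[b] += 1
                    if labels[i] != labels[j]:
                        cross[b] += 1
                    break
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, cross / np.maximum(total, 1), np.nan), total


def knn_bruteforce(mark_points, ref_points, k):
    """k-th nearest neighbour distances via full distance-matrix sorting."""
    out = []
    for p in np.asarray(mark_points, dtype=float):
        d = np.sort(np.hypot(*(np.asarray(ref_points, dtype=float) - p).T))
        out.append(d[k - 1])
    return np.array(out)


def grid_mode_search(points, sigma, pitch=1.0, pad=100.0):
    """Exhaustive KDE mode search: density maxima and per-point hill-climb assignment.

    Evaluates the Gaussian KDE on a regular grid of the given pitch and walks
    each localisation uphill cell by cell to its local maximum.  Returns the
    list of distinct maxima positions reached and the per-point assignment
    index into that list.
    """
    points = np.asarray(points, dtype=float)
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = np.zeros(gx.shape)
    for p in points:
        dens += np.exp(-((gx - p[0]) ** 2 + (gy - p[1]) ** 2) / (2 * sigma**2))

    def climb(ix, iy):
        while True:
            best = dens[ix, iy]
            bix, biy = ix, iy
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    jx, jy = ix + dx, iy + dy
                    if 0 <= jx < dens.shape[0] and 0 <= jy < dens.shape[1] and dens[jx, jy] > best:
                        best, bix, biy = dens[jx, jy], jx, jy
            if (bix, biy) == (ix, iy):
                return ix, iy
            ix, iy = bix, biy

    maxima = []
    assignment = []
    for p in points:
        ix = int(round((p[0] - lo[0]) / pitch))
        iy = int(round((p[1] - lo[1]) / pitch))
        mx, my = climb(ix, iy)
        pos = (xs[mx], ys[my])
        for mi, m in enumerate(maxima):
            if np.hypot(pos[0] - m[0], pos[1] - m[1]) < 2 * pitch:
                assignment.append(mi)
                break
        else:
            maxima.append(pos)
            assignment.append(len(maxima) - 1)
    return np.array(maxima), np.array(assignment)


def welch_by_hand(a, b):
    """Welch two-sided t-test from first principles (statistic, dof, p-value)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), dof)
    return t, dof, p
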
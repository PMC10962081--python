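"""Mean-shift clustering of single-mark localisations and cluster-width statistics.

Localisations of one histone-mark class are clustered by mean shift with a
Gaussian kernel (bandwidth = the field-standard "sigma", 50 nm by default) and
a minimum cluster occupancy of 15 localisations.  Cluster width is reported as
FWHM: the maximum-likelihood scale of an isotropic 2-D Gaussian fitted to the
member displacements from the cluster centre, corrected for small-sample bias,
times 2*sqrt(2*ln 2).  Width distributions are summarised by the median, the
interquartile range and a probability-normalised histogram, and compared
between marks with a two-sided Mann-Whitney rank-sum test.

Clustering is performed independently within each ROI (fibres from different
cells must never be pooled into one cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

from .exceptions import DegenerateClusterError, EmptyInputError, InsufficientDataError
from .io_formats import LocalisationTable, ResultDocument
from .synthetic_data import FWHM_PER_SIGMA

_GAUSS_SUPPORT = 5.0  # kernel truncation radius in bandwidths


@dataclass(frozen=True)
class ClusteringParams:
    """Mean-shift parameters; lengths in nm.

    ``merge_radius`` defaults to half the bandwidth; converged modes closer
    than this are pooled into one cluster.  ``kernel`` may be ``"gaussian"``
    (default) or ``"flat"`` (uniform weights within one bandwidth) for
    sensitivity checks.
    """

    bandwidth_sigma: float = 50.0
    min_points: int = 15
    merge_radius: Optional[float] = None
    convergence_tol: float = 0.1
    max_iter: int = 500
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.bandwidth_sigma <= 0 or self.min_points < 1:
            raise ValueError("bandwidth_sigma > 0 and min_points >= 1 required")
        if self.kernel not in ("gaussian", "flat"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def effective_merge_radius(self) -> float:
        return self.bandwidth_sigma / 2 if self.merge_radius is None else self.merge_radius


@dataclass
class ClusterRecord:
    """One detected cluster: centre of mass, members and fitted width."""

    cluster_id: int
    roi_id: str
    centre: np.ndarray  # (2,) nm
    members: np.ndarray  # positional row indices into the source table
    fwhm: float  # nm; NaN if the cluster is degenerate (all members coincident)

    @property
    def member_count(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """All clusters of one mark found in a localisation table."""

    mark: str
    clusters: list[ClusterRecord]
    params: ClusteringParams

    def __len__(self) -> int:
        return len(self.clusters)

    def centres(self, roi_id: Optional[str] = None) -> np.ndarray:
        recs = [c for c in self.clusters if roi_id is None or c.roi_id == roi_id]
        return np.array([c.centre for c in recs]).reshape(-1, 2)

    @property
    def widths(self) -> np.ndarray:
        return np.array([c.fwhm for c in self.clusters])

    def to_document(self) -> ResultDocument:
        table = pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "roi": [c.roi_id for c in self.clusters],
                "x_nm": [c.centre[0] for c in self.clusters],
                "y_nm": [c.centre[1] for c in self.clusters],
                "n": [c.member_count for c in self.clusters],
                "fwhm_nm": [c.fwhm for c in self.clusters],
            }
        )
        meta = {
            "mark": self.mark,
            "n_clusters": len(self.clusters),
            "bandwidth_sigma": self.params.bandwidth_sigma,
            "min_points": self.params.min_points,
            "kernel": self.params.kernel,
        }
        return ResultDocument(kind="ClusterSet", meta=meta, table=table)


def _shift_step(X: np.ndarray, tree: cKDTree, Y: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """One batched mean-shift update of the seed positions Y."""
    h = params.bandwidth_sigma
    radius = _GAUSS_SUPPORT * h if params.kernel == "gaussian" else h
    nbrs = tree.query_ball_point(Y, radius)
    counts = np.array([len(v) for v in nbrs])
    out = Y.copy()
    ok = counts > 0
    if not ok.any():
        return out
    flat = np.concatenate([nbrs[i] for i in np.flatnonzero(ok)])
    pts = X[flat]
    rep = np.repeat(Y[ok], counts[ok], axis=0)
    if params.kernel == "gaussian":
        w = np.exp(-0.5 * np.sum((pts - rep) ** 2, axis=1) / h**2)
    else:
        w = np.ones(len(pts))
    offsets = np.concatenate([[0], np.cumsum(counts[ok])[:-1]]).astype(int)
    sw = np.add.reduceat(w, offsets)
    swp = np.add.reduceat(w[:, None] * pts, offsets, axis=0)
    out[ok] = swp / sw[:, None]
    return out


def _converge_modes(X: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Run every point uphill to its density mode; returns final positions."""
    tree = cKDTree(X)
    Y = X.copy()
    active = np.arange(len(Y))
    for _ in range(params.max_iter):
        if len(active) == 0:
            break
        newY = _shift_step(X, tree, Y[active], params)
        moved = np.linalg.norm(newY - Y[active], axis=1)
        Y[active] = newY
        active = active[moved > params.convergence_tol]
    return Y


def _group_modes(modes: np.ndarray, merge_radius: float) -> np.ndarray:
    """Label converged modes by single-linkage components within merge_radius."""
    n = len(modes)
    pairs = cKDTree(modes).query_pairs(merge_radius, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def mean_shift_cluster(
    table: LocalisationTable, mark: str, params: ClusteringParams = ClusteringParams()
) -> ClusterSet:
    """Cluster all localisations of ``mark`` with mean shift, per ROI.

    Modes converging within ``merge_radius`` of each other are pooled; only
    pools with at least ``min_points`` members are kept (their centre is the
    member mean).  Localisations converging to a discarded mode stay
    unassigned.  The result is deterministic for a given table and params.
    """
    clusters: list[ClusterRecord] = []
    next_id = 0
    mark_mask = (table.df["mark"] == mark).to_numpy()
    for roi_id in table.rois:
        rows = np.flatnonzero(mark_mask & (table.df["roi"] == roi_id).to_numpy())
        if len(rows) == 0:
            continue
        X = table.df.iloc[rows][["x", "y"]].to_numpy(dtype=float)
        modes = _converge_modes(X, params)
        labels = _group_modes(modes, params.effective_merge_radius)
        for lab in np.unique(labels):
            members = rows[labels == lab]
            if len(members) < params.min_points:
                continue
            pts = table.df.iloc[members][["x", "y"]].to_numpy(dtype=float)
            centre = pts.mean(axis=0)
            rec = ClusterRecord(next_id, roi_id, centre, members, np.nan)
            try:
                rec.fwhm = estimate_fwhm(rec, table)
            except DegenerateClusterError:
                warnings.warn(f"cluster {next_id}: all members coincident, FWHM undefined")
            clusters.append(rec)
            next_id += 1
    return ClusterSet(mark=mark, clusters=clusters, params=params)


def estimate_fwhm(cluster: ClusterRecord, table: LocalisationTable) -> float:
    """FWHM of the isotropic 2-D Gaussian best fitting the cluster members.

    The radial scale is the ML estimate ``sigma^2 = sum |x_i - mean|^2 / (2(n-1))``
    (the n-1 removes the mean-estimation bias), de-biased for the chi-type
    skew of the square root via the exact Gaussian small-sample factor, then
    converted by FWHM = 2*sqrt(2 ln 2) * sigma.
    """
    pts = table.df.iloc[cluster.members][["x", "y"]].to_numpy(dtype=float)
    n = len(pts)
    d2 = np.sum((pts - pts.mean(axis=0)) ** 2)
    if d2 == 0.0:
        raise DegenerateClusterError(f"cluster {cluster.cluster_id}: zero spatial extent")
    m = 2 * (n - 1)  # chi-square degrees of freedom of d2 / sigma^2
    s = np.sqrt(d2 / m)
    c4 = np.sqrt(2.0 / m) * np.exp(gammaln((m + 1) / 2) - gammaln(m / 2))
    return float(FWHM_PER_SIGMA * s / c4)


@dataclass
class WidthDistribution:
    """Summary of one mark's cluster-width (FWHM) sample."""

    mark: str
    widths: np.ndarray
    median: float
    iqr: tuple[float, float]
    bin_edges: np.ndarray
    probabilities: np.ndarray  # normalised frequencies summing to 1

    def to_document(self) -> ResultDocument:
        table = pd.DataFrame(
            {
                "bin_left_nm": self.bin_edges[:-1],
                "bin_right_nm": self.bin_edges[1:],
                "probability": self.probabilities,
            }
        )
        meta = {
            "mark": self.mark,
            "n": len(self.widths),
            "median_nm": self.median,
            "iqr_low_nm": self.iqr[0],
            "iqr_high_nm": self.iqr[1],
        }
        return ResultDocument(kind="WidthDistribution", meta=meta, table=table)


def width_distribution(clusterset: ClusterSet, bins: np.ndarray) -> WidthDistribution:
    """Median, IQR and probability-normalised histogram of cluster FWHMs.

    Quantiles use linear interpolation of order statistics.  Degenerate
    clusters (undefined width) are excluded.  Frequencies are normalised by
    the number of histogrammed clusters so the bar heights are probabilities.
    """
    widths = clusterset.widths
    widths = widths[np.isfinite(widths)]
    if len(widths) == 0:
        raise EmptyInputError("no clusters with a defined width")
    counts, edges = np.histogram(widths, bins=np.asarray(bins, dtype=float))
    total = counts.sum()
    probs = counts / total if total else counts.astype(float)
    return WidthDistribution(
        mark=clusterset.mark,
        widths=widths,
        median=float(np.median(widths)),
        iqr=(float(np.quantile(widths, 0.25)), float(np.quantile(widths, 0.75))),
        bin_edges=edges,
        probabilities=probs,
    )


@dataclass
class WidthComparison:
    """Median-shift and rank-sum comparison between two width distributions."""

    mark_a: str
    mark_b: str
    median_a: float
    median_b: float
    percent_median_difference: float  # 100 * (median_b - median_a) / median_a
    u_statistic: float
    p_value: float

    def to_document(self) -> ResultDocument:
        meta = {
            "mark_a": self.mark_a,
            "mark_b": self.mark_b,
            "median_a_nm": self.median_a,
            "median_b_nm": self.median_b,
            "percent_median_difference": self.percent_median_difference,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
        }
        return ResultDocument(kind="WidthComparison", meta=meta)


def compare_widths(a: WidthDistribution, b: WidthDistribution) -> WidthComparison:
    """Percent median difference of b relative to a, with Mann-Whitney p-value."""
    if len(a.widths) < 2 or len(b.widths) < 2:
        raise InsufficientDataError("need >= 2 widths per group for a rank-sum test")
    u, p = mannwhitneyu(a.widths, b.widths, alternative="two-sided")
    return WidthComparison(
        mark_a=a.mark,
        mark_b=b.mark,
        median_a=a.median,
        median_b=b.median,
        percent_median_difference=100.0 * (b.median - a.median) / a.median,
        u_statistic=float(u),
        p_value=float(p),
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; use when more than two marks are compared."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
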
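"""Mutual-exclusivity statistics for two histone-mark localisation classes.

Two complementary quantifications:

* **Overlap fraction** — cluster one mark, then count what fraction of the
  other mark's localisations fall within a fixed radius (50 nm, the average
  cluster half-width) of a cluster centre.  Reported per ROI and as the
  median across ROIs; the analysis is run in both directions to avoid bias
  from unequal localisation abundance.
* **Mark connection function (MCF)** — for each distance bin, the probability
  that a pair of localisations separated by that distance carries the two
  different marks.  Normalised by 2*p_A*p_B (the random-labelling expectation
  for unordered cross pairs) so that 1 means "random"; the ``centred`` field
  (normalised − 1) matches the zero-centred presentation.  A Monte-Carlo
  random-labelling null (labels permuted within ROI, positions fixed) gives a
  pointwise 95% envelope, from which per-bin repulsion/attraction verdicts
  are derived.

Pair counting never crosses ROI boundaries; pooling across ROIs weights each
ROI by its pair counts.  No edge correction is applied (the MCF is a ratio of
pair counts at the same distance, so window effects largely cancel); an
optional periodic box is available for simulated rectangular windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .clustering import ClusterSet
from .exceptions import AnalysisError, InsufficientDataError
from .io_formats import LocalisationTable, ResultDocument


@dataclass
class OverlapResult:
    """Fraction of `other_mark` localisations within `radius` of `clustered_mark` cluster centres."""

    clustered_mark: str
    other_mark: str
    radius: float
    per_roi_fractions: dict[str, float]
    median_fraction: float

    def to_document(self) -> ResultDocument:
        table = pd.DataFrame(
            {
                "roi": list(self.per_roi_fractions),
                "overlap_fraction": list(self.per_roi_fractions.values()),
            }
        )
        meta = {
            "clustered_mark": self.clustered_mark,
            "other_mark": self.other_mark,
            "radius_nm": self.radius,
            "median_fraction": self.median_fraction,
        }
        return ResultDocument(kind="OverlapResult", meta=meta, table=table)


def overlap_fraction(
    clusters: ClusterSet,
    other: LocalisationTable,
    other_mark: str,
    radius: float = 50.0,
    pooled: bool = False,
) -> OverlapResult:
    """Per-ROI overlap fractions of ``other_mark`` against ``clusters``.

    A localisation overlaps if its nearest cluster centre (same ROI) is
    within ``radius``.  With ``pooled=True`` a single fraction over all
    localisations is reported instead of the per-ROI median.
    """
    if len(clusters) == 0:
        raise AnalysisError("overlap undefined: empty cluster set")
    sub = other.for_mark(other_mark)
    if len(sub) == 0:
        raise AnalysisError(f"no localisations of mark {other_mark!r}")
    fractions: dict[str, float] = {}
    n_hit_total = 0
    n_total = 0
    for roi_id in sub.rois:
        centres = clusters.centres(roi_id)
        pts = sub.for_roi(roi_id).coords()
        if len(centres) == 0:
            continue  # no clusters in this ROI: fraction undefined, skipped
        d, _ = cKDTree(centres).query(pts, k=1)
        n_hit = int((d <= radius).sum())
        fractions[roi_id] = n_hit / len(pts)
        n_hit_total += n_hit
        n_total += len(pts)
    if not fractions:
        raise AnalysisError("no ROI contains both clusters and other-mark localisations")
    median = (
        n_hit_total / n_total if pooled else float(np.median(list(fractions.values())))
    )
    return OverlapResult(
        clustered_mark=clusters.mark,
        other_mark=other_mark,
        radius=radius,
        per_roi_fractions=fractions,
        median_fraction=median,
    )


@dataclass
class MCFResult:
    """Binned cross-mark connection function with its random-labelling envelope."""

    mark_a: str
    mark_b: str
    bin_edges: np.ndarray
    n_pairs: np.ndarray  # all same-ROI pairs per bin
    p_cross: np.ndarray  # raw cross-mark probability per bin; NaN where empty
    normalised: np.ndarray  # p_cross / (2 p_A p_B); 1 = random labelling
    centred: np.ndarray  # normalised - 1; 0 = random labelling
    envelope_low: np.ndarray  # 2.5% null quantile on the centred scale
    envelope_high: np.ndarray  # 97.5% null quantile
    n_permutations: int
    seed: int

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n_pairs == 0

    def to_document(self) -> ResultDocument:
        table = pd.DataFrame(
            {
                "bin_left_nm": self.bin_edges[:-1],
                "bin_right_nm": self.bin_edges[1:],
                "n_pairs": self.n_pairs,
                "p_cross": self.p_cross,
                "normalised": self.normalised,
                "centred": self.centred,
                "envelope_low": self.envelope_low,
                "envelope_high": self.envelope_high,
            }
        )
        meta = {
            "mark_a": self.mark_a,
            "mark_b": self.mark_b,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        return ResultDocument(kind="MCFResult", meta=meta, table=table)


def _pairs_within(coords: np.ndarray, rmax: float, box: Optional[float]) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs within rmax and their distances; min-image if a periodic box is given."""
    if box is not None:
        tree = cKDTree(np.mod(coords, box), boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.empty(0)
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return pairs, np.hypot(diff[:, 0], diff[:, 1])


def mark_connection(
    table: LocalisationTable,
    mark_a: str,
    mark_b: str,
    bin_edges: Optional[np.ndarray] = None,
    n_permutations: int = 199,
    seed: int = 0,
    box: Optional[float] = None,
) -> MCFResult:
    """Cross-mark connection function of ``mark_a`` vs ``mark_b`` with a permutation null.

    For each distance bin, ``p_cross`` is the fraction of same-ROI unordered
    pairs in that bin with one member of each mark.  ``normalised`` divides
    by 2*p_A*p_B (observed pooled label proportions).  The null envelope is
    the pointwise 2.5%/97.5% range of the centred statistic over
    ``n_permutations`` random relabellings (within ROI).  Pass
    ``n_permutations=0`` to skip the null (envelopes become NaN).  ``box``
    enables toroidal (min-image) distances for periodic simulation windows.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 520.0, 20.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    sub = table.df[table.df["mark"].isin([mark_a, mark_b])]
    if len(sub) < 2:
        raise InsufficientDataError(f"need >= 2 localisations of {mark_a!r}/{mark_b!r}")
    n_bins = len(bin_edges) - 1
    rmax = bin_edges[-1]

    per_roi: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (pairs, pair bin index, point labels)
    for roi_id in dict.fromkeys(sub["roi"]):
        grp = sub[sub["roi"] == roi_id]
        coords = grp[["x", "y"]].to_numpy(dtype=float)
        labels = (grp["mark"] == mark_a).to_numpy()
        pairs, dist = _pairs_within(coords, rmax, box)
        if len(pairs) == 0:
            continue
        bin_idx = np.searchsorted(bin_edges, dist, side="right") - 1
        keep = (bin_idx >= 0) & (bin_idx < n_bins) & (dist >= bin_edges[0]) & (dist < bin_edges[-1])
        per_roi.append((pairs[keep], bin_idx[keep], labels))

    total = np.zeros(n_bins, dtype=np.int64)
    cross = np.zeros(n_bins, dtype=np.int64)
    for pairs, bin_idx, labels in per_roi:
        total += np.bincount(bin_idx, minlength=n_bins)
        is_cross = labels[pairs[:, 0]] != labels[pairs[:, 1]]
        cross += np.bincount(bin_idx[is_cross], minlength=n_bins)

    p_a = float((sub["mark"] == mark_a).mean())
    p_b = 1.0 - p_a
    norm_const = 2.0 * p_a * p_b
    with np.errstate(invalid="ignore"):
        p_cross = np.where(total > 0, cross / np.maximum(total, 1), np.nan)
    if norm_const > 0:
        normalised = p_cross / norm_const
    else:  # one mark absent: raw p_cross is 0 but the normalised MCF is undefined
        normalised = np.full(n_bins, np.nan)
    centred = normalised - 1.0

    env_low = np.full(n_bins, np.nan)
    env_high = np.full(n_bins, np.nan)
    if n_permutations > 0 and norm_const > 0:
        rng = np.random.default_rng(seed)
        null = np.full((n_permutations, n_bins), np.nan)
        for p in range(n_permutations):
            cross_p = np.zeros(n_bins, dtype=np.int64)
            for pairs, bin_idx, labels in per_roi:
                perm = rng.permutation(labels)
                is_cross = perm[pairs[:, 0]] != perm[pairs[:, 1]]
                cross_p += np.bincount(bin_idx[is_cross], minlength=n_bins)
            with np.errstate(invalid="ignore"):
                null[p] = np.where(total > 0, cross_p / np.maximum(total, 1), np.nan) / norm_const - 1.0
        nonempty = total > 0
        env_low[nonempty] = np.quantile(null[:, nonempty], 0.025, axis=0)
        env_high[nonempty] = np.quantile(null[:, nonempty], 0.975, axis=0)

    return MCFResult(
        mark_a=mark_a,
        mark_b=mark_b,
        bin_edges=bin_edges,
        n_pairs=total,
        p_cross=p_cross,
        normalised=normalised,
        centred=centred,
        envelope_low=env_low,
        envelope_high=env_high,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class ExclusivityVerdict:
    """Per-bin and summary classification of the MCF against its null envelope."""

    per_bin: list[str]  # "repulsion" / "random" / "attraction" / "empty"
    summary: str
    scale_limit: float

    def to_document(self) -> ResultDocument:
        meta = {"summary": self.summary, "scale_limit_nm": self.scale_limit}
        return ResultDocument(
            kind="ExclusivityVerdict",
            meta=meta,
            table=pd.DataFrame({"verdict": self.per_bin}),
        )


def exclusivity_verdict(mcf: MCFResult, scale_limit: float = 200.0) -> ExclusivityVerdict:
    """Classify each bin vs the null envelope; summarise bins below ``scale_limit``.

    A bin is "repulsion" if the centred MCF lies below the lower envelope,
    "attraction" if above the upper, else "random".  The summary is the
    majority verdict over non-empty bins whose centre is below
    ``scale_limit`` (ties resolve to "random").
    """
    if mcf.n_permutations == 0:
        raise AnalysisError("verdict requires an MCF computed with a null envelope")
    per_bin = []
    for c, lo, hi, n in zip(mcf.centred, mcf.envelope_low, mcf.envelope_high, mcf.n_pairs):
        if n == 0:
            per_bin.append("empty")
        elif c < lo:
            per_bin.append("repulsion")
        elif c > hi:
            per_bin.append("attraction")
        else:
            per_bin.append("random")
    in_scope = [
        v
        for v, centre in zip(per_bin, mcf.bin_centres)
        if centre < scale_limit and v != "empty"
    ]
    if not in_scope:
        raise AnalysisError(f"no non-empty bins below {scale_limit} nm")
    counts = {v: in_scope.count(v) for v in ("repulsion", "random", "attraction")}
    best = max(counts.values())
    leaders = [v for v, c in counts.items() if c == best]
    summary = leaders[0] if len(leaders) == 1 else "random"
    return ExclusivityVerdict(per_bin=per_bin, summary=summary, scale_limit=scale_limit)
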
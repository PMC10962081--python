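"""k-nearest-neighbour association of histone marks with elongating polymerase.

For every localisation of a mark, the Euclidean distance to its k-th nearest
reference localisation (RPol-PSer2, Ser2-phosphorylated RNA polymerase II) is
computed; k defaults to {5, 9, 21} so the statistic ignores isolated false
localisations while staying within the nearest cluster.  Per-ROI empirical
distribution functions are summarised at the median and the 90% quantile and
compared between two marks with a Welch t-test across ROIs, the direction of
the effect being the mark with the smaller mean quantile.

Quantiles use the right-continuous empirical convention: the smallest datum
whose cumulative probability reaches q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

from .exceptions import InsufficientDataError, ValidationError
from .io_formats import LocalisationTable, ResultDocument

DEFAULT_KS = (5, 9, 21)


def empirical_quantile(values: np.ndarray, q: float) -> float:
    """Right-continuous empirical quantile: smallest datum with F(x) >= q."""
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) == 0:
        raise InsufficientDataError("quantile of empty sample")
    idx = max(int(np.ceil(q * len(values))) - 1, 0)
    return float(values[idx])


@dataclass
class KnnResult:
    """k-th nearest reference-localisation distance for every mark localisation."""

    mark: str
    reference: str
    k: int
    roi_id: str
    distances: np.ndarray  # nm, one per mark localisation

    @property
    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted distances, cumulative probabilities)."""
        d = np.sort(self.distances)
        return d, np.arange(1, len(d) + 1) / len(d)

    @property
    def median(self) -> float:
        return empirical_quantile(self.distances, 0.5)

    @property
    def q90(self) -> float:
        return empirical_quantile(self.distances, 0.9)

    def to_document(self) -> ResultDocument:
        meta = {
            "mark": self.mark,
            "reference": self.reference,
            "k": self.k,
            "roi": self.roi_id,
            "median_nm": self.median,
            "q90_nm": self.q90,
        }
        return ResultDocument(
            kind="KnnResult", meta=meta, table=pd.DataFrame({"distance_nm": self.distances})
        )


def knn_distances(
    marks: LocalisationTable, reference: LocalisationTable, k: int
) -> KnnResult:
    """Distance from each mark localisation to its k-th nearest reference point.

    Both tables are taken as one ROI's worth of points (use
    :func:`knn_by_roi` to split a mixed table).
    """
    if len(reference) < k:
        raise InsufficientDataError(
            f"reference has {len(reference)} localisations, fewer than k={k}"
        )
    if len(marks) == 0:
        raise InsufficientDataError("no mark localisations")
    d, _ = cKDTree(reference.coords()).query(marks.coords(), k=k)
    dist = d[:, k - 1] if k > 1 else np.atleast_1d(d)
    rois = set(marks.rois) | set(reference.rois)
    roi_id = rois.pop() if len(rois) == 1 else "pooled"
    return KnnResult(
        mark=marks.marks[0],
        reference=reference.marks[0],
        k=k,
        roi_id=roi_id,
        distances=np.asarray(dist, dtype=float),
    )


def knn_by_roi(
    table: LocalisationTable, mark: str, reference: str, k: int
) -> list[KnnResult]:
    """Per-ROI knn distances of ``mark`` to ``reference`` within one mixed table.

    ROIs with fewer than k reference localisations or no mark localisations
    are skipped.
    """
    results = []
    for roi_id in table.rois:
        sub = table.for_roi(roi_id)
        m, r = sub.for_mark(mark), sub.for_mark(reference)
        if len(r) < k or len(m) == 0:
            continue
        results.append(knn_distances(m, r, k))
    return results


def knn_profile(
    marks: LocalisationTable,
    reference: LocalisationTable,
    ks: Sequence[int] = DEFAULT_KS,
) -> dict[int, KnnResult]:
    """knn distances for several k, asserting monotonicity in k as a robustness check."""
    out = {k: knn_distances(marks, reference, k) for k in sorted(ks)}
    ks_sorted = sorted(out)
    for k_lo, k_hi in zip(ks_sorted, ks_sorted[1:]):
        if np.any(out[k_hi].distances < out[k_lo].distances - 1e-9):
            raise AssertionError("knn distances must be non-decreasing in k")
    return out


@dataclass
class AssociationComparison:
    """Across-ROI comparison of one quantile of knn distances between two marks."""

    mark_a: str
    mark_b: str
    k: int
    quantile: float
    per_roi_a: np.ndarray
    per_roi_b: np.ndarray
    t_statistic: float
    p_value: float
    direction: str  # which mark sits closer to the reference

    def to_document(self) -> ResultDocument:
        rows = [
            {"mark": self.mark_a, "roi_quantile_nm": v} for v in self.per_roi_a
        ] + [{"mark": self.mark_b, "roi_quantile_nm": v} for v in self.per_roi_b]
        meta = {
            "mark_a": self.mark_a,
            "mark_b": self.mark_b,
            "k": self.k,
            "quantile": self.quantile,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "direction": self.direction,
        }
        return ResultDocument(kind="AssociationComparison", meta=meta, table=pd.DataFrame(rows))


def compare_association(
    a: Sequence[KnnResult], b: Sequence[KnnResult], quantile: float = 0.9
) -> AssociationComparison:
    """Welch t-test of per-ROI knn-distance quantiles between two marks."""
    if not a or not b:
        raise InsufficientDataError("empty knn result collection")
    ks = {r.k for r in a} | {r.k for r in b}
    if len(ks) != 1:
        raise ValidationError(f"mismatched k between inputs: {sorted(ks)}")
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 ROIs per mark")
    qa = np.array([empirical_quantile(r.distances, quantile) for r in a])
    qb = np.array([empirical_quantile(r.distances, quantile) for r in b])
    t, p = ttest_ind(qa, qb, equal_var=False)
    direction = a[0].mark if qa.mean() < qb.mean() else b[0].mark
    return AssociationComparison(
        mark_a=a[0].mark,
        mark_b=b[0].mark,
        k=ks.pop(),
        quantile=quantile,
        per_roi_a=qa,
        per_roi_b=qb,
        t_statistic=float(t),
        p_value=float(p),
        direction=direction,
    )
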
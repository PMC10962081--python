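"""1-D analyses of paired-channel intensity profiles along fibres.

Covers the STED line-scan workflow: extract a two-channel profile along a
polyline ROI from a pixel image (bilinear interpolation, uniform arc-length
sampling), detect intensity peaks with an sd-relative prominence threshold
(the "tolerance factor"), pool inter-peak spacings, and cross-correlate the
two channels over a lag range to find the displacement of one signal relative
to the other.  Per-ROI best lags that fail the |r| > 1.96/sqrt(n) significance
cut are discarded before displacement medians are compared between conditions
with a Welch t-test.

Sign convention: a positive lag means channel B is displaced towards larger
arc length relative to channel A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.ndimage import map_coordinates
from scipy.stats import ttest_ind

from .exceptions import AnalysisError, InsufficientDataError, ValidationError
from .io_formats import IntensityProfile, PolylineROI, ResultDocument

#: two-sided 5% normal quantile used in the correlation significance cut
SIGNIFICANCE_MULTIPLIER = 1.96


def extract_profile(
    grid: np.ndarray, pixel_size: float, roi: PolylineROI, step: float
) -> IntensityProfile:
    """Sample a two-channel image along a polyline ROI at uniform arc steps.

    ``grid`` is (2, H, W) with pixel centres at ``(i + 0.5) * pixel_size`` nm;
    values between centres are bilinearly interpolated.  The profile has
    ``floor(arc_length / step) + 1`` samples.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3 or grid.shape[0] != 2:
        raise ValidationError("grid must be a (2, H, W) two-channel image")
    if step <= 0:
        raise ValidationError("step must be > 0")
    h, w = grid.shape[1:]
    for vi, (vx, vy) in enumerate(roi.vertices):
        if not (0.0 <= vx <= w * pixel_size and 0.0 <= vy <= h * pixel_size):
            raise ValidationError(
                f"ROI {roi.roi_id!r} vertex {vi} at ({vx}, {vy}) nm is outside the image"
            )
    # arc-length parametrisation of the polyline
    seg = np.diff(roi.vertices, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arcs = np.concatenate([[0.0], np.cumsum(seglen)])
    n = int(np.floor(arcs[-1] / step)) + 1
    s = np.arange(n) * step
    x = np.interp(s, arcs, roi.vertices[:, 0])
    y = np.interp(s, arcs, roi.vertices[:, 1])
    rows = y / pixel_size - 0.5
    cols = x / pixel_size - 0.5
    channels = [
        map_coordinates(grid[c], [rows, cols], order=1, mode="nearest") for c in (0, 1)
    ]
    return IntensityProfile(roi.roi_id, step, channels[0], channels[1])


@dataclass
class PeakSet:
    """Detected intensity peaks of one channel along one ROI, in arc-length nm."""

    roi_id: str
    positions: np.ndarray  # strictly increasing, nm
    tolerance_factor: float
    channel: str

    def __len__(self) -> int:
        return len(self.positions)


def find_peaks(
    profile: IntensityProfile, channel: str = "b", tolerance_factor: float = 0.17
) -> PeakSet:
    """Detect local maxima whose prominence exceeds ``tolerance_factor`` × channel sd.

    Prominence is the height of a maximum above the higher of the two
    flanking minima that delimit it; sd is the population standard deviation
    of the channel, so detection is invariant to affine intensity rescaling.
    Plateau peaks report their arc-length midpoint; profile endpoints are
    never peaks.  A zero-variance channel yields no peaks (with a warning).
    """
    values = profile.channel_a if channel == "a" else profile.channel_b
    if profile.n < 3:
        raise ValidationError("peak detection needs >= 3 samples")
    sd = float(np.std(values))
    if sd == 0.0:
        warnings.warn(f"profile {profile.roi_id!r}: zero-variance channel, no peaks")
        return PeakSet(profile.roi_id, np.empty(0), tolerance_factor, channel)
    idx, props = _signal.find_peaks(
        values, prominence=tolerance_factor * sd, plateau_size=(1, None)
    )
    positions = 0.5 * (props["left_edges"] + props["right_edges"]) * profile.step
    return PeakSet(profile.roi_id, positions, tolerance_factor, channel)


@dataclass
class SpacingStats:
    """Successive inter-peak distances pooled across ROIs."""

    spacings: np.ndarray
    mean: float
    sd: float  # sample sd (ddof=1); NaN for a single spacing
    n: int

    def to_document(self) -> ResultDocument:
        meta = {"mean_nm": self.mean, "sd_nm": self.sd, "n": self.n}
        return ResultDocument(
            kind="SpacingStats", meta=meta, table=pd.DataFrame({"spacing_nm": self.spacings})
        )


def spacing_stats(peaksets: Sequence[PeakSet]) -> SpacingStats:
    """Pool successive peak differences across ROIs; mean and sample sd."""
    diffs = [np.diff(ps.positions) for ps in peaksets if len(ps) >= 2]
    if not diffs:
        raise InsufficientDataError("no ROI with >= 2 peaks")
    spacings = np.concatenate(diffs)
    sd = float(np.std(spacings, ddof=1)) if len(spacings) > 1 else float("nan")
    return SpacingStats(spacings, float(spacings.mean()), sd, len(spacings))


@dataclass
class CrossCorrResult:
    """Lagged Pearson correlation of the two channels of one profile."""

    roi_id: str
    lags: np.ndarray  # nm, symmetric around 0 at the profile step
    corr: np.ndarray  # Pearson r per lag, NaN where a segment is constant
    best_lag: float  # nm, at maximal |corr| (ties -> smallest |lag|)
    best_corr: float
    n: int  # overlap sample count at the best lag
    significant: bool  # |best_corr| > 1.96 / sqrt(n)

    def to_document(self) -> ResultDocument:
        meta = {
            "roi": self.roi_id,
            "best_lag_nm": self.best_lag,
            "best_corr": self.best_corr,
            "n": self.n,
            "significant": self.significant,
        }
        return ResultDocument(
            kind="CrossCorrResult",
            meta=meta,
            table=pd.DataFrame({"lag_nm": self.lags, "corr": self.corr}),
        )


def cross_correlate(profile: IntensityProfile, max_lag: float) -> CrossCorrResult:
    """Normalised cross-correlation of channel B against channel A.

    At each integer-sample lag in ±``max_lag`` the Pearson correlation is
    recomputed on the overlapping segments (each mean-subtracted and
    sd-normalised over the overlap), so |r| <= 1 holds at every lag and no
    zero padding is involved.  The best lag maximises |r|; ties resolve to
    the smallest |lag| (negative before positive).  The significance flag
    applies the |r| > 1.96/sqrt(n) cut with n the overlap length at the best
    lag.
    """
    a, b, n, step = profile.channel_a, profile.channel_b, profile.n, profile.step
    if n < 3:
        raise ValidationError("cross-correlation needs >= 3 samples")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise AnalysisError(f"profile {profile.roi_id!r}: zero-variance channel")
    max_k = int(np.floor(max_lag / step))
    if max_k > n - 3:
        raise ValidationError("max_lag leaves fewer than 3 overlapping samples")
    ks = np.arange(-max_k, max_k + 1)
    corr = np.full(len(ks), np.nan)
    overlap = np.empty(len(ks), dtype=int)
    for i, k in enumerate(ks):
        if k >= 0:
            sa, sb = a[: n - k], b[k:]
        else:
            sa, sb = a[-k:], b[: n + k]
        overlap[i] = len(sa)
        da, db = sa - sa.mean(), sb - sb.mean()
        denom = np.sqrt((da**2).sum() * (db**2).sum())
        if denom > 0:
            corr[i] = float((da * db).sum() / denom)
    finite = np.isfinite(corr)
    if not finite.any():
        raise AnalysisError(f"profile {profile.roi_id!r}: correlation undefined at all lags")
    # maximise |corr|; break ties toward the smallest absolute lag
    order = np.lexsort((ks, np.abs(ks), -np.abs(np.where(finite, corr, -np.inf))))
    best = order[0]
    n_best = int(overlap[best])
    best_corr = float(corr[best])
    return CrossCorrResult(
        roi_id=profile.roi_id,
        lags=ks * step,
        corr=corr,
        best_lag=float(ks[best] * step),
        best_corr=best_corr,
        n=n_best,
        significant=bool(abs(best_corr) > SIGNIFICANCE_MULTIPLIER / np.sqrt(n_best)),
    )


@dataclass
class DisplacementSummary:
    """Absolute best lags of one condition's significant ROIs, with the Welch comparison."""

    condition: str
    other_condition: str
    abs_lags: np.ndarray
    median_abs_lag: float
    t_statistic: float
    p_value: float
    n_discarded: int  # ROIs dropped by the significance cut

    def to_document(self) -> ResultDocument:
        meta = {
            "condition": self.condition,
            "other_condition": self.other_condition,
            "median_abs_lag_nm": self.median_abs_lag,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_discarded": self.n_discarded,
        }
        return ResultDocument(
            kind="DisplacementSummary",
            meta=meta,
            table=pd.DataFrame({"abs_lag_nm": self.abs_lags}),
        )


def displacement_summary(
    results_a: Sequence[CrossCorrResult],
    results_b: Sequence[CrossCorrResult],
    condition_a: str = "A",
    condition_b: str = "B",
) -> tuple[DisplacementSummary, DisplacementSummary]:
    """Median absolute displacement per condition and a Welch t-test between them.

    Non-significant ROIs are discarded before anything else, mirroring the
    correlation workflow's 5% cut.
    """
    sig_a = np.array([abs(r.best_lag) for r in results_a if r.significant])
    sig_b = np.array([abs(r.best_lag) for r in results_b if r.significant])
    for lags, name in ((sig_a, condition_a), (sig_b, condition_b)):
        if len(lags) < 2:
            raise InsufficientDataError(
                f"condition {name!r}: fewer than 2 significant ROIs"
            )
    t, p = ttest_ind(sig_a, sig_b, equal_var=False)
    mk = lambda lags, cond, other, total: DisplacementSummary(
        condition=cond,
        other_condition=other,
        abs_lags=lags,
        median_abs_lag=float(np.median(lags)),
        t_statistic=float(t),
        p_value=float(p),
        n_discarded=total - len(lags),
    )
    return (
        mk(sig_a, condition_a, condition_b, len(results_a)),
        mk(sig_b, condition_b, condition_a, len(results_b)),
    )
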
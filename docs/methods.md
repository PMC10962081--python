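# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `loopstate`, and what the synthetic-data generator does and
does not emulate.

## Data model

A **localisation table** is a marked planar point pattern: positions (x, y)
in nm, a mark label per point (histone modification or RPol-PSer2 channel),
and an ROI identifier.  ROIs represent fibres (or nuclear-interior crops)
from different cells: no analysis ever pools *pairs* or *clusters* across
ROIs, only per-ROI summary statistics.  Coordinates are continuous 2-D with
arbitrary origin; z, frame and intensity columns of input files are ignored.
An **intensity profile** is a pair of non-negative channel series sampled at
a constant arc-length step (20 nm by default, the STED pixel pitch) along a
fibre polyline.

Throughout, the Gaussian FWHM↔σ conversion is fixed at
FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ.

## Mean-shift clustering and cluster width

Localisations of one mark are clustered per ROI by mean shift with a
Gaussian kernel of bandwidth σ = `bandwidth_sigma` (default 50 nm, the
cluster length scale).  Each point is run uphill on the kernel density
estimate until it moves less than `convergence_tol` (0.1 nm) or `max_iter`
(500) iterations elapse; the kernel is truncated at 5 bandwidths for speed
(the neglected weight is < 4·10⁻⁶ of the peak).  Converged mode positions
within `merge_radius` (default σ/2) are pooled by single linkage; pools with
at least `min_points` (default 15) members become clusters with centre equal
to the member mean, and points converging to discarded modes stay
unassigned.  The result is deterministic and invariant to input row order
(verified to 10⁻⁹ nm).  A flat-kernel variant (uniform weights within one
bandwidth) is available for sensitivity checks; it matches
`sklearn.cluster.MeanShift` on well-separated clusters.

Cluster width is the FWHM of an isotropic 2-D Gaussian fitted to member
displacements from the centre.  With n members and squared displacement sum
D² about the member mean, D²/σ² is χ² with m = 2(n−1) degrees of freedom, so
the estimator is

σ̂ = √(D²/m) / c₄(m),  c₄(m) = √(2/m)·Γ((m+1)/2)/Γ(m/2),

which removes both the mean-estimation bias and the square-root (chi) bias;
FWHM = 2.3548·σ̂.  A cluster whose members all coincide has no defined width
(NaN, with a warning).  On simulated isotropic clusters the median estimate
is unbiased to well under 1 nm at n ≈ 60.

Width distributions report the median, the interquartile range and a
histogram normalised to probabilities (frequencies divided by the number of
histogrammed clusters).  All quantiles of widths use linear interpolation of
order statistics (`numpy` default).  Two width samples are compared by
100·(median_b − median_a)/median_a and a two-sided Mann–Whitney rank-sum
test; when more than two marks are compared, Holm step-down adjustment of the
p-values is available.

The FWHM definition (radial ML fit, not a histogram fit to a rendered
image) is a pinned choice; other definitions would shift absolute widths by
a few per cent.

## Overlap fraction

One mark is clustered; for each localisation of the *other* mark the
distance to the nearest same-ROI cluster centre is computed, and the
fraction within `radius` (default 50 nm, the average cluster half-width
scale) is the ROI's overlap fraction.  The median across ROIs is reported
(a pooled variant exists), and the analysis is run in both directions to
avoid bias from unequal mark abundance.  ROIs without clusters contribute no
fraction.

## Mark connection function (MCF)

For distance bins [r₁, r₂) (default 20-nm bins from 0 to 500 nm), the raw
statistic is

p_cross(bin) = (# same-ROI unordered pairs in the bin with different marks) /
               (# same-ROI unordered pairs in the bin),

pooled over ROIs by summing counts (so ROIs are weighted by their pair
counts).  Division by 2·p̂_A·p̂_B — the cross probability under random
labelling with the observed pooled proportions — gives the `normalised`
field (1 = random); `centred` = normalised − 1 serves the zero-centred
presentation.  Both are emitted.  Empty bins are flagged (NaN), never
silently dropped.

The null model is **random labelling**: marks are permuted over the fixed
positions, independently within each ROI; the pointwise 2.5%/97.5% quantiles
of the centred statistic over `n_permutations` (default 199) permutations
form the envelope.  A bin is classed "repulsion" below the envelope,
"attraction" above it, otherwise "random"; the summary verdict is the
majority class over non-empty bins below `scale_limit` (default 200 nm),
ties resolving to "random".

No edge correction is applied: the MCF is a ratio of pair counts at the same
distance, so window geometry largely cancels; an optional periodic
(min-image) distance mode supports rectangular simulation windows.  Note
that within-ROI permutation also centres the envelope slightly below zero
when mark proportions differ between ROIs — the observed statistic is
subject to the same structure, so the comparison remains calibrated
(verified: under random allocation ~95% of bins fall inside the envelope).

Two structural facts worth knowing when interpreting verdicts: (i) if every
cluster carries both marks at the global mixing ratio, the MCF is exactly
random — attraction requires cross pairs to *dominate* short distances
(e.g. co-localised pairs); (ii) fully exclusive alternating clusters show
genuine weak attraction at the inter-cluster spacing, so the repulsion range
reflects the within-cluster scale.

## Profile analysis

**Extraction.** A two-channel pixel image (pixel centres at
(i + 0.5)·pixel_size nm) is sampled along a polyline ROI at uniform
arc-length steps by bilinear interpolation; sample count is
⌊arc length / step⌋ + 1.

**Peak detection.** A local maximum is kept iff its prominence — its height
above the higher of the two flanking minima delimiting it — is at least
`tolerance_factor` × the population sd of the channel.  The sd-relative
threshold makes detection invariant to affine intensity rescaling and makes
0.17 a permissive and 1.0 a stringent setting.  Plateaus report their
arc-length midpoint; endpoints are never peaks.  Implementation:
`scipy.signal.find_peaks` with a prominence threshold.

**Spacings.** Successive peak differences are pooled across ROIs; the mean
and the sample sd (ddof = 1) are reported.  Two resolution effects bound
what any tolerance can recover when spacings are broadly distributed
(e.g. gamma with mean 276 nm, sd 164 nm under 100 nm-wide peaks): peaks
closer than about one peak FWHM merge (inflating the mean), while noise can
add spurious peaks at low thresholds (deflating it).  The recommended
calibration, used by the acceptance script, selects the tolerance on a
*pilot simulation with known truth* as the grid value whose detected peak
count matches the true count — balancing the two error modes — and is
near-perfect in recall on noiseless controls.

**Cross-correlation.** For integer-sample lags within ±`max_lag`, the
Pearson correlation of the overlapping channel segments is recomputed per
lag (each segment mean-subtracted and sd-normalised over the overlap, no
zero padding), so |r| ≤ 1 at every lag.  The best lag maximises |r|, ties
resolving to the smallest |lag|; the significance flag applies the
|r| > 1.96/√n cut with n the overlap length at the best lag.  Positive lag
means channel B displaced towards larger arc length;
best_lag(a, b) = −best_lag(b, a).  Because the best lag is a maximum over
many scanned lags, pure-noise profiles exceed the per-lag cutoff far more
often than 5% — the cut is a per-lag criterion applied to the selected lag,
as in the source workflow, not a family-wise test.  Displacement summaries
use significant ROIs only: median |best lag| per condition and a two-sided
Welch (unequal-variance) t-test between conditions.

## Polymerase association (knn distances)

For each mark localisation the distance to its k-th nearest reference
(RPol-PSer2) localisation in the same ROI is computed (k ∈ {5, 9, 21} by
default: large enough to ignore isolated false localisations, small enough
to stay within the nearest cluster).  Distances are measured from mark to
reference; the opposite direction is a role swap.  Per-ROI ECDFs are
summarised at the median and 90% quantile using the right-continuous
empirical convention (smallest datum with cumulative probability ≥ q), and
marks are compared by a Welch t-test across per-ROI quantiles, direction
given by the smaller mean.  knn distances are checked monotone
non-decreasing in k on every multi-k run.

## Synthetic-data generator

**Fibres.** A fibre is a 2-D random walk of 10-nm steps whose heading turns
by at most `curvature` radians per step (default 0.3; 0 gives a straight
fibre — used when a guaranteed minimum centre separation matters, since a
random walk can self-approach).  Cluster centres sit along the arc at
spacings drawn from a gamma distribution matched to (`spacing_mean`,
`spacing_sd`) — gamma rather than normal to guarantee positivity while
matching a reported mean ± sd.  Each cluster draws Poisson(`locs_per_cluster_mean`)
localisations from an isotropic Gaussian with σ = cluster_fwhm/2.3548.  With
probability `exclusivity` a cluster is single-class (class chosen by fair
coin), otherwise each localisation flips a fair coin.  Defaults (50 nm FWHM,
~200 nm spacings, ~60 localisations per cluster, two fully exclusive marks)
reflect the imaged fibre geometry.

**Contamination** relocates a per-ROI fraction of second-class localisations
to uniform positions within a 50-nm disc around randomly chosen first-class
cluster centres.  Because points are moved (not relabelled), the realised
overlap fraction is counted exactly and recorded in the truth, making
overlap-recovery tests sharp.  **Background** adds per-class uniform points
at `background_rate` per µm² over the fibre bounding box.

**Profiles.** Channel A is a unit-amplitude Gaussian peak train (FWHM
`peak_fwhm`, gamma spacings); channel B is channel A circularly rolled by
`channel_shift` rounded to whole samples (the realised shift is recorded as
the truth) plus i.i.d. Gaussian noise of sd `noise_sd` × peak amplitude
(SNR = 1/noise_sd), clipped at zero to keep intensities non-negative (the
clip affects only the noise baseline).

Not modelled: fluorophore photophysics and multi-blinking (localisation
precision is folded into the cluster σ), 3-D structure, label density
variation, rendered pixel images of localisations, realistic fibre
curvature statistics.  Passing recovery tests therefore demonstrates the
estimators are correct for the stated point-process/peak-train model, not
that real-data values are reproduced: real acquisitions add detection
artefacts, manual ROI curation and unknown true widths/spacings.

Every generator is a deterministic function of its config seed.  The
pipeline runner derives per-stage seeds as SHA-256(global seed : stage
name) mod 2³¹, so adding stages never perturbs existing streams.

## Degenerate inputs and error policy

Empty mark selections cluster to an empty set (not an error); empty cluster
sets make overlap undefined (error); single-mark tables give p_cross = 0
with undefined normalised MCF; zero-variance profile channels yield no peaks
(warning) but make correlation undefined (error); fewer than k reference
points, fewer than 2 significant ROIs, or fewer than 2 widths per group are
errors naming the deficit.  Result files round-trip all floats at 17
significant digits.

## Problem sizes

The default verification runs use desk-scale simulations chosen to give
comfortable Monte-Carlo margins: ~300 clusters for width recovery, 20
profiles for displacement recovery, ~200 spacings for spacing recovery, 10
ROIs for overlap recovery, 2,000 points × 100 allocations for the
random-labelling MCF baseline.  Each completes in seconds on one CPU.
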
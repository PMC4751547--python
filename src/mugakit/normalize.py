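"""Polar intensity transform and LRR/BAF normalization.

Two-channel intensities (x, y) are re-expressed as a channel sum
``R = x + y`` and a normalized angle ``theta = (2/pi) * arctan(y/x)``,
which is 0 at pure x signal (the A allele) and 1 at pure y signal (B).
Per-marker centroids of the three canonical genotype clusters (AA, AB,
BB) are estimated as trimmed means of R and theta over samples called in
each cluster; the B-allele frequency (BAF) is then a piecewise-linear
rescaling of theta anchored at 0 / 0.5 / 1 on the three centroids, and
the log R ratio (LRR) is log2 of observed R over the R expected at the
observed theta.  Deviations of LRR from zero indicate copy-number
change; BAF near 0, 0.5 and 1 indicates the three genotype states.

A thresholded quantile normalization (:func:`tqn_normalize`) can align
each sample's per-channel intensity distribution to a reference batch
before the polar transform, capping the per-probe adjustment ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PolarIntensity",
    "ClusterCentroids",
    "NormalizedSignal",
    "polar_transform",
    "estimate_centroids",
    "compute_baf_lrr",
    "tqn_normalize",
]


@dataclass
class PolarIntensity:
    """Arrays of channel-sum R >= 0 and normalized angle theta in [0, 1].

    theta is NaN where both channels were zero (undefined angle).
    """

    R: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.R.shape != self.theta.shape:
            raise ValueError("R and theta must have the same shape")


@dataclass
class ClusterCentroids:
    """Per-cluster (theta, R) centroids for one marker; absent = NaN."""

    theta: dict[str, float]  # keys AA, AB, BB
    R: dict[str, float]
    n_support: dict[str, int]

    def present(self) -> list[str]:
        return [c for c in ("AA", "AB", "BB") if not math.isnan(self.theta[c])]


@dataclass
class NormalizedSignal:
    """Per-observation BAF in [0, 1] and LRR in log2 units (NaN = missing)."""

    baf: np.ndarray
    lrr: np.ndarray
    low_confidence: bool = False


def polar_transform(x, y) -> PolarIntensity:
    """Map channel intensities to (R, theta).

    R = x + y; theta = (2/pi) * arctan(y/x), so theta = 0 on the x axis
    (pure A signal) and 1 on the y axis (pure B).  Points with both
    channels zero get theta = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intensities must be nonnegative")
    R = x + y
    with np.errstate(invalid="ignore"):
        theta = (2.0 / math.pi) * np.arctan2(y, x)
    theta = np.where(R > 0, theta, np.nan)
    return PolarIntensity(R=R, theta=theta)


def _trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean after dropping trim/2 of the values from each tail by rank."""
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan
    return float(stats.trim_mean(values, trim / 2.0))


def estimate_centroids(
    polar: PolarIntensity, calls: np.ndarray, trim: float = 0.05
) -> ClusterCentroids:
    """Trimmed-mean genotype-cluster centroids for one marker.

    ``calls`` holds string or :class:`~mugakit.datamodel.Call` codes
    aligned with the polar arrays.  Per cluster, the most extreme
    ``trim`` fraction of values (trim/2 per tail, theta and R trimmed
    independently by rank) is omitted before averaging.  Clusters with no
    supporting sample are absent (NaN).
    """
    from .datamodel import Call

    calls = np.asarray(calls)
    if calls.dtype.kind in "iu":
        code = {int(Call.AA): "AA", int(Call.AB): "AB", int(Call.BB): "BB"}
        labels = np.array([code.get(int(c), "N") for c in calls])
    else:
        labels = calls.astype(str)
    theta_c, r_c, n_c = {}, {}, {}
    for cluster in ("AA", "AB", "BB"):
        mask = (labels == cluster) & ~np.isnan(polar.theta)
        n_c[cluster] = int(mask.sum())
        theta_c[cluster] = _trimmed_mean(polar.theta[mask], trim)
        r_c[cluster] = _trimmed_mean(polar.R[mask], trim)
    return ClusterCentroids(theta=theta_c, R=r_c, n_support=n_c)


def compute_baf_lrr(
    polar: PolarIntensity, centroids: ClusterCentroids
) -> NormalizedSignal:
    """BAF and LRR for one marker's observations given its centroids.

    BAF maps theta piecewise-linearly through (theta_AA, 0),
    (theta_AB, 0.5), (theta_BB, 1), clipped to [0, 1] outside the
    centroid range.  The expected R at the observed theta is the linear
    interpolation of centroid R values (clamped to the nearest centroid
    outside the range) and LRR = log2(R / R_expected).  Markers with
    fewer than two observed clusters yield a low-confidence signal: BAF
    missing, LRR computed against the single cluster's R.
    """
    present = centroids.present()
    theta = np.asarray(polar.theta, dtype=float)
    R = np.asarray(polar.R, dtype=float)
    baf = np.full_like(theta, np.nan)
    lrr = np.full_like(theta, np.nan)
    if not present:
        return NormalizedSignal(baf=baf, lrr=lrr, low_confidence=True)

    t_anchor = np.array([centroids.theta[c] for c in present])
    order = np.argsort(t_anchor)
    t_anchor = t_anchor[order]
    r_anchor = np.array([centroids.R[c] for c in present])[order]
    baf_levels = {"AA": 0.0, "AB": 0.5, "BB": 1.0}
    b_anchor = np.array([baf_levels[present[i]] for i in order])

    ok = ~np.isnan(theta)
    if len(present) >= 2:
        baf[ok] = np.clip(np.interp(theta[ok], t_anchor, b_anchor), 0.0, 1.0)
    r_expected = np.interp(theta[ok], t_anchor, r_anchor)  # clamps outside
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(r_expected > 0, np.log2(R[ok] / r_expected), np.nan)
    lrr[ok] = vals
    return NormalizedSignal(baf=baf, lrr=lrr, low_confidence=len(present) < 2)


def tqn_normalize(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    reference_quantiles: np.ndarray,
    ratio_cap: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholded quantile normalization of a sample's two channels.

    Each channel's values (across markers, one sample) are mapped onto
    the reference quantile distribution by rank; the per-probe adjustment
    is then capped so normalized/raw stays within
    [1/ratio_cap, ratio_cap].  Returns (x, y, capped_mask).

    ``reference_quantiles`` is a sorted array of the reference batch's
    pooled per-channel intensity distribution (any length; it is
    resampled to the channel length by linear interpolation).
    """
    ref = np.sort(np.asarray(reference_quantiles, dtype=float))
    if ref.size == 0:
        raise ValueError("reference quantile array is empty")

    def map_channel(v: np.ndarray) -> np.ndarray:
        n = v.size
        order = np.argsort(v, kind="stable")
        grid = np.linspace(0, 1, n)
        target = np.interp(grid, np.linspace(0, 1, ref.size), ref)
        out = np.empty_like(v, dtype=float)
        out[order] = target
        return out

    x_raw = np.asarray(x_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    xq, yq = map_channel(x_raw), map_channel(y_raw)
    capped = np.zeros(x_raw.shape, dtype=bool)
    out = []
    for raw, q in ((x_raw, xq), (y_raw, yq)):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(raw > 0, q / raw, 1.0)
        clipped = np.clip(ratio, 1.0 / ratio_cap, ratio_cap)
        capped |= clipped != ratio
        out.append(np.where(raw > 0, raw * clipped, q))
    return out[0], out[1], capped
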
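"""Per-probe cluster analysis in the intensity plane.

Two tasks live here:

*Multiallelic cluster detection* (:func:`cluster_multiallelic`).  A
nominally biallelic probe can show more than three clusters in the
(x, y) intensity plane when off-target variation creates additional
hybridization alleles.  A trio-informed nonparametric procedure counts
clusters: founder-strain replicates seed one cluster per founder, seed
clusters are iteratively merged when mutually nearest and sufficiently
close; F1 samples are then assigned to their parents' shared cluster or
form candidate heterozygous clusters, followed by another merge pass.

*Construct presence calling* (:func:`call_constructs`).  Probes
targeting engineered constructs (transgenes, reporters, resistance
cassettes) have no true alternate allele; presence is called from raw
fluorescence along the informative axis only, summed across a target's
probes, by fitting a two-component (absence vs presence) univariate
Gaussian mixture to the log10 sum intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "ConstructCall",
    "GaussianMixture1D",
    "cluster_multiallelic",
    "fit_gmm_1d",
    "call_constructs",
]


@dataclass
class ClusterModel:
    """Final clusters for one marker and the sample -> cluster assignment."""

    centers: np.ndarray  # (n_clusters, 2) in the (x, y) plane
    assignment: dict[str, int]  # sample label -> cluster index
    n_clusters: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.n_clusters != len(self.centers):
            raise ValueError("n_clusters inconsistent with centers")


def _theta_of(center: np.ndarray) -> float:
    return float(np.arctan2(center[1], center[0]))


class _Cluster:
    __slots__ = ("points", "members")

    def __init__(self, points: np.ndarray, members: list[str]):
        self.points = np.asarray(points, dtype=float).reshape(-1, 2)
        self.members = list(members)

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def merged(self, other: "_Cluster") -> "_Cluster":
        return _Cluster(
            np.vstack([self.points, other.points]), self.members + other.members
        )


def _median_spread(clusters: list[_Cluster]) -> float:
    """Median within-cluster point distance to its centroid (noise scale)."""
    devs = []
    for c in clusters:
        if len(c.points) > 1:
            devs.extend(np.linalg.norm(c.points - c.center, axis=1))
    return float(np.median(devs)) if devs else 0.0


def _merge_pass(
    clusters: list[_Cluster], merge_dist_factor: float
) -> list[_Cluster]:
    """Iteratively merge mutual nearest neighbors within the merge radius."""
    while len(clusters) > 1:
        spread = _median_spread(clusters)
        radius = merge_dist_factor * spread
        centers = np.array([c.center for c in clusters])
        dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(dist, np.inf)
        nn = dist.argmin(axis=1)
        best: tuple[int, int] | None = None
        for i in range(len(clusters)):
            j = nn[i]
            if nn[j] == i and i < j and dist[i, j] <= radius:
                if best is None or dist[i, j] < dist[best]:
                    best = (i, j)
        if best is None:
            break
        i, j = best
        merged = clusters[i].merged(clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters


def cluster_multiallelic(
    founder_points: dict[str, np.ndarray],
    f1_points: dict[tuple[str, str], np.ndarray],
    merge_dist_factor: float = 2.0,
) -> ClusterModel:
    """Trio-informed cluster count for one probe.

    ``founder_points`` maps each founder strain to an (n_replicates, 2)
    array of normalized (x, y) intensities; ``f1_points`` maps unordered
    parent pairs to the points of that F1 class.

    Step 1 seeds one cluster per founder (its replicate centroid) and
    merges clusters that are mutual nearest neighbors with centroids
    within ``merge_dist_factor`` times the median within-cluster spread.
    Step 2 assigns each F1 class to its parents' cluster when the parents
    share one, otherwise creates a candidate heterozygous cluster at the
    F1 centroid; the merge pass is then repeated over all clusters.

    Cluster labels in the output are ordered by the angle of the cluster
    center so repeated runs are comparable.
    """
    if not founder_points:
        raise ValueError("need at least one founder")
    for f, pts in founder_points.items():
        if np.asarray(pts).reshape(-1, 2).shape[0] == 0:
            raise ValueError(f"founder {f} has no points")

    clusters = [_Cluster(pts, [f]) for f, pts in founder_points.items()]
    clusters = _merge_pass(clusters, merge_dist_factor)

    def cluster_of(label: str) -> int | None:
        for k, c in enumerate(clusters):
            if label in c.members:
                return k
        return None

    for (p1, p2), pts in f1_points.items():
        label = f"{p1}x{p2}"
        k1, k2 = cluster_of(p1), cluster_of(p2)
        if k1 is not None and k1 == k2:
            c = clusters[k1]
            clusters[k1] = _Cluster(
                np.vstack([c.points, np.asarray(pts).reshape(-1, 2)]),
                c.members + [label],
            )
        else:
            clusters.append(_Cluster(pts, [label]))
    clusters = _merge_pass(clusters, merge_dist_factor)

    order = sorted(range(len(clusters)), key=lambda k: _theta_of(clusters[k].center))
    assignment: dict[str, int] = {}
    centers = []
    for rank, k in enumerate(order):
        centers.append(clusters[k].center)
        for m in clusters[k].members:
            assignment[m] = rank
    return ClusterModel(
        centers=np.array(centers), assignment=assignment, n_clusters=len(clusters)
    )


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture for construct presence calling
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixture1D:
    """Two-component univariate Gaussian mixture fitted by EM."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False

    def posterior_high(self, s: np.ndarray) -> np.ndarray:
        """Posterior probability of the higher-mean component."""
        hi = int(np.argmax(self.means))
        lo = 1 - hi
        log_p = np.stack([
            _log_normal(s, self.means[lo], self.sds[lo]) + np.log(self.weights[lo]),
            _log_normal(s, self.means[hi], self.sds[hi]) + np.log(self.weights[hi]),
        ])
        m = log_p.max(axis=0)
        p = np.exp(log_p - m)
        return p[1] / p.sum(axis=0)


def _log_normal(x, mu, sd):
    return -0.5 * np.log(2 * np.pi * sd**2) - (x - mu) ** 2 / (2 * sd**2)


def fit_gmm_1d(
    s: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_sd: float = 1e-4,
) -> GaussianMixture1D:
    """EM fit of a two-component Gaussian mixture to univariate data.

    Means are initialized at the 25th and 75th percentiles, standard
    deviations at the overall sd, weights at 0.5.  Iteration stops when
    the absolute log-likelihood change drops below ``tol``.  The
    log-likelihood trace is retained (it is nondecreasing).
    """
    s = np.asarray(s, dtype=float)
    mu = np.percentile(s, [25.0, 75.0]).astype(float)
    sd = np.full(2, max(float(s.std()), min_sd))
    w = np.array([0.5, 0.5])
    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_p = np.stack([
            _log_normal(s, mu[k], sd[k]) + np.log(w[k]) for k in range(2)
        ])
        m = log_p.max(axis=0)
        p = np.exp(log_p - m)
        tot = p.sum(axis=0)
        ll = float((m + np.log(tot)).sum())
        resp = p / tot
        lls.append(ll)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
        nk = resp.sum(axis=1)
        w = nk / s.size
        mu = (resp * s).sum(axis=1) / nk
        var = (resp * (s - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(np.maximum(var, min_sd**2))
    return GaussianMixture1D(
        means=mu, sds=sd, weights=w, log_likelihoods=lls, converged=converged
    )


@dataclass
class ConstructCall:
    sample_id: str
    target: str
    log10_sum: float
    posterior_present: float
    call: str  # "present" / "absent"
    non_separable: bool = False


def call_constructs(
    raw: dict[str, dict[str, float]],
    probe_targets: dict[str, str],
    informative_axis: dict[str, str],
    intensity_floor: float = 1.0,
    separation_sds: float = 2.0,
    targets: list[str] | None = None,
) -> list[ConstructCall]:
    """Presence/absence calls for construct targets.

    ``raw`` maps sample -> probe -> (x, y) raw intensity pair or a dict
    with keys "x"/"y"; ``probe_targets`` maps probe -> target construct;
    ``informative_axis`` maps probe -> "x" or "y".  Per sample and
    target, the raw intensity along the informative axis is summed across
    the target's probes (floored at ``intensity_floor``), log10-
    transformed, and a two-component Gaussian mixture is fitted across
    samples.  A sample is called present when the posterior of the
    higher-mean component exceeds 0.5.  If the fitted means differ by
    less than ``separation_sds`` times the pooled sd, the target is
    flagged non-separable and every call is absent (with the flag set).
    """
    by_target: dict[str, list[str]] = {t: [] for t in (targets or [])}
    for probe, target in probe_targets.items():
        by_target.setdefault(target, []).append(probe)
    out: list[ConstructCall] = []
    samples = list(raw)
    for target, probes in by_target.items():
        if not probes:
            raise ValueError(f"target {target} has no probes")
        sums = []
        for s in samples:
            total = 0.0
            for probe in probes:
                val = raw[s][probe]
                axis = informative_axis[probe]
                v = val[axis] if isinstance(val, dict) else val[0 if axis == "x" else 1]
                total += max(float(v), intensity_floor)
            sums.append(np.log10(total))
        svals = np.array(sums)
        gmm = fit_gmm_1d(svals)
        pooled_sd = float(np.sqrt(np.mean(gmm.sds**2)))
        non_sep = abs(gmm.means[1] - gmm.means[0]) < separation_sds * pooled_sd
        post = gmm.posterior_high(svals)
        for s, sv, p in zip(samples, svals, post):
            present = (not non_sep) and p > 0.5
            out.append(ConstructCall(
                sample_id=s,
                target=target,
                log10_sum=float(sv),
                posterior_present=float(p),
                call="present" if present else "absent",
                non_separable=bool(non_sep),
            ))
    return out
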
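"""Donor-mosaic reconstruction for congenic and background verification.

A sample's genome is modeled as a mosaic of segments copied from a panel
of candidate donor strains (e.g. an inbred background plus possible
introgressed donors).  Hidden states are the donors; the observation at
each marker is the sample's genotype call.  A call matching the donor's
is emitted with probability 1 - epsilon, a mismatching call with epsilon
(no-calls are uninformative and emitted uniformly).  Transitions between
adjacent markers switch donors with a probability scaled by the genetic
(cM) distance between them, so switch points concentrate where
recombination is likely.

The Viterbi path gives the segmentation; forward-backward posteriors are
attached per marker.  Donors whose path likelihoods are within a
log-likelihood margin on a segment are collapsed into an equivalence
group ("A|B"), which is how intervals consistent with several
indistinguishable substrains are reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import Call, GeneticMap

__all__ = ["HMMParams", "MosaicSegment", "MosaicResult", "viterbi_mosaic"]


@dataclass
class HMMParams:
    #: per-marker genotype error / donor-mismatch probability
    epsilon: float = 0.01
    #: expected donor-segment length in cM (sets the switch rate)
    expected_segment_cM: float = 10.0
    #: log-likelihood margin below which competing donors collapse
    margin_delta: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.expected_segment_cM <= 0:
            raise ValueError("expected_segment_cM must be positive")


@dataclass
class MosaicSegment:
    chromosome: str
    start_bp: int
    end_bp: int
    donors: frozenset[str]  # singleton unless collapsed
    mean_posterior: float
    n_markers: int

    @property
    def label(self) -> str:
        return "|".join(sorted(self.donors))


@dataclass
class MosaicResult:
    segments: list[MosaicSegment]
    path: np.ndarray  # Viterbi donor index per marker
    posteriors: np.ndarray  # (n_markers, n_donors), rows sum to 1
    donors: list[str]
    log_likelihood: float


def _emission_log(
    sample: np.ndarray, donor_calls: np.ndarray, epsilon: float
) -> np.ndarray:
    """(n_markers, n_donors) log emission probabilities."""
    sample = sample[:, None]
    match = donor_calls == sample
    log_e = np.where(match, np.log(1 - epsilon), np.log(epsilon))
    uninformative = (sample == Call.N) | (donor_calls == Call.N)
    log_e = np.where(uninformative, np.log(1.0 / 3.0), log_e)
    return log_e


def viterbi_mosaic(
    sample_calls: np.ndarray,
    donor_panel: dict[str, np.ndarray],
    positions_bp: np.ndarray,
    chromosome: str,
    genetic_map: GeneticMap | None = None,
    params: HMMParams | None = None,
) -> MosaicResult:
    """Decode a sample's donor mosaic along one chromosome.

    ``donor_panel`` maps donor name to a call vector aligned with
    ``sample_calls`` and ``positions_bp``.  If a genetic map is given,
    inter-marker distances are measured in cM; otherwise 1 Mb is treated
    as 1 cM.  Segment boundaries fall at the midpoint between the
    flanking markers of a state change, and segments whose donor cannot
    be distinguished from competitors within ``margin_delta``
    log-likelihood units are labeled with the equivalence group of
    indistinguishable donors.
    """
    params = params or HMMParams()
    sample = np.asarray(sample_calls, dtype=np.int8)
    usable = {}
    for name, calls in donor_panel.items():
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != sample.shape:
            raise ValueError(f"donor {name} not aligned with the sample")
        if (calls == Call.N).all():
            warnings.warn(f"donor {name} has no genotypes; dropped", stacklevel=2)
            continue
        usable[name] = calls
    if len(usable) < 2:
        raise ValueError("need at least 2 usable donors")
    donors = list(usable)
    donor_calls = np.stack([usable[d] for d in donors], axis=1)
    n_markers, n_donors = donor_calls.shape
    pos = np.asarray(positions_bp, dtype=float)

    if genetic_map is not None:
        cm = genetic_map.interpolate_cM(pos, chromosome)
    else:
        cm = pos / 1e6
    dist_cm = np.maximum(np.diff(cm), 1e-6)
    # per-interval switch probability from the expected segment length
    tau = 1.0 - np.exp(-dist_cm / params.expected_segment_cM)
    tau = np.clip(tau, 1e-12, 1.0 - 1e-12)

    log_e = _emission_log(sample, donor_calls, params.epsilon)

    # Viterbi
    delta = np.log(1.0 / n_donors) + log_e[0]
    back = np.zeros((n_markers, n_donors), dtype=np.int32)
    for t in range(1, n_markers):
        stay = np.log(1 - tau[t - 1])
        switch = np.log(tau[t - 1] / (n_donors - 1))
        cand = delta[None, :] + np.where(
            np.eye(n_donors, dtype=bool), stay, switch
        )  # cand[j, i]: from i to j
        back[t] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + log_e[t]
    path = np.zeros(n_markers, dtype=np.int32)
    path[-1] = int(delta.argmax())
    ll = float(delta.max())
    for t in range(n_markers - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]

    posteriors = _forward_backward(log_e, tau, n_donors)

    segments = _segment_path(
        path, posteriors, donors, pos, chromosome, log_e, params.margin_delta
    )
    return MosaicResult(
        segments=segments, path=path, posteriors=posteriors,
        donors=donors, log_likelihood=ll,
    )


def _forward_backward(log_e: np.ndarray, tau: np.ndarray, n_donors: int) -> np.ndarray:
    n = log_e.shape[0]
    alpha = np.zeros_like(log_e)
    beta = np.zeros_like(log_e)
    alpha[0] = np.log(1.0 / n_donors) + log_e[0]
    for t in range(1, n):
        stay, switch = np.log(1 - tau[t - 1]), np.log(tau[t - 1] / (n_donors - 1))
        trans = np.where(np.eye(n_donors, dtype=bool), stay, switch)
        prev = alpha[t - 1][:, None] + trans  # from i (rows) to j (cols)
        alpha[t] = _logsumexp_axis0(prev) + log_e[t]
    beta[-1] = 0.0
    for t in range(n - 2, -1, -1):
        stay, switch = np.log(1 - tau[t]), np.log(tau[t] / (n_donors - 1))
        trans = np.where(np.eye(n_donors, dtype=bool), stay, switch)
        nxt = trans + (log_e[t + 1] + beta[t + 1])[None, :]
        beta[t] = _logsumexp_axis1(nxt)
    log_post = alpha + beta
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    return post / post.sum(axis=1, keepdims=True)


def _logsumexp_axis0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


def _logsumexp_axis1(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _segment_path(
    path, posteriors, donors, pos, chromosome, log_e, margin_delta
) -> list[MosaicSegment]:
    segments: list[MosaicSegment] = []
    n = len(path)
    starts = [0] + [t for t in range(1, n) if path[t] != path[t - 1]]
    ends = starts[1:] + [n]
    for s, e in zip(starts, ends):
        donor_idx = int(path[s])
        # segment-local log-likelihood per donor (emissions only):
        # competitors within margin_delta are indistinguishable here
        seg_ll = log_e[s:e].sum(axis=0)
        group = {
            donors[k] for k in range(len(donors))
            if seg_ll[donor_idx] - seg_ll[k] <= margin_delta
        }
        group.add(donors[donor_idx])
        start_bp = (
            int(pos[s]) if s == 0 else int((pos[s - 1] + pos[s]) // 2) + 1
        )
        end_bp = int(pos[e - 1]) if e == n else int((pos[e - 1] + pos[e]) // 2)
        segments.append(MosaicSegment(
            chromosome=chromosome,
            start_bp=start_bp,
            end_bp=end_bp,
            donors=frozenset(group),
            mean_posterior=float(posteriors[s:e, donor_idx].mean()),
            n_markers=e - s,
        ))
    return segments
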
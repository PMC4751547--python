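"""Marker selection for multi-founder genotyping-array design.

Given a set of candidate SNPs with known alleles in F founder strains,
the goal is to choose one SNP per target interval along each chromosome
so that short sliding windows of consecutive chosen SNPs discriminate as
many founder-derived genotype states as possible.  For F founders the
states are the F homozygous haplotypes plus C(F, 2) unordered
heterozygous combinations (36 states for F = 8).

The informativeness of a w-SNP window is the number of distinct
genotype-state vectors it induces (:func:`window_score`); a chromosome's
path score is the sum over all complete sliding windows.  The number of
paths is exponential in the number of intervals, so the optimum is
approximated by a beam search that retains only the highest-scoring
paths at each step (:func:`beam_select`).

Supporting selectors cover recombination-hotspot-local windows
(:func:`hotspot_select`), uniform genome coverage
(:func:`select_uniform_spacing`) and the slotting of wild-caught novel
SNPs into 1-Mb windows (:func:`place_wild_snps`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FounderHaplotypeSet, normalize_chromosome

__all__ = [
    "CandidateSNP",
    "SelectionProblem",
    "BeamResult",
    "filter_candidates",
    "partition_intervals",
    "split_by_intervals",
    "window_score",
    "window_scores_batch",
    "beam_select",
    "beam_select_chromosome",
    "exhaustive_select_chromosome",
    "hotspot_select",
    "select_uniform_spacing",
    "place_wild_snps",
    "n_genotype_states",
]

DEFAULT_SEED = 20151218

_TRANSITIONS = ({"A", "G"}, {"C", "T"})
_TWO_BEAD = ({"A", "T"}, {"C", "G"})


def n_genotype_states(n_founders: int) -> tuple[int, int]:
    """Return (n_heterozygous_classes, n_total_states) for F founders.

    F homozygous states plus C(F, 2) unordered heterozygous combinations;
    (28, 36) for F = 8.
    """
    n_het = n_founders * (n_founders - 1) // 2
    return n_het, n_founders + n_het


@dataclass
class CandidateSNP:
    """A candidate target SNP with its founder allele codes.

    ``founder_alleles`` holds 0 (reference allele A), 1 (alternate B) or
    -1 (missing) per founder.  ``is_single_bead`` and ``is_transition``
    default from the allele pair: [A/T] and [C/G] SNPs need two bead
    types; transitions are A<->G and C<->T.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]
    founder_alleles: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    position_cM: float | None = None
    is_single_bead: bool | None = None
    min_dist_to_neighbor_bp: int = 10**9
    flank_unique: bool = True
    is_transition: bool | None = None
    maf: float = 0.0

    def __post_init__(self) -> None:
        self.chromosome = normalize_chromosome(self.chromosome)
        self.founder_alleles = np.asarray(self.founder_alleles, dtype=np.int8)
        pair = {a.upper() for a in self.alleles}
        if self.is_single_bead is None:
            self.is_single_bead = pair not in _TWO_BEAD
        if self.is_transition is None:
            self.is_transition = pair in _TRANSITIONS
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.marker_id}: maf must be in [0, 0.5], got {self.maf}")


@dataclass
class SelectionProblem:
    """One-SNP-per-interval selection instance for a set of chromosomes."""

    candidates: dict[str, list[CandidateSNP]]  # per chromosome, sorted by cM
    founders: FounderHaplotypeSet | None
    n_intervals: dict[str, int]
    window_size: int = 5
    beam_width: int = 100_000
    dedup_suffix: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")


@dataclass
class BeamResult:
    chosen: list[CandidateSNP]
    score: int
    flagged_short: bool = False  # fewer chosen SNPs than one window


# ---------------------------------------------------------------------------
# Candidate filtering and interval partitioning
# ---------------------------------------------------------------------------

def filter_candidates(
    variants: list[CandidateSNP], min_neighbor_bp: int = 50
) -> list[CandidateSNP]:
    """Keep single-bead, flank-unique candidates >= ``min_neighbor_bp`` from
    any adjacent variant.  Input must be position-sorted; order is preserved.
    """
    pos = [v.position_bp for v in variants]
    if pos != sorted(pos):
        raise ValueError("candidates must be sorted by position")
    return [
        v for v in variants
        if v.is_single_bead
        and v.flank_unique
        and v.min_dist_to_neighbor_bp >= min_neighbor_bp
    ]


def partition_intervals(
    candidates: list[CandidateSNP], n: int, window_size: int = 5
) -> list[tuple[float, float]]:
    """Partition the candidates' cM span into equal-size target intervals.

    Tries ``n`` intervals first and decrements until every interval holds
    at least one candidate.  Intervals are half-open [lo, hi) on the cM
    axis, the last one closed.  Raises if no feasible count >= window_size
    exists.
    """
    if not candidates:
        raise ValueError("no candidates to partition")
    cm = np.array([c.position_cM for c in candidates], dtype=float)
    if np.isnan(cm).any():
        raise ValueError("all candidates need a cM position")
    lo, hi = float(cm.min()), float(cm.max())
    for n_try in range(n, window_size - 1, -1):
        edges = np.linspace(lo, hi, n_try + 1)
        # assign each candidate to its interval; last interval closed
        idx = np.minimum(np.searchsorted(edges, cm, side="right") - 1, n_try - 1)
        if len(np.unique(idx)) == n_try:
            return [(float(edges[i]), float(edges[i + 1])) for i in range(n_try)]
    raise ValueError(
        f"no interval count in [{window_size}, {n}] leaves every interval nonempty"
    )


def split_by_intervals(
    candidates: list[CandidateSNP], boundaries: list[tuple[float, float]]
) -> list[list[CandidateSNP]]:
    """Assign candidates to interval bins given partition boundaries."""
    edges = np.array([b[0] for b in boundaries] + [boundaries[-1][1]])
    out: list[list[CandidateSNP]] = [[] for _ in boundaries]
    for c in candidates:
        i = int(np.searchsorted(edges, c.position_cM, side="right")) - 1
        i = min(max(i, 0), len(boundaries) - 1)
        out[i].append(c)
    return out


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def _het_index_pairs(n_founders: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(itertools.combinations(range(n_founders), 2))
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    return i, j


def window_scores_batch(configs: np.ndarray) -> np.ndarray:
    """Vectorized window scores for complete (no-missing) configurations.

    ``configs`` is an (N, F, w) array of 0/1 founder alleles; returns the
    (N,) array of counts of distinct genotype-state vectors.  Missing
    alleles are not supported here; use :func:`window_score` for those.
    """
    configs = np.asarray(configs, dtype=np.int64)
    if configs.ndim != 3:
        raise ValueError("expected an (N, F, w) array")
    if (configs < 0).any():
        raise ValueError("batch scorer does not support missing alleles")
    n, f, w = configs.shape
    hi, hj = _het_index_pairs(f)
    hom = 2 * configs                                   # (N, F, w)
    het = configs[:, hi, :] + configs[:, hj, :]          # (N, C(F,2), w)
    states = np.concatenate([hom, het], axis=1)          # (N, S, w)
    weights = 3 ** np.arange(w, dtype=np.int64)
    codes = states @ weights                             # (N, S)
    codes.sort(axis=1)
    return 1 + (np.diff(codes, axis=1) != 0).sum(axis=1)


def _state_masks(window: np.ndarray) -> list[tuple[int, ...]]:
    """Per-state, per-SNP bitmasks of consistent genotype dosages.

    ``window`` is (F, w) with values 0/1/-1.  A genotype dosage in
    {0, 1, 2} occupies one bit; a missing founder allele widens the set of
    dosages consistent with that state (wildcard).
    """
    f, w = window.shape
    masks: list[tuple[int, ...]] = []
    for a in range(f):  # homozygous states
        row = []
        for m in range(w):
            al = window[a, m]
            row.append(0b101 if al == -1 else (1 << (2 * al)))
        masks.append(tuple(row))
    for a, b in itertools.combinations(range(f), 2):  # heterozygous states
        row = []
        for m in range(w):
            x, y = window[a, m], window[b, m]
            if x == -1 and y == -1:
                row.append(0b111)
            elif x == -1 or y == -1:
                known = y if x == -1 else x
                row.append((1 << known) | (1 << (known + 1)))
            else:
                row.append(1 << (x + y))
        masks.append(tuple(row))
    return masks


def window_score(window: np.ndarray) -> int:
    """Number of founder genotype states distinguishable by a SNP window.

    ``window`` is an (F, w) array of founder alleles (0/1, -1 missing).
    Each of the F + C(F, 2) genotype states induces a vector of unordered
    per-SNP allele pairs; the score is the number of distinct vectors,
    between 1 (all states collide) and F + C(F, 2).

    A missing founder allele acts as a wildcard: a state whose vector is
    consistent with another state's vector collides with it, and
    colliding states are counted once (conservative scoring via connected
    components of the collision graph).
    """
    window = np.asarray(window)
    if window.ndim != 2:
        raise ValueError("window must be an (F, w) array")
    if (window >= 0).all():
        return int(window_scores_batch(window[None, :, :])[0])
    masks = _state_masks(window)
    s = len(masks)
    # union-find over collision pairs
    parent = list(range(s))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(s):
        for b in range(a + 1, s):
            if all(ma & mb for ma, mb in zip(masks[a], masks[b])):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(x) for x in range(s)})


def _candidate_alleles(cands: list[CandidateSNP]) -> np.ndarray:
    return np.stack([c.founder_alleles for c in cands], axis=1)  # (F, w)


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------

def beam_select_chromosome(
    intervals: list[list[CandidateSNP]],
    window_size: int = 5,
    beam_width: int = 100_000,
    dedup_suffix: bool = False,
) -> BeamResult:
    """Choose one SNP per interval maximizing summed sliding-window scores.

    Standard beam extension: every retained path is extended by every
    candidate in the next interval, the newly completed window's score is
    added, and the beam is pruned to ``beam_width`` paths by score (ties
    kept in insertion order).  With a beam at least as wide as the number
    of distinct paths the result is the exhaustive optimum.

    A chromosome with fewer intervals than ``window_size`` has no complete
    window; the result carries score 0 and ``flagged_short``.
    """
    if any(len(iv) == 0 for iv in intervals):
        raise ValueError("every interval must contain at least one candidate")
    w = window_size
    n = len(intervals)
    any_missing = any(
        (c.founder_alleles < 0).any() for iv in intervals for c in iv
    )

    # paths: list of index tuples into intervals; scores in lockstep
    paths: list[tuple[int, ...]] = [(i,) for i in range(len(intervals[0]))]
    scores = np.zeros(len(paths), dtype=np.int64)
    paths, scores = _prune(paths, scores, beam_width, dedup_suffix, w)

    for step in range(1, n):
        cands = intervals[step]
        n_p, n_c = len(paths), len(cands)
        new_paths = [p + (ci,) for p in paths for ci in range(n_c)]
        new_scores = np.repeat(scores, n_c)
        if step >= w - 1:
            # score the window formed by the last w choices of each new path
            windows = np.empty((n_p * n_c, _n_founders(intervals), w), dtype=np.int8)
            for k, p in enumerate(new_paths):
                for off in range(w):
                    iv = step - w + 1 + off
                    windows[k, :, off] = intervals[iv][p[iv]].founder_alleles
            if any_missing:
                add = np.array([window_score(windows[k]) for k in range(len(new_paths))])
            else:
                add = window_scores_batch(windows)
            new_scores = new_scores + add
        paths, scores = _prune(new_paths, new_scores, beam_width, dedup_suffix, w)

    best = int(np.argmax(scores))
    chosen = [intervals[i][ci] for i, ci in enumerate(paths[best])]
    return BeamResult(chosen=chosen, score=int(scores[best]), flagged_short=n < w)


def _n_founders(intervals: list[list[CandidateSNP]]) -> int:
    return len(intervals[0][0].founder_alleles)


def _prune(paths, scores, beam_width, dedup_suffix, window_size):
    if dedup_suffix:
        best_by_suffix: dict[tuple[int, ...], int] = {}
        for k, p in enumerate(paths):
            key = p[-(window_size - 1):] if window_size > 1 else ()
            j = best_by_suffix.get(key)
            if j is None or scores[k] > scores[j]:
                best_by_suffix[key] = k
        keep = sorted(best_by_suffix.values())
        paths = [paths[k] for k in keep]
        scores = scores[keep]
    if len(paths) > beam_width:
        order = np.argsort(-scores, kind="stable")[:beam_width]
        order.sort()  # keep insertion order among retained paths
        paths = [paths[k] for k in order]
        scores = scores[order]
    return paths, scores


def exhaustive_select_chromosome(
    intervals: list[list[CandidateSNP]], window_size: int = 5
) -> BeamResult:
    """Exact optimum by full path enumeration (small instances only)."""
    n_paths = 1
    for iv in intervals:
        n_paths *= len(iv)
    if n_paths > 3**12:
        raise ValueError(f"instance too large for exhaustive search ({n_paths} paths)")
    w = window_size
    n = len(intervals)
    any_missing = any(
        (c.founder_alleles < 0).any() for iv in intervals for c in iv
    )
    paths = list(itertools.product(*[range(len(iv)) for iv in intervals]))
    if any_missing:
        scores = np.zeros(len(paths), dtype=np.int64)
        for k, path in enumerate(paths):
            for start in range(n - w + 1):
                cands = [intervals[start + off][path[start + off]]
                         for off in range(w)]
                scores[k] += window_score(_candidate_alleles(cands))
    else:
        f = _n_founders(intervals)
        # (n_paths, F, n) allele tensor, then score every sliding window
        alleles = np.empty((len(paths), f, n), dtype=np.int8)
        for i, iv in enumerate(intervals):
            per_cand = np.stack([c.founder_alleles for c in iv])  # (n_c, F)
            idx = np.array([p[i] for p in paths])
            alleles[:, :, i] = per_cand[idx]
        scores = np.zeros(len(paths), dtype=np.int64)
        for start in range(n - w + 1):
            scores += window_scores_batch(alleles[:, :, start:start + w])
    best = int(np.argmax(scores))
    chosen = [intervals[i][ci] for i, ci in enumerate(paths[best])]
    return BeamResult(chosen, int(max(scores[best], 0)), flagged_short=n < w)


def beam_select(problem: SelectionProblem) -> dict[str, BeamResult]:
    """Run the per-chromosome beam selection for a whole problem."""
    out: dict[str, BeamResult] = {}
    for chrom, cands in problem.candidates.items():
        bounds = partition_intervals(
            cands, problem.n_intervals[chrom], problem.window_size
        )
        intervals = split_by_intervals(cands, bounds)
        out[chrom] = beam_select_chromosome(
            intervals, problem.window_size, problem.beam_width, problem.dedup_suffix
        )
    return out


# ---------------------------------------------------------------------------
# Hotspot-local selection
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    chosen: list[CandidateSNP]
    score: int
    off_center: bool


def hotspot_select(
    candidates: list[CandidateSNP],
    center_start_bp: int,
    center_end_bp: int,
    w: int = 4,
) -> HotspotResult:
    """Pick the most informative run of w consecutive SNPs near a hotspot.

    Among all runs of ``w`` consecutive candidates whose bp span overlaps
    the central region (typically the central 100 bp of a recombination
    hotspot's binding site), return the run maximizing the window score;
    ties broken by smaller span, then by proximity of the run midpoint to
    the region center.  If no run overlaps, the best run nearest the
    center is returned flagged ``off_center``.
    """
    cands = sorted(candidates, key=lambda c: c.position_bp)
    if len(cands) < w:
        raise ValueError(f"need at least {w} candidates near the hotspot")
    center_mid = (center_start_bp + center_end_bp) / 2.0
    runs = []
    for s in range(len(cands) - w + 1):
        run = cands[s:s + w]
        lo, hi = run[0].position_bp, run[-1].position_bp
        overlaps = lo <= center_end_bp and hi >= center_start_bp
        score = window_score(_candidate_alleles(run))
        span = hi - lo
        mid_dist = abs((lo + hi) / 2.0 - center_mid)
        runs.append((run, score, span, mid_dist, overlaps))
    overlapping = [r for r in runs if r[4]]
    pool, off_center = (overlapping, False) if overlapping else (runs, True)
    if off_center:
        # nearest to the center first, then the usual criteria
        best = min(pool, key=lambda r: (r[3], -r[1], r[2]))
    else:
        best = min(pool, key=lambda r: (-r[1], r[2], r[3]))
    return HotspotResult(chosen=best[0], score=best[1], off_center=off_center)


# ---------------------------------------------------------------------------
# Uniform-spacing and wild-SNP placement
# ---------------------------------------------------------------------------

def select_uniform_spacing(
    candidates: list[CandidateSNP],
    k: int,
    domain: tuple[int, int] | None = None,
) -> list[CandidateSNP]:
    """Greedy gap-halving selection of k candidates covering a domain.

    Repeatedly finds the largest gap between already-selected positions
    (and the domain boundaries) and picks the unselected candidate closest
    to that gap's midpoint, until ``k`` are picked.  Output is
    position-sorted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    pos = np.array([c.position_bp for c in candidates], dtype=float)
    if domain is None:
        domain = (int(pos.min()), int(pos.max()))
    lo, hi = float(domain[0]), float(domain[1])
    selected: list[int] = []
    remaining = set(range(len(candidates)))
    for _ in range(k):
        anchors = sorted([lo, hi] + [pos[i] for i in selected])
        gaps = [(anchors[i + 1] - anchors[i], (anchors[i] + anchors[i + 1]) / 2)
                for i in range(len(anchors) - 1)]
        _, mid = max(gaps, key=lambda g: g[0])
        pick = min(remaining, key=lambda i: (abs(pos[i] - mid), pos[i]))
        selected.append(pick)
        remaining.discard(pick)
    return sorted((candidates[i] for i in selected), key=lambda c: c.position_bp)


@dataclass
class WildPick:
    snp: CandidateSNP
    window_start_bp: int
    slot: str  # "transition_1", "transition_2", "transversion_mid"
    spacing_violated: bool


def place_wild_snps(
    novel: list[CandidateSNP],
    chromosome_length_bp: int,
    window_bp: int = 1_000_000,
    min_spacing_bp: int = 100_000,
    seed: int = DEFAULT_SEED,
) -> list[WildPick]:
    """Slot novel wild-mouse SNPs into 1-Mb windows along a chromosome.

    Per window: one transition from each 500-kb half, and one transversion
    from the middle third.  Within a slot candidates are ranked by MAF
    descending with seeded random tie-breaks; a pick closer than
    ``min_spacing_bp`` to any previous pick is taken only when no
    compliant candidate exists in its slot, and flagged.  Empty slots
    yield fewer picks.
    """
    rng = np.random.default_rng(seed)
    tiebreak = {id(c): rng.random() for c in novel}
    picks: list[WildPick] = []
    placed_positions: list[int] = []

    def slot_candidates(w0: int, slot: str) -> list[CandidateSNP]:
        half = window_bp // 2
        third = window_bp // 3
        if slot == "transition_1":
            lo, hi, trans = w0, w0 + half, True
        elif slot == "transition_2":
            lo, hi, trans = w0 + half, w0 + window_bp, True
        else:  # transversion in the middle third of the window
            lo, hi, trans = w0 + third, w0 + 2 * third + 1, False
        return [
            c for c in novel
            if lo <= c.position_bp < hi and c.is_transition == trans
        ]

    for w0 in range(0, chromosome_length_bp, window_bp):
        for slot in ("transition_1", "transition_2", "transversion_mid"):
            pool = slot_candidates(w0, slot)
            pool = [c for c in pool if c.position_bp not in placed_positions]
            if not pool:
                continue
            pool.sort(key=lambda c: (-c.maf, tiebreak[id(c)]))
            compliant = [
                c for c in pool
                if all(abs(c.position_bp - p) >= min_spacing_bp
                       for p in placed_positions)
            ]
            if compliant:
                chosen, violated = compliant[0], False
            else:
                chosen, violated = pool[0], True
            picks.append(WildPick(chosen, w0, slot, violated))
            placed_positions.append(chosen.position_bp)
    return picks
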
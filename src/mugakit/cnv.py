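"""Copy-number support: paralogous-SNP filtering and region LRR summaries.

Segmental duplications collapse paralogous sequence onto a single
reference locus, so short-read pileups there show *pseudoheterozygosity*
(several bases each supported by multiple reads) together with excess
coverage.  :func:`flag_paralogous` applies the strict printed
thresholds: more than 3 reads for each of two or more bases, read depth
above 50, and a minimum spacing between flagged sites.

For arrays, copy-number change shifts the log R ratio away from zero:
a single-copy deletion halves intensity (LRR near -1, i.e. log2(1/2))
and a duplication raises it (log2(3/2) ~ +0.58).
:func:`summarize_region_lrr` averages LRR over the probes of each
target region and applies a symmetric screening threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import normalize_chromosome

__all__ = [
    "PileupSite",
    "RegionCNSummary",
    "flag_paralogous",
    "summarize_region_lrr",
]


@dataclass
class PileupSite:
    chromosome: str
    position_bp: int
    depth: int
    base_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.chromosome = normalize_chromosome(self.chromosome)
        if sum(self.base_counts.values()) > self.depth:
            raise ValueError(
                f"{self.chromosome}:{self.position_bp}: base counts exceed depth"
            )


def flag_paralogous(
    sites: list[PileupSite],
    min_alt_reads: int = 4,
    min_depth: int = 51,
    min_spacing_bp: int = 51,
) -> list[PileupSite]:
    """Flag paralogous-SNP candidates from pileup summaries.

    A site qualifies when at least two nucleotides each have read count
    >= ``min_alt_reads`` (i.e. strictly more than 3 reads) and depth
    >= ``min_depth`` (strictly more than 50).  Qualifying sites closer
    than ``min_spacing_bp`` to a previously flagged site are dropped in a
    left-to-right scan.  Input must be position-sorted.
    """
    pos = [(s.chromosome, s.position_bp) for s in sites]
    if pos != sorted(pos):
        raise ValueError("pileup sites must be sorted by position")
    flagged: list[PileupSite] = []
    last_kept: dict[str, int] = {}
    for site in sites:
        n_supported = sum(
            1 for c in site.base_counts.values() if c >= min_alt_reads
        )
        if n_supported < 2 or site.depth < min_depth:
            continue
        prev = last_kept.get(site.chromosome)
        if prev is not None and site.position_bp - prev < min_spacing_bp:
            continue
        flagged.append(site)
        last_kept[site.chromosome] = site.position_bp
    return flagged


@dataclass
class RegionCNSummary:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    mean_lrr: float
    n_probes: int
    call: str  # loss / normal / gain / withheld


def summarize_region_lrr(
    lrr: np.ndarray,
    marker_chromosomes: np.ndarray,
    marker_positions: np.ndarray,
    samples: list[str],
    regions: list[tuple[str, int, int]],
    gain_threshold: float = 0.3,
    min_probes: int = 3,
) -> list[RegionCNSummary]:
    """Mean LRR per sample per region with a screening gain/loss call.

    ``lrr`` is (n_markers, n_samples); regions are (chromosome,
    start_bp, end_bp), 1-based inclusive.  The call is gain when the
    mean exceeds ``+gain_threshold``, loss below ``-gain_threshold``,
    normal otherwise; regions covered by fewer than ``min_probes``
    markers get their call withheld.
    """
    lrr = np.asarray(lrr, dtype=float)
    chroms = np.asarray(marker_chromosomes, dtype=str)
    pos = np.asarray(marker_positions, dtype=int)
    out: list[RegionCNSummary] = []
    for chrom, start, end in regions:
        chrom = normalize_chromosome(chrom)
        rows = np.where((chroms == chrom) & (pos >= start) & (pos <= end))[0]
        for j, sample in enumerate(samples):
            vals = lrr[rows, j]
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            mean = float(vals.mean()) if n else float("nan")
            if n < min_probes:
                call = "withheld"
            elif mean > gain_threshold:
                call = "gain"
            elif mean < -gain_threshold:
                call = "loss"
            else:
                call = "normal"
            out.append(RegionCNSummary(
                sample_id=sample, chromosome=chrom, start_bp=start,
                end_bp=end, mean_lrr=mean, n_probes=n, call=call,
            ))
    return out
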
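"""Strain-informativeness analytics.

Covers pairwise informative-marker counting between strains, replicate
and F1-hybrid concordance, discovery of subspecies-diagnostic markers
(markers whose minor allele is near-exclusive to one of the three
M. musculus subspecies: dom = domesticus, mus = musculus,
cas = castaneus), density-driven augmentation of the diagnostic catalog,
and the recoding of haploid-lineage (Y / mitochondrial) genotypes into
four-state character sequences for phylogeny export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AUTOSOMES, Call, MarkerAnnotation

__all__ = [
    "AlleleFrequencyTable",
    "DiagnosticCatalog",
    "allele_frequencies",
    "count_informative",
    "concordance",
    "f1_concordance",
    "find_diagnostic",
    "augment_density",
    "recode_for_phylogeny",
]

SUBSPECIES = ("dom", "mus", "cas")
_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class AlleleFrequencyTable:
    """Per-marker allele counts and MAF within each subspecies."""

    markers: list[str]
    n_samples: dict[str, int]  # per subspecies
    alt_counts: dict[str, np.ndarray]  # allele copies of the alternate allele
    call_counts: dict[str, np.ndarray]  # diploid genotypes observed

    def maf(self, subspecies: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.alt_counts[subspecies] / (2.0 * self.call_counts[subspecies])
        return np.minimum(freq, 1.0 - freq)


@dataclass
class DiagnosticCatalog:
    """Markers diagnostic for a single subspecies."""

    diagnostic_for: dict[str, frozenset[str]]  # marker -> subset of SUBSPECIES
    diagnostic_allele: dict[str, dict[str, str]]  # marker -> subspecies -> allele
    n_carriers_outside: dict[str, dict[str, int]] = field(default_factory=dict)

    def markers_for(self, subspecies: str) -> list[str]:
        return [m for m, s in self.diagnostic_for.items() if subspecies in s]


def _as_calls(v) -> np.ndarray:
    return np.asarray(v, dtype=np.int8)


def count_informative(
    sample_a,
    sample_b,
    tiers: np.ndarray | list[int],
    allowed_tiers: frozenset[int] = frozenset({1, 2}),
) -> int:
    """Markers (in allowed tiers) called for opposite homozygotes in a pair."""
    a, b = _as_calls(sample_a), _as_calls(sample_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must be aligned to a shared manifest")
    t = np.asarray(tiers)
    if t.shape != a.shape:
        raise ValueError("tier vector must align with the genotype vectors")
    in_tier = np.isin(t, list(allowed_tiers))
    opposite = ((a == Call.AA) & (b == Call.BB)) | ((a == Call.BB) & (b == Call.AA))
    return int((in_tier & opposite).sum())


def concordance(sample_a, sample_b) -> float:
    """Fraction of co-called (both nonmissing) markers with identical calls."""
    a, b = _as_calls(sample_a), _as_calls(sample_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must be aligned")
    both = (a != Call.N) & (b != Call.N)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no overlapping nonmissing markers")
    return float((a[both] == b[both]).sum() / n)


def f1_concordance(
    f1,
    parent1,
    parent2,
    chromosomes: np.ndarray | list[str] | None = None,
) -> float:
    """Concordance of observed F1 genotypes with parental predictions.

    Restricted to autosomal markers where both parents are nonmissing
    homozygotes; the prediction is AB when the parents differ and the
    shared homozygote otherwise.  Returns the fraction of nonmissing F1
    calls matching the prediction.
    """
    f, p1, p2 = _as_calls(f1), _as_calls(parent1), _as_calls(parent2)
    if not (f.shape == p1.shape == p2.shape):
        raise ValueError("genotype vectors must be aligned")
    eligible = np.isin(p1, [Call.AA, Call.BB]) & np.isin(p2, [Call.AA, Call.BB])
    if chromosomes is not None:
        eligible &= np.isin(np.asarray(chromosomes, dtype=str), AUTOSOMES)
    eligible &= f != Call.N
    if not eligible.any():
        raise ValueError("no eligible markers (parents not co-called homozygous)")
    predicted = np.where(p1 == p2, p1, Call.AB)
    return float((f[eligible] == predicted[eligible]).sum() / eligible.sum())


def allele_frequencies(
    markers: list[str],
    calls: np.ndarray,
    subspecies_labels: list[str],
) -> AlleleFrequencyTable:
    """Tabulate alternate-allele counts per subspecies from panel calls."""
    calls = _as_calls(calls)
    labels = np.asarray(subspecies_labels)
    alt_counts, call_counts, n_samples = {}, {}, {}
    for sub in SUBSPECIES:
        cols = labels == sub
        sub_calls = calls[:, cols]
        alt = (sub_calls == Call.BB).sum(axis=1) * 2 + (sub_calls == Call.AB).sum(axis=1)
        called = (sub_calls != Call.N).sum(axis=1)
        alt_counts[sub] = alt.astype(int)
        call_counts[sub] = called.astype(int)
        n_samples[sub] = int(cols.sum())
    return AlleleFrequencyTable(
        markers=list(markers), n_samples=n_samples,
        alt_counts=alt_counts, call_counts=call_counts,
    )


def find_diagnostic(
    markers: list[str],
    calls: np.ndarray,
    subspecies_labels: list[str],
    manifest: list[MarkerAnnotation] | None = None,
    max_mismatch: int = 2,
) -> DiagnosticCatalog:
    """Markers with an allele (near-)exclusive to one subspecies.

    An allele is diagnostic for subspecies ``s`` when at least one sample
    of ``s`` carries it and at most ``max_mismatch`` samples outside
    ``s`` do.  Carriers are individuals with at least one allele copy
    (heterozygotes count).
    """
    calls = _as_calls(calls)
    labels = np.asarray(subspecies_labels)
    for sub in SUBSPECIES:
        if not (labels == sub).any():
            raise ValueError(f"no samples labeled {sub}")
    by_id = {m.marker_id: m for m in (manifest or [])}
    carries = {
        "ref": (calls == Call.AA) | (calls == Call.AB),
        "alt": (calls == Call.BB) | (calls == Call.AB),
    }
    diagnostic_for: dict[str, frozenset[str]] = {}
    diagnostic_allele: dict[str, dict[str, str]] = {}
    n_outside: dict[str, dict[str, int]] = {}
    for i, marker in enumerate(markers):
        subs, alleles, outs = set(), {}, {}
        for sub in SUBSPECIES:
            inside = labels == sub
            for which in ("ref", "alt"):
                row = carries[which][i]
                n_in = int(row[inside].sum())
                n_out = int(row[~inside].sum())
                if n_in >= 1 and n_out <= max_mismatch:
                    subs.add(sub)
                    ann = by_id.get(marker)
                    alleles[sub] = (
                        (ann.allele_ref if which == "ref" else ann.allele_alt)
                        if ann else which
                    )
                    outs[sub] = n_out
                    break
        if subs:
            diagnostic_for[marker] = frozenset(subs)
            diagnostic_allele[marker] = alleles
            n_outside[marker] = outs
    return DiagnosticCatalog(diagnostic_for, diagnostic_allele, n_outside)


@dataclass
class DensityAugmentation:
    """Stage-0 catalog plus markers added to satisfy the density target."""

    selected: dict[str, list[str]]  # subspecies -> position-sorted marker ids
    added: dict[str, list[str]]
    deficits: list[tuple[str, int, int]]  # (subspecies, region_start, region_end)


def _max_gap(positions: list[int], lo: int, hi: int) -> int:
    pts = [lo] + sorted(positions) + [hi]
    return max(b - a for a, b in zip(pts, pts[1:]))


def augment_density(
    catalog: DiagnosticCatalog,
    candidates: dict[str, list[tuple[str, int, float]]],
    region: tuple[int, int],
    recomb_intervals: list[tuple[int, int]] | None = None,
    target_bp: int = 300_000,
    maf_steps: np.ndarray | None = None,
    seed: int = 0,
) -> DensityAugmentation:
    """Augment the diagnostic catalog to one marker per ``target_bp``.

    ``candidates`` maps each subspecies to (marker_id, position_bp, maf)
    tuples of available diagnostic markers within ``region`` (a single
    maximal region, 1-based bp).  The density criterion is a maximal-gap
    one: the region is satisfied when no gap between consecutive selected
    markers (or region edges) exceeds ``target_bp``.

    Stage 1 iterates MAF thresholds from 0.45 down to 0.00 in steps of
    0.05; at each step every candidate with MAF strictly above the
    threshold joins the eligible pool and markers are added by the
    uniform-spacing greedy until the density target is met or thresholds
    are exhausted.  Stage 2 places one seeded-random diagnostic marker in
    each recombination interval still lacking one for a subspecies.
    Previously selected markers are never removed; unmeetable density is
    reported as a deficit, not raised.
    """
    from .markersel import CandidateSNP

    if maf_steps is None:
        maf_steps = np.arange(0.45, -0.001, -0.05)
    rng = np.random.default_rng(seed)
    lo, hi = region
    selected: dict[str, list[str]] = {}
    added: dict[str, list[str]] = {}
    deficits: list[tuple[str, int, int]] = []

    subs = tuple(s for s in SUBSPECIES if s in candidates)
    pos_of: dict[str, dict[str, int]] = {}
    for sub in subs:
        added[sub] = []
        pos_of[sub] = {mid: pos for mid, pos, _ in candidates.get(sub, [])}
        base = [m for m in catalog.markers_for(sub) if m in pos_of[sub]]
        chosen = set(base)
        chosen_pos = [pos_of[sub][m] for m in base]
        pool_sorted = sorted(candidates.get(sub, []), key=lambda c: c[1])
        for thr in maf_steps:
            if _max_gap(chosen_pos, lo, hi) <= target_bp:
                break
            eligible = [
                c for c in pool_sorted if c[2] > thr and c[0] not in chosen
            ]
            if not eligible:
                continue
            # add greedily by gap-halving until density met or pool empty
            while eligible and _max_gap(chosen_pos, lo, hi) > target_bp:
                cands = [
                    CandidateSNP(mid, "1", pos, ("A", "G"), maf=maf)
                    for mid, pos, maf in eligible
                ]
                # seed greedy with existing picks by shrinking to one pick
                pick = _closest_to_largest_gap(cands, chosen_pos, lo, hi)
                if pick is None:
                    break
                chosen.add(pick.marker_id)
                chosen_pos.append(pick.position_bp)
                added[sub].append(pick.marker_id)
                eligible = [c for c in eligible if c[0] != pick.marker_id]
        if _max_gap(chosen_pos, lo, hi) > target_bp:
            deficits.append((sub, lo, hi))
        selected[sub] = sorted(chosen, key=lambda m: pos_of[sub][m])

    for start, end in recomb_intervals or []:
        for sub in subs:
            have = any(start <= pos_of[sub][m] <= end for m in selected[sub])
            if have:
                continue
            avail = [
                c for c in candidates.get(sub, [])
                if start <= c[1] <= end and c[0] not in selected[sub]
            ]
            if not avail:
                deficits.append((sub, start, end))
                continue
            pick = avail[int(rng.integers(len(avail)))]
            selected[sub] = sorted(
                selected[sub] + [pick[0]], key=lambda m: pos_of[sub][m]
            )
            added[sub].append(pick[0])
    return DensityAugmentation(selected=selected, added=added, deficits=deficits)


def _closest_to_largest_gap(cands, chosen_pos, lo, hi):
    pts = [lo] + sorted(chosen_pos) + [hi]
    gaps = [(b - a, (a + b) / 2) for a, b in zip(pts, pts[1:])]
    _, mid = max(gaps, key=lambda g: g[0])
    best = min(cands, key=lambda c: (abs(c.position_bp - mid), c.position_bp))
    return best


def recode_for_phylogeny(
    calls: np.ndarray,
    samples: list[str],
    alleles: list[tuple[str, str]],
    seed: int = 0,
) -> dict[str, str]:
    """Recode haploid-lineage calls into 4-state character sequences.

    Per marker: AA -> reference nucleotide, BB -> alternate nucleotide;
    AB and N are each assigned a distinct nucleotide drawn (seeded) from
    the two non-allelic nucleotides, so heterozygous calls and no-calls
    (both typically caused by off-target variation disrupting
    hybridization) are retained as phylogenetically informative states.
    Codes are fixed per marker and shared across samples; the four codes
    at a marker are pairwise distinct.
    """
    calls = _as_calls(calls)
    if calls.shape != (len(alleles), len(samples)):
        raise ValueError("calls must be (n_markers, n_samples)")
    rng = np.random.default_rng(seed)
    code_table = []
    for ref, alt in alleles:
        ref, alt = ref.upper(), alt.upper()
        if ref == alt or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            raise ValueError(f"degenerate or non-nucleotide alleles: {ref}/{alt}")
        others = [n for n in _NUCLEOTIDES if n not in (ref, alt)]
        ab = others[int(rng.integers(2))]
        nn = others[0] if ab == others[1] else others[1]
        code_table.append({Call.AA: ref, Call.BB: alt, Call.AB: ab, Call.N: nn})
    out = {}
    for j, s in enumerate(samples):
        out[s] = "".join(
            code_table[i][Call(calls[i, j])] for i in range(len(alleles))
        )
    return out
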
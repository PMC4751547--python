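"""Synthetic genotyping-array data with complete ground truth.

The generator emulates a multi-founder mouse genotyping experiment:
founder haplotypes over a marker manifest, inbred founder replicates,
all C(F, 2) F1 hybrid classes, and outbred mosaic genomes produced by
Markov switching along the genetic map.  From the genotypes it fabricates
two-channel hybridization intensities whose per-array total-intensity
statistic d matches the reference distribution of a well-behaved array:

* good mode: d ~ Normal(0.97, 0.42) floored at 0 (an approximately
  symmetric distribution with mean near 1);
* failed mode: d right-skewed with low mean (Gamma, mean 0.45), the
  signature of a failed hybridization;
* diverged mode: the good-mode distribution mixed with a spike near
  zero, as seen for samples genetically distant from the reference
  genome (a fraction of probes fail to hybridize).

Female samples emit only background intensity at Y-linked markers (and
no calls), copy-number regions scale d by copy/2, and a configurable
fraction of probes behave as VINOs (variable-intensity
oligonucleotides) whose alternate-allele carriers lose intensity.

Every simulated observable is recorded in :class:`SimTruth`, so tests
can check recovery against the generating configuration.  d is the
primary simulated quantity; the channel pair (x, y) is reconstructed
from (d, theta), which pins the QC-relevant marginal exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    Call,
    FounderHaplotypeSet,
    GeneticMap,
    GenotypeMatrix,
    IntensityMatrix,
    MarkerAnnotation,
    SampleInfo,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedPanel",
    "simulate_panel",
    "simulate_intensities",
    "draw_d",
    "simulate_construct_intensities",
]

DEFAULT_FOUNDERS = ["AJ", "B6", "129S1", "NOD", "NZO", "CAST", "PWK", "WSB"]


@dataclass
class SimConfig:
    """Generating conditions for a synthetic array experiment."""

    seed: int
    n_founders: int = 8
    #: chromosome -> (length_bp, length_cM, n_markers); X/Y/M fractions
    #: mirror a real array, where autosomal probes dominate
    chromosomes: dict[str, tuple[int, float, int]] = field(default_factory=lambda: {
        "1": (100_000_000, 100.0, 1000),
        "2": (80_000_000, 80.0, 800),
        "X": (60_000_000, 60.0, 100),
        "Y": (3_000_000, 0.0, 83),
        "M": (16_300, 0.0, 32),
    })
    #: per-marker alternate-allele frequency among founders
    founder_alt_freq: float = 0.5
    #: sd of the angular noise around cluster centers (theta units)
    noise_sd: float = 0.02
    #: fraction of autosomal probes behaving as VINOs
    vino_fraction: float = 0.0
    d_good_mean: float = 0.97
    d_good_sd: float = 0.42
    d_failed_mean: float = 0.45
    d_failed_shape: float = 2.0
    diverged_spike_fraction: float = 0.2
    background_d_mean: float = 0.05
    background_d_sd: float = 0.03
    #: missing-call fraction added to failed-mode arrays
    failed_missing_fraction: float = 0.20
    n_founder_replicates: int = 1
    n_outbred: int = 0
    outbred_generations: int = 10
    raw_scale: float = 1500.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        for name in ("vino_fraction", "diverged_spike_fraction",
                     "failed_missing_fraction", "founder_alt_freq"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")


@dataclass
class SimTruth:
    """Ground truth for every simulated observable."""

    genotypes: GenotypeMatrix
    sample_sex: dict[str, str]
    sample_mode: dict[str, str]
    #: outbred sample -> haplotype index -> list of (chrom, start_bp,
    #: end_bp, founder)
    mosaic_segments: dict[str, dict[int, list[tuple[str, int, int, str]]]]
    vino_markers: list[str]
    cnv_regions: dict[str, list[tuple[str, int, int, int]]]  # +copy number
    construct_carriers: dict[str, set[str]]

    def complete_for(self, samples: list[str]) -> bool:
        return all(
            s in self.sample_sex and s in self.sample_mode for s in samples
        )


@dataclass
class SimulatedPanel:
    config: SimConfig
    manifest: list[MarkerAnnotation]
    genetic_map: GeneticMap
    founders: FounderHaplotypeSet
    genotypes: GenotypeMatrix
    samples: list[SampleInfo]
    truth: SimTruth

    @property
    def marker_chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.manifest])

    @property
    def marker_positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.manifest])


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("T", "C"), ("G", "A")]


def _build_manifest(config: SimConfig, rng) -> tuple[list[MarkerAnnotation], GeneticMap]:
    manifest: list[MarkerAnnotation] = []
    anchors: dict[str, list[tuple[int, float]]] = {}
    for chrom, (length_bp, length_cm, n) in config.chromosomes.items():
        if n >= length_bp:
            pos = np.arange(1, n + 1)
        else:
            draw = rng.integers(1, length_bp + 1, size=4 * n + 16)
            pos = np.unique(draw)
            while len(pos) < n:  # tiny chromosomes may need a top-up
                draw = rng.integers(1, length_bp + 1, size=4 * n + 16)
                pos = np.unique(np.concatenate([pos, draw]))
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        for i, p in enumerate(pos):
            ref, alt = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
            cm = length_cm * (p - 1) / max(length_bp - 1, 1)
            manifest.append(MarkerAnnotation(
                marker_id=f"{chrom}_{i:05d}", chromosome=chrom,
                position_bp=int(p), allele_ref=ref, allele_alt=alt,
                position_cM=float(cm),
            ))
        anchors[chrom] = [(1, 0.0), (length_bp, max(length_cm, 1e-9))]
    return manifest, GeneticMap(anchors)


def _founder_alleles(config: SimConfig, n_markers: int, rng) -> np.ndarray:
    """(n_markers, F) founder alleles; monomorphic markers are redrawn once."""
    a = (rng.random((n_markers, config.n_founders)) < config.founder_alt_freq)
    return a.astype(np.int8)


def _mosaic_haplotype(
    founder_ids: np.ndarray, cm: np.ndarray, generations: int, rng
) -> np.ndarray:
    """Markov founder-of-origin chain along one chromosome's markers."""
    n = len(cm)
    out = np.empty(n, dtype=np.int32)
    out[0] = rng.integers(len(founder_ids))
    # expected number of recombinations scales with generations
    switch = 1.0 - np.exp(-generations * np.maximum(np.diff(cm), 0.0) / 100.0)
    for t in range(1, n):
        if rng.random() < switch[t - 1]:
            out[t] = rng.integers(len(founder_ids))
        else:
            out[t] = out[t - 1]
    return out


def _calls_from_haplotypes(
    hap1_allele: np.ndarray, hap2_allele: np.ndarray
) -> np.ndarray:
    calls = np.where(
        hap1_allele == hap2_allele,
        np.where(hap1_allele == 1, Call.BB, Call.AA),
        Call.AB,
    ).astype(np.int8)
    return calls


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Simulate founders, all F1 classes and optional outbred mosaics.

    Founder samples are fully inbred (replicated ``n_founder_replicates``
    times); each of the C(F, 2) F1 classes is derived deterministically
    from its parents; outbred samples carry two independent mosaic
    haplotypes switching founders along the genetic map.  Sexes alternate
    within each group; females are called N at Y-linked markers, and
    mitochondrial/Y calls are hemizygous (reported as homozygous calls).
    """
    rng = np.random.default_rng(config.seed)
    manifest, gmap = _build_manifest(config, rng)
    n_markers = len(manifest)
    founder_names = (
        DEFAULT_FOUNDERS[:config.n_founders]
        if config.n_founders <= len(DEFAULT_FOUNDERS)
        else [f"F{i}" for i in range(config.n_founders)]
    )
    alleles = _founder_alleles(config, n_markers, rng)
    founders = FounderHaplotypeSet(
        founders=founder_names,
        markers=[m.marker_id for m in manifest],
        alleles=alleles,
    )
    chrom_arr = np.array([m.chromosome for m in manifest])
    pos_arr = np.array([m.position_bp for m in manifest])
    cm_arr = np.array([m.position_cM for m in manifest])

    sample_ids: list[str] = []
    infos: list[SampleInfo] = []
    columns: list[np.ndarray] = []
    sexes: dict[str, str] = {}
    mosaics: dict[str, dict[int, list[tuple[str, int, int, str]]]] = {}

    def add_sample(sid, group, sex, parents, hap1, hap2):
        a1 = alleles[np.arange(n_markers), hap1]
        a2 = alleles[np.arange(n_markers), hap2]
        calls = _calls_from_haplotypes(a1, a2)
        haploid = (chrom_arr == "Y") | (chrom_arr == "M")
        if sex == "M":  # males are hemizygous on X as well
            haploid = haploid | (chrom_arr == "X")
        calls[haploid] = np.where(a1[haploid] == 1, Call.BB, Call.AA)
        if sex == "F":
            calls[chrom_arr == "Y"] = Call.N
        sample_ids.append(sid)
        sexes[sid] = sex
        infos.append(SampleInfo(
            sample_id=sid, group=group, known_sex=sex,
            strain_or_parents=parents,
        ))
        columns.append(calls)

    sex_cycle = itertools.cycle(["F", "M"])
    for f_idx, fname in enumerate(founder_names):
        for rep in range(config.n_founder_replicates):
            sid = f"{fname}_r{rep}" if config.n_founder_replicates > 1 else fname
            hap = np.full(n_markers, f_idx, dtype=np.int64)
            add_sample(sid, "classical_inbred", next(sex_cycle), (fname,), hap, hap)
    for f1_idx, f2_idx in itertools.combinations(range(config.n_founders), 2):
        p1, p2 = founder_names[f1_idx], founder_names[f2_idx]
        sid = f"{p1}x{p2}"
        hap1 = np.full(n_markers, f1_idx, dtype=np.int64)
        hap2 = np.full(n_markers, f2_idx, dtype=np.int64)
        add_sample(sid, "cc_f1", next(sex_cycle), (p1, p2), hap1, hap2)
    for k in range(config.n_outbred):
        sid = f"DO_{k:03d}"
        hap1 = np.empty(n_markers, dtype=np.int64)
        hap2 = np.empty(n_markers, dtype=np.int64)
        segs: dict[int, list[tuple[str, int, int, str]]] = {0: [], 1: []}
        for chrom in config.chromosomes:
            rows = np.where(chrom_arr == chrom)[0]
            for h, hap in enumerate((hap1, hap2)):
                chain = _mosaic_haplotype(
                    np.arange(config.n_founders), cm_arr[rows],
                    config.outbred_generations, rng,
                )
                hap[rows] = chain
                starts = [0] + [t for t in range(1, len(rows))
                                if chain[t] != chain[t - 1]]
                ends = starts[1:] + [len(rows)]
                for s, e in zip(starts, ends):
                    segs[h].append((
                        chrom, int(pos_arr[rows][s]), int(pos_arr[rows][e - 1]),
                        founder_names[int(chain[s])],
                    ))
        add_sample(sid, "do", next(sex_cycle), (), hap1, hap2)
        mosaics[sid] = segs

    calls = np.stack(columns, axis=1)
    geno = GenotypeMatrix(
        markers=[m.marker_id for m in manifest], samples=sample_ids, calls=calls
    )
    autosomal = np.where((chrom_arr != "Y") & (chrom_arr != "M"))[0]
    n_vino = int(round(config.vino_fraction * len(autosomal)))
    vino_rows = rng.choice(autosomal, size=n_vino, replace=False) if n_vino else []
    truth = SimTruth(
        genotypes=GenotypeMatrix(  # pre-noise copy: later intensity
            markers=list(geno.markers),  # simulation may N out calls
            samples=list(geno.samples),
            calls=calls.copy(),
        ),
        sample_sex=sexes,
        sample_mode={s: "good" for s in sample_ids},
        mosaic_segments=mosaics,
        vino_markers=[manifest[i].marker_id for i in vino_rows],
        cnv_regions={},
        construct_carriers={},
    )
    return SimulatedPanel(
        config=config, manifest=manifest, genetic_map=gmap,
        founders=founders, genotypes=geno, samples=infos, truth=truth,
    )


def draw_d(mode: str, n: int, config: SimConfig, rng) -> np.ndarray:
    """Draw n per-probe total-intensity values for one array.

    good: Normal(d_good_mean, d_good_sd) floored at 0; failed: Gamma with
    mean ``d_failed_mean`` (right-skewed); diverged: good-mode values
    with ``diverged_spike_fraction`` of probes replaced by a near-zero
    spike.
    """
    if mode == "good":
        return np.maximum(rng.normal(config.d_good_mean, config.d_good_sd, n), 0.0)
    if mode == "failed":
        scale = config.d_failed_mean / config.d_failed_shape
        return rng.gamma(config.d_failed_shape, scale, n)
    if mode == "diverged":
        d = np.maximum(rng.normal(config.d_good_mean, config.d_good_sd, n), 0.0)
        spike = rng.random(n) < config.diverged_spike_fraction
        d[spike] = np.abs(rng.normal(
            config.background_d_mean, config.background_d_sd, spike.sum()
        ))
        return d
    raise ValueError(f"unknown array mode: {mode!r}")


def simulate_intensities(
    panel: SimulatedPanel,
    modes: dict[str, str] | None = None,
    cnv_regions: dict[str, list[tuple[str, int, int, int]]] | None = None,
) -> IntensityMatrix:
    """Fabricate channel intensities consistent with the panel's calls.

    ``modes`` maps sample -> good/failed/diverged (default good);
    ``cnv_regions`` maps sample -> (chrom, start_bp, end_bp, copy)
    regions whose probes have d scaled by copy/2.  Failed-mode arrays
    additionally have a fraction of their calls set to N in the panel's
    genotype matrix (mirroring the high missingness of failed
    hybridizations).  The angle theta is centered at 0 / 0.5 / 1 for
    AA / AB / BB calls with Gaussian noise; no-calls get a diffuse angle.
    """
    config = panel.config
    modes = dict(modes or {})
    cnv_regions = cnv_regions or {}
    rng = np.random.default_rng(config.seed + 1)
    geno = panel.genotypes
    chrom_arr = panel.marker_chromosomes
    pos_arr = panel.marker_positions
    n_markers, n_samples = geno.calls.shape
    vino_rows = np.array(
        [i for i, m in enumerate(panel.manifest)
         if m.marker_id in set(panel.truth.vino_markers)],
        dtype=int,
    )
    x = np.empty((n_markers, n_samples))
    y = np.empty((n_markers, n_samples))
    for j, sid in enumerate(geno.samples):
        mode = modes.get(sid, "good")
        panel.truth.sample_mode[sid] = mode
        d = draw_d(mode, n_markers, config, rng)
        if mode == "failed":
            drop = rng.random(n_markers) < config.failed_missing_fraction
            geno.calls[drop, j] = Call.N
        if panel.truth.sample_sex.get(sid) == "F":
            yrows = chrom_arr == "Y"
            d[yrows] = np.abs(rng.normal(
                config.background_d_mean, config.background_d_sd, yrows.sum()
            ))
        elif panel.truth.sample_sex.get(sid) == "M":
            # hemizygous X: one copy, roughly half intensity
            d[chrom_arr == "X"] *= 0.5
        if len(vino_rows):
            carrier = geno.calls[vino_rows, j] == Call.BB
            rows = vino_rows[carrier]
            d[rows] = np.abs(rng.normal(
                config.background_d_mean, config.background_d_sd, len(rows)
            ))
            geno.calls[rows, j] = Call.N
        for chrom, start, end, copy in cnv_regions.get(sid, []):
            sel = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
            d[sel] *= copy / 2.0
        panel.truth.cnv_regions.setdefault(sid, []).extend(cnv_regions.get(sid, []))

        calls = geno.calls[:, j]
        theta = np.empty(n_markers)
        theta[calls == Call.AA] = np.abs(
            rng.normal(0.0, config.noise_sd, int((calls == Call.AA).sum()))
        )
        theta[calls == Call.AB] = rng.normal(
            0.5, config.noise_sd, int((calls == Call.AB).sum())
        )
        theta[calls == Call.BB] = 1.0 - np.abs(
            rng.normal(0.0, config.noise_sd, int((calls == Call.BB).sum()))
        )
        theta[calls == Call.N] = rng.random(int((calls == Call.N).sum()))
        theta = np.clip(theta, 0.0, 1.0)
        phi = theta * math.pi / 2.0
        x[:, j] = d * np.cos(phi)
        y[:, j] = d * np.sin(phi)
    return IntensityMatrix(
        markers=geno.markers, samples=geno.samples,
        x_raw=x * config.raw_scale, y_raw=y * config.raw_scale,
        x_norm=x, y_norm=y,
    )


def simulate_construct_intensities(
    samples: list[str],
    carriers: dict[str, set[str]],
    n_probes_per_target: int = 2,
    present_log10_mean: float = 3.5,
    absent_log10_mean: float = 2.5,
    log10_sd: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, dict[str, float | tuple]], dict[str, str], dict[str, str]]:
    """Raw construct-probe intensities for presence/absence calling.

    ``carriers`` maps target construct -> set of carrier sample ids.  The
    per-target log10 *sum* of informative-axis raw intensity is Normal
    with mean ``present_log10_mean`` for carriers and
    ``absent_log10_mean`` for non-carriers (a 1.0 log10 separation by
    default), spread ``log10_sd``.  Returns (raw, probe_targets,
    informative_axis) ready for
    :func:`mugakit.cluster.call_constructs`.
    """
    rng = np.random.default_rng(seed)
    probe_targets: dict[str, str] = {}
    informative_axis: dict[str, str] = {}
    raw: dict[str, dict[str, tuple[float, float]]] = {s: {} for s in samples}
    for target, who in carriers.items():
        probes = [f"{target}_p{i}" for i in range(n_probes_per_target)]
        for p in probes:
            probe_targets[p] = target
            informative_axis[p] = "x"
        for s in samples:
            mean = present_log10_mean if s in who else absent_log10_mean
            total = 10 ** rng.normal(mean, log10_sd)
            # split the target's total intensity evenly across its probes
            share = total / n_probes_per_target
            for p in probes:
                raw[s][p] = (share, float(np.abs(rng.normal(20.0, 5.0))))
    return raw, probe_targets, informative_axis
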